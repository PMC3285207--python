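# Methods

## Model and procedure

The pipeline identifies miRNA pairs whose co-expression is conserved
between two species and interprets them functionally.

**Preprocessing.** Each expression dataset is quantile-normalized on its
own (columns forced onto the vector of per-rank row means; ties receive the
mean of the tied reference quantiles). Probe-level rows are collapsed to
mature miRNAs: probes mapping to several miRNAs are ambiguous and dropped,
several probes for one miRNA are combined by the per-sample median. A
species' datasets are then restricted to the miRNAs present on every
platform and concatenated sample-wise. Normalization is applied per
dataset *before* probe collapse and intersection because the reference
distribution is a platform property. Expression values are taken as given
(no log policy is imposed); missing values must be resolved upstream —
the statistic definitions stay exact that way.

Note one consequence of tie-averaging: quantile normalization is exactly
idempotent only on tie-free columns. Ties are merged on the first pass, so
a second pass redistributes the reference over the merged values; this is
inherent to the averaging convention, not an implementation artifact.

**Orthology.** Pre-miRNA sequences extended by 11 bp flanks (the
Microprocessor cleaves ~11 bp into the lower stem, so flanks carry signal)
are compared all-against-all with a local aligner (match +1, mismatch −1,
gap open −2, gap extend −1; a length-L gap costs 2+(L−1)). Candidate pairs
are reciprocal best hits; a tied argmax disqualifies its row/column
(silent tie-breaking is irreproducible), and because disqualified
sequences stop competing, disqualification iterates to a fixpoint —
this keeps the procedure symmetric under swapping the species. Precursor
pairs expand to mature-arm pairs (arms matched by label) kept only when
the seeds (nucleotides 2–7, compared on the RNA alphabet) are identical;
duplicate mature assignments are resolved greedily by precursor alignment
score so the final map is 1:1. Pairs whose members lack expression are
flagged rather than dropped. Genomic coordinates are 1-based inclusive on
all input tables.

**Edge calling.** Per species, Pearson correlations over all miRNAs;
zero-variance rows are excluded from ranking with a logged warning and
propagate as missing. For each anchor, the other miRNAs are ranked by
correlation in *descending* order (this is a positive-co-expression
statistic; negative co-expression is out of scope) with average ranks for
ties and missing values ranked last; the rank ratio divides by the total
miRNA count N, so the best untied partner has ratio 1/N and no ratio
reaches 1. A pair is represented by the *minimum* of its two directional
ratios. For an orthologous pair this gives one ratio per species, and

    P(r) = Pr(U(1) <= r(1), ..., U(n) <= r(n)),   U_i iid Uniform(0,1)

is computed by the recursion V_0 = 1,
V_k = sum_{i=1..k} (−1)^(i−1) V_{k−i} r_(n−k+1)^i / i!, P = n!·V_n,
which the tests pin against the n = 2 closed form 2·r1·r2 − r1² (to 1e-12
on a 1000-point grid) and a 10⁶-draw Monte Carlo oracle for n = 3. Edges
are pairs with Bonferroni-corrected P < α over m = all scored ortholog
pairs; α defaults to 0.05.

### What the order-statistic p-value is, and is not

P(r) is a *joint CDF evaluated at the observed point*, not a probability
integral transform. Under the global null each species' pair ratio is
approximately Uniform(0,1), and the statistic W = 2UV − min(U,V)² then has
the distribution function (derived by integrating over {u < v})

    K(t) = 2[u0 − u0²/2 + (t/2)·ln(√t/u0) − (t − u0²)/4],  u0 = 1 − √(1−t),

which is markedly non-uniform mid-range (K(0.25) ≈ 0.46). The unit suite
verifies that the pipeline's null p_raw distribution matches K within 0.1
(sup-norm) while sitting far from uniform (KS > 0.15). Two practical
consequences:

* raw P values must not be read as calibrated tail probabilities in the
  moderate range;
* Bonferroni control still holds where it matters: validity at the extreme
  tail plus the granularity bound — the smallest achievable P is
  (1/N)², attained only at mutual rank 1 in both species — keep the
  family-wise error of the edge caller within its binomial band (measured
  0/200 null simulations at 100 miRNAs, 100 samples, 60 ortholog nodes).

A related limit: the statistic sees only ranks. A pair strongly
co-expressed in one species needs just one chance mutual-rank-1 event in
the other species (probability ≈ 1/(2N) per pair) to become
indistinguishable from a conserved pair. At α = 0.05 the Bonferroni budget
*allots* about 5% of datasets one such false edge; no choice of N or
ortholog count eliminates it while keeping true pairs detectable.

**Validation.** (i) Orthology permutation: members are redrawn uniformly
without replacement per species; the rank-ratio tables are map-independent,
so each rep only rescores pairs. (ii) Subsampling: a fraction (default
80%) of samples per species, pipeline rerun; overlap = |subsample edges ∩
full edges| / |subsample edges|, reps with empty subsample networks are
excluded from the mean and counted. (iii) ROC against a reference
expression set: positives are shared pairs with reference PCC ≥ τ
(τ ∈ {0.5, 0.7, 0.9}; |PCC| optionally), ranking score −p_raw, AUC by the
Mann–Whitney identity (equal to trapezoidal ROC integration; tested to
1e-10), significance by label permutation. All empirical p-values use the
plus-one convention (b+1)/(R+1) and are never zero.

**Pair characterization.** Genomic distance is the inter-interval gap
(0 on overlap/abutment, strand ignored, None across chromosomes); smaller
distances for co-expressed pairs are tested one-sided by Wilcoxon rank
sum. Cluster (10 kb), family and shared-TF flags are counted against
nulls of equally many distinct random pairs (universe: the network's
nodes, configurable). Target sets are optionally screened by TargetScan-
style context score ≤ −0.3 (more negative = stronger predicted
repression); per-pair overlaps use the hypergeometric upper tail with
BH-FDR across pairs; common targets are tested for GO-term enrichment at
p < 0.001. Expression-related genes are those with |PCC| > 0.5 against
the miRNA in a paired mRNA matrix; knockout/transfection-affected genes
exceed fold change 1.2, by default direction-agnostically
(max(FC, 1/FC) > 1.2, since knockout and overexpression flip the expected
direction; a strict ratio mode exists), unioned across cell lines. The
same-family/not-same-family reruns are a plain filter on the
characterization table — no separate code path.

**Disease sub-networks.** Causal-grade disease labels are mapped onto the
network; the count of edges with intersecting disease sets is tested by
(a) redrawing equally many distinct random pairs and (b) redrawing, per
disease, an equally sized set of miRNAs from the node universe — counts
taken over miRNAs *mapped* to the universe, so the null preserves each
disease's footprint on the network. Communities come from walktrap
(short-random-walk distances, agglomerative merging, cut at maximum
Newman–Girvan modularity) with walk length t = 4 by default; both are
config knobs, and isolated nodes are singletons. Sub-networks are
profiled by common targets: genes hit by ≥ k members, k defaulting to
⌈0.85 · members-with-targets⌉ (the "shared by nearly all members" rule),
with a family-collapsed variant that first intersects same-family members'
sets; enrichment is the plain hypergeometric upper tail at p < 0.001
(no conditional parent–child testing).

## Synthetic data: what it emulates, and what it does not

The generator produces the statistical structure the analysis assumes and
nothing else. Planted co-expressed pairs follow a latent-factor Gaussian
model: per pair and species, x = √λ·f + √(1−λ)·σ·ε with a shared factor f,
so the population correlation is λ/(λ + (1−λ)σ²) — equal to the latent
loading λ at σ = 1. (The loading is defined as a variance fraction
precisely so that λ = 0.9 yields correlation 0.9.) Conserved pairs carry
their factor in both species; single-species pairs in one only, existing
so tests can verify that conservation, not single-species correlation,
drives edge calls. Orthologous sequences are mutated copies (substitution
rate 0.05, hard-capped at 10% of sites) with protected seeds; annotation
plants cluster membership (50% of conserved pairs within 10 kb), shared
seeds/families (30%), shared TFs (50%), target-set Jaccard 0.5 for planted
vs ≈0.05 background (sets built constructively, so the planted overlap is
exact), causal disease labels covering one planted community, a GO term
equal to that community's common target core, fold-change tables where
targets exceed 1.2, and an mRNA matrix anti-correlated with each gene's
targeting miRNA. Not emulated: probe chemistry, batch/platform effects,
heavy-tailed expression, correlated backgrounds, miRNA biogenesis. Passing
tests therefore demonstrate correctness of the statistics and recovery
under the stated generative model — not performance on any real compendium.

## Problem sizes and defaults

Defaults: 300 miRNAs/species, 60 ortholog nodes, 60 samples/species, 20
planted conserved + 5 single-species pairs, λ = 0.9, σ = 1, 2000 genes,
3 communities. The sizing rule is the granularity inequality: edges exist
only if (1/N)² < α / C(K,2), i.e. K ≲ 0.31·N; at N = 300, K = 60 the
margin is ~2.5×. (At 100 miRNAs with ≥ 40 ortholog nodes no pair can ever
reach significance — worth checking before running any real study.) Sample
counts are desk-scale stand-ins for the hundreds of array samples a real
compendium supplies. Null-distribution reps default to 1000 in the library
and 200 in the demo bundle; permutation p-values then bottom out at
1/1001 and 1/201 respectively. The planted-partition community graph uses
p_in = 0.9, p_out = 0.02. The demo's community analysis runs on the
*derived* network, which under this generator is a perfect matching
(min-rank-ratio edges at Bonferroni granularity require mutual rank 1, so
node degrees are 1); multi-node community recovery is exercised on the
planted-partition graph, whose ground truth the generator also emits.

## Numerical conventions and degenerate inputs

Rank ties: average ranks everywhere (correlation ranking, quantile
normalization, AUC). Argmax ties in orthology: disqualification, not
tie-breaking. Zero-variance rows: excluded from ranking, NaN correlation.
Empty subsample networks: flagged, excluded from overlap means. α = 0:
valid, yields an empty network and downstream stages short-circuit.
P values are clipped to [0, 1]; the recursion is exact (no quadrature).
Coordinates: 1-based inclusive externally. All randomness flows from one
master seed (numpy SeedSequence children per generator stream; fixed
per-stage offsets in the pipeline so stages are independently
reproducible); fixed seed means byte-identical output files on rerun.

## Known limitations

Two-species only at the pipeline level (the p-value routine itself is
n-ary). Positive co-expression only. Raw order-statistic P values are not
calibrated (see above). Orthology quality depends on the local-alignment
score being a faithful similarity; paralog families with near-identical
precursors resolve by score, which on real genomes may need manual review.
Hypergeometric GO enrichment is unconditional; parent–child dependencies
between terms are not modeled.
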