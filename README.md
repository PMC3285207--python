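# comirnet

Conserved cross-species miRNA co-expression networks from paired
human/mouse expression compendia, with order-statistic edge calling,
permutation validation, functional characterization of co-expressed pairs,
and disease sub-network discovery.

## The problem

Single-miRNA knockouts rarely produce phenotypes: miRNAs act in groups,
co-regulating processes by targeting common transcripts. Co-expression
across many heterogeneous datasets is evidence of such functional
cooperation — and co-expression that is *conserved* between species is much
stronger evidence than co-expression in one species alone. `comirnet` is a
library (plus a thin CLI) for systems biologists who want to build and
interrogate such conserved co-expression networks, and to test whether
co-expressed miRNA pairs share genomic clusters, families, upstream
transcription factors, predicted targets, and disease associations.

## The statistic

For each species *s*, compute all pairwise Pearson correlations, rank every
miRNA against each anchor miRNA in descending correlation order, and divide
ranks by the miRNA count *N* to obtain rank ratios. A pair (A, B) is
represented by its minimum directional rank ratio
r<sub>s</sub> = min(rr(A→B), rr(B→A)). An orthologous pair observed in
*n* species yields (r<sub>1</sub>, …, r<sub>n</sub>), and the probability
of ratios jointly this small under independence is the joint CDF of
uniform order statistics

> P(r) = Pr(U<sub>(1)</sub> ≤ r<sub>(1)</sub>, …, U<sub>(n)</sub> ≤ r<sub>(n)</sub>),
> U<sub>i</sub> iid Uniform(0, 1),

computed by the standard recursion (for *n* = 2:
P = 2r<sub>1</sub>r<sub>2</sub> − r<sub>1</sub>², r<sub>1</sub> ≤ r<sub>2</sub>).
Edges are pairs whose Bonferroni-corrected P (over all scored ortholog
pairs) falls below α = 0.05. Orthology itself is derived from pre-miRNA
(+11 bp flank) sequences by reciprocal best local-alignment hits with
identical seed regions (nucleotides 2–7).

The network is validated by permuting the orthology map (edge-count null),
by 80% sample subsampling (edge overlap with the full network), and by ROC
against an independent reference expression set (AUC via the Mann–Whitney
identity). Pairs are characterized by genomic distance (Wilcoxon rank-sum
vs background), 10 kb cluster/family/TF sharing (random-pair nulls), and
hypergeometric target/expression-related/knockout-affected gene overlaps
with BH-FDR. Disease analysis counts edges whose endpoints share a causal
disease annotation (two permutation schemes), finds dense sub-networks with
walktrap (random-walk) community detection, and profiles each sub-network
by genes targeted by ≥ k members (optionally collapsing same-family members
first) with hypergeometric GO enrichment.

A synthetic-data module generates the full study — paired expression
matrices with planted conserved (and deliberately single-species) pairs
under a latent-factor Gaussian model, orthologous sequences, and an
annotation bundle with planted cluster/family/TF/target/disease structure —
so every claim is testable against known ground truth.

## Worked example

```python
from comirnet import (SyntheticConfig, generate_expression_pair,
                      pearson_matrix, rank_ratios, score_all_pairs,
                      build_network)

cfg = SyntheticConfig(seed=1)            # 300 miRNAs/species, 60 orthologs,
human, mouse, orthology, truth = generate_expression_pair(cfg)  # 20 planted pairs
t1 = rank_ratios(pearson_matrix(human), "human")
t2 = rank_ratios(pearson_matrix(mouse), "mouse")
net = build_network(score_all_pairs(t1, t2, orthology), alpha=0.05)
```

Running `python examples/01_build_network.py` prints:

```
scored pairs:     1770
network:          40 nodes, 20 edges
planted recall:   1.00
false edges:      0
```

All 20 planted conserved pairs — and nothing else — survive Bonferroni
correction over the 1770 scored ortholog pairs: each planted pair sits at
mutual rank 1 in both species (rank ratio 1/300 each side), giving
P = (1/300)² ≈ 1.1×10⁻⁵ < 0.05/1770. `examples/02–05` continue the same
study through validation (orthology-permutation p = 0.002, 100% subsample
overlap, AUC ≈ 0.999), pair characterization (10 same-cluster pairs vs
0.27 expected under random pairing, p = 0.002), and disease sub-networks
(7/20 edges share a disease; p ≤ 0.008 under both permutation schemes; the
planted GO term is the sub-network's top enrichment).

The same run is available from the shell:

```bash
comirnet simulate --outdir demo --seed 1
comirnet all --config demo/config.yaml    # or per stage: preprocess, ortho,
                                          # network, validate, annotate, subnets
```

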