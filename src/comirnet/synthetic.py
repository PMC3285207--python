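"""Synthetic two-species miRNA expression data with known ground truth.

The generator emulates the statistical structure the conserved
co-expression analysis assumes, without modeling array chemistry or miRNA
biogenesis:

* paired human/mouse expression matrices under a latent-factor Gaussian
  model — each planted co-expressed pair (i, j) shares, per species, a
  latent factor f, with rows ``sqrt(l)*f + sqrt(1-l)*sd*e``, so the
  population correlation of a planted pair is ``l / (l + (1-l)*sd^2)``
  (= the latent loading l when sd = 1);
* *conserved* pairs carry the factor in both species, *single-species*
  pairs in only one — the latter exist so tests can verify that cross-
  species conservation, not single-species correlation, drives edge calls;
* a 1:1 orthology map (human miRNA i <-> mouse miRNA i for the first
  ``n_orthologs`` indices) and pre-miRNA/mature sequences consistent with
  it (orthologs differ by at most 10% substitutions and share seeds);
* an annotation bundle whose planted pairs preferentially share 10 kb
  clusters, families (identical synthetic 6-mer seeds), upstream TFs and
  predicted targets, plus GO sets, causal disease labels concentrated in
  one planted community, knockout fold-change tables, and a paired mRNA
  matrix anti-correlated with its targeting miRNAs;
* a planted-partition community graph over the ortholog nodes, the ground
  truth for community-recovery checks.

Everything is deterministic for a fixed seed: each part draws from its own
child of one master ``numpy`` SeedSequence.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from .annotation import AnnotationBundle, CLUSTER_DISTANCE_BP
from .errors import ConfigurationError
from .expression import ExpressionMatrix
from .orthology import OrthologyMap

SPECIES1 = "human"
SPECIES2 = "mouse"

_BASES = np.array(list("ACGU"))


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic benchmark.

    Defaults are sized so that planted pairs are recoverable at Bonferroni
    alpha = 0.05: the smallest achievable order-statistic p is 1/N^2 (N =
    miRNAs per species), which must fall below alpha / C(K, 2) (K = ortholog
    nodes).  With N = 300 and K = 60 the margin is ~2.5x.  Sample counts are
    a desk-scale stand-in for the hundreds of array samples a real
    compendium provides.
    """

    n_mirnas_per_species: int = 300
    n_orthologs: int = 60
    n_samples_human: int = 60
    n_samples_mouse: int = 60
    n_planted_conserved: int = 20
    n_planted_single_species: int = 5
    latent_loading: float = 0.9
    noise_sd: float = 1.0
    n_genes: int = 2000
    planted_target_jaccard: float = 0.5
    background_target_jaccard: float = 0.05
    n_communities: int = 3
    seed: int = 0

    def __post_init__(self):
        pos = {
            "n_mirnas_per_species": self.n_mirnas_per_species,
            "n_samples_human": self.n_samples_human,
            "n_samples_mouse": self.n_samples_mouse,
            "n_orthologs": self.n_orthologs,
            "n_genes": self.n_genes,
        }
        for name, value in pos.items():
            if value < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {value}")
        if self.n_orthologs > self.n_mirnas_per_species:
            raise ConfigurationError(
                f"n_orthologs ({self.n_orthologs}) must not exceed "
                f"n_mirnas_per_species ({self.n_mirnas_per_species})"
            )
        if self.n_planted_conserved < 0 or self.n_planted_single_species < 0:
            raise ConfigurationError("planted pair counts must be >= 0")
        if 2 * self.n_planted_conserved + 2 * self.n_planted_single_species > self.n_orthologs:
            raise ConfigurationError(
                "2*n_planted_conserved + 2*n_planted_single_species "
                f"({2 * self.n_planted_conserved + 2 * self.n_planted_single_species}) "
                f"must not exceed n_orthologs ({self.n_orthologs})"
            )
        if not 0.0 < self.latent_loading <= 1.0:
            raise ConfigurationError(
                f"latent_loading must lie in (0, 1], got {self.latent_loading}"
            )
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be positive, got {self.noise_sd}")
        for name in ("planted_target_jaccard", "background_target_jaccard"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.n_communities < 0:
            raise ConfigurationError("n_communities must be >= 0")

    # -- identifiers ------------------------------------------------------
    def human_ids(self) -> list[str]:
        return [f"hsa-miR-{i:04d}" for i in range(self.n_mirnas_per_species)]

    def mouse_ids(self) -> list[str]:
        return [f"mmu-miR-{i:04d}" for i in range(self.n_mirnas_per_species)]

    def ortholog_pairs(self) -> list[tuple[str, str]]:
        h, m = self.human_ids(), self.mouse_ids()
        return [(h[i], m[i]) for i in range(self.n_orthologs)]

    def _streams(self) -> dict[str, np.random.Generator]:
        names = [
            "expression", "reference", "locations", "families", "tf", "targets",
            "go", "disease", "fc", "mrna", "sequences", "community",
        ]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass(frozen=True)
class GroundTruth:
    """What was planted, in species1 (human) node labels."""

    conserved_pairs: frozenset[tuple[str, str]]
    single_species_pairs: tuple[tuple[tuple[str, str], str], ...]
    community_assignment: dict[str, int] = field(default_factory=dict)
    disease_community: int | None = None

    def planted_nodes(self) -> set[str]:
        out = {n for p in self.conserved_pairs for n in p}
        out |= {n for (p, _) in self.single_species_pairs for n in p}
        return out


def _planted_layout(config: SyntheticConfig) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Ortholog indices used for planted pairs: conserved pairs first, then
    single-species pairs, in consecutive blocks (rows are exchangeable, so
    randomizing positions would add nothing)."""
    conserved = [(2 * t, 2 * t + 1) for t in range(config.n_planted_conserved)]
    base = 2 * config.n_planted_conserved
    single = [
        (base + 2 * t, base + 2 * t + 1) for t in range(config.n_planted_single_species)
    ]
    return conserved, single


def _plant(
    x: np.ndarray, pairs: list[tuple[int, int]], loading: float, noise_sd: float,
    rng: np.random.Generator,
) -> None:
    n_samples = x.shape[1]
    a = math.sqrt(loading)
    b = math.sqrt(1.0 - loading) * noise_sd
    for i, j in pairs:
        f = rng.standard_normal(n_samples)
        x[i] = a * f + b * rng.standard_normal(n_samples)
        x[j] = a * f + b * rng.standard_normal(n_samples)


def generate_expression_pair(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, OrthologyMap, GroundTruth]:
    """Paired two-species expression with planted co-expression.

    Returns (human matrix, mouse matrix, orthology map, ground truth); the
    ground truth also carries a community assignment over the ortholog nodes
    (pairs kept within one community) and the label of the disease-enriched
    community.
    """
    rng = config._streams()["expression"]
    n, sh, sm = config.n_mirnas_per_species, config.n_samples_human, config.n_samples_mouse
    xh = config.noise_sd * rng.standard_normal((n, sh))
    xm = config.noise_sd * rng.standard_normal((n, sm))
    conserved_idx, single_idx = _planted_layout(config)
    _plant(xh, conserved_idx, config.latent_loading, config.noise_sd, rng)
    _plant(xm, conserved_idx, config.latent_loading, config.noise_sd, rng)
    # single-species pairs alternate between the two species
    single_h = [p for t, p in enumerate(single_idx) if t % 2 == 0]
    single_m = [p for t, p in enumerate(single_idx) if t % 2 == 1]
    _plant(xh, single_h, config.latent_loading, config.noise_sd, rng)
    _plant(xm, single_m, config.latent_loading, config.noise_sd, rng)

    hids, mids = config.human_ids(), config.mouse_ids()
    human = ExpressionMatrix(
        pd.DataFrame(xh, index=hids, columns=[f"hs{j:03d}" for j in range(sh)]),
        species=SPECIES1, dataset_id="synthetic",
    )
    mouse = ExpressionMatrix(
        pd.DataFrame(xm, index=mids, columns=[f"mm{j:03d}" for j in range(sm)]),
        species=SPECIES2, dataset_id="synthetic",
    )
    orthology = OrthologyMap(pairs=config.ortholog_pairs())

    conserved = frozenset(tuple(sorted((hids[i], hids[j]))) for i, j in conserved_idx)
    singles = []
    for t, (i, j) in enumerate(single_idx):
        species = SPECIES1 if t % 2 == 0 else SPECIES2
        singles.append((tuple(sorted((hids[i], hids[j]))), species))

    assignment: dict[str, int] = {}
    if config.n_communities > 0:
        ortho_nodes = [hids[i] for i in range(config.n_orthologs)]
        pair_blocks = conserved_idx + single_idx
        paired_nodes = []
        for t, (i, j) in enumerate(pair_blocks):
            c = t % config.n_communities
            assignment[hids[i]] = c
            assignment[hids[j]] = c
            paired_nodes += [hids[i], hids[j]]
        rest = [nd for nd in ortho_nodes if nd not in assignment]
        for t, nd in enumerate(rest):
            assignment[nd] = t % config.n_communities
    truth = GroundTruth(
        conserved_pairs=conserved,
        single_species_pairs=tuple(singles),
        community_assignment=assignment,
        disease_community=0 if config.n_communities > 0 else None,
    )
    return human, mouse, orthology, truth


def generate_reference_matrix(
    config: SyntheticConfig, truth: GroundTruth, n_samples: int = 40
) -> ExpressionMatrix:
    """An independent human expression set with the same planted structure,
    standing in for a validation platform (e.g. PCR-based)."""
    rng = config._streams()["reference"]
    n = config.n_mirnas_per_species
    x = config.noise_sd * rng.standard_normal((n, n_samples))
    hids = config.human_ids()
    index = {h: i for i, h in enumerate(hids)}
    pairs = [tuple(index[m] for m in p) for p in sorted(truth.conserved_pairs)]
    pairs += [
        tuple(index[m] for m in p)
        for (p, sp) in truth.single_species_pairs
        if sp == SPECIES1
    ]
    _plant(x, pairs, config.latent_loading, config.noise_sd, rng)
    return ExpressionMatrix(
        pd.DataFrame(x, index=hids, columns=[f"ref{j:03d}" for j in range(n_samples)]),
        species=SPECIES1, dataset_id="reference",
    )


def generate_community_network(
    config: SyntheticConfig,
    truth: GroundTruth,
    p_in: float = 0.9,
    p_out: float = 0.02,
) -> nx.Graph:
    """Planted-partition graph over the ortholog nodes.

    Within-community edges appear with probability ``p_in``, between-
    community edges with ``p_out``; the ground-truth partition is
    ``truth.community_assignment``.
    """
    if not truth.community_assignment:
        raise ConfigurationError("ground truth has no community assignment (n_communities=0)")
    rng = config._streams()["community"]
    nodes = sorted(truth.community_assignment)
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            same = truth.community_assignment[a] == truth.community_assignment[b]
            if rng.random() < (p_in if same else p_out):
                g.add_edge(a, b)
    return g


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def _shared_seed_strings(config: SyntheticConfig, family_fraction: float) -> dict[str, str]:
    """One 6-mer seed per human miRNA; the first ``family_fraction`` of
    planted conserved pairs share a seed (same family)."""
    rng = config._streams()["families"]
    hids = config.human_ids()
    seeds = {
        h: "".join(rng.choice(_BASES, size=6)) for h in hids
    }
    conserved_idx, _ = _planted_layout(config)
    n_fam = math.ceil(family_fraction * len(conserved_idx))
    for i, j in conserved_idx[:n_fam]:
        seeds[hids[j]] = seeds[hids[i]]
    return seeds


def _clusters_from_locations(
    locations: dict[str, tuple[str, int, int, str]], threshold: int = CLUSTER_DISTANCE_BP
) -> dict[str, str]:
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for mir, (chrom, start, end, _) in locations.items():
        by_chrom.setdefault(chrom, []).append((start, end, mir))
    clusters: dict[str, str] = {}
    cluster_id = 0
    for chrom in sorted(by_chrom):
        entries = sorted(by_chrom[chrom])
        current: list[str] = []
        last_end = None
        for start, end, mir in entries:
            if last_end is not None and start - last_end - 1 >= threshold:
                for m in current:
                    clusters[m] = f"clu{cluster_id:04d}"
                cluster_id += 1
                current = []
            current.append(mir)
            last_end = max(last_end or end, end)
        for m in current:
            clusters[m] = f"clu{cluster_id:04d}"
        cluster_id += 1
    return clusters


def _jaccard_shared_count(k: int, jaccard: float) -> int:
    # |A∩B| = s for equal set sizes k: J = s / (2k - s)  =>  s = 2kJ/(1+J)
    return int(round(2 * k * jaccard / (1 + jaccard))) if jaccard > 0 else 0


def generate_annotations(
    config: SyntheticConfig,
    truth: GroundTruth,
    cluster_fraction: float = 0.5,
    family_fraction: float = 0.3,
    tf_fraction: float = 0.5,
    target_set_size: int = 100,
    disease_core_size: int = 30,
    n_go_terms: int = 20,
    n_tfs: int = 20,
) -> AnnotationBundle:
    """Annotation bundle whose planted pairs preferentially share clusters,
    families, TFs, targets and diseases.

    Raises a configuration error when the requested target Jaccard levels
    cannot be realized within the gene universe.
    """
    streams = config._streams()
    hids = config.human_ids()
    index = {h: i for i, h in enumerate(hids)}
    conserved_idx, _ = _planted_layout(config)
    genes = [f"g{i:05d}" for i in range(config.n_genes)]

    # -- genomic locations -------------------------------------------------
    rng = streams["locations"]
    locations: dict[str, tuple[str, int, int, str]] = {}
    n_clustered = math.ceil(cluster_fraction * len(conserved_idx))
    region = 0
    for t, (i, j) in enumerate(conserved_idx):
        chrom = f"chr{region % 20 + 1}"
        base = 1 + (region // 20) * 3_000_000
        region += 1
        if t < n_clustered:
            gap = int(rng.integers(100, 9000))
            locations[hids[i]] = (chrom, base, base + 79, "+")
            locations[hids[j]] = (chrom, base + 80 + gap, base + 159 + gap, "+")
        else:
            locations[hids[i]] = (chrom, base, base + 79, "+")
            chrom2 = f"chr{region % 20 + 1}"
            base2 = 1 + (region // 20) * 3_000_000
            region += 1
            locations[hids[j]] = (chrom2, base2, base2 + 79, "+")
    for h in hids:
        if h not in locations:
            chrom = f"chr{region % 20 + 1}"
            base = 1 + (region // 20) * 3_000_000
            region += 1
            locations[h] = (chrom, base, base + 79, "+")
    clusters = _clusters_from_locations(locations)

    families_seeds = _shared_seed_strings(config, family_fraction)
    families = dict(families_seeds)  # family ID = the seed 6-mer

    # -- TF edges ----------------------------------------------------------
    rng = streams["tf"]
    tfs = [f"TF{i:02d}" for i in range(n_tfs)]
    tf_edges: set[tuple[str, str]] = set()
    n_tf_pairs = math.ceil(tf_fraction * len(conserved_idx))
    for t, (i, j) in enumerate(conserved_idx[:n_tf_pairs]):
        tf = tfs[t % n_tfs]
        tf_edges.add((tf, hids[i]))
        tf_edges.add((tf, hids[j]))
    for h in hids:
        for _ in range(rng.poisson(0.5)):
            tf_edges.add((str(rng.choice(tfs)), h))

    # -- target sets -------------------------------------------------------
    rng = streams["targets"]
    k = target_set_size
    if k > config.n_genes:
        raise ConfigurationError(
            f"target_set_size ({k}) exceeds the gene universe ({config.n_genes})"
        )
    bj = config.background_target_jaccard
    if bj > 0:
        pool_size = min(config.n_genes, int(round(k * (1 + bj) / (2 * bj))))
        if pool_size < k:
            raise ConfigurationError(
                f"background_target_jaccard={bj} unreachable: needs a pool of "
                f">= {k} genes, universe allows {pool_size}"
            )
        pool = np.array(genes[:pool_size], dtype=object)
        target_sets = {h: set(rng.choice(pool, size=k, replace=False)) for h in hids}
    else:
        if k * len(hids) > config.n_genes:
            raise ConfigurationError(
                "background_target_jaccard=0 needs disjoint sets: "
                f"{k}*{len(hids)} genes required, universe has {config.n_genes}"
            )
        pool = np.array(genes, dtype=object)
        target_sets = {
            h: set(genes[t * k : (t + 1) * k]) for t, h in enumerate(hids)
        }

    disease_nodes = {
        node
        for node, c in truth.community_assignment.items()
        if truth.disease_community is not None and c == truth.disease_community
    }
    core = set(genes[-disease_core_size:])  # kept out of the background pool
    for node in disease_nodes:
        extra = [g for g in target_sets[node] if g not in core]
        target_sets[node] = core | set(extra[: k - len(core)])

    s_target = _jaccard_shared_count(k, config.planted_target_jaccard)
    if s_target > k:
        raise ConfigurationError("planted_target_jaccard unreachable for equal set sizes")
    for i, j in conserved_idx:
        a, b = hids[i], hids[j]
        set_a = sorted(target_sets[a])
        must_share = sorted(core & set(set_a)) if b in disease_nodes else []
        shareable = [g for g in set_a if g not in must_share]
        shared = set(must_share) | set(shareable[: max(0, s_target - len(must_share))])
        fresh_pool = [g for g in pool if g not in set(set_a)]
        need = k - len(shared)
        if need > len(fresh_pool):
            raise ConfigurationError(
                f"planted_target_jaccard={config.planted_target_jaccard} unreachable: "
                f"not enough genes outside {a}'s set"
            )
        fresh = rng.choice(np.array(fresh_pool, dtype=object), size=need, replace=False)
        target_sets[b] = shared | set(fresh)

    target_scores = {
        h: {g: float(rng.uniform(-0.6, -0.05)) for g in sorted(target_sets[h])}
        for h in hids
    }

    # -- GO sets -----------------------------------------------------------
    rng = streams["go"]
    go_sets: dict[str, set[str]] = {}
    if disease_nodes:
        go_sets["GO:SYN0000"] = set(core)
    universe_arr = np.array(genes, dtype=object)
    for t in range(1, n_go_terms):
        go_sets[f"GO:SYN{t:04d}"] = set(rng.choice(universe_arr, size=50, replace=False))

    # -- disease labels ----------------------------------------------------
    rng = streams["disease"]
    disease: dict[str, set[str]] = {}
    for node in sorted(disease_nodes):
        disease.setdefault(node, set()).add("synthetic_carcinoma")
    scatter = rng.choice(np.array(hids[: config.n_orthologs], dtype=object),
                         size=min(5, config.n_orthologs), replace=False)
    for node in scatter:
        disease.setdefault(str(node), set()).add("synthetic_glioma")

    # -- knockout / transfection fold changes ------------------------------
    rng = streams["fc"]
    fc_tables: dict[str, dict[str, dict[str, float]]] = {}
    for h in hids[: config.n_orthologs]:
        table: dict[str, dict[str, float]] = {}
        non_targets = rng.choice(universe_arr, size=min(300, config.n_genes), replace=False)
        for cell in ("cellA", "cellB"):
            fc: dict[str, float] = {}
            for g in sorted(target_sets[h]):
                fc[g] = float(rng.uniform(1.3, 2.5))
            for g in non_targets:
                if g not in fc:
                    fc[str(g)] = float(np.exp(rng.uniform(-0.1, 0.1)))
            table[cell] = fc
        fc_tables[h] = table

    # -- paired mRNA matrix ------------------------------------------------
    rng = streams["mrna"]
    human, _, _, _ = generate_expression_pair(config)
    xh = human.values.to_numpy()
    driver_of: dict[str, int] = {}
    for h in hids:
        for g in target_sets[h]:
            driver_of.setdefault(g, index[h])
    mrna = rng.standard_normal((config.n_genes, config.n_samples_human))
    for gi, g in enumerate(genes):
        if g in driver_of:
            row = xh[driver_of[g]]
            z = (row - row.mean()) / (row.std() or 1.0)
            mrna[gi] = -0.8 * z + 0.6 * rng.standard_normal(config.n_samples_human)
    mrna_expr = ExpressionMatrix(
        pd.DataFrame(mrna, index=genes, columns=human.sample_ids),
        species=SPECIES1, dataset_id="synthetic-mrna",
    )

    return AnnotationBundle(
        locations=locations,
        clusters=clusters,
        families=families,
        tf_edges=tf_edges,
        target_sets=target_sets,
        target_scores=target_scores,
        go_sets=go_sets,
        disease=disease,
        fc_tables=fc_tables,
        mrna_expr=mrna_expr,
        gene_universe=genes,
    )


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------

class SpeciesSequences(NamedTuple):
    precursors: dict[str, str]       # precursor ID -> pre-miRNA (+flanks)
    matures: dict[str, str]          # mature ID -> 22-nt sequence
    precursor_to_mature: dict[str, list[tuple[str, str | None]]]


def _mutate(
    seq: str, rate: float, rng: np.random.Generator, protected: set[int] = frozenset()
) -> str:
    """Substitute bases at ~``rate`` per site, capped at 10% of the length,
    never touching ``protected`` positions."""
    chars = list(seq)
    candidates = [i for i in range(len(chars)) if i not in protected]
    n_sub = min(rng.binomial(len(candidates), rate), len(seq) // 10)
    if n_sub == 0:
        return seq
    sites = rng.choice(len(candidates), size=n_sub, replace=False)
    for s in sites:
        i = candidates[int(s)]
        options = [b for b in "ACGU" if b != chars[i]]
        chars[i] = options[int(rng.integers(0, 3))]
    return "".join(chars)


def generate_sequences(
    config: SyntheticConfig,
    truth: GroundTruth,
    mutation_rate: float = 0.05,
    family_fraction: float = 0.3,
) -> tuple[SpeciesSequences, SpeciesSequences]:
    """Pre-miRNA(+flank) and mature sequences for both species.

    Orthologous precursors differ by at most 10% substitutions and their
    mature seeds (positions 2-7) are identical; non-orthologous mouse
    sequences are random.  The seed strings agree with the family annotation
    produced by :func:`generate_annotations` under the same config.
    """
    if not 0.0 <= mutation_rate <= 0.1:
        raise ConfigurationError("mutation_rate must lie in [0, 0.1]")
    rng = config._streams()["sequences"]
    seeds = _shared_seed_strings(config, family_fraction)
    hids, mids = config.human_ids(), config.mouse_ids()

    def random_seq(length: int) -> str:
        return "".join(rng.choice(_BASES, size=length))

    h_prec: dict[str, str] = {}
    h_mat: dict[str, str] = {}
    h_map: dict[str, list[tuple[str, str | None]]] = {}
    m_prec: dict[str, str] = {}
    m_mat: dict[str, str] = {}
    m_map: dict[str, list[tuple[str, str | None]]] = {}

    mature_offset = 11 + 20  # flank + 5' arm padding

    for i, h in enumerate(hids):
        mature = random_seq(1) + seeds[h] + random_seq(15)  # 22 nt, seed at 2-7
        prec = random_seq(mature_offset) + mature + random_seq(31)
        prec_id = h.replace("miR", "mir")
        h_prec[prec_id] = prec
        h_mat[h] = mature
        h_map[prec_id] = [(h, "5p")]
        m = mids[i]
        m_prec_id = m.replace("miR", "mir")
        if i < config.n_orthologs:
            protected = set(range(mature_offset + 1, mature_offset + 7))
            prec_m = _mutate(prec, mutation_rate, rng, protected)
            mature_m = prec_m[mature_offset : mature_offset + 22]
            m_prec[m_prec_id] = prec_m
            m_mat[m] = mature_m
        else:
            mature_m = random_seq(22)
            m_prec[m_prec_id] = random_seq(mature_offset) + mature_m + random_seq(31)
            m_mat[m] = mature_m
        m_map[m_prec_id] = [(m, "5p")]

    return (
        SpeciesSequences(h_prec, h_mat, h_map),
        SpeciesSequences(m_prec, m_mat, m_map),
    )
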