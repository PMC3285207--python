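"""Characterization of co-expressed miRNA pairs.

Co-expressed pairs are profiled against genomic and functional annotation:
genomic distance (close pairs are typically co-transcribed from one
cluster), shared 10 kb clusters, shared families (identical seeds), shared
transcription factors, and overlap of predicted target sets,
expression-related genes and knockout/transfection-affected genes.  Each
count is compared against a random-pair null, and gene-set overlaps use the
hypergeometric upper tail with Benjamini-Hochberg correction across pairs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DataError, LookupFailure
from .expression import ExpressionMatrix
from .significance import NullDistribution

log = logging.getLogger(__name__)

CLUSTER_DISTANCE_BP = 10_000  # miRNAs within 10 kb form a cluster


@dataclass
class AnnotationBundle:
    """Everything known about the miRNAs beyond expression.

    locations are 1-based inclusive (chrom, start, end, strand); clusters
    and families map miRNA -> label; tf_edges is a set of (TF, miRNA);
    target_sets/go_sets map to gene sets over ``gene_universe``;
    target_scores optionally holds per-gene context scores (more negative =
    stronger predicted repression); disease maps miRNA -> set of disease
    labels ('causal'-grade only); fc_tables maps miRNA -> cell line ->
    gene -> fold change; mrna_expr is a paired mRNA matrix.
    """

    locations: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)
    clusters: dict[str, str] = field(default_factory=dict)
    families: dict[str, str] = field(default_factory=dict)
    tf_edges: set[tuple[str, str]] = field(default_factory=set)
    target_sets: dict[str, set[str]] = field(default_factory=dict)
    target_scores: dict[str, dict[str, float]] = field(default_factory=dict)
    go_sets: dict[str, set[str]] = field(default_factory=dict)
    disease: dict[str, set[str]] = field(default_factory=dict)
    fc_tables: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    mrna_expr: ExpressionMatrix | None = None
    gene_universe: list[str] = field(default_factory=list)

    def tf_sets(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for tf, mir in self.tf_edges:
            out.setdefault(mir, set()).add(tf)
        return out


@dataclass
class OverlapResult:
    k: int   # overlap
    K: int   # |set_a|
    n: int   # |set_b|
    N: int   # universe size
    p: float

    def as_tuple(self):
        return (self.k, self.K, self.n, self.N, self.p)


def genomic_distance(
    a: str, b: str, locations: Mapping[str, tuple[str, int, int, str]]
) -> int | None:
    """Gap in bp between two miRNA loci; 0 when they overlap or abut, None
    when on different chromosomes.  Strand is ignored."""
    try:
        ca, sa, ea, _ = locations[a]
        cb, sb, eb, _ = locations[b]
    except KeyError as exc:
        raise LookupFailure(f"no genomic location for {exc.args[0]!r}") from exc
    if ca != cb:
        return None
    if sa > sb:
        sa, ea, sb, eb = sb, eb, sa, ea
    return max(0, sb - ea - 1)


def distance_test(
    coexpr_distances: Sequence[float], background_distances: Sequence[float]
) -> float:
    """One-sided Wilcoxon rank-sum p that co-expressed pairs are closer."""
    if len(coexpr_distances) == 0 or len(background_distances) == 0:
        raise DataError("both distance samples must be nonempty")
    return float(
        mannwhitneyu(coexpr_distances, background_distances, alternative="less").pvalue
    )


def pair_flags(pair: tuple[str, str], bundle: AnnotationBundle) -> tuple[bool, bool, bool]:
    """(same_cluster, same_family, shared_tf); missing annotation means no."""
    a, b = pair
    same_cluster = (
        a in bundle.clusters and b in bundle.clusters
        and bundle.clusters[a] == bundle.clusters[b]
    )
    same_family = (
        a in bundle.families and b in bundle.families
        and bundle.families[a] == bundle.families[b]
    )
    tfs = bundle.tf_sets()
    shared_tf = bool(tfs.get(a, set()) & tfs.get(b, set()))
    return same_cluster, same_family, shared_tf


def _decode_pair(code: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    # unordered pair index -> (i, j), i < j, under lexicographic enumeration
    counts = np.arange(n - 1, 0, -1)
    starts = np.concatenate(([0], np.cumsum(counts)))
    i = np.searchsorted(starts, code, side="right") - 1
    j = code - starts[i] + i + 1
    return i, j


def sample_pairs(
    universe: Sequence[str], n_pairs: int, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """``n_pairs`` distinct unordered pairs without self-pairs."""
    n = len(universe)
    total = n * (n - 1) // 2
    if n < 2:
        raise ConfigurationError("pair universe must contain at least 2 miRNAs")
    if n_pairs > total:
        raise ConfigurationError(f"cannot draw {n_pairs} distinct pairs from C({n},2)={total}")
    codes = rng.choice(total, size=n_pairs, replace=False)
    i, j = _decode_pair(codes, n)
    return [(universe[a], universe[b]) for a, b in zip(i, j)]


def random_pair_null(
    universe: Sequence[str],
    n_pairs: int,
    reps: int,
    statistic: Callable[[tuple[str, str]], bool],
    seed: int = 0,
    observed_pairs: Iterable[tuple[str, str]] | None = None,
) -> NullDistribution:
    """Null of 'how many of n random distinct pairs satisfy the predicate'.

    When ``observed_pairs`` is given the observed statistic is the predicate
    count over those pairs; otherwise NaN (caller supplies it later).
    """
    if reps < 1:
        raise ConfigurationError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    samples = np.empty(reps)
    for r in range(reps):
        pairs = sample_pairs(universe, n_pairs, rng)
        samples[r] = sum(1 for p in pairs if statistic(p))
    observed = (
        float(sum(1 for p in observed_pairs if statistic(p)))
        if observed_pairs is not None
        else float("nan")
    )
    return NullDistribution("pair_predicate_count", samples, observed)


def filter_targets(
    target_sets: Mapping[str, set[str]],
    context_scores: Mapping[str, Mapping[str, float]] | None = None,
    context_cutoff: float | None = -0.3,
) -> dict[str, set[str]]:
    """Screen targets by context score (<= cutoff; more negative = stronger).

    ``context_cutoff=None`` disables filtering (sub-network analyses use the
    unfiltered sets).
    """
    if context_cutoff is None:
        return {m: set(s) for m, s in target_sets.items()}
    if context_scores is None:
        raise ConfigurationError("context_cutoff given but no context scores available")
    out: dict[str, set[str]] = {}
    for mir, genes in target_sets.items():
        scores = context_scores.get(mir, {})
        missing = [g for g in genes if g not in scores]
        if missing:
            raise ConfigurationError(
                f"context_cutoff given but {mir!r} lacks scores for e.g. {missing[:3]}"
            )
        kept = {g for g in genes if scores[g] <= context_cutoff}
        if not kept:
            log.warning("all targets of %s filtered out at cutoff %s", mir, context_cutoff)
        out[mir] = kept
    return out


def overlap_test(set_a: set, set_b: set, universe_size: int) -> OverlapResult:
    """Upper-tail hypergeometric test of |A ∩ B|.

    p = Pr(X >= k) for X ~ Hypergeom(N=universe, K=|A|, n=|B|).
    """
    K, n = len(set_a), len(set_b)
    if K > universe_size or n > universe_size:
        raise DataError(
            f"set sizes ({K}, {n}) exceed the declared universe ({universe_size})"
        )
    k = len(set_a & set_b)
    p = float(hypergeom.sf(k - 1, universe_size, K, n))
    return OverlapResult(k=k, K=K, n=n, N=universe_size, p=min(1.0, p))


def fdr_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def expression_related_genes(
    mirna_row: pd.Series, mrna_expr: ExpressionMatrix, pcc_cutoff: float = 0.5
) -> set[str]:
    """Genes whose expression tracks the miRNA: |PCC| > cutoff over matched
    samples."""
    if list(mirna_row.index) != mrna_expr.sample_ids:
        if set(mirna_row.index) != set(mrna_expr.sample_ids):
            raise DataError("miRNA and mRNA matrices cover different samples")
        mirna_row = mirna_row.loc[mrna_expr.sample_ids]
    x = mirna_row.to_numpy(dtype=float)
    if x.std() == 0:
        return set()
    g = mrna_expr.values.to_numpy(dtype=float)
    gx = g - g.mean(axis=1, keepdims=True)
    xx = x - x.mean()
    denom = np.sqrt((gx**2).sum(axis=1) * (xx**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = gx @ xx / denom
    hits = np.abs(r) > pcc_cutoff
    return {g for g, h in zip(mrna_expr.feature_ids, hits) if h}


def affected_genes(
    fc_table: Mapping[str, Mapping[str, float]],
    fc_cutoff: float = 1.2,
    direction_agnostic: bool = True,
) -> set[str]:
    """Genes changed beyond the fold-change cutoff after knockout or
    transfection of a miRNA, unioned across cell lines.

    Direction-agnostic by default (max(FC, 1/FC) > cutoff), because knockout
    and transfection flip the expected direction; set
    ``direction_agnostic=False`` to require the reported ratio itself to
    exceed the cutoff.
    """
    out: set[str] = set()
    for cell, genes in fc_table.items():
        for gene, fc in genes.items():
            if fc <= 0:
                raise DataError(f"nonpositive fold change {fc} for {gene!r} in {cell!r}")
            eff = max(fc, 1.0 / fc) if direction_agnostic else fc
            if eff > fc_cutoff:
                out.add(gene)
    return out


def pair_coherence(
    common_genes: set[str],
    go_sets: Mapping[str, set[str]],
    universe_size: int,
    p_cutoff: float = 0.001,
) -> list[tuple[str, float]]:
    """GO terms enriched (hypergeometric upper tail, p < cutoff) in a pair's
    common genes."""
    if not common_genes:
        return []
    hits = []
    for term, genes in go_sets.items():
        res = overlap_test(common_genes, set(genes), universe_size)
        if res.k >= 1 and res.p < p_cutoff:
            hits.append((term, res.p))
    return sorted(hits, key=lambda t: t[1])


def characterize_pairs(
    pairs: Sequence[tuple[str, str]],
    bundle: AnnotationBundle,
    mirna_expr: ExpressionMatrix | None = None,
    context_cutoff: float | None = -0.3,
    pcc_cutoff: float = 0.5,
    fc_cutoff: float = 1.2,
    go_p_cutoff: float = 0.001,
) -> pd.DataFrame:
    """Full per-pair characterization table (one row per co-expressed pair).

    Target overlaps use context-filtered sets and are BH-corrected across
    pairs; expression-related and affected-gene overlaps are computed when
    the pair has the required data, else left missing.
    """
    targets = (
        filter_targets(bundle.target_sets, bundle.target_scores, context_cutoff)
        if bundle.target_sets
        else {}
    )
    n_universe = len(bundle.gene_universe)
    mrna_genes = set(bundle.mrna_expr.feature_ids) if bundle.mrna_expr is not None else set()
    expr_cache: dict[str, set[str]] = {}
    rows = []
    for a, b in pairs:
        same_cluster, same_family, shared_tf = pair_flags((a, b), bundle)
        dist = (
            genomic_distance(a, b, bundle.locations)
            if a in bundle.locations and b in bundle.locations
            else None
        )
        row: dict = {
            "mirna_a": a,
            "mirna_b": b,
            "distance_bp": dist,
            "same_cluster": same_cluster,
            "same_family": same_family,
            "shared_tf": shared_tf,
        }
        if a in targets and b in targets and n_universe:
            res = overlap_test(targets[a], targets[b], n_universe)
            row.update(
                target_overlap_k=res.k, target_overlap_p=res.p,
                target_size_a=res.K, target_size_b=res.n,
            )
            common = targets[a] & targets[b]
            terms = pair_coherence(common, bundle.go_sets, n_universe, go_p_cutoff)
            row["coherent_processes"] = ";".join(t for t, _ in terms)
            row["n_coherent_processes"] = len(terms)
        if (
            bundle.mrna_expr is not None
            and mirna_expr is not None
            and a in mirna_expr.values.index
            and b in mirna_expr.values.index
        ):
            for mir in (a, b):
                if mir not in expr_cache:
                    expr_cache[mir] = expression_related_genes(
                        mirna_expr.values.loc[mir], bundle.mrna_expr, pcc_cutoff
                    )
            res = overlap_test(expr_cache[a], expr_cache[b], len(mrna_genes))
            row.update(expr_related_overlap_k=res.k, expr_related_overlap_p=res.p)
        if a in bundle.fc_tables and b in bundle.fc_tables and n_universe:
            aff_a = affected_genes(bundle.fc_tables[a], fc_cutoff)
            aff_b = affected_genes(bundle.fc_tables[b], fc_cutoff)
            res = overlap_test(aff_a, aff_b, n_universe)
            row.update(affected_overlap_k=res.k, affected_overlap_p=res.p)
        rows.append(row)
    out = pd.DataFrame(rows)
    if "target_overlap_p" in out.columns:
        mask = out["target_overlap_p"].notna()
        q = np.full(len(out), np.nan)
        q[mask.to_numpy()] = fdr_adjust(out.loc[mask, "target_overlap_p"].to_numpy())
        out["target_overlap_q"] = q
    return out
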