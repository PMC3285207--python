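"""Validation of the network: permutation nulls, subsampling, ROC.

Three complementary checks mirror standard practice for co-expression
networks: (i) permuting the orthology map destroys cross-species
correspondence, so the observed edge count should exceed the permuted
counts; (ii) rebuilding the network from random 80% sample subsets measures
robustness to sample heterogeneity; (iii) ranking scored pairs against an
independent reference expression set yields ROC curves whose AUC quantifies
agreement with reference co-expression.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .coexpression import build_network, pearson_matrix, rank_ratios, score_all_pairs
from .errors import ConfigurationError, DataError
from .expression import ExpressionMatrix
from .orthology import OrthologyMap

log = logging.getLogger(__name__)


def empirical_pvalue(samples: np.ndarray, observed: float) -> float:
    """Upper-tail permutation p with the plus-one convention (never zero)."""
    samples = np.asarray(samples, dtype=float)
    return float((1 + np.sum(samples >= observed)) / (len(samples) + 1))


@dataclass
class NullDistribution:
    statistic_name: str
    samples: np.ndarray
    observed: float
    empirical_p: float = field(init=False)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        self.empirical_p = empirical_pvalue(self.samples, self.observed)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.statistic_name: self.samples})


def permute_orthology(
    orthology: OrthologyMap,
    features1: list[str],
    features2: list[str],
    seed: int | np.random.Generator,
) -> OrthologyMap:
    """Random re-pairing: draw |orthology| miRNAs per species without
    replacement and link them positionally."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    k = len(orthology)
    if len(features1) < k or len(features2) < k:
        raise DataError(
            f"need >= {k} features per species to permute, "
            f"got {len(features1)} and {len(features2)}"
        )
    a = rng.choice(np.asarray(features1, dtype=object), size=k, replace=False)
    b = rng.choice(np.asarray(features2, dtype=object), size=k, replace=False)
    return OrthologyMap(pairs=list(zip(a.tolist(), b.tolist())))


def edge_count_null(
    table1,
    table2,
    orthology: OrthologyMap,
    reps: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> NullDistribution:
    """Edge-count null over permuted orthology maps.

    The per-species rank-ratio tables are fixed (they do not depend on the
    map), so each rep only rescores pairs under a permuted map and rebuilds
    the network.
    """
    if reps < 1:
        raise ConfigurationError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    observed = build_network(score_all_pairs(table1, table2, orthology), alpha).number_of_edges()
    samples = np.empty(reps)
    for r in range(reps):
        perm = permute_orthology(orthology, table1.feature_ids, table2.feature_ids, rng)
        scores = score_all_pairs(table1, table2, perm)
        samples[r] = build_network(scores, alpha).number_of_edges()
    return NullDistribution("edge_count", samples, float(observed))


@dataclass
class SubsampleResult:
    mean_edge_count: float
    mean_overlap: float
    edge_counts: np.ndarray
    overlaps: np.ndarray
    n_empty: int


def subsample_robustness(
    m1: ExpressionMatrix,
    m2: ExpressionMatrix,
    orthology: OrthologyMap,
    frac: float = 0.8,
    reps: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> SubsampleResult:
    """Rebuild the network from random sample subsets of each species.

    Per rep, ``frac`` of samples is drawn without replacement per species and
    the full pipeline rerun; overlap = fraction of subsample edges also in
    the full-data network.  Reps with an empty subsample network carry no
    overlap information and are excluded from the mean (counted in
    ``n_empty``).
    """
    if not 0.0 < frac <= 1.0:
        raise ConfigurationError(f"frac must lie in (0, 1], got {frac}")
    n1 = max(1, int(round(frac * m1.n_samples)))
    n2 = max(1, int(round(frac * m2.n_samples)))
    if n1 < 3 or n2 < 3:
        raise ConfigurationError(
            f"frac={frac} leaves fewer than 3 samples ({n1}, {n2}); correlation undefined"
        )
    rng = np.random.default_rng(seed)

    def edges_of(a: ExpressionMatrix, b: ExpressionMatrix) -> set[tuple[str, str]]:
        t1 = rank_ratios(pearson_matrix(a), a.species)
        t2 = rank_ratios(pearson_matrix(b), b.species)
        net = build_network(score_all_pairs(t1, t2, orthology), alpha)
        return {tuple(sorted(e)) for e in net.edges}

    full = edges_of(m1, m2)
    counts = np.empty(reps)
    overlaps = np.full(reps, np.nan)
    for r in range(reps):
        s1 = rng.choice(m1.sample_ids, size=n1, replace=False)
        s2 = rng.choice(m2.sample_ids, size=n2, replace=False)
        sub = edges_of(m1.subset_samples(s1), m2.subset_samples(s2))
        counts[r] = len(sub)
        if sub:
            overlaps[r] = len(sub & full) / len(sub)
    n_empty = int(np.isnan(overlaps).sum())
    if n_empty:
        log.info("%d/%d subsample networks were empty; excluded from overlap mean", n_empty, reps)
    mean_overlap = float(np.nanmean(overlaps)) if n_empty < reps else 0.0
    return SubsampleResult(
        mean_edge_count=float(counts.mean()),
        mean_overlap=mean_overlap,
        edge_counts=counts,
        overlaps=overlaps,
        n_empty=n_empty,
    )


def auc_rank_sum(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC via the Mann-Whitney identity (average ranks handle ties)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("AUC needs at least one positive and one negative")
    ranks = rankdata(scores)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


@dataclass
class RocResult:
    threshold: float
    auc: float
    n_pos: int
    n_neg: int
    fpr: np.ndarray
    tpr: np.ndarray
    permutation_p: float


def roc_evaluate(
    scores: pd.DataFrame,
    reference: ExpressionMatrix,
    pcc_thresholds=(0.5, 0.7, 0.9),
    member_columns: tuple[str, str] = ("member1_a", "member1_b"),
    use_absolute: bool = False,
    permutation_reps: int = 1000,
    seed: int = 0,
) -> dict[float, RocResult]:
    """ROC evaluation of scored pairs against reference co-expression.

    For each threshold tau, a scored pair present in the reference matrix is
    a positive when its reference Pearson correlation is >= tau (or
    |PCC| >= tau with ``use_absolute``); pairs are ranked by -p_raw.  The
    permutation p shuffles labels.  Thresholds with no positives or no
    negatives are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    ref_ids = set(reference.feature_ids)
    mask = scores[member_columns[0]].isin(ref_ids) & scores[member_columns[1]].isin(ref_ids)
    shared = scores[mask]
    if shared[member_columns[0]].nunique() + shared[member_columns[1]].nunique() < 2 or shared.empty:
        raise DataError("reference shares too few miRNAs with the scored pairs")
    corr = pearson_matrix(reference)
    pcc = np.array(
        [corr.at[a, b] for a, b in zip(shared[member_columns[0]], shared[member_columns[1]])]
    )
    rank_score = -shared["p_raw"].to_numpy()
    results: dict[float, RocResult] = {}
    for tau in pcc_thresholds:
        if not 0.0 < tau < 1.0:
            raise ConfigurationError(f"PCC threshold must lie in (0, 1), got {tau}")
        labels = (np.abs(pcc) >= tau) if use_absolute else (pcc >= tau)
        labels &= ~np.isnan(pcc)
        n_pos = int(labels.sum())
        n_neg = int(len(labels) - n_pos)
        if n_pos == 0 or n_neg == 0:
            log.warning("threshold %.2f skipped: %d positives, %d negatives", tau, n_pos, n_neg)
            continue
        auc = auc_rank_sum(rank_score, labels)
        fpr, tpr, _ = roc_curve(labels, rank_score)
        perm = np.empty(permutation_reps)
        for r in range(permutation_reps):
            perm[r] = auc_rank_sum(rank_score, rng.permutation(labels))
        results[float(tau)] = RocResult(
            threshold=float(tau),
            auc=auc,
            n_pos=n_pos,
            n_neg=n_neg,
            fpr=fpr,
            tpr=tpr,
            permutation_p=empirical_pvalue(perm, auc),
        )
    return results
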