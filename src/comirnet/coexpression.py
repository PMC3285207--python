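"""Core statistic: conserved co-expression via rank-ratio order statistics.

For each species, all pairwise Pearson correlations are computed and, for
every anchor miRNA, the other miRNAs are ranked by correlation in descending
order.  The rank divided by the total miRNA count N is the *rank ratio*; for
a pair (A, B) the minimum of the two directional ratios represents the pair,
so a pair near the top of each other's lists gets a ratio near 1/N.  For an
orthologous pair observed in two species this yields one rank ratio per
species, and the probability of ratios jointly at least this small under
independence is the joint CDF of uniform order statistics,

    P(r) = Pr(U_(1) <= r_(1), ..., U_(n) <= r_(n)),  U_i iid Uniform(0, 1),

which for n = 2 species reduces to 2*r1*r2 - r1^2 (r1 <= r2).  Pairs are
Bonferroni-corrected over all scored ortholog pairs and an edge is drawn
when the corrected p falls below alpha.

Note the joint-CDF statistic is *not* a probability integral transform: under
the global null its distribution over pairs is anti-conservative mid-range
(see docs/methods.md).  Family-wise error of the Bonferroni edge caller is
controlled regardless, because Bonferroni only needs per-test validity at the
extreme tail, and the rank-ratio granularity bounds the smallest achievable
p at 1/N^2.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ConfigurationError, DataError, LookupFailure
from .expression import ExpressionMatrix
from .orthology import OrthologyMap

log = logging.getLogger(__name__)


def pearson_matrix(m: ExpressionMatrix) -> pd.DataFrame:
    """All-pairs Pearson correlation over features.

    Rows with zero variance have no defined correlation; their entries
    (including the diagonal) are NaN and a warning is logged.  Requires at
    least 3 samples.
    """
    if m.n_samples < 3:
        raise DataError(f"need >=3 samples for correlation, got {m.n_samples}")
    if m.has_missing():
        raise DataError("matrix contains missing values")
    x = m.values.to_numpy(dtype=float)
    sd = x.std(axis=1)
    flat = sd == 0
    if flat.any():
        log.warning("%d zero-variance rows excluded from ranking", int(flat.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - x.mean(axis=1, keepdims=True)) / np.where(flat, np.nan, sd)[:, None]
        corr = z @ z.T / x.shape[1]
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, np.where(flat, np.nan, 1.0))
    return pd.DataFrame(corr, index=m.values.index, columns=m.values.index)


@dataclass
class RankRatioTable:
    """Directional rank ratios for one species.

    ``ratios[a, b]`` is the descending-correlation rank of feature a in
    anchor b's list, divided by the total feature count N.  The diagonal is
    NaN.  Ties receive average ranks; undefined correlations rank last.
    """

    species: str
    feature_ids: list[str]
    ratios: np.ndarray

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def index_of(self, feature: str) -> int:
        try:
            return self.feature_ids.index(feature)
        except ValueError as exc:
            raise LookupFailure(f"unknown feature {feature!r}") from exc

    def min_ratio_matrix(self) -> np.ndarray:
        """Symmetric matrix of min(rr(A,B), rr(B,A))."""
        return np.fmin(self.ratios, self.ratios.T)


def rank_ratios(corr: pd.DataFrame, species: str = "") -> RankRatioTable:
    """Rank every feature against every anchor, descending by correlation.

    The denominator is the total feature count N (not N-1), so the best
    untied partner has ratio 1/N and no ratio reaches 1.  NaN correlations
    (zero-variance rows) are ranked after all defined ones.
    """
    if corr.shape[0] != corr.shape[1] or not corr.index.equals(corr.columns):
        raise DataError("correlation matrix must be square with matching labels")
    c = corr.to_numpy(dtype=float)
    n = c.shape[0]
    # rank within columns (anchors) on negated correlation; NaN correlations
    # rank after all defined ones, and the diagonal strictly after those
    key = np.where(np.isnan(c), 10.0, -c)  # finite sentinel > any -corr
    np.fill_diagonal(key, 20.0)
    ranks = rankdata(key, method="average", axis=0)
    ratios = ranks / n
    np.fill_diagonal(ratios, np.nan)
    return RankRatioTable(species=species, feature_ids=[str(i) for i in corr.index], ratios=ratios)


def pair_rank_ratio(table: RankRatioTable, a: str, b: str) -> float:
    """min(rr(A,B), rr(B,A)) — the pair's representative rank ratio."""
    if a == b:
        raise DataError("self-pairs have no rank ratio")
    i, j = table.index_of(a), table.index_of(b)
    return float(min(table.ratios[i, j], table.ratios[j, i]))


def order_statistic_pvalue(r: Sequence[float]) -> float:
    """Joint CDF of n iid Uniform(0,1) order statistics at the sorted input.

    Computed by the standard recursion

        V_0 = 1,   V_k = sum_{i=1}^{k} (-1)^(i-1) V_{k-i} r_{(n-k+1)}^i / i!,
        P = n! * V_n,

    which for n = 2 reduces to the closed form 2*r1*r2 - r1^2.
    """
    r = sorted(float(v) for v in r)
    if not r:
        raise ConfigurationError("need at least one rank ratio")
    if r[0] < 0.0 or r[-1] > 1.0:
        raise ConfigurationError(f"rank ratios must lie in [0, 1], got {r}")
    n = len(r)
    v = [1.0] + [0.0] * n
    for k in range(1, n + 1):
        acc = 0.0
        base = r[n - k]
        for i in range(1, k + 1):
            acc += (-1) ** (i - 1) * v[k - i] * base**i / math.factorial(i)
        v[k] = acc
    p = math.factorial(n) * v[n]
    return float(min(1.0, max(0.0, p)))


def _pvalues_two_species(r1: np.ndarray, r2: np.ndarray) -> np.ndarray:
    """Vectorized n=2 closed form; agrees with the recursion to 1e-12."""
    a = np.minimum(r1, r2)
    b = np.maximum(r1, r2)
    return np.clip(2.0 * a * b - a * a, 0.0, 1.0)


def score_all_pairs(
    table1: RankRatioTable,
    table2: RankRatioTable,
    orthology: OrthologyMap,
    usable_only: bool = True,
) -> pd.DataFrame:
    """Score every unordered pair of ortholog nodes.

    Returns a DataFrame with one row per pair: node labels (species1 member
    IDs), the per-species member IDs, the per-species min rank ratios, the
    raw order-statistic p and the Bonferroni-corrected p (m = number of
    scored pairs).
    """
    pairs = orthology.usable_pairs() if usable_only else list(orthology.pairs)
    for a, b in pairs:
        if a not in table1.feature_ids:
            raise LookupFailure(f"ortholog member {a!r} absent from species1 table")
        if b not in table2.feature_ids:
            raise LookupFailure(f"ortholog member {b!r} absent from species2 table")
    k = len(pairs)
    idx1 = np.array([table1.index_of(a) for a, _ in pairs], dtype=int)
    idx2 = np.array([table2.index_of(b) for _, b in pairs], dtype=int)
    m1 = table1.min_ratio_matrix()
    m2 = table2.min_ratio_matrix()
    iu, ju = np.triu_indices(k, 1)
    r1 = m1[idx1[iu], idx1[ju]]
    r2 = m2[idx2[iu], idx2[ju]]
    p_raw = _pvalues_two_species(r1, r2)
    m_tests = len(p_raw)
    p_corr = np.minimum(1.0, p_raw * m_tests)
    labels = [a for a, _ in pairs]
    return pd.DataFrame(
        {
            "node_a": [labels[i] for i in iu],
            "node_b": [labels[j] for j in ju],
            "member1_a": [pairs[i][0] for i in iu],
            "member1_b": [pairs[j][0] for j in ju],
            "member2_a": [pairs[i][1] for i in iu],
            "member2_b": [pairs[j][1] for j in ju],
            f"r_{table1.species or 'species1'}": r1,
            f"r_{table2.species or 'species2'}": r2,
            "p_raw": p_raw,
            "p_corrected": p_corr,
        }
    )


def build_network(scores: pd.DataFrame, alpha: float = 0.05) -> nx.Graph:
    """Undirected network of pairs with Bonferroni-corrected p < alpha.

    Nodes are ortholog nodes labeled by their species1 member ID, carrying
    both members as attributes; edges carry the PairScore fields.
    """
    if not 0.0 <= alpha < 1.0:
        raise ConfigurationError(f"alpha must lie in [0, 1), got {alpha}")
    g = nx.Graph(alpha=alpha, n_scored_pairs=len(scores))
    hits = scores[scores["p_corrected"] < alpha]
    r_cols = [c for c in scores.columns if c.startswith("r_")]
    for row in hits.itertuples(index=False):
        d = row._asdict()
        a, b = sorted((d["node_a"], d["node_b"]))
        for node, m1c, m2c in ((d["node_a"], "member1_a", "member2_a"),
                               (d["node_b"], "member1_b", "member2_b")):
            g.add_node(node, members={"species1": d[m1c], "species2": d[m2c]})
        attrs = {c: d[c] for c in (*r_cols, "p_raw", "p_corrected")}
        g.add_edge(a, b, **attrs)
    return g


def project_to_species(net: nx.Graph, species: str) -> nx.Graph:
    """Single-species view: relabel nodes to that species' member IDs.

    ``species`` is ``"species1"`` or ``"species2"`` (or the labels stored on
    the graph).  The edge set is unchanged; each node remembers its ortholog
    node under the ``ortholog_node`` attribute.
    """
    key = species if species in ("species1", "species2") else None
    if key is None:
        labels = net.graph.get("species_labels", {})
        key = next((k for k, v in labels.items() if v == species), None)
        if key is None:
            raise LookupFailure(f"unknown species {species!r}")
    mapping = {n: net.nodes[n]["members"][key] for n in net.nodes}
    proj = nx.relabel_nodes(net, mapping, copy=True)
    for orig, new in mapping.items():
        proj.nodes[new]["ortholog_node"] = orig
    return proj
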