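"""Disease mapping and sub-network analysis.

Causal disease annotations are mapped onto the co-expression network; the
count of edges whose endpoints share a disease is tested against two
permutation nulls (random pairs, and random disease-miRNA sets of matched
sizes).  Densely connected sub-networks are found with short-random-walk
(walktrap) community detection, and each sub-network is profiled by its
members' common targets — genes hit by at least k members, optionally after
collapsing same-family members into one intersected target set — with
hypergeometric GO enrichment of those common genes.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import igraph as ig
import networkx as nx
import numpy as np

from .annotation import overlap_test, sample_pairs
from .errors import ConfigurationError, DataError
from .significance import NullDistribution

log = logging.getLogger(__name__)


def shared_disease_pairs(
    edges: Iterable[tuple[str, str]], disease_map: Mapping[str, set[str]]
) -> tuple[int, list[tuple[str, str]]]:
    """Edges whose endpoints' disease sets intersect.

    Unannotated miRNAs share nothing.  ``disease_map`` is expected to carry
    causal-grade associations only.
    """
    hits = [
        (a, b)
        for a, b in edges
        if disease_map.get(a, set()) & disease_map.get(b, set())
    ]
    return len(hits), hits


def disease_null(
    edges: Sequence[tuple[str, str]],
    disease_map: Mapping[str, set[str]],
    universe: Sequence[str],
    scheme: str = "pair-permutation",
    reps: int = 1000,
    seed: int = 0,
) -> NullDistribution:
    """Permutation null for the shared-disease edge count.

    ``pair-permutation`` redraws |edges| distinct random pairs from the node
    universe, keeping the disease map fixed; ``disease-permutation`` keeps
    the edges and redraws, per disease, an equally sized random miRNA set
    from the universe.
    """
    if reps < 1:
        raise ConfigurationError("reps must be >= 1")
    if scheme not in ("pair-permutation", "disease-permutation"):
        raise ConfigurationError(f"unknown permutation scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    observed, _ = shared_disease_pairs(edges, disease_map)
    n_edges = len(list(edges))
    samples = np.empty(reps)
    if scheme == "pair-permutation":
        for r in range(reps):
            pairs = sample_pairs(list(universe), n_edges, rng)
            samples[r], _ = shared_disease_pairs(pairs, disease_map)
    else:
        # per-disease counts are taken over miRNAs mapped to the universe:
        # the permutation redraws equally sized sets of *mapped* disease
        # miRNAs, preserving each disease's footprint on the network
        universe_set = set(universe)
        by_disease: dict[str, int] = {}
        for mir, diseases in disease_map.items():
            if mir not in universe_set:
                continue
            for d in diseases:
                by_disease[d] = by_disease.get(d, 0) + 1
        universe_arr = np.asarray(list(universe), dtype=object)
        for d, count in by_disease.items():
            if count > len(universe_arr):
                raise DataError(
                    f"disease {d!r} annotates {count} miRNAs but the universe has "
                    f"only {len(universe_arr)}"
                )
        for r in range(reps):
            permuted: dict[str, set[str]] = {}
            for d, count in by_disease.items():
                members = rng.choice(universe_arr, size=count, replace=False)
                for m in members:
                    permuted.setdefault(str(m), set()).add(d)
            samples[r], _ = shared_disease_pairs(edges, permuted)
    return NullDistribution(f"shared_disease_pairs[{scheme}]", samples, float(observed))


@dataclass
class CommunityPartition:
    assignment: dict[str, int]
    modularity: float
    walk_length: int

    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, label in self.assignment.items():
            out.setdefault(label, []).append(node)
        return out


def walktrap_communities(network: nx.Graph, t: int = 4) -> CommunityPartition:
    """Short-random-walk (walktrap) communities, cut at maximum modularity.

    Distances between nodes derive from t-step random-walk transition
    profiles; communities are merged agglomeratively and the merge-sequence
    cut maximizing Newman-Girvan modularity is returned (Pons & Latapy, via
    igraph).  Isolated nodes become singleton communities.
    """
    if t < 1:
        raise ConfigurationError("walk length t must be >= 1")
    if network.number_of_nodes() == 0:
        raise DataError("cannot detect communities in an empty graph")
    nodes = [str(n) for n in network.nodes]
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[str(a)], index[str(b)]) for a, b in network.edges]
    g = ig.Graph(n=len(nodes), edges=edges)
    if g.ecount() == 0:
        assignment = {n: i for i, n in enumerate(nodes)}
        return CommunityPartition(assignment=assignment, modularity=0.0, walk_length=t)
    dendrogram = g.community_walktrap(steps=t)
    clustering = dendrogram.as_clustering()
    assignment = {nodes[v]: int(lbl) for v, lbl in enumerate(clustering.membership)}
    return CommunityPartition(
        assignment=assignment,
        modularity=float(g.modularity(clustering.membership)),
        walk_length=t,
    )


def common_targets(target_sets: Mapping[str, set[str]], k: int) -> set[str]:
    """Genes targeted by at least k of the members.

    k = number of members gives the plain intersection; k = 1 the union.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if k > len(target_sets):
        raise ConfigurationError(
            f"k={k} exceeds the {len(target_sets)} members with target sets"
        )
    counts: dict[str, int] = {}
    for genes in target_sets.values():
        for gene in genes:
            counts[gene] = counts.get(gene, 0) + 1
    return {gene for gene, c in counts.items() if c >= k}


def family_collapse(
    target_sets: Mapping[str, set[str]],
    family_map: Mapping[str, str],
    k: int,
) -> set[str]:
    """Common targets after collapsing same-family members.

    Members of one family (identical seeds, hence near-identical predicted
    targets) are first intersected into a single family target set; the
    collapsed sets (plus singletons for unmapped members) then go through
    :func:`common_targets` at threshold k.
    """
    groups: dict[str, list[str]] = {}
    for mir in target_sets:
        fam = family_map.get(mir, f"__singleton__{mir}")
        groups.setdefault(fam, []).append(mir)
    collapsed: dict[str, set[str]] = {}
    for fam, members in groups.items():
        s = set(target_sets[members[0]])
        for m in members[1:]:
            s &= target_sets[m]
        collapsed[fam] = s
    return common_targets(collapsed, k)


def default_common_target_threshold(n_members: int, fraction: float = 0.85) -> int:
    """ceil(fraction * members), the 'shared by nearly all members' rule."""
    return max(1, math.ceil(fraction * n_members))


@dataclass
class SubnetworkReport:
    members: list[str]
    disease_counts: dict[str, int]
    k: int
    common_target_genes: set[str]
    family_collapsed_k: int | None
    family_collapsed_genes: set[str] | None
    enriched_processes: list[tuple[str, float]]
    expr_related_processes: list[tuple[str, float]] = field(default_factory=list)
    affected_processes: list[tuple[str, float]] = field(default_factory=list)


def _enrich(
    genes: set[str], go_sets: Mapping[str, set[str]], universe_size: int, p_cutoff: float
) -> list[tuple[str, float]]:
    hits = []
    for term, term_genes in go_sets.items():
        res = overlap_test(genes, set(term_genes), universe_size)
        if res.k >= 1 and res.p < p_cutoff:
            hits.append((term, res.p))
    return sorted(hits, key=lambda t: t[1])


def subnetwork_enrichment(
    members: Sequence[str],
    target_sets: Mapping[str, set[str]],
    go_sets: Mapping[str, set[str]],
    universe_size: int,
    k: int | None = None,
    p_cutoff: float = 0.001,
    disease_map: Mapping[str, set[str]] | None = None,
    family_map: Mapping[str, str] | None = None,
    expr_related_sets: Mapping[str, set[str]] | None = None,
    affected_sets: Mapping[str, set[str]] | None = None,
) -> SubnetworkReport:
    """Profile one sub-network: common targets at threshold k (default
    ceil(0.85 * members with targets)), family-collapsed common targets, and
    hypergeometric GO enrichment of each common-gene set."""
    with_targets = {m: target_sets[m] for m in members if m in target_sets}
    if not with_targets:
        raise DataError("no sub-network member has a target set")
    if k is None:
        k = default_common_target_threshold(len(with_targets))
    common = common_targets(with_targets, k)
    fam_k = None
    fam_genes = None
    if family_map is not None:
        n_collapsed = len(
            {family_map.get(m, f"__singleton__{m}") for m in with_targets}
        )
        fam_k = min(k, n_collapsed) if n_collapsed else None
        fam_genes = family_collapse(with_targets, family_map, fam_k) if fam_k else None
    disease_counts: dict[str, int] = {}
    if disease_map:
        for m in members:
            for d in disease_map.get(m, set()):
                disease_counts[d] = disease_counts.get(d, 0) + 1
    report = SubnetworkReport(
        members=list(members),
        disease_counts=disease_counts,
        k=k,
        common_target_genes=common,
        family_collapsed_k=fam_k,
        family_collapsed_genes=fam_genes,
        enriched_processes=_enrich(common, go_sets, universe_size, p_cutoff),
    )
    if expr_related_sets:
        avail = {m: expr_related_sets[m] for m in members if m in expr_related_sets}
        if avail:
            kk = min(default_common_target_threshold(len(avail)), len(avail))
            genes = common_targets(avail, kk)
            report.expr_related_processes = _enrich(genes, go_sets, universe_size, p_cutoff)
    if affected_sets:
        avail = {m: affected_sets[m] for m in members if m in affected_sets}
        if avail:
            kk = min(default_common_target_threshold(len(avail)), len(avail))
            genes = common_targets(avail, kk)
            report.affected_processes = _enrich(genes, go_sets, universe_size, p_cutoff)
    return report
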