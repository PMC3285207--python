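"""Configuration-driven orchestration of the full analysis.

Stages (in order): ``preprocess`` (quantile normalization, probe collapse,
platform intersection, per species), ``ortho`` (sequence-based orthology, or
a precomputed map), ``network`` (rank ratios, order-statistic p-values,
Bonferroni edges), ``validate`` (orthology-permutation null, subsampling
robustness, ROC vs a reference set), ``annotate`` (per-pair
characterization with random-pair nulls) and ``subnets`` (disease mapping,
walktrap communities, common-target enrichment).  Every stage writes its
tables under the configured output directory and the run manifest records
seed, config hash and per-stage row counts.  All randomness flows from the
single master seed through fixed per-stage offsets, so each stage is
reproducible in isolation.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io
from .annotation import (
    AnnotationBundle,
    characterize_pairs,
    pair_flags,
    random_pair_null,
)
from .coexpression import (
    build_network,
    pearson_matrix,
    project_to_species,
    rank_ratios,
    score_all_pairs,
)
from .errors import ComirnetError, ConfigurationError, PipelineError
from .expression import ExpressionMatrix
from .orthology import find_orthologs
from .preprocess import intersect_datasets, map_probes, quantile_normalize
from .significance import edge_count_null, roc_evaluate, subsample_robustness
from .subnetworks import (
    disease_null,
    shared_disease_pairs,
    subnetwork_enrichment,
    walktrap_communities,
)

log = logging.getLogger(__name__)

STAGES = ("preprocess", "ortho", "network", "validate", "annotate", "subnets")

# fixed per-stage seed offsets so stages are reproducible independently
_SEED_OFFSETS = {"ortho_null": 11, "subsample": 23, "roc": 37, "pairs_null": 51, "disease_null": 67}


@dataclass
class PipelineConfig:
    """All knobs and input paths of one run; unknown YAML keys are rejected."""

    outdir: str = "comirnet_run"
    species1: str = "human"
    species2: str = "mouse"
    expression1: list[str] = field(default_factory=list)
    expression2: list[str] = field(default_factory=list)
    probe_map1: str | None = None
    probe_map2: str | None = None
    orthology: str | None = None
    precursors1: str | None = None
    precursors2: str | None = None
    matures1: str | None = None
    matures2: str | None = None
    precursor_mature1: str | None = None
    precursor_mature2: str | None = None
    locations: str | None = None
    clusters: str | None = None
    families: str | None = None
    tf_edges: str | None = None
    disease: str | None = None
    targets_gmt: str | None = None
    target_scores: str | None = None
    go_gmt: str | None = None
    fc_tables: str | None = None
    mrna_expression: str | None = None
    reference_expression: str | None = None
    alpha: float = 0.05
    flank_bp: int = 11
    context_cutoff: float | None = -0.3
    pcc_cutoff: float = 0.5
    fc_cutoff: float = 1.2
    reps_orthology_null: int = 1000
    reps_random_pairs: int = 1000
    reps_disease_null: int = 1000
    subsample_frac: float = 0.8
    subsample_reps: int = 100
    roc_thresholds: list[float] = field(default_factory=lambda: [0.5, 0.7, 0.9])
    walk_length: int = 4
    k_common_fraction: float = 0.85
    go_p_cutoff: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.alpha < 1.0:
            raise ConfigurationError(f"alpha must lie in [0, 1), got {self.alpha}")
        if not 0.0 < self.subsample_frac <= 1.0:
            raise ConfigurationError("subsample_frac must lie in (0, 1]")
        if self.walk_length < 1:
            raise ConfigurationError("walk_length must be >= 1")
        if not 0.0 < self.k_common_fraction <= 1.0:
            raise ConfigurationError("k_common_fraction must lie in (0, 1]")
        for name in ("reps_orthology_null", "reps_random_pairs", "reps_disease_null",
                     "subsample_reps"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _outdir(config: PipelineConfig) -> Path:
    p = Path(config.outdir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def _matrix_path(config: PipelineConfig, which: int) -> Path:
    species = config.species1 if which == 1 else config.species2
    return _outdir(config) / f"matrix_{species}.tsv"


def _stage_preprocess(config: PipelineConfig, manifest: dict) -> None:
    for which, (paths, pm_path) in enumerate(
        [(config.expression1, config.probe_map1), (config.expression2, config.probe_map2)], start=1
    ):
        species = config.species1 if which == 1 else config.species2
        if not paths:
            raise ConfigurationError(f"no expression datasets configured for {species}")
        probe_map = io.read_probe_map_tsv(pm_path) if pm_path else None
        datasets = []
        for p in paths:
            m = io.read_expression_tsv(p, species=species)
            m = quantile_normalize(m)
            if probe_map is not None:
                m = map_probes(m, probe_map)
            datasets.append(m)
        merged = intersect_datasets(datasets)
        io.write_expression_tsv(merged, _matrix_path(config, which))
        manifest["stages"]["preprocess"][species] = {
            "datasets": len(datasets),
            "features": merged.n_features,
            "samples": merged.n_samples,
        }


def _stage_ortho(config: PipelineConfig, manifest: dict) -> None:
    out = _outdir(config) / "orthology.tsv"
    if config.orthology:
        omap = io.read_orthology_tsv(config.orthology)
        source = "precomputed"
    else:
        needed = (config.precursors1, config.precursors2, config.matures1, config.matures2,
                  config.precursor_mature1, config.precursor_mature2)
        if any(p is None for p in needed):
            raise ConfigurationError(
                "either 'orthology' or all sequence inputs (precursors, matures, "
                "precursor_mature tables) must be configured"
            )
        m1 = io.read_expression_tsv(_matrix_path(config, 1), species=config.species1)
        m2 = io.read_expression_tsv(_matrix_path(config, 2), species=config.species2)
        omap = find_orthologs(
            io.read_fasta(config.precursors1),
            io.read_fasta(config.precursors2),
            io.read_precursor_mature_tsv(config.precursor_mature1),
            io.read_precursor_mature_tsv(config.precursor_mature2),
            io.read_fasta(config.matures1),
            io.read_fasta(config.matures2),
            expressed1=set(m1.feature_ids),
            expressed2=set(m2.feature_ids),
        )
        source = "sequence"
    io.write_orthology_tsv(omap, out)
    manifest["stages"]["ortho"] = {
        "source": source,
        "pairs": len(omap),
        "usable_pairs": len(omap.usable_pairs()),
    }


def _load_tables(config: PipelineConfig):
    m1 = io.read_expression_tsv(_matrix_path(config, 1), species=config.species1)
    m2 = io.read_expression_tsv(_matrix_path(config, 2), species=config.species2)
    omap = io.read_orthology_tsv(_outdir(config) / "orthology.tsv")
    t1 = rank_ratios(pearson_matrix(m1), config.species1)
    t2 = rank_ratios(pearson_matrix(m2), config.species2)
    # restrict the map to members with expression
    usable = {
        p: (omap.usable.get(p, True)
            and p[0] in set(m1.feature_ids) and p[1] in set(m2.feature_ids))
        for p in omap.pairs
    }
    omap.usable = usable
    return m1, m2, omap, t1, t2


def _stage_network(config: PipelineConfig, manifest: dict) -> None:
    _, _, omap, t1, t2 = _load_tables(config)
    scores = score_all_pairs(t1, t2, omap)
    scores.to_csv(_outdir(config) / "pair_scores.tsv", sep="\t", index=False,
                  float_format=io.FLOAT_FORMAT)
    net = build_network(scores, config.alpha)
    edges = sorted(tuple(sorted(e)) for e in net.edges)
    with open(_outdir(config) / "edges.tsv", "w") as fh:
        fh.write("node_a\tnode_b\tp_corrected\n")
        for a, b in edges:
            fh.write(f"{a}\t{b}\t{net.edges[a, b]['p_corrected']:.6g}\n")
    manifest["stages"]["network"] = {
        "scored_pairs": len(scores),
        "nodes": net.number_of_nodes(),
        "edges": net.number_of_edges(),
        "alpha": config.alpha,
    }


def _read_network(config: PipelineConfig):
    scores_path = _outdir(config) / "pair_scores.tsv"
    import pandas as pd

    scores = pd.read_csv(scores_path, sep="\t")
    return scores, build_network(scores, config.alpha)


def _stage_validate(config: PipelineConfig, manifest: dict) -> None:
    m1, m2, omap, t1, t2 = _load_tables(config)
    seed = config.seed
    null = edge_count_null(t1, t2, omap, reps=config.reps_orthology_null,
                           alpha=config.alpha, seed=seed + _SEED_OFFSETS["ortho_null"])
    null.to_frame().to_csv(_outdir(config) / "orthology_null.tsv", sep="\t", index=False,
                           float_format=io.FLOAT_FORMAT)
    sub = subsample_robustness(
        m1, m2, omap, frac=config.subsample_frac, reps=config.subsample_reps,
        alpha=config.alpha, seed=seed + _SEED_OFFSETS["subsample"],
    )
    result = {
        "orthology_null": {
            "observed_edges": null.observed,
            "empirical_p": null.empirical_p,
            "null_mean": float(null.samples.mean()),
            "reps": len(null.samples),
        },
        "subsample": {
            "frac": config.subsample_frac,
            "mean_edge_count": sub.mean_edge_count,
            "mean_overlap": sub.mean_overlap,
            "n_empty": sub.n_empty,
        },
    }
    if config.reference_expression:
        scores, _ = _read_network(config)
        ref = io.read_expression_tsv(config.reference_expression, species=config.species1)
        roc = roc_evaluate(
            scores, ref, pcc_thresholds=config.roc_thresholds,
            seed=seed + _SEED_OFFSETS["roc"],
        )
        result["roc"] = {
            f"{tau:g}": {"auc": r.auc, "n_pos": r.n_pos, "n_neg": r.n_neg,
                          "permutation_p": r.permutation_p}
            for tau, r in roc.items()
        }
    io.write_json(result, _outdir(config) / "validation.json")
    manifest["stages"]["validate"] = result


def _load_bundle(config: PipelineConfig) -> AnnotationBundle:
    bundle = AnnotationBundle()
    if config.locations:
        bundle.locations = io.read_locations_tsv(config.locations)
    if config.clusters:
        bundle.clusters = io.read_mapping_tsv(config.clusters)
    if config.families:
        bundle.families = io.read_mapping_tsv(config.families)
    if config.tf_edges:
        bundle.tf_edges = set(io.read_pairs_tsv(config.tf_edges))
    if config.disease:
        bundle.disease = io.read_disease_tsv(config.disease)
    if config.targets_gmt:
        bundle.target_sets = io.read_gmt(config.targets_gmt)
    if config.target_scores:
        bundle.target_scores = io.read_target_scores_tsv(config.target_scores)
    if config.go_gmt:
        bundle.go_sets = io.read_gmt(config.go_gmt)
    if config.fc_tables:
        bundle.fc_tables = io.read_fc_tables_tsv(config.fc_tables)
    if config.mrna_expression:
        bundle.mrna_expr = io.read_expression_tsv(config.mrna_expression)
    universe = set()
    for s in bundle.target_sets.values():
        universe |= s
    for s in bundle.go_sets.values():
        universe |= s
    if bundle.mrna_expr is not None:
        universe |= set(bundle.mrna_expr.feature_ids)
    bundle.gene_universe = sorted(universe)
    return bundle


def _stage_annotate(config: PipelineConfig, manifest: dict) -> None:
    scores, net = _read_network(config)
    if net.number_of_edges() == 0:
        io.write_json({"note": "empty network; stage short-circuited"},
                      _outdir(config) / "annotation_summary.json")
        manifest["stages"]["annotate"] = {"short_circuited": True}
        return
    human_net = project_to_species(net, "species1")
    pairs = [tuple(sorted(e)) for e in human_net.edges]
    bundle = _load_bundle(config)
    m1 = io.read_expression_tsv(_matrix_path(config, 1), species=config.species1)
    table = characterize_pairs(
        pairs, bundle, mirna_expr=m1, context_cutoff=config.context_cutoff,
        pcc_cutoff=config.pcc_cutoff, fc_cutoff=config.fc_cutoff,
        go_p_cutoff=config.go_p_cutoff,
    )
    table.to_csv(_outdir(config) / "pair_characterization.tsv", sep="\t", index=False,
                 float_format=io.FLOAT_FORMAT)
    universe = sorted(human_net.nodes)
    summary: dict = {"n_pairs": len(pairs)}
    predicates = {
        "same_cluster": lambda p: pair_flags(p, bundle)[0],
        "same_family": lambda p: pair_flags(p, bundle)[1],
        "shared_tf": lambda p: pair_flags(p, bundle)[2],
    }
    if len(universe) >= 2:
        for name, pred in predicates.items():
            null = random_pair_null(
                universe, len(pairs), config.reps_random_pairs, pred,
                seed=config.seed + _SEED_OFFSETS["pairs_null"], observed_pairs=pairs,
            )
            summary[name] = {
                "observed": null.observed,
                "null_mean": float(null.samples.mean()),
                "empirical_p": null.empirical_p,
            }
    io.write_json(summary, _outdir(config) / "annotation_summary.json")
    manifest["stages"]["annotate"] = {"pairs": len(pairs), "columns": len(table.columns)}


def _stage_subnets(config: PipelineConfig, manifest: dict) -> None:
    _, net = _read_network(config)
    if net.number_of_edges() == 0:
        io.write_json({"note": "empty network; stage short-circuited"},
                      _outdir(config) / "subnetworks.json")
        manifest["stages"]["subnets"] = {"short_circuited": True}
        return
    human_net = project_to_species(net, "species1")
    bundle = _load_bundle(config)
    edges = [tuple(sorted(e)) for e in human_net.edges]
    universe = sorted(human_net.nodes)
    count, shared = shared_disease_pairs(edges, bundle.disease)
    result: dict = {"shared_disease_pairs": count}
    if bundle.disease and len(universe) >= 2:
        for scheme in ("pair-permutation", "disease-permutation"):
            null = disease_null(
                edges, bundle.disease, universe, scheme=scheme,
                reps=config.reps_disease_null,
                seed=config.seed + _SEED_OFFSETS["disease_null"],
            )
            result[f"null[{scheme}]"] = {
                "empirical_p": null.empirical_p,
                "null_mean": float(null.samples.mean()),
            }
    partition = walktrap_communities(human_net, t=config.walk_length)
    with open(_outdir(config) / "communities.tsv", "w") as fh:
        fh.write("mirna\tcommunity\n")
        for node in sorted(partition.assignment):
            fh.write(f"{node}\t{partition.assignment[node]}\n")
    result["modularity"] = partition.modularity
    result["n_communities"] = len(set(partition.assignment.values()))
    reports = {}
    for label, members in sorted(partition.communities().items()):
        if len(members) < 3:
            continue
        with_targets = [m for m in members if m in bundle.target_sets]
        if not with_targets or not bundle.gene_universe:
            continue
        import math as _math

        k = max(1, _math.ceil(config.k_common_fraction * len(with_targets)))
        rep = subnetwork_enrichment(
            members, bundle.target_sets, bundle.go_sets, len(bundle.gene_universe),
            k=k, p_cutoff=config.go_p_cutoff, disease_map=bundle.disease,
            family_map=bundle.families,
        )
        reports[str(label)] = {
            "members": rep.members,
            "disease_counts": rep.disease_counts,
            "k": rep.k,
            "n_common_targets": len(rep.common_target_genes),
            "n_family_collapsed_targets": (
                len(rep.family_collapsed_genes) if rep.family_collapsed_genes is not None else None
            ),
            "enriched_processes": rep.enriched_processes,
        }
    result["subnetworks"] = reports
    io.write_json(result, _outdir(config) / "subnetworks.json")
    manifest["stages"]["subnets"] = {
        "shared_disease_pairs": count,
        "n_communities": result["n_communities"],
        "reported_subnetworks": len(reports),
    }


_STAGE_FUNCS = {
    "preprocess": _stage_preprocess,
    "ortho": _stage_ortho,
    "network": _stage_network,
    "validate": _stage_validate,
    "annotate": _stage_annotate,
    "subnets": _stage_subnets,
}


def run_pipeline(config: PipelineConfig, stages=None) -> dict:
    """Run the configured stages in order and return the manifest."""
    from . import __version__

    stages = list(STAGES) if stages is None else [s for s in STAGES if s in set(stages)]
    outdir = _outdir(config)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "versions": {"comirnet": __version__, "numpy": np.__version__},
        "stages": {"preprocess": {}},
    }
    for stage in stages:
        log.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](config, manifest)
        except ComirnetError as exc:
            raise PipelineError(stage, str(exc)) from exc
    io.write_json(manifest, outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# demo dataset
# ---------------------------------------------------------------------------

def demo_dataset(outdir, seed: int = 0, config=None, null_reps: int = 200) -> Path:
    """Write a self-contained synthetic input bundle plus a pipeline config.

    Returns the path to the written config YAML.  The bundle exercises every
    stage: probe-level expression in two datasets per species, probe maps
    (with multi-mapping decoys), precursor/mature FASTA plus
    precursor-to-mature tables, the full annotation bundle, a reference
    expression set and the ground-truth JSON.
    """
    from .synthetic import (
        SyntheticConfig,
        generate_annotations,
        generate_expression_pair,
        generate_reference_matrix,
        generate_sequences,
    )

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config or SyntheticConfig(seed=seed)
    human, mouse, omap, truth = generate_expression_pair(cfg)
    bundle = generate_annotations(cfg, truth)
    seqs1, seqs2 = generate_sequences(cfg, truth)
    reference = generate_reference_matrix(cfg, truth)

    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(20)[19])
    paths: dict[str, str] = {}

    for which, m in (("1", human), ("2", mouse)):
        # probe-level view: one probe per miRNA, duplicate probes for the
        # first 10, plus two ambiguous decoys that the mapping step must drop
        probe_rows = {}
        probe_map = {}
        for mir in m.feature_ids:
            probe_rows[f"p:{mir}"] = m.values.loc[mir].to_numpy()
            probe_map[f"p:{mir}"] = [mir]
        for mir in m.feature_ids[:10]:
            probe_rows[f"p2:{mir}"] = (
                m.values.loc[mir].to_numpy() + 0.05 * rng.standard_normal(m.n_samples)
            )
            probe_map[f"p2:{mir}"] = [mir]
        decoys = m.feature_ids[:2]
        probe_rows["p:ambiguous"] = rng.standard_normal(m.n_samples)
        probe_map["p:ambiguous"] = decoys
        import pandas as pd

        probe_df = pd.DataFrame(probe_rows).T
        probe_df.columns = m.sample_ids
        half = m.n_samples // 2
        for d, cols in (("a", m.sample_ids[:half]), ("b", m.sample_ids[half:])):
            em = ExpressionMatrix(probe_df[cols], species=m.species, dataset_id=f"d{d}")
            p = outdir / f"expression_{m.species}_{d}.tsv"
            io.write_expression_tsv(em, p)
            paths.setdefault(f"expression{which}", []).append(str(p))
        pm_path = outdir / f"probe_map_{m.species}.tsv"
        io.write_probe_map_tsv(probe_map, pm_path)
        paths[f"probe_map{which}"] = str(pm_path)

    for which, s, species in (("1", seqs1, "human"), ("2", seqs2, "mouse")):
        pp = outdir / f"precursors_{species}.fasta"
        mp = outdir / f"matures_{species}.fasta"
        tp = outdir / f"precursor_mature_{species}.tsv"
        io.write_fasta(s.precursors, pp)
        io.write_fasta(s.matures, mp)
        io.write_precursor_mature_tsv(s.precursor_to_mature, tp)
        paths[f"precursors{which}"] = str(pp)
        paths[f"matures{which}"] = str(mp)
        paths[f"precursor_mature{which}"] = str(tp)

    io.write_locations_tsv(bundle.locations, outdir / "locations.tsv")
    io.write_mapping_tsv(bundle.clusters, outdir / "clusters.tsv", "mirna", "cluster")
    io.write_mapping_tsv(bundle.families, outdir / "families.tsv", "mirna", "family")
    io.write_pairs_tsv(sorted(bundle.tf_edges), outdir / "tf_edges.tsv", ("tf", "mirna"))
    io.write_disease_tsv(bundle.disease, outdir / "disease.tsv")
    io.write_gmt(bundle.target_sets, outdir / "targets.gmt")
    io.write_target_scores_tsv(bundle.target_scores, outdir / "target_scores.tsv")
    io.write_gmt(bundle.go_sets, outdir / "go_sets.gmt")
    io.write_fc_tables_tsv(bundle.fc_tables, outdir / "fc_tables.tsv")
    io.write_expression_tsv(bundle.mrna_expr, outdir / "mrna_expression.tsv")
    io.write_expression_tsv(reference, outdir / "reference_expression.tsv")
    io.write_json(
        {
            "conserved_pairs": sorted(sorted(p) for p in truth.conserved_pairs),
            "single_species_pairs": [
                {"pair": sorted(p), "species": sp} for p, sp in truth.single_species_pairs
            ],
            "community_assignment": truth.community_assignment,
            "disease_community": truth.disease_community,
            "synthetic_config": dataclasses.asdict(cfg),
        },
        outdir / "ground_truth.json",
    )

    pc = PipelineConfig(
        outdir=str(outdir / "run"),
        expression1=paths["expression1"],
        expression2=paths["expression2"],
        probe_map1=paths["probe_map1"],
        probe_map2=paths["probe_map2"],
        precursors1=paths["precursors1"],
        precursors2=paths["precursors2"],
        matures1=paths["matures1"],
        matures2=paths["matures2"],
        precursor_mature1=paths["precursor_mature1"],
        precursor_mature2=paths["precursor_mature2"],
        locations=str(outdir / "locations.tsv"),
        clusters=str(outdir / "clusters.tsv"),
        families=str(outdir / "families.tsv"),
        tf_edges=str(outdir / "tf_edges.tsv"),
        disease=str(outdir / "disease.tsv"),
        targets_gmt=str(outdir / "targets.gmt"),
        target_scores=str(outdir / "target_scores.tsv"),
        go_gmt=str(outdir / "go_sets.gmt"),
        fc_tables=str(outdir / "fc_tables.tsv"),
        mrna_expression=str(outdir / "mrna_expression.tsv"),
        reference_expression=str(outdir / "reference_expression.tsv"),
        reps_orthology_null=null_reps,
        reps_random_pairs=null_reps,
        reps_disease_null=null_reps,
        subsample_reps=max(10, null_reps // 4),
        seed=seed,
    )
    cfg_path = outdir / "config.yaml"
    pc.to_yaml(cfg_path)
    return cfg_path
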