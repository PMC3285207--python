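"""The generator must plant exactly the structure the analysis assumes."""
import numpy as np
import pytest

from comirnet import (
    ConfigurationError,
    SyntheticConfig,
    generate_annotations,
    generate_community_network,
    generate_expression_pair,
    generate_sequences,
)


def _corr(m, a, b):
    return float(np.corrcoef(m.values.loc[a], m.values.loc[b])[0, 1])


def _jaccard(a, b):
    return len(a & b) / len(a | b)


@pytest.mark.parametrize(
    "kwargs,fragment",
    [
        (dict(n_mirnas_per_species=0), "n_mirnas_per_species"),
        (dict(n_orthologs=301), "n_orthologs"),
        (dict(n_planted_conserved=40, n_planted_single_species=0, n_orthologs=60),
         "n_planted_conserved"),
        (dict(latent_loading=0.0), "latent_loading"),
        (dict(noise_sd=0.0), "noise_sd"),
        (dict(planted_target_jaccard=1.5), "planted_target_jaccard"),
    ],
)
def test_config_invariants_name_the_violated_bound(kwargs, fragment):
    with pytest.raises(ConfigurationError, match=fragment):
        SyntheticConfig(**kwargs)


def test_fixed_seed_gives_bit_identical_outputs(small_config):
    h1, m1, o1, t1 = generate_expression_pair(small_config)
    h2, m2, o2, t2 = generate_expression_pair(small_config)
    assert h1.values.equals(h2.values)
    assert m1.values.equals(m2.values)
    assert o1.pairs == o2.pairs
    assert t1 == t2
    b1 = generate_annotations(small_config, t1, target_set_size=40, disease_core_size=10)
    b2 = generate_annotations(small_config, t2, target_set_size=40, disease_core_size=10)
    assert b1.target_sets == b2.target_sets
    assert b1.locations == b2.locations
    s1a, _ = generate_sequences(small_config, t1)
    s1b, _ = generate_sequences(small_config, t2)
    assert s1a.precursors == s1b.precursors


def test_different_seeds_differ(small_config):
    import dataclasses

    other = dataclasses.replace(small_config, seed=small_config.seed + 1)
    h1, *_ = generate_expression_pair(small_config)
    h2, *_ = generate_expression_pair(other)
    assert not h1.values.equals(h2.values)


def test_no_planting_yields_empty_ground_truth():
    cfg = SyntheticConfig(
        n_mirnas_per_species=20, n_orthologs=10, n_samples_human=10,
        n_samples_mouse=10, n_planted_conserved=0, n_planted_single_species=0,
        n_genes=100, seed=0,
    )
    _, _, _, truth = generate_expression_pair(cfg)
    assert truth.conserved_pairs == frozenset()
    assert truth.single_species_pairs == ()


def test_planted_pairs_strongly_correlated_in_both_species():
    # latent loading 0.9 with unit noise puts the population correlation at
    # 0.9; sample correlations at 100 samples stay well above 0.5
    for seed in range(5):
        cfg = SyntheticConfig(
            n_mirnas_per_species=40, n_orthologs=20, n_samples_human=100,
            n_samples_mouse=100, n_planted_conserved=5, n_planted_single_species=0,
            latent_loading=0.9, noise_sd=1.0, n_genes=100, seed=seed,
        )
        h, m, o, truth = generate_expression_pair(cfg)
        mouse_of = dict(o.pairs)
        for a, b in truth.conserved_pairs:
            assert _corr(h, a, b) > 0.5
            assert _corr(m, mouse_of[a], mouse_of[b]) > 0.5


def test_single_species_pairs_correlated_only_in_their_species(small_data, small_config):
    h, m, o, truth = small_data
    mouse_of = dict(o.pairs)
    for (a, b), species in truth.single_species_pairs:
        if species == "human":
            assert _corr(h, a, b) > 0.5
            assert abs(_corr(m, mouse_of[a], mouse_of[b])) < 0.5
        else:
            assert _corr(m, mouse_of[a], mouse_of[b]) > 0.5
            assert abs(_corr(h, a, b)) < 0.5


def test_planted_correlation_beats_background_99th_percentile():
    # over 20 seeds: mean planted pair correlation above the 99th percentile
    # of background pair correlations (loading >= 0.8, >= 60 samples)
    rng = np.random.default_rng(0)
    for seed in range(20):
        cfg = SyntheticConfig(
            n_mirnas_per_species=60, n_orthologs=20, n_samples_human=60,
            n_samples_mouse=60, n_planted_conserved=4, n_planted_single_species=0,
            latent_loading=0.8, n_genes=100, seed=seed,
        )
        h, _, _, truth = generate_expression_pair(cfg)
        corr = np.corrcoef(h.values.to_numpy())
        ids = h.feature_ids
        idx = {f: i for i, f in enumerate(ids)}
        planted = [(idx[a], idx[b]) for a, b in truth.conserved_pairs]
        planted_nodes = {i for p in planted for i in p}
        mean_planted = np.mean([corr[i, j] for i, j in planted])
        iu = np.triu_indices(len(ids), 1)
        background = [
            corr[i, j] for i, j in zip(*iu)
            if i not in planted_nodes and j not in planted_nodes
        ]
        assert mean_planted > np.percentile(background, 99)


def test_annotations_reference_only_known_ids(small_config, small_data, small_bundle):
    h, _, o, truth = small_data
    known = set(h.feature_ids)
    assert set(small_bundle.locations) <= known
    assert set(small_bundle.families) <= known
    assert set(small_bundle.target_sets) <= known
    assert {m for _, m in small_bundle.tf_edges} <= known
    assert set(small_bundle.disease) <= known
    genes = set(small_bundle.gene_universe)
    for s in small_bundle.target_sets.values():
        assert s <= genes
    for s in small_bundle.go_sets.values():
        assert s <= genes


def test_planted_target_jaccard_realized(small_config, small_data, small_bundle):
    _, _, _, truth = small_data
    for a, b in truth.conserved_pairs:
        j = _jaccard(small_bundle.target_sets[a], small_bundle.target_sets[b])
        assert abs(j - small_config.planted_target_jaccard) < 0.1


def test_jaccard_one_means_identical_sets():
    cfg = SyntheticConfig(
        n_mirnas_per_species=12, n_orthologs=8, n_samples_human=10, n_samples_mouse=10,
        n_planted_conserved=2, n_planted_single_species=0, n_genes=500,
        planted_target_jaccard=1.0, seed=3,
    )
    _, _, _, truth = generate_expression_pair(cfg)
    bundle = generate_annotations(cfg, truth, target_set_size=30, disease_core_size=5)
    for a, b in truth.conserved_pairs:
        assert bundle.target_sets[a] == bundle.target_sets[b]


def test_background_jaccard_zero_means_disjoint_sets():
    cfg = SyntheticConfig(
        n_mirnas_per_species=10, n_orthologs=6, n_samples_human=10, n_samples_mouse=10,
        n_planted_conserved=1, n_planted_single_species=0, n_genes=500,
        background_target_jaccard=0.0, n_communities=0, seed=3,
    )
    _, _, _, truth = generate_expression_pair(cfg)
    bundle = generate_annotations(cfg, truth, target_set_size=40, disease_core_size=5)
    planted_nodes = truth.planted_nodes()
    background = [m for m in bundle.target_sets if m not in planted_nodes]
    assert not (bundle.target_sets[background[0]] & bundle.target_sets[background[1]])


def test_disease_labels_cover_exactly_the_disease_community(small_data, small_bundle):
    _, _, _, truth = small_data
    expected = {
        n for n, c in truth.community_assignment.items() if c == truth.disease_community
    }
    carriers = {
        m for m, ds in small_bundle.disease.items() if "synthetic_carcinoma" in ds
    }
    assert carriers == expected


def test_clustered_pairs_lie_within_10kb(small_data, small_bundle):
    _, _, _, truth = small_data
    n_close = 0
    for a, b in truth.conserved_pairs:
        ca, sa, ea, _ = small_bundle.locations[a]
        cb, sb, eb, _ = small_bundle.locations[b]
        if ca == cb and abs(sb - ea) < 10_000:
            n_close += 1
            assert small_bundle.clusters[a] == small_bundle.clusters[b]
    assert n_close >= 1  # the configured fraction of pairs is clustered


def test_orthologous_sequences_share_seed_and_diverge_at_most_10_percent(
    small_config, small_data
):
    _, _, o, truth = small_data
    s1, s2 = generate_sequences(small_config, truth, mutation_rate=0.05)
    for h, m in o.pairs:
        assert s1.matures[h][1:7] == s2.matures[m][1:7]
        ph = s1.precursors[h.replace("miR", "mir")]
        pm = s2.precursors[m.replace("miR", "mir")]
        assert len(ph) == len(pm)
        diffs = sum(1 for x, y in zip(ph, pm) if x != y)
        assert diffs <= len(ph) // 10


def test_zero_mutation_rate_gives_identical_orthologous_sequences(small_config, small_data):
    _, _, o, truth = small_data
    s1, s2 = generate_sequences(small_config, truth, mutation_rate=0.0)
    for h, m in o.pairs:
        assert s1.precursors[h.replace("miR", "mir")] == s2.precursors[m.replace("miR", "mir")]


def test_random_sequences_have_quarter_identity(small_config, small_data):
    # non-orthologous sequences are independent uniform draws over 4 bases
    _, _, o, truth = small_data
    s1, s2 = generate_sequences(small_config, truth)
    non_ortho = [m for m in s2.matures if m not in {b for _, b in o.pairs}]
    idents = []
    h_ids = list(s1.matures)
    for i, m in enumerate(non_ortho):
        hm = s1.matures[h_ids[i % len(h_ids)]]
        mm = s2.matures[m]
        idents.append(np.mean([x == y for x, y in zip(hm, mm)]))
    assert abs(np.mean(idents) - 0.25) < 0.03


def test_community_network_is_dense_within_and_sparse_between(small_config, small_data):
    _, _, _, truth = small_data
    g = generate_community_network(small_config, truth, p_in=0.9, p_out=0.02)
    assert set(g.nodes) == set(truth.community_assignment)
    within = between = wtot = btot = 0
    nodes = sorted(g.nodes)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            same = truth.community_assignment[a] == truth.community_assignment[b]
            if same:
                wtot += 1
                within += g.has_edge(a, b)
            else:
                btot += 1
                between += g.has_edge(a, b)
    assert within / wtot > 0.75
    assert between / btot < 0.1
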