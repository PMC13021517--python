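import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.neighbors import NearestCentroid

from celldag import (
    Ontology,
    SimConfig,
    SyntheticAtlas,
    apply_inclusion_filters,
    coarsen_labels,
    generate_ontology,
    normalize,
    simulate_counts,
    split_id_ood,
)


def longest_path_from_root(ont):
    import networkx as nx

    g = nx.DiGraph(ont.edges).reverse()  # parent -> child
    if not g.nodes:
        return 0
    return nx.dag_longest_path_length(g)


class TestSimConfig:
    def test_invalid_gamma_names_the_field(self):
        with pytest.raises(ValueError, match="granularity_gamma"):
            SimConfig(granularity_gamma=1.5)

    def test_marker_budget_enforced(self):
        with pytest.raises(ValueError, match="n_genes"):
            SimConfig(n_leaves=8, markers_per_leaf=5, n_genes=30)

    def test_unknown_field_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            SimConfig.from_dict({"n_leaves": 4, "typo_field": 1})

    def test_dict_roundtrip(self):
        cfg = SimConfig(n_leaves=4, n_genes=32, markers_per_leaf=3)
        assert SimConfig.from_dict(cfg.to_dict()) == cfg


class TestGenerateOntology:
    def test_single_leaf_is_single_node(self):
        ont = generate_ontology(SimConfig(n_leaves=1, n_genes=8, markers_per_leaf=1))
        assert len(ont) == 1 and not ont.edges

    def test_leaf_count_and_depth_respected(self):
        for seed in range(5):
            cfg = SimConfig(n_leaves=8, max_depth=3, seed=seed)
            ont = generate_ontology(cfg)
            tax = ont.classify_nodes()
            assert int(tax.is_leaf.sum()) == 8
            assert longest_path_from_root(ont) <= 3

    def test_zero_extra_edge_prob_yields_a_tree(self):
        cfg = SimConfig(n_leaves=8, extra_edge_prob=0.0, seed=3)
        ont = generate_ontology(cfg)
        roots = 0
        for node in ont.node_ids:
            n_parents = len(ont.parents(node))
            roots += n_parents == 0
            assert n_parents <= 1
        assert roots == 1

    def test_extra_parents_keep_dag_and_leaf_set(self):
        cfg = SimConfig(n_leaves=10, max_depth=4, extra_edge_prob=0.8, seed=1)
        ont = generate_ontology(cfg)  # Ontology() raises on cycles
        assert int(ont.classify_nodes().is_leaf.sum()) == 10

    def test_same_seed_same_edges(self):
        cfg = SimConfig(seed=11)
        assert generate_ontology(cfg).edges == generate_ontology(cfg).edges

    def test_infeasible_depth_rejected(self):
        with pytest.raises(ValueError, match="max_depth"):
            generate_ontology(
                SimConfig(n_leaves=3, max_depth=0, n_genes=16, markers_per_leaf=1)
            )


class TestSimulateCounts:
    def test_poisson_limit_recovers_program_means(self):
        cfg = SimConfig(
            n_leaves=2,
            n_genes=16,
            markers_per_leaf=2,
            nb_dispersion=np.inf,
            study_effect_sd=0.0,
            n_studies=1,
            cells_per_study=6000,
            donors_per_study=2,
            library_size_target=800.0,
            seed=5,
        )
        dag = generate_ontology(cfg)
        atlas = simulate_counts(dag, cfg)
        leaves = sorted(set(atlas.true_label))
        # reconstruct a leaf's program mean from the generator's definition
        base = np.full(16, cfg.nb_mean)
        for i, leaf in enumerate(leaves):
            program = base.copy()
            program[i * 2 : (i + 1) * 2] *= cfg.marker_fold
            program *= cfg.library_size_target / program.sum()
            cells = atlas.counts[atlas.true_label == leaf].toarray()
            assert len(cells) >= 2500
            assert np.allclose(cells.mean(axis=0), program, rtol=0.05)

    def test_no_study_effect_means_match_across_studies(self):
        cfg = SimConfig(
            n_leaves=2,
            n_genes=16,
            markers_per_leaf=2,
            study_effect_sd=0.0,
            n_studies=2,
            cells_per_study=2000,
            seed=2,
        )
        atlas = simulate_counts(generate_ontology(cfg), cfg)
        from scipy.stats import ttest_ind

        leaf = sorted(set(atlas.true_label))[0]
        a = atlas.counts[
            (atlas.study_id == "study0") & (atlas.true_label == leaf)
        ].toarray()
        b = atlas.counts[
            (atlas.study_id == "study1") & (atlas.true_label == leaf)
        ].toarray()
        pvals = ttest_ind(a, b, axis=0).pvalue
        assert (pvals > 0.01 / len(pvals)).all()  # Bonferroni at alpha=0.01

    def test_markers_make_leaves_separable(self):
        cfg = SimConfig(
            n_leaves=4,
            n_genes=32,
            markers_per_leaf=4,
            marker_fold=20.0,
            nb_dispersion=np.inf,
            study_effect_sd=0.0,
            n_studies=1,
            cells_per_study=400,
            library_size_target=5000.0,
            seed=7,
        )
        atlas = simulate_counts(generate_ontology(cfg), cfg)
        x = np.asarray(normalize(atlas.counts).todense())
        clf = NearestCentroid().fit(x, atlas.true_label)
        assert (clf.predict(x) == atlas.true_label).all()

    def test_bitwise_reproducible(self):
        cfg = SimConfig(n_leaves=4, n_genes=24, markers_per_leaf=2, cells_per_study=50)
        dag = generate_ontology(cfg)
        a = simulate_counts(dag, cfg)
        b = simulate_counts(dag, cfg)
        assert (a.counts != b.counts).nnz == 0
        assert (a.true_label == b.true_label).all()


@pytest.fixture
def small_atlas():
    cfg = SimConfig(
        n_leaves=4, n_genes=24, markers_per_leaf=2, cells_per_study=100, seed=9
    )
    return simulate_counts(generate_ontology(cfg), cfg), cfg


class TestCoarsenLabels:
    def test_gamma_zero_is_identity(self, small_atlas):
        atlas, _ = small_atlas
        out = coarsen_labels(atlas, 0.0, seed=0)
        assert (out.observed_label == out.true_label).all()

    def test_gamma_one_coarsens_everything(self, small_atlas):
        atlas, _ = small_atlas
        out = coarsen_labels(atlas, 1.0, seed=0)
        assert (out.observed_label != out.true_label).all()
        for obs, true in zip(out.observed_label, out.true_label):
            assert obs in atlas.ontology.ancestors(true)

    def test_coarsened_fraction_near_gamma(self):
        cfg = SimConfig(
            n_leaves=4,
            n_genes=24,
            markers_per_leaf=2,
            n_studies=2,
            cells_per_study=5000,
            seed=1,
        )
        atlas = simulate_counts(generate_ontology(cfg), cfg)
        out = coarsen_labels(atlas, 0.5, seed=3)
        frac = (out.observed_label != out.true_label).mean()
        assert 0.48 < frac < 0.52

    def test_observed_is_self_or_ancestor_invariant(self, small_atlas):
        atlas, _ = small_atlas
        out = coarsen_labels(atlas, 0.6, seed=4)
        for obs, true in zip(out.observed_label, out.true_label):
            assert obs == true or obs in atlas.ontology.ancestors(true)


class TestSplit:
    def test_ood_is_exactly_the_held_out_study(self, small_atlas):
        atlas, _ = small_atlas
        train, id_test, ood = split_id_ood(atlas, ["study3"], seed=0)
        assert set(ood.study_id) == {"study3"}
        assert (ood.cell_ids == atlas.cell_ids[atlas.study_id == "study3"]).all()
        assert train.n_cells + id_test.n_cells + ood.n_cells == atlas.n_cells

    def test_donors_never_straddle_train_and_id_test(self, small_atlas):
        atlas, _ = small_atlas
        train, id_test, _ = split_id_ood(atlas, ["study3"], seed=0)
        assert not (set(train.donor_id) & set(id_test.donor_id))

    def test_empty_and_full_holdouts_rejected(self, small_atlas):
        atlas, _ = small_atlas
        with pytest.raises(ValueError, match="nonempty"):
            split_id_ood(atlas, [])
        with pytest.raises(ValueError, match="every study"):
            split_id_ood(atlas, atlas.studies)
        with pytest.raises(ValueError, match="unknown"):
            split_id_ood(atlas, ["study99"])


class TestNormalize:
    def test_closed_form_small_cell(self):
        out = normalize(np.array([[1.0, 1.0, 2.0]]))
        assert np.allclose(out, np.log([2501, 2501, 5001]))

    def test_zero_gene_column_stays_zero(self):
        out = normalize(np.array([[1.0, 0.0], [3.0, 0.0]]))
        assert (out[:, 1] == 0).all()

    def test_cell_already_at_target_only_logs(self):
        counts = np.array([[4000.0, 6000.0]])
        assert np.allclose(normalize(counts), np.log1p(counts))

    def test_sparse_and_dense_agree(self, rng):
        counts = rng.integers(0, 20, size=(10, 8)) + 1
        dense = normalize(counts)
        sparse = normalize(sp.csr_matrix(counts))
        assert np.allclose(np.asarray(sparse.todense()), dense)

    def test_zero_cell_rejected_with_ids(self):
        counts = np.array([[1.0, 2.0], [0.0, 0.0]])
        with pytest.raises(ValueError, match="cellB"):
            normalize(counts, cell_ids=["cellA", "cellB"])


def _dummy_atlas(labels, donors):
    n = len(labels)
    ont = Ontology(sorted(set(labels)))
    return SyntheticAtlas(
        counts=sp.csr_matrix(np.ones((n, 1))),
        cell_ids=np.array([f"c{i}" for i in range(n)]),
        gene_ids=np.array(["g0"]),
        true_label=np.array(labels),
        observed_label=np.array(labels),
        study_id=np.array(["s0"] * n),
        donor_id=np.array(donors),
        ontology=ont,
    )


class TestInclusionFilters:
    def test_zero_thresholds_are_identity(self, small_atlas):
        atlas, _ = small_atlas
        out, dropped = apply_inclusion_filters(atlas, 0, 0)
        assert out.n_cells == atlas.n_cells and not dropped

    def test_cell_count_boundary(self):
        labels = ["keep"] * 5000 + ["drop"] * 4999
        donors = [f"d{i % 40}" for i in range(len(labels))]
        atlas = _dummy_atlas(labels, donors)
        out, dropped = apply_inclusion_filters(atlas, min_cells=5000, min_donors=30)
        assert set(out.observed_label) == {"keep"}
        assert "drop" in dropped and "4999 cells" in dropped["drop"]

    def test_donor_count_boundary(self):
        labels = ["ok"] * 60 + ["few"] * 60
        donors = [f"d{i % 30}" for i in range(60)] + [f"e{i % 29}" for i in range(60)]
        atlas = _dummy_atlas(labels, donors)
        out, dropped = apply_inclusion_filters(atlas, min_cells=50, min_donors=30)
        assert set(out.observed_label) == {"ok"}
        assert "29 donors" in dropped["few"]

    def test_dropping_everything_rejected(self, small_atlas):
        atlas, _ = small_atlas
        with pytest.raises(ValueError, match="every class"):
            apply_inclusion_filters(atlas, min_cells=10**6, min_donors=1)


class TestAtlasIO:
    def test_disk_roundtrip(self, tmp_path, small_atlas):
        atlas, _ = small_atlas
        atlas.write(tmp_path)
        loaded = SyntheticAtlas.read(tmp_path)
        assert (loaded.counts != atlas.counts).nnz == 0
        assert (loaded.observed_label == atlas.observed_label).all()
        assert loaded.ontology.node_ids == atlas.ontology.node_ids
        assert loaded.ontology.edges == atlas.ontology.edges
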