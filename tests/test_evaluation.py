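import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gagam import (
    ClusterAssignment,
    GeneSetPair,
    ami,
    ari,
    cluster_cells,
    gini,
    lsi_embed,
    ragi,
    rank_differential_activity,
)

from oracles import oracle_ami, oracle_ari, oracle_gini


def _ca(labels):
    return ClusterAssignment([f"c{i}" for i in range(len(labels))], np.array(labels))


class TestAgreementMetrics:
    def test_identical_partitions_score_one(self):
        a = _ca([0, 0, 1, 1, 2])
        assert ari(a, a) == pytest.approx(1.0)
        assert ami(a, a) == pytest.approx(1.0)

    def test_relabeling_invariance(self):
        a, b = _ca([0, 0, 1, 1]), _ca([1, 1, 0, 0])
        assert ari(a, b) == pytest.approx(1.0)
        assert ami(a, b) == pytest.approx(1.0)

    def test_all_ones_contingency_case(self):
        # contingency table of all ones: ARI = -0.5 under the adjustment
        a, b = _ca([0, 0, 1, 1]), _ca([0, 1, 0, 1])
        assert ari(a, b) == pytest.approx(-0.5)
        assert oracle_ari([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(-0.5)

    def test_single_cluster_has_zero_ami(self):
        a, b = _ca([0, 0, 0, 0]), _ca([0, 1, 0, 1])
        assert ami(a, b) == pytest.approx(0.0)

    def test_mismatched_cells_rejected(self):
        a = _ca([0, 1])
        b = ClusterAssignment(["x", "y"], np.array([0, 1]))
        with pytest.raises(ValueError):
            ari(a, b)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_contingency_formula_oracles(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 14))
        la = rng.integers(0, 3, n).tolist()
        lb = rng.integers(0, 3, n).tolist()
        assert ari(_ca(la), _ca(lb)) == pytest.approx(oracle_ari(la, lb), abs=1e-10)
        assert ami(_ca(la), _ca(lb)) == pytest.approx(oracle_ami(la, lb), abs=1e-8)


class TestGini:
    @pytest.mark.parametrize(
        "values, expected",
        [((1, 1, 1, 1), 0.0), ((1, 0, 0, 0), 0.75), ((0, 0, 0), 0.0)],
    )
    def test_closed_forms(self, values, expected):
        assert gini(values) == pytest.approx(expected, abs=1e-12)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            gini([1.0, -0.1])

    @settings(max_examples=40, derandomize=True)
    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=12),
        st.floats(0.1, 10),
    )
    def test_scale_invariance_and_oracle_agreement(self, values, c):
        g = gini(values)
        assert g == pytest.approx(oracle_gini(values), abs=1e-9)
        assert gini([c * v for v in values]) == pytest.approx(g, abs=1e-9)


class TestLsiAndClustering:
    def test_block_matrix_separates_groups(self):
        # two perfectly separated cell groups over 4 features; within-group
        # embedding distances must be far smaller than between-group ones
        M = np.array(
            [[5, 4, 0, 0], [4, 5, 0, 0], [0, 0, 7, 2], [0, 0, 2, 7]], dtype=float
        )
        emb = lsi_embed(M, n_components=2, drop_first=False)
        within = max(
            np.linalg.norm(emb[0] - emb[1]), np.linalg.norm(emb[2] - emb[3])
        )
        between = min(
            np.linalg.norm(emb[i] - emb[j]) for i in (0, 1) for j in (2, 3)
        )
        assert between > 2 * within

    def test_duplicating_cells_preserves_relative_distances(self):
        rng = np.random.default_rng(0)
        M = rng.random((6, 5)) + 0.1
        emb1 = lsi_embed(M, n_components=3, drop_first=False)
        emb2 = lsi_embed(np.hstack([M, M]), n_components=3, drop_first=False)[:5]

        def dists(e):
            d = np.linalg.norm(e[:, None, :] - e[None, :, :], axis=-1)
            return d / d.max()

        np.testing.assert_allclose(dists(emb1[:5]), dists(emb2), atol=1e-6)

    def test_rank_one_matrix_reconstructs(self):
        M = np.outer([1.0, 2.0, 3.0], [1.0, 1.0, 2.0, 4.0])
        emb = lsi_embed(M, n_components=1, drop_first=False)
        assert emb.shape == (4, 1)
        assert np.abs(emb).min() > 0

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            lsi_embed(np.zeros((4, 4)), n_components=2)

    def test_kmeans_recovers_blobs_and_is_deterministic(self):
        rng = np.random.default_rng(1)
        blob1 = rng.normal(0, 0.2, (20, 2))
        blob2 = rng.normal(5, 0.2, (20, 2))
        X = np.vstack([blob1, blob2])
        cells = [f"c{i}" for i in range(40)]
        a = cluster_cells(X, cells, "kmeans", param=2, seed=0)
        b = cluster_cells(X, cells, "kmeans", param=2, seed=0)
        assert (a.labels == b.labels).all()
        truth = _ca([0] * 20 + [1] * 20)
        assert ari(a, truth) == pytest.approx(1.0)

    def test_k_larger_than_cells_rejected(self):
        with pytest.raises(ValueError):
            cluster_cells(np.zeros((3, 2)), ["a", "b", "c"], "kmeans", param=5, seed=0)

    def test_leiden_runs_and_is_deterministic(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 0.1, (15, 3)), rng.normal(4, 0.1, (15, 3))])
        cells = [f"c{i}" for i in range(30)]
        a = cluster_cells(X, cells, "leiden", param=1.0, seed=0)
        b = cluster_cells(X, cells, "leiden", param=1.0, seed=0)
        assert (a.labels == b.labels).all()
        assert a.n_clusters >= 2


class TestRagi:
    def test_marker_concentration_minus_uniform_housekeeping(self):
        # 4 clusters of 2 cells; marker active only in cluster 0
        X = np.array(
            [
                [1, 1, 0, 0, 0, 0, 0, 0],  # marker: cluster means (1,0,0,0)
                [1, 1, 1, 1, 1, 1, 1, 1],  # housekeeping: uniform
            ],
            dtype=float,
        )
        clusters = _ca([0, 0, 1, 1, 2, 2, 3, 3])
        sets = GeneSetPair({"M"}, {"H"})
        score, p, per_gene = ragi(X, ["M", "H"], clusters, sets)
        assert score == pytest.approx(0.75)
        assert per_gene["M"] == pytest.approx(0.75)
        assert per_gene["H"] == pytest.approx(0.0)

    def test_identical_profiles_give_zero(self):
        X = np.tile([1.0, 2.0, 1.0, 2.0], (4, 1))
        clusters = _ca([0, 0, 1, 1])
        sets = GeneSetPair({"a", "b"}, {"c", "d"})
        score, p, _ = ragi(X, ["a", "b", "c", "d"], clusters, sets)
        assert score == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_single_cluster_rejected(self):
        X = np.ones((2, 4))
        with pytest.raises(ValueError, match="2 clusters"):
            ragi(X, ["a", "b"], _ca([0, 0, 0, 0]), GeneSetPair({"a"}, {"b"}))

    def test_absent_markers_rejected(self):
        X = np.ones((1, 4))
        with pytest.raises(ValueError, match="marker"):
            ragi(X, ["h"], _ca([0, 0, 1, 1]), GeneSetPair({"missing"}, {"h"}))

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError):
            GeneSetPair({"a"}, {"a", "b"})

    def test_planted_markers_yield_positive_significant_ragi(self):
        rng = np.random.default_rng(5)
        n_per = 20
        clusters = _ca([0] * 10 + [1] * 10 + [2] * 10)
        genes, rows = [], []
        for i in range(n_per):  # markers: concentrated in one cluster
            t = i % 3
            row = rng.uniform(0, 0.1, 30)
            row[10 * t : 10 * (t + 1)] += 1.0
            genes.append(f"m{i}")
            rows.append(row)
        for i in range(n_per):  # housekeeping: flat
            genes.append(f"h{i}")
            rows.append(rng.uniform(0.9, 1.1, 30))
        X = np.vstack(rows)
        sets = GeneSetPair({f"m{i}" for i in range(n_per)}, {f"h{i}" for i in range(n_per)})
        score, p, _ = ragi(X, genes, clusters, sets)
        assert score > 0
        assert p < 0.05


class TestDifferentialActivity:
    def test_exclusive_gene_tops_its_cluster(self):
        X = np.array(
            [
                [1, 1, 0, 0, 0, 0],
                [0, 0, 1, 1, 0, 0],
                [0, 0, 0, 0, 1, 1],
                [0.5, 0.5, 0.5, 0.5, 0.5, 0.5],
            ]
        )
        genes = ["gA", "gB", "gC", "flat"]
        clusters = _ca([0, 0, 1, 1, 2, 2])
        table = rank_differential_activity(X, genes, clusters, top_n=2)
        tops = table[table["rank"] == 1].set_index("cluster")["gene"]
        assert tops[0] == "gA" and tops[1] == "gB" and tops[2] == "gC"

    def test_constant_gene_never_outranks_informative_ones(self):
        X = np.array([[1, 1, 0, 0], [0.5, 0.5, 0.5, 0.5]])
        table = rank_differential_activity(X, ["g", "flat"], _ca([0, 0, 1, 1]), top_n=1)
        assert (table[table["cluster"] == 0]["gene"] == "g").all()

    def test_planted_simulation_markers_rank_first(self):
        from gagam import SimulationConfig, build_gagam, simulate

        cfg = SimulationConfig(
            n_genes=9, n_celltypes=3, cells_per_type=30, marker_genes_per_type=1, seed=3
        )
        ds = simulate(cfg)
        gam, _ = build_gagam(ds.D, ds.annotation, ds.truth_connections)
        table = rank_differential_activity(gam.gagam, gam.gene_ids, ds.truth_labels)
        tops = table[table["rank"] == 1].set_index("cluster")["gene"]
        # marker gene of type t is gene index t (one marker per type)
        for t in range(3):
            assert tops[t] == f"G{t:03d}"
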