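"""The per-sample pipeline: PCA, kNN graph, walktrap, cuts, recuts, aggregation."""

import numpy as np
import pandas as pd
import pytest

from cellpool import (
    CoreParams,
    ExpressionTable,
    IntegrityError,
    MergeDendrogram,
    ParameterError,
    aggregate_expression,
    build_knn_graph,
    compute_pca,
    cut_to_k,
    recut,
    supercells_for_sample,
    target_supercell_count,
    walktrap_dendrogram,
)
from cellpool.core import KNNGraph, _allocate_groups

from helpers import best_modularity_bipartition


class TestPCA:
    def test_default_components_capped_at_ten(self, rng):
        scores = compute_pca(rng.normal(size=(30, 12)), n_pcs=10)
        assert scores.n_components == 10

    def test_fewer_markers_than_pcs_uses_marker_count(self, rng):
        scores = compute_pca(rng.normal(size=(30, 8)), n_pcs=10)
        assert scores.n_components == 8

    def test_single_varying_marker_dominates_first_component(self, rng):
        X = np.full((20, 4), 2.0)
        X[:, 2] = rng.normal(size=20)
        scores = compute_pca(X, n_pcs=4)
        centred = X[:, 2] - X[:, 2].mean()
        # equal up to sign
        sign = np.sign(np.dot(scores.scores[:, 0], centred))
        np.testing.assert_allclose(scores.scores[:, 0] * sign, centred, atol=1e-10)
        np.testing.assert_allclose(scores.explained_variance[1:], 0, atol=1e-10)

    def test_variances_match_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(6, 3)) @ np.diag([3.0, 1.0, 0.2])
        scores = compute_pca(X, n_pcs=3)
        eig = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
        np.testing.assert_allclose(scores.explained_variance, eig, rtol=1e-10)
        assert (np.diff(scores.explained_variance) <= 1e-12).all()

    def test_invalid_n_pcs_rejected(self, rng):
        with pytest.raises(ParameterError):
            compute_pca(rng.normal(size=(5, 3)), n_pcs=0)


class TestKNNGraph:
    def test_line_points_match_exhaustive_oracle(self):
        X = np.array([[0.0], [1.0], [2.0], [4.0]])
        g = build_knn_graph(X, k=1)
        assert set(map(tuple, g.edges)) == {(0, 1), (1, 2), (2, 3)}

    def test_two_points_single_edge(self):
        g = build_knn_graph(np.array([[0.0], [1.0]]), k=1)
        assert set(map(tuple, g.edges)) == {(0, 1)}

    def test_duplicated_points_tie_broken_by_lowest_index(self):
        X = np.array([[0.0], [0.0], [1.0]])
        g = build_knn_graph(X, k=1)
        # node 2 ties between nodes 0 and 1; lowest index wins; graph simple
        assert set(map(tuple, g.edges)) == {(0, 1), (0, 2)}
        assert len(g.edges) == len(set(map(tuple, g.edges)))

    def test_k_too_large_rejected_with_instruction(self):
        with pytest.raises(ParameterError, match="lower k"):
            build_knn_graph(np.zeros((3, 2)), k=3)

    def test_union_symmetrisation_degree_floor(self, rng):
        g = build_knn_graph(rng.normal(size=(50, 3)), k=5)
        assert (g.degrees() >= 5).all()
        # no self loops
        assert (g.edges[:, 0] != g.edges[:, 1]).all()

    def test_matches_brute_force_oracle_on_random_points(self, rng):
        X = rng.normal(size=(40, 2))
        g = build_knn_graph(X, k=3)
        d = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        np.fill_diagonal(d, np.inf)
        expected = set()
        for i in range(40):
            for j in np.argsort(d[i])[:3]:
                expected.add((min(i, j), max(i, j)))
        assert set(map(tuple, g.edges)) == expected


def _clique_pair_graph():
    edges = (
        [(i, j) for i in range(5) for j in range(i + 1, 5)]
        + [(i, j) for i in range(5, 10) for j in range(i + 1, 10)]
        + [(4, 5)]
    )
    return KNNGraph(n=10, k=4, edges=np.array(edges))


class TestWalktrap:
    def test_single_node_empty_merge_list(self):
        d = walktrap_dendrogram(KNNGraph(n=1, k=1, edges=np.empty((0, 2), int)))
        assert d.components == [{"nodes": [0], "merges": []}]

    def test_two_cliques_cut_at_two_recovers_cliques(self):
        g = _clique_pair_graph()
        d = walktrap_dendrogram(g, steps=4, sample_id="S")
        part = cut_to_k(d, 2)
        found = {
            frozenset(map(int, grp))
            for grp in part.mapping.groupby("supercell_id")["cell_id"].apply(list)
        }
        oracle = best_modularity_bipartition(10, [tuple(e) for e in g.edges])
        assert found == {frozenset(map(int, s)) for s in oracle}
        assert found == {frozenset(range(5)), frozenset(range(5, 10))}

    def test_triangle_cut_at_three_gives_singletons(self):
        g = KNNGraph(n=3, k=1, edges=np.array([(0, 1), (1, 2), (0, 2)]))
        d = walktrap_dendrogram(g)
        part = cut_to_k(d, 3)
        assert part.n_supercells == 3

    def test_disconnected_graph_handled_per_component(self):
        # two triangles, no connection
        edges = np.array([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        d = walktrap_dendrogram(KNNGraph(n=6, k=2, edges=edges))
        assert d.n_components == 2
        assert sum(len(c["merges"]) for c in d.components) == 6 - 2

    def test_merge_count_invariant(self, rng):
        g = build_knn_graph(rng.normal(size=(60, 3)), k=3)
        d = walktrap_dendrogram(g)
        assert sum(len(c["merges"]) for c in d.components) == 60 - d.n_components


class TestCut:
    @pytest.fixture
    def dendro(self):
        return walktrap_dendrogram(_clique_pair_graph(), sample_id="S")

    def test_cut_at_n_gives_singletons(self, dendro):
        assert cut_to_k(dendro, 10).n_supercells == 10

    def test_cut_at_component_count_gives_one_group(self, dendro):
        part = cut_to_k(dendro, 1)
        assert part.n_supercells == 1

    @pytest.mark.parametrize("k", range(1, 11))
    def test_every_level_yields_exactly_k(self, dendro, k):
        assert cut_to_k(dendro, k).n_supercells == k

    def test_out_of_range_reports_bounds(self, dendro):
        with pytest.raises(ParameterError, match=r"\[1, 10\]"):
            cut_to_k(dendro, 11)

    def test_labels_ordered_by_smallest_member(self, dendro):
        part = cut_to_k(dendro, 2)
        first = part.mapping.loc[part.mapping["cell_id"] == "0", "supercell_id"].iloc[0]
        assert first == "S_SC_1"

    def test_allocation_largest_remainder(self):
        # components of sizes 7 and 3, k=5 -> quotas 3.5 / 1.5 -> 4 / 1? No:
        # floors 3/1, one leftover goes to the larger remainder (tie -> lower
        # index): 4/1... both remainders 0.5, tie broken to component 0.
        assert _allocate_groups([7, 3], 5) == [4, 1]
        assert _allocate_groups([8, 2], 5) == [4, 1]
        assert _allocate_groups([5, 5], 4) == [2, 2]
        assert _allocate_groups([1, 9], 5) == [1, 4]


class TestTargetCount:
    @pytest.mark.parametrize(
        "n,gamma,expected",
        [
            (85_715, 20, 4_286),  # round-half-up: 4285.75 -> 4286
            (841_644, 20, 42_082),  # 42082.2 -> 42082
            (10, 20, 1),  # clamped to 1
            (50, 20, 3),  # 2.5 rounds up (half-up)
            (100, 1, 100),  # gamma 1: every cell its own supercell
        ],
    )
    def test_rounding_and_clamping(self, n, gamma, expected):
        assert target_supercell_count(n, gamma, 1) == expected

    def test_lower_clamp_to_components(self):
        assert target_supercell_count(100, 50, 5) == 5


class TestEndToEnd:
    def test_supercell_count_matches_formula(self, mixture_table):
        sub = mixture_table.restrict_to_sample("S1")
        part, dendro = supercells_for_sample(sub, CoreParams(gamma=20, seed=3))
        expected = target_supercell_count(sub.n_cells, 20, dendro.n_components)
        assert part.n_supercells == expected

    def test_gamma_one_identity(self, tiny_table):
        part, _ = supercells_for_sample(tiny_table, CoreParams(gamma=1, seed=0))
        assert part.n_supercells == tiny_table.n_cells
        expr = aggregate_expression(tiny_table, part)
        np.testing.assert_array_equal(
            expr.data[tiny_table.markers].to_numpy(),
            tiny_table.data[tiny_table.markers].to_numpy(),
        )
        assert (expr.data["n_cells"] == 1).all()

    def test_single_cell_sample(self):
        df = pd.DataFrame({"cell_id": ["a"], "sample_id": ["S"], "m": [1.0]})
        part, _ = supercells_for_sample(
            ExpressionTable(df, ["m"]), CoreParams(gamma=20, seed=0)
        )
        assert part.n_supercells == 1

    def test_multi_sample_input_rejected(self, mixture_table):
        with pytest.raises(ParameterError, match="one sample"):
            supercells_for_sample(mixture_table, CoreParams())

    def test_determinism_same_seed_same_partition(self, mixture_table):
        sub = mixture_table.restrict_to_sample("S2")
        p1, _ = supercells_for_sample(sub, CoreParams(gamma=15, seed=11))
        p2, _ = supercells_for_sample(sub, CoreParams(gamma=15, seed=11))
        pd.testing.assert_frame_equal(p1.mapping, p2.mapping)


@pytest.fixture(scope="module")
def sample_run(mixture_table):
    sub = mixture_table.restrict_to_sample("S1")
    params = CoreParams(gamma=20, seed=3)
    part, dendro = supercells_for_sample(sub, params)
    return sub, params, part, dendro


class TestRecut:
    def test_recut_at_original_gamma_is_identical(self, sample_run):
        _, params, part, dendro = sample_run
        pd.testing.assert_frame_equal(recut(dendro, params.gamma).mapping, part.mapping)

    def test_recut_is_stateless(self, sample_run):
        _, _, _, dendro = sample_run
        once = recut(dendro, 10)
        recut(dendro, 20)
        again = recut(dendro, 10)
        pd.testing.assert_frame_equal(once.mapping, again.mapping)

    def test_recut_equals_fresh_run(self, sample_run):
        sub, params, _, dendro = sample_run
        fresh, _ = supercells_for_sample(
            sub, CoreParams(gamma=10, seed=params.seed)
        )
        pd.testing.assert_frame_equal(recut(dendro, 10).mapping, fresh.mapping)

    def test_store_round_trip_and_checksum(self, sample_run, tmp_path):
        sub, _, part, dendro = sample_run
        path = dendro.save(tmp_path / "store.json")
        loaded = MergeDendrogram.load(path)
        loaded.verify_against(sub)
        pd.testing.assert_frame_equal(recut(loaded, 20).mapping, part.mapping)

    def test_checksum_mismatch_refused(self, sample_run, tmp_path):
        sub, _, _, dendro = sample_run
        tampered = ExpressionTable(
            sub.data.assign(M1=sub.data["M1"] + 1.0), sub.markers
        )
        with pytest.raises(IntegrityError, match="checksum"):
            dendro.verify_against(tampered)


class TestAggregation:
    def test_singleton_supercell_equals_cell(self, tiny_table):
        part, _ = supercells_for_sample(tiny_table, CoreParams(gamma=1, seed=0))
        expr = aggregate_expression(tiny_table, part)
        row = expr.data.iloc[0]
        cell = tiny_table.data.iloc[0]
        for m in tiny_table.markers:
            assert row[m] == cell[m]

    @pytest.mark.parametrize(
        "values,how,expected", [([1.0, 3.0], "mean", 2.0), ([1.0, 2.0, 9.0], "median", 2.0)]
    )
    def test_mean_and_median_arithmetic(self, values, how, expected):
        df = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(len(values))],
                "sample_id": "S",
                "m": values,
            }
        )
        table = ExpressionTable(df, ["m"])
        mapping = pd.DataFrame(
            {"cell_id": df["cell_id"], "sample_id": "S", "supercell_id": "S_SC_1"}
        )
        from cellpool import SupercellPartition

        expr = aggregate_expression(table, SupercellPartition(mapping), how)
        assert expr.data["m"].iloc[0] == expected
        assert expr.data["n_cells"].iloc[0] == len(values)

    def test_weighted_mean_conservation(self, rng):
        n = 1000
        df = pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(n)],
                "sample_id": "S",
                "m1": rng.normal(size=n),
                "m2": rng.exponential(size=n),
            }
        )
        table = ExpressionTable(df, ["m1", "m2"])
        part, _ = supercells_for_sample(table, CoreParams(gamma=20, seed=1))
        expr = aggregate_expression(table, part)
        for m in table.markers:
            total = (expr.data[m] * expr.data["n_cells"]).sum()
            assert total == pytest.approx(df[m].sum(), rel=1e-9)

    def test_cell_missing_from_partition_named(self, tiny_table):
        from cellpool import SupercellPartition

        mapping = pd.DataFrame(
            {
                "cell_id": ["c0", "c1", "c2", "c3", "c4"],
                "sample_id": "S1",
                "supercell_id": "S1_SC_1",
            }
        )
        with pytest.raises(IntegrityError, match="c5"):
            aggregate_expression(tiny_table, SupercellPartition(mapping))

    def test_partition_totality_and_confinement(self, mixture_table, default_params):
        from cellpool import run_all_samples

        res = run_all_samples(mixture_table, default_params)
        assert set(res.partition.mapping["cell_id"]) == set(
            mixture_table.data["cell_id"]
        )
        spans = res.partition.mapping.groupby("supercell_id")["sample_id"].nunique()
        assert (spans == 1).all()
        # member counts conserve per sample
        per_sample = res.expression.data.groupby("sample_id")["n_cells"].sum()
        counts = mixture_table.data["sample_id"].value_counts()
        assert per_sample.to_dict() == counts.to_dict()
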