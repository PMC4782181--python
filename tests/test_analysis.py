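"""Hubs, connectivity comparison, enrichment, outliers, and scaling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wtonet import (
    ConsensusNetwork,
    WTONetwork,
    align_networks,
    benjamini_hochberg,
    classical_mds,
    compare_connectivity,
    dataset_scaling,
    degrees,
    hubs,
    overlap_enrichment,
    wto_outliers,
)
from wtonet.analysis import adjust_batch


def consensus_of(edges):
    df = pd.DataFrame(edges, columns=["grf_a", "grf_b", "median_wto"])
    df["p_value"] = 0.01
    df["n_present"] = 10
    df["sign_consistent"] = True
    return ConsensusNetwork(links=df, threshold_used=0.3, alpha_used=0.05)


class TestDegrees:
    def test_star_hub_at_floor(self):
        edges = [("HUB", f"L{i:02d}", 0.5) for i in range(26)]
        net = consensus_of(edges)
        deg = degrees(net)
        assert deg["HUB"] == 26
        assert hubs(deg, 25) == ["HUB"]
        assert hubs(deg, 26) == []  # strictly greater than the floor

    def test_empty_network(self):
        deg = degrees(consensus_of([]))
        assert deg.empty and hubs(deg) == []

    def test_mixed_sign_edges_count(self):
        net = consensus_of([("A", "B", 0.5), ("A", "C", -0.6)])
        assert degrees(net)["A"] == 2

    def test_wto_network_requires_cutoff(self):
        omega = np.array([[0.0, 0.5], [0.5, 0.0]])
        net = WTONetwork(["A", "B"], omega)
        with pytest.raises(ValueError):
            degrees(net)
        assert degrees(net, cutoff=0.3)["A"] == 1
        assert degrees(net, cutoff=0.6)["A"] == 0


class TestCompareConnectivity:
    def test_fully_separated_exact(self):
        deg = pd.Series(
            {"a1": 10, "a2": 11, "a3": 12, "b1": 1, "b2": 2, "b3": 3}
        )
        p = compare_connectivity(deg, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert p == pytest.approx(1 / 20)  # 1 / C(6,3)

    def test_identical_multisets_near_half(self):
        deg = pd.Series({f"a{i}": i for i in range(6)} | {f"b{i}": i for i in range(6)})
        p = compare_connectivity(deg, [f"a{i}" for i in range(6)], [f"b{i}" for i in range(6)])
        assert 0.4 < p < 0.65

    def test_one_vs_one(self):
        deg = pd.Series({"a": 5, "b": 1})
        assert compare_connectivity(deg, ["a"], ["b"]) == pytest.approx(0.5)

    def test_group_validation(self):
        deg = pd.Series({"a": 1, "b": 2})
        with pytest.raises(ValueError, match="overlap"):
            compare_connectivity(deg, ["a"], ["a", "b"])
        with pytest.raises(ValueError, match="non-empty"):
            compare_connectivity(deg, [], ["b"])
        with pytest.raises(ValueError, match="absent"):
            compare_connectivity(deg, ["a"], ["zzz"])


class TestOverlapEnrichment:
    def test_closed_form_hypergeometric(self):
        # background 20, |b| = 5, |a| = 4, overlap 4:
        # P(X >= 4) = C(5,4) C(15,0) / C(20,4) = 5 / 4845
        bg = [f"g{i}" for i in range(20)]
        res = overlap_enrichment(bg[:4], bg[:5], bg, n_perm=0)
        assert res.p_hyper == pytest.approx(5 / 4845)
        assert res.overlap_k == 4

    def test_disjoint_sets_p_one(self):
        bg = [f"g{i}" for i in range(10)]
        res = overlap_enrichment(bg[:3], bg[5:8], bg, n_perm=0)
        assert res.p_hyper == pytest.approx(1.0)
        assert res.overlap_k == 0

    def test_matches_fisher_exact_on_random_tables(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            N = int(rng.integers(10, 60))
            bg = [f"g{i}" for i in range(N)]
            na, nb = int(rng.integers(1, N)), int(rng.integers(1, N))
            a = list(rng.choice(bg, size=na, replace=False))
            b = list(rng.choice(bg, size=nb, replace=False))
            res = overlap_enrichment(a, b, bg, n_perm=0)
            k = res.overlap_k
            table = [[k, na - k], [nb - k, N - na - nb + k]]
            _, p_fisher = stats.fisher_exact(table, alternative="greater")
            assert res.p_hyper == pytest.approx(p_fisher, rel=1e-9)

    def test_permutation_p_agrees_with_analytic(self):
        rng = np.random.default_rng(7)
        bg = [f"g{i}" for i in range(40)]
        a = list(rng.choice(bg, size=12, replace=False))
        b = list(rng.choice(bg, size=15, replace=False))
        res = overlap_enrichment(a, b, bg, n_perm=10000, seed=0)
        # permutation null of the external resampling is hypergeometric
        assert res.p_perm_external == pytest.approx(res.p_hyper, abs=0.02)
        assert res.p_perm_internal == pytest.approx(res.p_hyper, abs=0.02)

    def test_outside_background_rejected(self):
        with pytest.raises(ValueError, match="alien"):
            overlap_enrichment(["alien"], ["g1"], ["g1", "g2"])

    def test_haldane_correction_on_zero_cell(self):
        bg = [f"g{i}" for i in range(10)]
        res = overlap_enrichment(bg[:3], bg[:3], bg, n_perm=0)
        assert np.isfinite(res.odds_ratio) and res.odds_ratio > 1


class TestBenjaminiHochberg:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )
        # distinct case, step-up by hand: sorted q = (0.04, 0.06, 0.0533, 0.5),
        # right-to-left minimum caps 0.06 at 0.0533
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.04, 0.03, 0.5]),
            [0.04, 0.16 / 3, 0.16 / 3, 0.5],
        )

    def test_single_and_equal(self):
        np.testing.assert_allclose(benjamini_hochberg([0.2]), [0.2])
        np.testing.assert_allclose(benjamini_hochberg([0.1] * 5), [0.1] * 5)

    def test_bounds_and_order_preserved(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=50)
        q = benjamini_hochberg(p)
        assert np.all(q >= p) and np.all(q <= 1.0)
        # adjusting a reordered copy gives the same values reordered
        perm = rng.permutation(50)
        np.testing.assert_allclose(benjamini_hochberg(p[perm]), q[perm])

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    def test_adjust_batch_fills_results(self):
        bg = [f"g{i}" for i in range(20)]
        r1 = overlap_enrichment(bg[:4], bg[:5], bg, n_perm=0)
        r2 = overlap_enrichment(bg[:3], bg[10:], bg, n_perm=0)
        out = adjust_batch([r1, r2])
        assert out[0].p_adjusted == pytest.approx(
            benjamini_hochberg([r1.p_hyper, r2.p_hyper])[0]
        )


class TestWtoOutliers:
    def test_gross_outlier(self):
        res = wto_outliers([1, 2, 3, 4, 100])
        np.testing.assert_array_equal(res.outliers, [100])
        assert res.count == 1

    def test_uniform_grid_no_outliers(self):
        assert wto_outliers(np.linspace(-1, 1, 21)).count == 0

    def test_fixed_11_values_hand_computed_hinges(self):
        # sorted: 1..10 and 50; hinges: Q1 = (3+4)/2 = 3.5, Q3 = (8+9)/2 = 8.5,
        # IQR = 5, fences [-4, 16] -> only 50 is outside
        v = [7, 1, 50, 3, 9, 2, 8, 4, 10, 5, 6]
        res = wto_outliers(v)
        assert (res.q1, res.q3) == (3.5, 8.5)
        assert (res.lower_fence, res.upper_fence) == (-4.0, 16.0)
        np.testing.assert_array_equal(res.outliers, [50])

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        v = rng.standard_cauchy(200)
        assert wto_outliers(v).count == wto_outliers(rng.permutation(v)).count

    def test_matches_r_boxplot_stats_convention(self):
        # cross-checked against R boxplot.stats(c(1:10, 50))$out -> 50
        res = wto_outliers(list(range(1, 11)) + [50])
        np.testing.assert_array_equal(res.outliers, [50])

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            wto_outliers([1, 2, 3])


def _stack_of(columns):
    """Stack with full pair universe from per-dataset omega vectors."""
    from wtonet.consensus import WTOStack

    pairs = [(f"A{i}", f"B{i}") for i in range(len(next(iter(columns.values()))))]
    df = pd.DataFrame(columns, index=pd.MultiIndex.from_tuples(pairs))
    return WTOStack(values=df)


class TestDatasetScaling:
    def test_identical_datasets_distance_zero(self):
        v = np.linspace(-0.5, 0.5, 12)
        stack = _stack_of({"d1": v, "d2": v, "d3": v + 0.1})
        comp = dataset_scaling(stack)
        assert comp.distances.loc["d1", "d2"] == pytest.approx(0.0)
        # coincident points in the embedding
        np.testing.assert_allclose(
            comp.coordinates.loc["d1"], comp.coordinates.loc["d2"], atol=1e-8
        )

    def test_triangle_distances_reproduced(self):
        # construct three vectors with pairwise distances 3, 4, 5
        v1 = np.zeros(2)
        v2 = np.array([3.0, 0.0])
        v3 = np.array([3.0, 4.0])
        stack = _stack_of({"d1": v1, "d2": v2, "d3": v3})
        comp = dataset_scaling(stack)
        X = comp.coordinates.to_numpy()
        for (i, a), (j, b) in [((0, "d1"), (1, "d2")), ((0, "d1"), (2, "d3")),
                               ((1, "d2"), (2, "d3"))]:
            emb = np.linalg.norm(X[i] - X[j])
            assert emb == pytest.approx(comp.distances.loc[a, b], abs=1e-8)

    def test_pairwise_complete_handling(self):
        v = np.array([0.1, 0.2, 0.3, 0.4])
        cols = {
            "d1": v,
            "d2": v + 0.05,
            "d3": np.array([np.nan, 0.2, 0.3, 0.4]),
        }
        comp = dataset_scaling(_stack_of(cols))
        assert np.isfinite(comp.distances.to_numpy()).all()

    def test_no_shared_pairs_rejected(self):
        cols = {
            "d1": np.array([0.1, np.nan, 0.3, np.nan]),
            "d2": np.array([np.nan, 0.2, np.nan, 0.4]),
            "d3": np.array([0.1, 0.2, 0.3, 0.4]),
        }
        with pytest.raises(ValueError, match="share no defined pairs"):
            dataset_scaling(_stack_of(cols))

    def test_requires_three_datasets(self):
        with pytest.raises(ValueError):
            dataset_scaling(_stack_of({"d1": np.zeros(4), "d2": np.zeros(4)}))

    def test_classical_mds_recovers_planar_configuration(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(6, 2))
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        X = classical_mds(D)
        D2 = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        np.testing.assert_allclose(D2, D, atol=1e-8)
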