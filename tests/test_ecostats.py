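"""CCA, ordination cluster permutation test, G-test, trend tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from ecodemarc import ecostats


def toy_table(seed=0, n_var=3, n_samp=5):
    rng = np.random.default_rng(seed)
    Y = pd.DataFrame(rng.integers(1, 30, size=(n_var, n_samp)).astype(float),
                     index=[f"v{i}" for i in range(n_var)],
                     columns=[f"s{i}" for i in range(n_samp)])
    env = pd.DataFrame(
        {"temperature": rng.uniform(60, 68, n_samp),
         "depth": rng.uniform(80, 560, n_samp)},
        index=Y.columns)
    return Y, env


def dense_eigen_oracle(Y: pd.DataFrame, env: pd.DataFrame) -> np.ndarray:
    """Brute-force generalized-eigen CCA eigenvalues."""
    Ym = Y.to_numpy(dtype=float).T
    P = Ym / Ym.sum()
    r, c = P.sum(axis=1), P.sum(axis=0)
    Qbar = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    X = env.to_numpy(dtype=float)
    Xc = X - r @ X
    Xs = Xc / np.sqrt(r @ (Xc**2))
    Xw = np.sqrt(r)[:, None] * Xs
    H = Xw @ np.linalg.pinv(Xw.T @ Xw) @ Xw.T
    Yhat = H @ Qbar
    eig = np.linalg.eigvalsh(Yhat @ Yhat.T)[::-1]
    return eig[eig > 1e-12]


class TestCCA:
    @pytest.mark.parametrize("seed,n_var,n_samp",
                             [(0, 3, 3), (1, 3, 5), (2, 5, 5), (3, 4, 5)])
    def test_eigenvalues_match_dense_oracle(self, seed, n_var, n_samp):
        Y, env = toy_table(seed, n_var, n_samp)
        res = ecostats.cca(Y, env)
        oracle = dense_eigen_oracle(Y, env)
        k = len(res.eigenvalues)
        assert np.allclose(np.sort(res.eigenvalues)[::-1], oracle[:k],
                           atol=1e-8)

    def test_matches_skbio_reference_implementation(self):
        skord = pytest.importorskip("skbio.stats.ordination")
        Y, env = toy_table(4, 4, 6)
        res = ecostats.cca(Y, env)
        sk = skord.cca(pd.DataFrame(Y.to_numpy().T, index=env.index,
                                    columns=Y.index), env)
        assert np.allclose(res.eigenvalues, sk.eigvals.values[:2], atol=1e-8)

    def test_inertia_decomposition_exact(self):
        Y, env = toy_table(5, 5, 5)
        res = ecostats.cca(Y, env)
        # residual (unconstrained) inertia recomputed by brute force
        assert 0 <= res.constrained_inertia <= res.total_inertia
        assert res.constrained_inertia == pytest.approx(
            float(res.eigenvalues.sum()), abs=1e-12)
        eig_oracle = dense_eigen_oracle(Y, env)
        assert res.constrained_inertia == pytest.approx(
            float(eig_oracle.sum()), abs=1e-8)

    def test_duplicating_samples_preserves_eigenvalues(self):
        Y, env = toy_table(6, 4, 4)
        res1 = ecostats.cca(Y, env)
        Y2 = pd.concat([Y, Y.add_suffix("_dup", axis=1)], axis=1)
        env2 = pd.concat([env, env.set_index(env.index + "_dup")])
        res2 = ecostats.cca(Y2, env2)
        assert np.allclose(res1.eigenvalues, res2.eigenvalues, atol=1e-10)

    def test_constant_predictor_raises(self):
        Y, env = toy_table(7)
        env["temperature"] = 63.0
        with pytest.raises(ValueError, match="degenerate"):
            ecostats.cca(Y, env)

    def test_shuffled_environment_explains_little(self):
        # env orthogonal to abundance structure: constrained fraction small
        rng = np.random.default_rng(8)
        fracs = []
        for rep in range(20):
            Y, env = toy_table(100 + rep, 30, 40)
            env.iloc[:] = rng.permutation(env.to_numpy())
            res = ecostats.cca(Y, env)
            fracs.append(res.constrained_inertia / res.total_inertia)
        assert np.mean(fracs) < 0.10


class TestPlotExport:
    def test_svg_export_with_pe_highlight(self, tmp_path):
        Y, env = toy_table(9, 6, 6)
        res = ecostats.cca(Y, env)
        out = tmp_path / "ordination.svg"
        ecostats.plot_ordination(res, {"PE1": ["v0", "v1"]}, str(out))
        assert out.exists() and out.stat().st_size > 0


class TestOrdtest:
    def test_planted_tight_cluster_detected(self):
        rng = np.random.default_rng(1)
        pts = pd.DataFrame(rng.normal(size=(40, 2)),
                           index=[f"v{i}" for i in range(40)])
        pts.iloc[:8] = rng.normal(scale=0.05, size=(8, 2)) + [3.0, 3.0]
        res = ecostats.ordtest_cluster(pts, [f"v{i}" for i in range(8)],
                                       n_perm=999, seed=5)
        assert res.p_value <= 0.005

    def test_singleton_group_not_testable(self):
        pts = pd.DataFrame(np.zeros((5, 2)), index=list("abcde"))
        res = ecostats.ordtest_cluster(pts, ["a"], n_perm=99, seed=0)
        assert not res.testable and res.p_value is None

    def test_zero_permutations_rejected(self):
        pts = pd.DataFrame(np.zeros((5, 2)), index=list("abcde"))
        with pytest.raises(ValueError):
            ecostats.ordtest_cluster(pts, ["a", "b"], n_perm=0)

    def test_p_bounded_below_by_permutation_count(self):
        rng = np.random.default_rng(2)
        pts = pd.DataFrame(rng.normal(size=(30, 2)),
                           index=[f"v{i}" for i in range(30)])
        res = ecostats.ordtest_cluster(pts, [f"v{i}" for i in range(5)],
                                       n_perm=99, seed=3)
        assert 1 / 100 <= res.p_value <= 1.0

    def test_tightening_cluster_never_raises_p(self):
        # shrink the planted cluster's spread; same background, same
        # cluster shape, same permutation seed (paired comparison)
        rng = np.random.default_rng(4)
        background = rng.normal(size=(40, 2))
        shape = rng.normal(size=(8, 2))
        pvals = []
        for scale in (1.0, 0.3, 0.05):
            pts = background.copy()
            pts[:8] = shape * scale + 2.0
            frame = pd.DataFrame(pts, index=[f"v{i}" for i in range(40)])
            res = ecostats.ordtest_cluster(frame,
                                           [f"v{i}" for i in range(8)],
                                           n_perm=499, seed=11)
            pvals.append(res.p_value)
        assert pvals[0] >= pvals[1] >= pvals[2]


class TestGTest:
    def test_independent_table_gives_zero(self):
        res = ecostats.g_test([[10, 10], [10, 10]])
        assert res.g == 0.0 and res.p_value == pytest.approx(1.0)

    def test_closed_form_on_association_table(self):
        O = np.array([[30.0, 10.0], [10.0, 30.0]])
        res = ecostats.g_test(O)
        E = np.outer(O.sum(1), O.sum(0)) / O.sum()
        expected = 2 * (O * np.log(O / E)).sum()
        assert res.g == pytest.approx(expected, abs=1e-10)
        assert res.df == 1

    def test_matches_independent_kl_formulation(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            O = rng.integers(1, 50, size=(3, 4)).astype(float)
            res = ecostats.g_test(O)
            n = O.sum()
            P = O / n
            Prow, Pcol = P.sum(1), P.sum(0)
            kl = (P * np.log(P / np.outer(Prow, Pcol))).sum()
            assert res.g == pytest.approx(2 * n * kl, abs=1e-9)

    def test_zero_row_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="dropping"):
            res = ecostats.g_test([[10, 20], [0, 0], [20, 10]])
        assert res.df == 1

    def test_pooling_identical_rows_preserves_g(self):
        O = np.array([[15.0, 5.0], [15.0, 5.0], [5.0, 25.0]])
        pooled = np.array([[30.0, 10.0], [5.0, 25.0]])
        # pooling rows with identical profiles cannot change the
        # independence structure's G contribution from the other rows
        g1 = ecostats.g_test(O)
        g2 = ecostats.g_test(pooled)
        assert g1.g == pytest.approx(g2.g, abs=1e-9)


class TestPerturbationTrend:
    def test_divergent_fixture_detected_with_directions(self):
        p1 = np.array([0.1, 0.2, 0.4])
        n = 2000
        counts = pd.DataFrame([(p1 * n).astype(int),
                               ((1 - p1) * n).astype(int)],
                              index=["A", "B"], columns=[0.0, 1.0, 2.0])
        res = ecostats.perturbation_trend(counts)
        assert res.interaction_p < 0.01
        assert res.slopes.loc["A", "direction"] == ecostats.UP
        assert res.slopes.loc["B", "direction"] == ecostats.DOWN

    def test_ancova_mode_agrees_on_fixture(self):
        p1 = np.array([0.1, 0.2, 0.4, 0.5])
        n = 2000
        counts = pd.DataFrame([(p1 * n).astype(int),
                               ((1 - p1) * n).astype(int)],
                              index=["A", "B"], columns=[0.0, 1.0, 2.0, 3.0])
        res = ecostats.perturbation_trend(counts, method="ancova")
        assert res.interaction_p < 0.05
        assert res.method == "ancova"

    def test_single_timepoint_rejected(self):
        counts = pd.DataFrame([[5], [5]], index=["A", "B"], columns=[0.0])
        with pytest.raises(ValueError, match="timepoints"):
            ecostats.perturbation_trend(counts)

    def test_homogeneity_flat_when_shares_constant(self):
        tot = np.array([200.0, 400.0, 1000.0])
        hfs = pd.DataFrame([0.5 * tot, 0.3 * tot], index=["h1", "h2"],
                           columns=[0.0, 1.0, 2.0]).astype(int)
        lfs = pd.Series(0.2 * tot, index=[0.0, 1.0, 2.0]).astype(int)
        res = ecostats.within_pe_homogeneity(hfs, lfs)
        assert res.worst_p > 0.3
        assert np.allclose(res.components["slope"], 0.0, atol=1e-8)

    def test_homogeneity_detects_composition_shift(self):
        tot = np.array([1000.0, 1000.0, 1000.0])
        hfs = pd.DataFrame([[700, 500, 300], [300, 500, 700]],
                           index=["h1", "h2"], columns=[0.0, 1.0, 2.0])
        res = ecostats.within_pe_homogeneity(hfs)
        assert res.worst_p < 0.01
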