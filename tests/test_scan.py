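"""PCA scan: standardization, components, robust null, global test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import racescan as rs
from racescan.scan import MAD_CONSISTENCY

from conftest import POLYMORPHIC_ONLY


def _simple_matrix(calls):
    calls = np.asarray(calls, dtype=np.int8)
    return rs.GenotypeMatrix(
        calls=calls,
        samples=[f"i{k}" for k in range(calls.shape[0])],
        snps=[f"s{j}" for j in range(calls.shape[1])],
    )


class TestStandardize:
    def test_formula_at_half_frequency(self):
        G = _simple_matrix([[0], [1], [2]])
        X = rs.standardize(G)
        np.testing.assert_allclose(
            X[:, 0], [-np.sqrt(2), 0.0, np.sqrt(2)], atol=1e-12
        )

    def test_missing_imputed_to_zero(self):
        G = _simple_matrix([[0], [2], [rs.MISSING]])
        X = rs.standardize(G)
        assert X[2, 0] == 0.0

    def test_column_means_near_zero(self, two_pop_panel):
        G, _ = two_pop_panel
        X = rs.standardize(G)
        assert np.abs(X.mean(axis=0)).max() < 1e-10

    def test_monomorphic_rejected_by_name(self):
        G = _simple_matrix([[0, 0], [0, 1], [0, 2]])
        with pytest.raises(rs.MonomorphicError, match="s0"):
            rs.standardize(G)


class TestFitPca:
    def test_rank_one_matrix_has_single_eigenvalue(self):
        u = np.arange(1, 9, dtype=float)
        v = np.array([1.0, -2.0, 3.0])
        X = np.outer(u, v)
        model = rs.fit_pca(X, 3)
        assert model.eigenvalues[0] > 1e-6
        np.testing.assert_allclose(model.eigenvalues[1:], 0.0, atol=1e-20)

    def test_two_population_separation(self):
        rng = np.random.default_rng(0)
        p1 = np.full(50, 0.5)
        p2 = p1.copy()
        p2[:10] += 0.3
        p1[:10] -= 0.3
        calls = np.vstack(
            [rng.binomial(2, p1, (20, 50)), rng.binomial(2, p2, (20, 50))]
        ).astype(np.int8)
        G = _simple_matrix(calls)
        X = rs.standardize(G)
        model = rs.fit_pca(X, 2)
        pc1 = model.scores[:, 0]
        assert pc1[:20].max() < pc1[20:].min() or pc1[20:].max() < pc1[:20].min()

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((6, 10))
        X -= X.mean(axis=0)
        model = rs.fit_pca(X, 5)
        recon = model.scores @ model.snp_weights.T
        np.testing.assert_allclose(recon, X, atol=1e-9)

    def test_k_too_large_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            rs.fit_pca(np.zeros((4, 10)), 4)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((10, 15))
        m1, m2 = rs.fit_pca(X, 4), rs.fit_pca(X.copy(), 4)
        np.testing.assert_array_equal(m1.scores, m2.scores)
        for k in range(4):
            assert m1.scores[np.argmax(np.abs(m1.scores[:, k])), k] > 0


class TestScree:
    def test_noise_spectrum_is_flat(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((100, 400))
        table = rs.scree(X, 10)
        props = table["proportion"].to_numpy()
        assert props.sum() <= 1.0 + 1e-12
        assert props[0] / props[9] < 2.0  # no dominant elbow

    def test_clustered_data_dominant_components(self):
        cfg = rs.SimConfig(
            seed=8, n_races=3, f_race=(0.4, 0.4, 0.4), f_loc=0.0,
            n_localities=1, n_diploids_per_locality=15,
            genes_per_category={"control": 60}, snps_per_gene=5,
            selected=None, migrant_rate=0, hybrid_rate=0, missing_rate=0,
        )
        G, _ = rs.simulate_panel(cfg)
        G, _ = rs.filter_snps(G, POLYMORPHIC_ONLY)
        table = rs.scree(rs.standardize(G), 10)
        props = table["proportion"].to_numpy()
        assert props[:2].sum() > 3 * props[2:].sum() / 8
        assert table.attrs["elbow"] == 2

    def test_single_component_table(self):
        rng = np.random.default_rng(4)
        table = rs.scree(rng.standard_normal((5, 8)), 1)
        assert len(table) == 1


class TestComponentScan:
    def test_loading_at_null_center_gives_p_one(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 200))
        X -= X.mean(axis=0)
        model = rs.fit_pca(X, 2)
        res = rs.component_scan(X, model)
        j = np.argmin(np.abs(res.loadings[:, 0] - np.median(res.loadings[:, 0])))
        assert res.p[j, 0] > 0.95

    def test_null_pvalue_calibration(self):
        # structureless panel: fraction p <= 0.05 within binomial tolerance
        cfg = rs.SimConfig(
            seed=42, n_races=2, f_race=(0.0, 0.0), f_loc=0.0, n_localities=1,
            n_diploids_per_locality=30,
            genes_per_category={"control": 1000}, snps_per_gene=5,
            selected=None, migrant_rate=0, hybrid_rate=0, missing_rate=0,
        )
        G, _ = rs.simulate_panel(cfg)
        G, _ = rs.filter_snps(G, POLYMORPHIC_ONLY)
        res, _ = rs.scan_panel(G, K=1)
        frac = (res.p[:, 0] <= 0.05).mean()
        n = len(res.snps)
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n)

    def test_planted_snps_rank_first(self):
        rng = np.random.default_rng(6)
        p1 = np.full(50, 0.5)
        p2 = p1.copy()
        p2[:10] += 0.35
        p1[:10] -= 0.35
        calls = np.vstack(
            [rng.binomial(2, p1, (40, 50)), rng.binomial(2, p2, (40, 50))]
        ).astype(np.int8)
        G = _simple_matrix(calls)
        X = rs.standardize(G)
        model = rs.fit_pca(X, 1)
        res = rs.component_scan(X, model, typed=G.typed, snps=G.snps)
        top10 = set(np.argsort(res.p[:, 0])[:10])
        assert top10 == set(range(10))

    def test_zero_scale_component_raises(self):
        X = np.zeros((6, 4))
        X[:, 0] = [1, -1, 1, -1, 1, -1]
        model = rs.fit_pca(X, 1)
        # all other columns have identical (0) loadings -> MAD 0
        with pytest.raises(rs.DegenerateComponentError):
            rs.component_scan(X, model)

    def test_order_invariance(self, two_pop_panel):
        G, _ = two_pop_panel
        res, _ = rs.scan_panel(G, K=2)
        rng = np.random.default_rng(7)
        perm_s = rng.permutation(G.n_samples)
        perm_j = rng.permutation(G.n_snps)
        G2 = G.take_samples(perm_s).take_snps(perm_j)
        res2, _ = rs.scan_panel(G2, K=2)
        lookup = res2.to_frame().loc[res.snps]
        np.testing.assert_allclose(
            np.abs(lookup["loading_pc1"].to_numpy()),
            np.abs(res.loadings[:, 0]),
            atol=1e-8,
        )
        np.testing.assert_allclose(
            lookup["p_pc1"].to_numpy(), res.p[:, 0], atol=1e-8
        )


class TestGlobalScan:
    def _result_from_z(self, z):
        n, K = z.shape
        return rs.ScanResult(
            snps=pd.Index([f"s{i}" for i in range(n)]),
            loadings=np.tanh(z / 10),
            z=z,
            p=2 * stats.norm.sf(np.abs(z)),
            q=np.ones((n, K)),
            alpha=0.05,
        )

    def test_zero_z_gives_p_one(self):
        z = np.vstack([np.zeros(3), np.random.default_rng(0).normal(size=(999, 3))])
        res = rs.global_scan(self._result_from_z(z))
        assert res.d2[0] == 0.0
        assert res.p_global[0] == 1.0

    def test_chi2_calibration_of_d2(self):
        rng = np.random.default_rng(11)
        z = rng.standard_normal((10_000, 4))
        res = rs.global_scan(self._result_from_z(z))
        assert abs(res.inflation - 1.0) < 0.05
        ks = stats.kstest(res.d2 / res.inflation, lambda x: stats.chi2.cdf(x, 4))
        assert ks.statistic < 0.05

    def test_rank_invariance_under_z_rescaling(self):
        rng = np.random.default_rng(12)
        z = rng.standard_normal((500, 3))
        r1 = rs.global_scan(self._result_from_z(z))
        r2 = rs.global_scan(self._result_from_z(2.0 * z))
        np.testing.assert_array_equal(
            np.argsort(r1.p_global), np.argsort(r2.p_global)
        )

    def test_k1_global_ranks_match_componentwise(self):
        rng = np.random.default_rng(13)
        z = rng.standard_normal((300, 1))
        res = rs.global_scan(self._result_from_z(z))
        np.testing.assert_array_equal(
            np.argsort(res.p_global), np.argsort(res.p[:, 0], kind="stable")
        )


class TestFdrAndPower:
    def test_planted_axis_fdr_and_power(self, two_pop_panel):
        G, truth = two_pop_panel
        res, _ = rs.scan_panel(G, K=1)
        sel = truth.loci["selected"].reindex(res.snps).to_numpy()
        flag = res.outliers[:, 0]
        power = (flag & sel).sum() / sel.sum()
        fdr = (flag & ~sel).sum() / max(flag.sum(), 1)
        assert power >= 0.8
        assert fdr <= 0.10  # 2x the nominal q <= 0.05

    def test_q_monotone_in_p_within_component(self, two_pop_panel):
        G, _ = two_pop_panel
        res, _ = rs.scan_panel(G, K=2)
        for k in range(2):
            order = np.argsort(res.p[:, k])
            assert np.all(np.diff(res.q[order, k]) >= -1e-12)


class TestExcludeCluster:
    def test_infinite_threshold_is_identity(self, study_shaped_panel):
        G, _, _ = study_shaped_panel
        G, _ = rs.filter_snps(G, POLYMORPHIC_ONLY)
        model = rs.fit_pca(rs.standardize(G), 8)
        out = rs.exclude_cluster(G, model, 1, np.inf)
        assert out.n_samples == G.n_samples

    def test_hyper_diverged_race_removed_intact(self, study_shaped_panel):
        # one race is 10x more drifted; PC1 isolates it completely
        G, _, cfg = study_shaped_panel
        G, _ = rs.filter_snps(G, POLYMORPHIC_ONLY)
        model = rs.fit_pca(rs.standardize(G), 8)
        with pytest.warns(UserWarning, match="excluding"):
            out = rs.exclude_cluster(G, model, 1, 0.1)
        races_left = set(out.sample_meta["host_race"])
        assert "race1" not in races_left
        assert len(races_left) == cfg.n_races - 1
        removed = set(G.samples) - set(out.samples)
        assert all(
            G.sample_meta.loc[s, "host_race"] == "race1" for s in removed
        )

    def test_remove_all_raises(self, study_shaped_panel):
        G, _, _ = study_shaped_panel
        G, _ = rs.filter_snps(G, POLYMORPHIC_ONLY)
        model = rs.fit_pca(rs.standardize(G), 3)
        with pytest.raises(rs.EmptyPanelError):
            rs.exclude_cluster(G, model, 1, -np.inf)


def test_mad_consistency_constant_matches_normal():
    # MAD of a standard normal is Phi^{-1}(0.75)
    assert abs(MAD_CONSISTENCY - stats.norm.ppf(0.75)) < 5e-6


def test_mcd_covariance_alternative_agrees_on_clean_null():
    rng = np.random.default_rng(17)
    z = rng.standard_normal((2000, 3))
    base = rs.ScanResult(
        snps=pd.Index([f"s{i}" for i in range(2000)]),
        loadings=np.tanh(z / 10), z=z,
        p=2 * stats.norm.sf(np.abs(z)), q=np.ones((2000, 3)), alpha=0.05,
    )
    ident = rs.global_scan(base)
    d2_ident = ident.d2.copy()
    mcd = rs.global_scan(base, covariance="mcd")
    # on uncorrelated z the two distance definitions rank SNPs alike
    r = stats.spearmanr(d2_ident, mcd.d2).statistic
    assert r > 0.95
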