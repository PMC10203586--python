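"""EM-REML, BLUEs, GRM construction and (multivariate) GBLUP."""

import warnings

import numpy as np
import pandas as pd
import pytest

from phenosel import mixed_models as mm
from phenosel.simdata import (
    GeneticMap,
    MarkerMatrix,
    SimConfig,
    TruthConfig,
    simulate_study,
)


def balanced_oneway(n_groups=30, n_per=6, s2g=2.0, s2e=1.0, seed=0):
    rng = np.random.default_rng(seed)
    g = rng.normal(0, np.sqrt(s2g), n_groups)
    y = np.repeat(g, n_per) + rng.normal(0, np.sqrt(s2e), n_groups * n_per)
    labels = np.repeat(np.arange(n_groups), n_per)
    Z = (labels[:, None] == np.arange(n_groups)[None, :]).astype(float)
    return y, Z, labels


class TestEmReml:
    def test_matches_anova_estimators_balanced_oneway(self):
        """On a balanced one-way layout REML equals the method-of-moments
        ANOVA estimators (expected mean squares)."""
        y, Z, labels = balanced_oneway()
        n_groups, n_per = Z.shape[1], 6
        vc, _, _ = em_reml_quiet(y, np.ones((len(y), 1)), {"group": Z})
        df = pd.DataFrame({"y": y, "g": labels})
        group_means = df.groupby("g")["y"].mean()
        msb = n_per * group_means.var(ddof=1)
        msw = df.groupby("g")["y"].apply(lambda s: s.var(ddof=1)).mean()
        s2g_anova = (msb - msw) / n_per
        assert vc.sigma2_e == pytest.approx(msw, rel=1e-4)
        assert vc.sigma2["group"] == pytest.approx(s2g_anova, rel=1e-3)

    def test_loglik_non_decreasing(self):
        y, Z, _ = balanced_oneway(seed=3)
        vc, _, _ = em_reml_quiet(y, np.ones((len(y), 1)), {"group": Z})
        ll = np.array(vc.loglik_trace)
        assert np.all(np.diff(ll) >= -1e-8)

    def test_rank_deficient_fixed_rejected(self):
        y, Z, _ = balanced_oneway(n_groups=5)
        X = np.ones((len(y), 2))  # duplicated intercept
        with pytest.raises(mm.IdentifiabilityError):
            mm.em_reml(y, X, {"group": Z})

    def test_zero_variance_component_recovered(self):
        """Simulated with no group effect, the REML estimate collapses to
        (nearly) zero on average over replicates."""
        est = []
        for seed in range(8):
            y, Z, _ = balanced_oneway(n_groups=20, n_per=5, s2g=0.0, s2e=1.0,
                                      seed=seed)
            vc, _, _ = em_reml_quiet(y, np.ones((len(y), 1)), {"group": Z})
            est.append(vc.sigma2["group"])
        assert np.mean(est) < 0.05


def em_reml_quiet(*args, **kwargs):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mm.em_reml(*args, **kwargs)


class TestRemlBlocks:
    def test_single_block_identifiability_error(self, tiny_sim):
        plots = tiny_sim.plots.copy()
        plots["block"] = "B1"
        with pytest.raises(mm.IdentifiabilityError):
            mm.reml_blocks(plots)

    def test_variances_on_simulated_design(self, tiny_sim):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vc = mm.reml_blocks(tiny_sim.plots)
        assert vc.sigma2["block"] >= 0
        assert vc.sigma2["sub_block"] >= 0
        assert vc.sigma2_e > 0


class TestBlues:
    def test_zero_block_variance_reduces_to_means(self, tiny_sim):
        vc = mm.VarianceComponents(sigma2={"block": 0.0, "sub_block": 0.0},
                                   sigma2_e=1.0)
        blues = mm.compute_blues(tiny_sim.plots, vc)
        means = (tiny_sim.plots.groupby(["env", "line"])["yield_t_ha"]
                 .mean().reset_index())
        merged = blues.merge(means, on=["env", "line"])
        assert np.abs(merged["blue"] - merged["yield_t_ha"]).max() < 1e-8

    def test_matches_dense_gls_oracle(self):
        """Toy 8-plot design: BLUEs equal the direct matrix-inverse GLS."""
        plots = pd.DataFrame({
            "env": ["E1"] * 8,
            "block": ["B1", "B1", "B1", "B1", "B2", "B2", "B2", "B2"],
            "sub_block": ["S1", "S1", "S2", "S2", "S3", "S3", "S4", "S4"],
            "line": ["L1", "L2", "L3", "L4", "L1", "L2", "L3", "L4"],
            "yield_t_ha": [9.1, 8.3, 10.2, 7.9, 9.8, 8.9, 10.6, 8.1],
        })
        s2b, s2s, s2e = 0.5, 0.3, 0.8
        vc = mm.VarianceComponents(sigma2={"block": s2b, "sub_block": s2s},
                                   sigma2_e=s2e)
        blues = mm.compute_blues(plots, vc)
        X = pd.get_dummies(plots["line"]).to_numpy(dtype=float)
        Zb = pd.get_dummies(plots["block"]).to_numpy(dtype=float)
        Zs = pd.get_dummies(plots["sub_block"]).to_numpy(dtype=float)
        V = s2b * Zb @ Zb.T + s2s * Zs @ Zs.T + s2e * np.eye(8)
        Vi = np.linalg.inv(V)
        beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ plots["yield_t_ha"])
        ref = pd.Series(beta, index=sorted(plots["line"].unique()))
        got = blues.set_index("line")["blue"]
        assert np.abs(got[ref.index] - ref).max() < 1e-8

    def test_absent_line_env_combinations_have_no_row(self, tiny_sim):
        vc = mm.VarianceComponents(sigma2={"block": 0.1, "sub_block": 0.1},
                                   sigma2_e=1.0)
        blues = mm.compute_blues(tiny_sim.plots, vc)
        present = set(map(tuple, tiny_sim.plots[["line", "env"]].drop_duplicates()
                          .to_numpy()))
        assert set(map(tuple, blues[["line", "env"]].to_numpy())) == present


class TestGrm:
    def test_identical_inbred_lines(self):
        dos = pd.DataFrame([[0, 2, 2, 0], [0, 2, 2, 0], [2, 0, 0, 2]],
                           index=["a", "b", "c"], columns=list("wxyz"),
                           dtype=float)
        g = mm.grm_vanraden(MarkerMatrix(dos))
        A = g.values()
        assert A[0, 1] == pytest.approx(A[0, 0])

    def test_hand_computed_toy(self):
        dos = pd.DataFrame([[0.0, 2.0, 1.0], [2.0, 0.0, 1.0], [2.0, 2.0, 0.0]],
                           index=["a", "b", "c"], columns=["m1", "m2", "m3"])
        p = dos.mean(axis=0).to_numpy() / 2
        Z = dos.to_numpy() - 2 * p
        expected = Z @ Z.T / (2 * np.sum(p * (1 - p)))
        got = mm.grm_vanraden(MarkerMatrix(dos)).values()
        assert np.abs(got - expected).max() < 1e-12

    def test_unrelated_panel_mean_off_diagonal_zero(self, rng):
        dos = pd.DataFrame(
            rng.choice([0.0, 2.0], size=(80, 400), p=[0.5, 0.5]),
            index=[f"L{i}" for i in range(80)],
        )
        A = mm.grm_vanraden(MarkerMatrix(dos)).values()
        off = A[~np.eye(80, dtype=bool)]
        # sample-frequency centering forces sum(G) = 0, so the off-diagonal
        # mean is exactly -mean(diag)/(n-1) ~ -2/(n-1) for inbred lines
        assert off.mean() == pytest.approx(-np.diag(A).mean() / 79, abs=1e-10)
        assert abs(off.mean()) < 0.05

    def test_monomorphic_only_rejected(self):
        dos = pd.DataFrame([[2.0, 0.0], [2.0, 0.0]], index=["a", "b"])
        with pytest.raises(ValueError, match="monomorphic"):
            mm.grm_vanraden(MarkerMatrix(dos))


def random_grm(n, rng, rank=None):
    M = rng.standard_normal((n, rank or n + 5))
    G = M @ M.T / M.shape[1]
    idx = [f"L{i}" for i in range(n)]
    return mm.GRM(pd.DataFrame(G, index=idx, columns=idx), pd.Series(dtype=float)), M


class TestGblup:
    def test_identity_grm_closed_form(self, rng):
        """G = I: u_hat = (y - ybar) / (1 + lambda) with lambda = s2e/s2g."""
        n = 25
        idx = [f"L{i}" for i in range(n)]
        grm = mm.GRM(pd.DataFrame(np.eye(n), index=idx, columns=idx),
                     pd.Series(dtype=float))
        y = pd.Series(rng.standard_normal(n), index=idx)
        s2g, s2e = 1.0, 0.5
        pred, _ = mm.gblup_fit(y, grm, (s2g, s2e))
        lam = s2e / s2g
        expected = y.mean() + (y - y.mean()) / (1 + lam)
        assert np.abs(pred - expected).max() < 1e-10

    def test_total_shrinkage_returns_mean(self, rng):
        grm, _ = random_grm(15, rng)
        y = pd.Series(rng.standard_normal(15), index=grm.line_ids)
        pred, _ = mm.gblup_fit(y, grm, (1e-12, 1.0))
        assert np.abs(pred - y.mean()).max() < 1e-6

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_rr_blup_equivalence(self, seed):
        """GRM = MM'/c GBLUP equals ridge regression on M with penalty
        c * lambda (property over random toys)."""
        rng = np.random.default_rng(seed)
        n, p = 50, 40
        M = rng.standard_normal((n, p))
        c = float(p)
        idx = [f"L{i}" for i in range(n)]
        grm = mm.GRM(pd.DataFrame(M @ M.T / c, index=idx, columns=idx),
                     pd.Series(dtype=float))
        y = pd.Series(M @ rng.standard_normal(p) * 0.2 + rng.standard_normal(n),
                      index=idx)
        s2g, s2e = 0.8, 0.6
        pred, _ = mm.gblup_fit(y, grm, (s2g, s2e))
        lam = s2e / s2g
        V = s2g * grm.values() + s2e * np.eye(n)
        Vi = np.linalg.inv(V)
        ones = np.ones(n)
        mu = ones @ Vi @ y.to_numpy() / (ones @ Vi @ ones)
        b = np.linalg.solve(M.T @ M + c * lam * np.eye(p), M.T @ (y.to_numpy() - mu))
        assert np.abs(pred.to_numpy() - (mu + M @ b)).max() < 1e-6

    def test_prediction_invariant_to_line_ordering(self, rng):
        grm, _ = random_grm(20, rng)
        y = pd.Series(rng.standard_normal(20), index=grm.line_ids)
        y.iloc[15:] = np.nan
        pred, _ = mm.gblup_fit(y, grm, (1.0, 1.0))
        perm = rng.permutation(20)
        idx = [grm.line_ids[i] for i in perm]
        grm2 = mm.GRM(grm.matrix.loc[idx, idx], grm.allele_freq)
        pred2, _ = mm.gblup_fit(y[idx], grm2, (1.0, 1.0))
        assert np.abs(pred2[pred.index] - pred).max() < 1e-10

    def test_estimated_variances_nonnegative(self, rng):
        grm, M = random_grm(40, rng)
        y = pd.Series(M.sum(axis=1) * 0.1 + rng.standard_normal(40),
                      index=grm.line_ids)
        pred, vc = mm.gblup_fit(y, grm)
        assert vc.sigma2["genetic"] >= 0
        assert vc.sigma2_e >= 0
        ll = np.array(vc.loglik_trace)
        assert np.all(np.diff(ll) >= -1e-8)


class TestMvGblup:
    def _setup(self, rng, n=30, masked=10):
        grm, M = random_grm(n, rng)
        u = M.sum(axis=1) / np.sqrt(M.shape[1])
        y = pd.Series(u + rng.standard_normal(n) * 0.7, index=grm.line_ids)
        co = pd.Series(u + rng.standard_normal(n) * 0.4, index=grm.line_ids,
                       name="co")
        y_masked = y.copy()
        y_masked.iloc[:masked] = np.nan
        return grm, y, y_masked, co

    def test_diagonal_covariance_equals_univariate(self, rng):
        grm, y, y_masked, co = self._setup(rng)
        G_t = np.diag([1.2, 0.9])
        R_t = np.diag([0.6, 0.8])
        Y = pd.DataFrame({"yield": y_masked, "co": co})
        pred_mv, _ = mm.mv_gblup_fit(Y, grm, (G_t, R_t))
        pred_uni, _ = mm.gblup_fit(y_masked, grm, (1.2, 0.6))
        assert np.abs(pred_mv - pred_uni).max() < 1e-6

    def test_no_masked_matches_univariate(self, rng):
        grm, y, _, co = self._setup(rng, masked=0)
        G_t = np.diag([1.0, 1.0])
        R_t = np.diag([0.5, 0.5])
        Y = pd.DataFrame({"yield": y, "co": co})
        pred_mv, _ = mm.mv_gblup_fit(Y, grm, (G_t, R_t))
        pred_uni, _ = mm.gblup_fit(y, grm, (1.0, 0.5))
        assert np.abs(pred_mv - pred_uni).max() < 1e-6

    def test_non_psd_covariance_rejected(self, rng):
        grm, y, y_masked, co = self._setup(rng)
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        Y = pd.DataFrame({"yield": y_masked, "co": co})
        with pytest.raises(ValueError, match="positive semi-definite"):
            mm.mv_gblup_fit(Y, grm, (bad, np.eye(2)))

    def test_informative_co_response_improves_masked_prediction(self):
        """A co-response genetically close to yield and observed everywhere
        raises masked-line accuracy over univariate GBLUP (averaged over
        replicates)."""
        gains = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            grm, y, y_masked, co = self._setup(rng, n=60, masked=20)
            masked = y_masked.isna()
            Y = pd.DataFrame({"yield": y_masked, "co": co})
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                pred_mv, _ = mm.mv_gblup_fit(Y, grm)
                pred_uni, _ = mm.gblup_fit(y_masked, grm)
            truth = y[masked]
            r_mv = np.corrcoef(pred_mv[masked], truth)[0, 1]
            r_uni = np.corrcoef(pred_uni[masked], truth)[0, 1]
            gains.append(r_mv - r_uni)
        assert np.mean(gains) > 0.0


class TestParameterRecovery:
    def test_heritability_ratio_recovered_on_simulated_trial(self):
        """Line-variance ratio from EM-REML on a simulated single-trial
        dataset tracks the configured h2 = 0.4 (line random, few
        replicates of moderate size keep this a quick check; the full
        20-replicate n=1000 version runs in the acceptance suite)."""
        ratios = []
        for seed in range(3):
            cfg = SimConfig(
                n_parents=8, n_biparental=4, n_threeway=0, lines_per_cross=50,
                n_markers=60, n_chrom=4,
                environments=SimConfig.tiny().environments[:1],
                truth=TruthConfig(h2=0.4, env_corr=1.0, sigma_block=0.0,
                                  sigma_subblock=0.0),
                panel=SimConfig.tiny().panel,
                replication=pd.DataFrame({"n_lines": [200], "Cam2016": [2]}),
            )
            sim = simulate_study(cfg, seed=100 + seed)
            plots = sim.plots
            y = plots["yield_t_ha"].to_numpy()
            Zl = pd.get_dummies(plots["line"]).to_numpy(dtype=float)
            vc, _, _ = em_reml_quiet(y, np.ones((len(y), 1)), {"line": Zl})
            ratios.append(vc.sigma2["line"] / (vc.sigma2["line"] + vc.sigma2_e))
        assert np.mean(ratios) == pytest.approx(0.4, abs=0.07)
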