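"""Headline study routines.

Each function runs one self-contained piece of the analysis at desk scale
and returns plain numbers: solver cross-checks, variance-component
recovery, the core phenomic-vs-genomic comparison under strong GxE, and
structural design checks. The numbered drivers under ``analysis/``, the
test suite and ``scripts/acceptance.py`` all call these.
"""

from __future__ import annotations

import hashlib
import warnings

import numpy as np
import pandas as pd

from . import mixed_models as mm
from . import penalized as pz
from . import trait_reduction as tr
from .evaluation import MaskingScheme, StudyData, run_scheme
from .simdata import (
    SimConfig,
    TruthConfig,
    build_design,
    simulate_study,
    full_trial_replication_spec,
)

__all__ = [
    "solver_oracles",
    "gblup_oracles",
    "heritability_recovery",
    "core_finding",
    "structural_checks",
    "core_conditions",
]


def solver_oracles(seed: int = 0) -> dict:
    """Cross-checks of the penalized solvers on small random problems:
    coordinate descent vs closed-form ridge, vs a brute-force objective
    grid (2 predictors), and PLS at full rank vs the OLS fit."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((40, 6))
    y = X @ rng.standard_normal(6) + rng.standard_normal(40)
    Xs, ys, _ = pz.standardize(
        pd.DataFrame(X, columns=[f"x{i}" for i in range(6)]), y
    )
    b_cd, *_ = pz.elastic_net_cd(Xs, ys, pz.PenaltySpec(0.0, 1.0, "ridge"),
                                 tol=1e-12)
    b_rf, _ = pz.ridge_closed_form(Xs, ys, 1.0)
    cd_vs_ridge = float(np.abs(b_cd - b_rf).max())

    X2 = rng.standard_normal((25, 2))
    y2 = X2 @ np.array([1.0, -0.5]) + 0.5 * rng.standard_normal(25)
    X2s, y2s, _ = pz.standardize(pd.DataFrame(X2, columns=["a", "b"]), y2)
    y2c = y2s - y2s.mean()
    lam1, lam2 = 0.1, 0.1
    b2, *_ = pz.elastic_net_cd(X2s, y2s, pz.PenaltySpec(lam1, lam2, "elastic_net"),
                               tol=1e-12)
    grid = np.linspace(-2, 2, 401)
    best_val, best_b = np.inf, None
    for a in grid:
        for c in grid:
            v = pz.objective(X2s, y2c, np.array([a, c]), lam1, lam2)
            if v < best_val:
                best_val, best_b = v, np.array([a, c])
    # refine the grid winner by local coordinate bisection
    from scipy.optimize import minimize

    res = minimize(lambda b: pz.objective(X2s, y2c, b, lam1, lam2), best_b,
                   method="Nelder-Mead",
                   options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000})
    cd_vs_grid = float(np.abs(b2 - res.x).max())

    X3 = rng.standard_normal((30, 4))
    y3 = X3 @ rng.standard_normal(4) + rng.standard_normal(30)
    cs = tr.pls_components(pd.DataFrame(X3), y3, k=4)
    X3s = (X3 - X3.mean(0)) / X3.std(0)
    A = np.column_stack([np.ones(30), X3s])
    beta, *_ = np.linalg.lstsq(A, y3, rcond=None)
    pls_vs_ols = float(np.abs(cs.fitted - A @ beta).max())
    return {
        "cd_vs_ridge_max_abs_diff": cd_vs_ridge,
        "cd_vs_grid_max_abs_diff": cd_vs_grid,
        "pls_fullrank_vs_ols_max_abs_diff": pls_vs_ols,
        "n": 40,
    }


def gblup_oracles(seed: int = 0, n: int = 50, p: int = 40) -> dict:
    """RR-BLUP equivalence (GRM = MM'/c vs ridge on M) and the reduction of
    diagonal-covariance multivariate GBLUP to the univariate fit."""
    rng = np.random.default_rng(seed)
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
    rr = float(np.abs(pred.to_numpy() - (mu + M @ b)).max())

    y_masked = y.copy()
    y_masked.iloc[: n // 3] = np.nan
    co = pd.Series(M.sum(axis=1) / np.sqrt(p) + rng.standard_normal(n) * 0.5,
                   index=idx, name="co")
    Y = pd.DataFrame({"yield": y_masked, "co": co})
    pred_mv, _ = mm.mv_gblup_fit(Y, grm, (np.diag([s2g, 1.0]), np.diag([s2e, 0.5])))
    pred_uni, _ = mm.gblup_fit(y_masked, grm, (s2g, s2e))
    mv = float(np.abs(pred_mv - pred_uni).max())
    return {
        "rrblup_equivalence_max_abs_diff": rr,
        "mv_diagonal_vs_univariate_max_abs_diff": mv,
        "n": n,
    }


def heritability_recovery(
    seed: int = 0, n_reps: int = 20, n_lines: int = 500, true_h2: float = 0.4
) -> dict:
    """EM-REML parameter recovery on simulated single-environment trials:
    n_lines x 2 replicates (= 1000 plots), line and sub-block random, the
    block variance simulated as zero. Reports the mean estimated
    heritability ratio and the mean estimated block variance."""
    ratios, block_vars = [], []
    for r in range(n_reps):
        cfg = SimConfig(
            n_parents=10, n_biparental=5, n_threeway=0,
            lines_per_cross=n_lines // 5, n_markers=60, n_chrom=4,
            environments=SimConfig.tiny().environments[:1],
            truth=TruthConfig(h2=true_h2, env_corr=1.0, sigma_block=0.0,
                              sigma_subblock=0.2),
            panel=SimConfig.tiny().panel,
            replication=pd.DataFrame({"n_lines": [n_lines], "Cam2016": [2]}),
        )
        sim = simulate_study(cfg, seed=seed * 1000 + r)
        plots = sim.plots
        y = plots["yield_t_ha"].to_numpy()
        Zl = pd.get_dummies(plots["line"]).to_numpy(dtype=float)
        Zb = pd.get_dummies(plots["block"]).to_numpy(dtype=float)
        Zs = pd.get_dummies(plots["sub_block"]).to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vc, _, _ = mm.em_reml(
                y, np.ones((len(y), 1)),
                {"line": Zl, "block": Zb, "sub_block": Zs},
            )
        tot = (vc.sigma2["line"] + vc.sigma2["block"] + vc.sigma2["sub_block"]
               + vc.sigma2_e)
        ratios.append(vc.sigma2["line"] / tot)
        block_vars.append(vc.sigma2["block"])
    return {
        "true_h2": true_h2,
        "mean_h2_ratio": float(np.mean(ratios)),
        "sd_h2_ratio": float(np.std(ratios, ddof=1)),
        "mean_block_variance": float(np.mean(block_vars)),
        "n_plots": 2 * n_lines,
        "n_reps": n_reps,
    }


def core_conditions() -> SimConfig:
    """The study conditions for the core phenomic-vs-genomic comparison:
    desk-scale trial (320 lines over 4 environments), between-environment
    genetic correlation 0.3, noisy bulk genotypes, and the default trait
    panel in which spectral categories carry ~60% of the yield signal."""
    cfg = SimConfig.demo()
    cfg.truth = TruthConfig(env_corr=0.3)
    return cfg


def core_finding(seed: int = 0, n_reps: int = 20, cv_path: int = 12) -> dict:
    """Whole-location prediction under strong GxE: elastic-net yield
    prediction of one full location from the other location of the same
    year, using phenomic traits, markers, or both, plus the
    10%-supplemented phenomic run. Accuracies are squared correlations on
    line BLUEs of the test location, averaged over replicates."""
    sim = simulate_study(core_conditions(), seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        data = StudyData.from_simulation(sim)
    scheme = MaskingScheme.whole_location(["Cam2016"], "Dux2016",
                                          unit="line_blues", n_reps=n_reps)
    sup = MaskingScheme.whole_location(["Cam2016"], "Dux2016", supplement=0.1,
                                       unit="line_blues", n_reps=n_reps)
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for key, pset, sch in (
            ("whole_location_phenomic_r2", "traits", scheme),
            ("whole_location_genomic_r2", "markers", scheme),
            ("whole_location_combined_r2", "combined", scheme),
            ("whole_location_phenomic_plus10pct_r2", "traits", sup),
        ):
            rec = run_scheme(data, "enet", pset, sch, seed=seed,
                             lambda1_rule="cv", cv_path=cv_path)
            sel = rec[rec["env"] == "Dux2016"]["accuracy"]
            out[key] = float(sel.mean())
            out[key.replace("_r2", "_sd")] = float(sel.std(ddof=1))
    out["n_reps"] = n_reps
    out["n_test_lines"] = int(
        rec[rec["env"] == "Dux2016"]["n_test"].iloc[0]
    )
    return out


def structural_checks(seed: int = 0, n_reps: int = 5) -> dict:
    """Design-shape and monotonicity checks: the full-trial replication
    pattern gives 4 plots per line and per-environment totals equal to the
    line count; the fraction-grid accuracy is monotone in the training
    fraction; redundancy pruning at 0.9 recovers the configured group
    count; the pipeline is bit-identical across reruns."""
    rng = np.random.default_rng(seed)
    spec = full_trial_replication_spec()
    env_ids = [c for c in spec.columns if c != "n_lines"]
    lines = [f"L{i:04d}" for i in range(int(spec["n_lines"].sum()))]
    design = build_design(lines, env_ids, spec, rng)
    per_line = design.groupby("line").size()
    per_env = design.groupby("env").size()

    sim = simulate_study(core_conditions(), seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        data = StudyData.from_simulation(sim)
    fractions = (0.1, 0.25, 0.75)
    accs = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for f in fractions:
            sch = MaskingScheme.fraction_grid({"Cam2016": f, "Dux2016": f},
                                              unit="plots", n_reps=n_reps)
            rec = run_scheme(data, "lasso", "traits", sch, seed=seed,
                             lambda1_rule="fixed", lambda1=0.02)
            accs.append(float(rec[rec["env"] == "pooled"]["accuracy"].mean()))

    panel = sim.panel
    traits = sim.plots[panel["trait_id"]]
    uniq = tr.unique_trait_count(traits, 0.9)

    realized = np.corrcoef(sim.truth.genetic_values.to_numpy().T)
    target = sim.truth.env_corr.to_numpy()
    corr_err = float(np.abs(realized - target).max())

    from .pipeline import StudyConfig, run_study
    import tempfile
    from pathlib import Path

    cfg = StudyConfig.from_dict({
        "seed": seed, "simulate": {"profile": "tiny"},
        "methods": ["enet"], "predictor_sets": ["traits"],
        "schemes": [{"kind": "fraction_grid",
                     "fractions": {"Cam2016": 0.5, "Dux2016": 0.5},
                     "unit": "plots", "n_reps": 2}],
        "evaluate": {"lambda1_rule": "fixed", "lambda1": 0.02},
    })
    with tempfile.TemporaryDirectory() as td:
        o1 = run_study(cfg, out=str(Path(td) / "a"))
        o2 = run_study(cfg, out=str(Path(td) / "b"))
        h1 = hashlib.sha256((o1 / "records.csv").read_bytes()).hexdigest()
        h2 = hashlib.sha256((o2 / "records.csv").read_bytes()).hexdigest()

    return {
        "plots_per_line_full_design": float(per_line.mean()),
        "plots_per_line_all_equal_4": float((per_line == 4).all()),
        "per_env_plots_equal_line_count": float((per_env == len(lines)).all()),
        "full_design_line_count": len(lines),
        "fraction_grid_accuracies": dict(zip(map(str, fractions), accs)),
        "fraction_grid_monotone": float(all(b >= a - 0.03
                                            for a, b in zip(accs, accs[1:]))),
        "unique_traits_at_r09": int(uniq),
        "configured_trait_groups": int(panel["group"].nunique()),
        "env_corr_max_abs_error": corr_err,
        "pipeline_rerun_identical": float(h1 == h2),
    }
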