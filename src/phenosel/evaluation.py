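"""Resampling/masking engine and prediction-accuracy bookkeeping.

Three scheme families drive all cross-validation results:

* fraction grids: within a year, a random fraction of each location's
  units (raw plots or line BLUEs) is kept for training and the rest
  validated, crossing the two locations' fractions;
* whole-location leave-out: entire locations train, one location tests
  (three training locations, or two from different / the same year);
* supplementation: whole-location training plus a small random fraction
  of the test location.

Each configuration is replicated with deterministically derived seeds and
scored as the squared Pearson correlation between predicted and observed
values, recorded per target environment and pooled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_rng
from . import marker_qc, mixed_models, penalized, trait_reduction
from .simdata import SimDataset

__all__ = [
    "MaskingScheme",
    "StudyData",
    "make_masks",
    "accuracy_r2",
    "spearman_shared_lines",
    "subset_traits",
    "run_scheme",
    "aggregate",
    "METHODS",
]

METHODS = ("lasso", "enet", "ridge", "gblup", "mv_gblup")

FRACTION_GRID = (1.0, 0.75, 0.5, 0.25, 0.15, 0.10, 0.05, 0.0)


@dataclass(frozen=True)
class MaskingScheme:
    """Declarative description of which units are masked per replicate.

    Either ``fractions`` (per-environment training fractions over the
    fraction grid) or ``train_envs``+``test_env`` (whole-location schemes,
    optionally supplemented with a fraction of the test environment) must
    be given.
    """

    id: str
    unit: str = "line_blues"  # or "plots"
    n_reps: int = 100
    fractions: tuple | None = None  # of (env, fraction)
    train_envs: tuple | None = None
    test_env: str | None = None
    supplement_fraction: float = 0.0

    def __post_init__(self):
        if self.unit not in ("plots", "line_blues"):
            raise ValueError("unit must be 'plots' or 'line_blues'")
        whole = self.train_envs is not None and self.test_env is not None
        if whole == (self.fractions is not None):
            raise ValueError("give either fractions or train_envs+test_env")
        if self.fractions is not None:
            fr = dict(self.fractions)
            if any(not 0.0 <= f <= 1.0 for f in fr.values()):
                raise ValueError("fractions must be in [0, 1]")
            if all(f == 0.0 for f in fr.values()):
                raise ValueError("at least one environment must contribute training")
        if not 0.0 <= self.supplement_fraction <= 1.0:
            raise ValueError("supplement fraction must be in [0, 1]")

    @property
    def envs(self) -> list:
        if self.fractions is not None:
            return [e for e, _ in self.fractions]
        return [*self.train_envs, self.test_env]

    @classmethod
    def fraction_grid(cls, env_fractions: dict, unit="line_blues", n_reps=100,
                      id: str | None = None) -> "MaskingScheme":
        sid = id or "frac_" + "_".join(f"{e}={f:g}" for e, f in env_fractions.items())
        return cls(sid, unit, n_reps, fractions=tuple(env_fractions.items()))

    @classmethod
    def whole_location(cls, train_envs, test_env, supplement: float = 0.0,
                       unit="line_blues", n_reps=100,
                       id: str | None = None) -> "MaskingScheme":
        sid = id or (
            f"loc_{'+'.join(train_envs)}->{test_env}"
            + (f"+{supplement:g}" if supplement else "")
        )
        return cls(sid, unit, n_reps, train_envs=tuple(train_envs),
                   test_env=test_env, supplement_fraction=supplement)


def make_masks(
    scheme: MaskingScheme, units: pd.DataFrame, rep: int, master_seed: int
) -> tuple[list, list]:
    """Split unit ids into (train, test) for one replicate.

    ``units`` needs columns unit_id and env. Sampling is a simple random
    sample without replacement, independent per environment; the replicate
    index perturbs the derived seed deterministically.
    """
    missing = [e for e in scheme.envs if e not in set(units["env"])]
    if missing:
        raise ValueError(f"scheme references unknown environments: {missing}")
    rng = child_rng(master_seed, "mask", scheme.id, rep)
    train, test = [], []
    if scheme.fractions is not None:
        for env, frac in scheme.fractions:
            ids = units.loc[units["env"] == env, "unit_id"].to_numpy()
            n_train = int(round(frac * len(ids)))
            pick = rng.choice(ids, size=n_train, replace=False)
            train.extend(pick)
            test.extend(np.setdiff1d(ids, pick))
    else:
        for env in scheme.train_envs:
            train.extend(units.loc[units["env"] == env, "unit_id"])
        ids = units.loc[units["env"] == scheme.test_env, "unit_id"].to_numpy()
        n_sup = int(round(scheme.supplement_fraction * len(ids)))
        pick = rng.choice(ids, size=n_sup, replace=False) if n_sup else np.array([], dtype=ids.dtype)
        train.extend(pick)
        test.extend(np.setdiff1d(ids, pick))
    if not train:
        raise ValueError("scheme produced an empty training set")
    return list(train), list(test)


def accuracy_r2(predicted, observed) -> float:
    """Squared Pearson correlation between predictions and observations;
    defined as 0 (with a warning) when either side has zero variance."""
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed lengths differ")
    if len(p) < 2:
        raise ValueError("need at least two pairs")
    if p.std(ddof=0) == 0 or o.std(ddof=0) == 0:
        warnings.warn("zero variance in accuracy_r2; returning 0", stacklevel=2)
        return 0.0
    return float(np.corrcoef(p, o)[0, 1] ** 2)


def spearman_shared_lines(blues_env1: pd.Series, blues_env2: pd.Series) -> float:
    """Spearman rank correlation of line values shared between two
    environments (average ranks on ties)."""
    shared = blues_env1.dropna().index.intersection(blues_env2.dropna().index)
    if len(shared) < 2:
        raise ValueError("need at least two shared lines")
    rho, _ = stats.spearmanr(blues_env1[shared], blues_env2[shared])
    return float(rho)


def subset_traits(
    plot_table: pd.DataFrame,
    panel: pd.DataFrame,
    categories=None,
    time_points=None,
) -> pd.DataFrame:
    """View of the plot table keeping only trait columns in the requested
    categories/time points (design and yield columns always retained)."""
    sel = pd.Series(True, index=panel["trait_id"].to_numpy())
    if categories is not None:
        unknown = set(categories) - set(panel["category"])
        if unknown:
            raise ValueError(f"unknown categories: {sorted(unknown)}")
        sel &= panel.set_index("trait_id")["category"].isin(categories)
    if time_points is not None:
        unknown = set(time_points) - set(panel["time_point"])
        if unknown:
            raise ValueError(f"unknown time points: {sorted(unknown)}")
        sel &= panel.set_index("trait_id")["time_point"].isin(time_points)
    chosen = [t for t in panel["trait_id"] if sel[t]]
    if not chosen:
        raise ValueError("trait subset selection is empty")
    other = [c for c in plot_table.columns if c not in set(panel["trait_id"])]
    return plot_table[other + chosen]


# ---------------------------------------------------------------------------
# study dataset prepared for evaluation
# ---------------------------------------------------------------------------


def _blues_table(plots: pd.DataFrame, varcomp, responses) -> pd.DataFrame:
    """GLS line estimates per environment for many responses at once
    (one factorisation per environment; the design part is shared)."""
    s2b = varcomp.sigma2.get("block", 0.0)
    s2s = varcomp.sigma2.get("sub_block", 0.0)
    s2e = varcomp.sigma2_e
    out = []
    for env, sub in plots.groupby("env", sort=False):
        Y = sub[responses].to_numpy(dtype=float)
        X, lines = mixed_models._dummies(sub["line"].astype(str))
        Zb, _ = mixed_models._dummies(sub["block"].astype(str))
        Zs, _ = mixed_models._dummies(sub["sub_block"].astype(str))
        Z = np.hstack([Zb, Zs])
        d = np.concatenate([np.full(Zb.shape[1], s2b), np.full(Zs.shape[1], s2s)])
        Zsc = Z * np.sqrt(d)
        K = np.eye(Z.shape[1]) + Zsc.T @ Zsc / s2e
        ViX = (X - Zsc @ np.linalg.solve(K, Zsc.T @ X) / s2e) / s2e
        beta = np.linalg.solve(X.T @ ViX, ViX.T @ Y)
        df = pd.DataFrame(beta, index=lines, columns=responses)
        df.insert(0, "env", env)
        df.index.name = "line"
        out.append(df.reset_index())
    return pd.concat(out, ignore_index=True)


@dataclass
class StudyData:
    """Everything run_scheme needs: plot table with traits, trait panel,
    QC'd genotypes, and the per-(line, environment) BLUE table for yield
    and every trait."""

    plots: pd.DataFrame
    panel: pd.DataFrame
    genotypes: mixed_models.MarkerMatrix
    blues: pd.DataFrame  # tidy: line, env, yield_t_ha + one column per trait
    env_year: dict = field(default_factory=dict)
    qc_report: object | None = None
    varcomp: object | None = None

    @property
    def trait_ids(self) -> list:
        return list(self.panel["trait_id"])

    @property
    def env_ids(self) -> list:
        return list(pd.unique(self.plots["env"]))

    @classmethod
    def from_simulation(
        cls,
        sim: SimDataset,
        pic_threshold: float = 0.1,
        r_threshold: float = 0.9,
        exclude_checks: bool = True,
    ) -> "StudyData":
        """Run the standard preparation chain on a simulated study: marker
        QC, REML block variances, and line-by-environment BLUEs for yield
        and all traits. Check plots are excluded by default."""
        plots = sim.plots
        if exclude_checks and "is_check" in plots:
            plots = plots[~plots["is_check"]].reset_index(drop=True)
        geno, report = marker_qc.run_qc(sim.genotypes, pic_threshold, r_threshold)
        vc = mixed_models.reml_blocks(plots)
        blues = _blues_table(plots, vc, ["yield_t_ha", *sim.panel["trait_id"]])
        env_year = {e.id: e.year for e in sim.environments}
        return cls(plots, sim.panel, geno, blues, env_year, report, vc)


# ---------------------------------------------------------------------------
# running a scheme
# ---------------------------------------------------------------------------


def _unit_table(data: StudyData, scheme: MaskingScheme) -> pd.DataFrame:
    """One row per maskable unit with its predictors and response."""
    traits = data.trait_ids
    if scheme.unit == "plots":
        tab = data.plots[["plot_id", "env", "line", "yield_t_ha", *traits]].copy()
        tab = tab.rename(columns={"plot_id": "unit_id"})
    else:
        tab = data.blues.copy()
        tab["unit_id"] = tab["line"].astype(str) + "@" + tab["env"].astype(str)
    return tab.set_index("unit_id")


def _marker_block(data: StudyData, lines) -> pd.DataFrame:
    dos = data.genotypes.dosages
    filled = dos.fillna(dos.mean(axis=0))
    return filled.reindex(lines).reset_index(drop=True)


def _records(pred, obs, env, scheme, method, predictor_set, rep) -> list:
    recs = []
    for e in pd.unique(env):
        sel = env == e
        if sel.sum() >= 2:
            recs.append(
                dict(scheme=scheme.id, method=method, predictor_set=predictor_set,
                     env=e, rep=rep, accuracy=accuracy_r2(pred[sel], obs[sel]),
                     n_test=int(sel.sum()))
            )
    if len(pd.unique(env)) > 1 and len(obs) >= 2:
        recs.append(
            dict(scheme=scheme.id, method=method, predictor_set=predictor_set,
                 env="pooled", rep=rep, accuracy=accuracy_r2(pred, obs),
                 n_test=int(len(obs)))
        )
    return recs


def _zscore_by_env(tab: pd.DataFrame, col: str, train_idx) -> pd.Series:
    """Standardise a column within environment using training moments."""
    out = pd.Series(np.nan, index=tab.index)
    for e in pd.unique(tab["env"]):
        sel = tab["env"] == e
        tr = sel & tab.index.isin(train_idx)
        mu = tab.loc[tr, col].mean()
        sd = tab.loc[tr, col].std(ddof=0) or 1.0
        if tr.sum() == 0:
            mu, sd = tab.loc[sel, col].mean(), tab.loc[sel, col].std(ddof=0) or 1.0
        out[sel] = (tab.loc[sel, col] - mu) / sd
    return out


def run_scheme(
    data: StudyData,
    method: str,
    predictor_set: str,
    scheme: MaskingScheme,
    seed: int = 0,
    trait_subset: dict | None = None,
    lambda1_rule: str = "cv",
    lambda1: float | None = None,
    cv_path: int = 20,
    cv_folds: int = 5,
    k_components: int = 3,
    co_kind: str = "pls",
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> pd.DataFrame:
    """Evaluate one (method, predictor set) under a masking scheme.

    Penalized methods fit on the unit table (plots or line BLUEs) with the
    response standardised per location; GBLUP methods operate on line BLUEs
    (within-environment z-scores, averaged over training environments per
    line) with the marker-derived relationship matrix, multivariate GBLUP
    adding PCO or PLS component scores of the trait panel as co-responses.
    Returns one accuracy row per (target environment, replicate) plus a
    pooled row.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    if method in ("gblup", "mv_gblup"):
        if predictor_set != "markers" and method == "gblup":
            raise ValueError("gblup uses marker data; predictor_set must be 'markers'")
        if data.genotypes is None:
            raise ValueError("GBLUP requires genotypes")
        if scheme.unit != "line_blues":
            raise ValueError("GBLUP schemes operate on line BLUEs")
    panel = data.panel
    if trait_subset is not None:
        sel = pd.Series(True, index=panel.index)
        if "categories" in trait_subset:
            sel &= panel["category"].isin(trait_subset["categories"])
        if "time_points" in trait_subset:
            sel &= panel["time_point"].isin(trait_subset["time_points"])
        panel = panel[sel]
        if panel.empty:
            raise ValueError("trait subset selection is empty")
    traits = list(panel["trait_id"])
    tab = _unit_table(data, scheme)
    tab = tab[tab["env"].isin(scheme.envs)]
    grm = comp = None
    if method in ("gblup", "mv_gblup"):
        grm = mixed_models.grm_vanraden(data.genotypes)
        if method == "mv_gblup":
            comp = _component_scores(data, traits, co_kind, k_components)
    records = []
    for rep in range(scheme.n_reps):
        train_ids, test_ids = make_masks(
            scheme, tab.reset_index()[["unit_id", "env"]], rep, seed
        )
        if len(test_ids) < 2:
            continue
        tr = tab.loc[train_ids]
        te = tab.loc[test_ids]
        if method in ("lasso", "enet", "ridge"):
            spec = {
                "lasso": penalized.PenaltySpec.lasso(),
                "enet": penalized.PenaltySpec.elastic_net(),
                "ridge": penalized.PenaltySpec.ridge(),
            }[method]
            blocks = {"traits": tr[traits]}
            test_blocks = [te[traits]]
            if predictor_set in ("markers", "combined"):
                blocks["markers"] = _marker_block(data, tr["line"])
                test_blocks = (
                    [te[traits], _marker_block(data, te["line"]).set_axis(te.index)]
                    if predictor_set == "combined"
                    else [_marker_block(data, te["line"]).set_axis(te.index)]
                )
                blocks["markers"].index = tr.index
            model = penalized.fit_predictor(
                blocks, tr["yield_t_ha"].to_numpy(), predictor_set, spec,
                lambda1_rule=lambda1_rule, lambda1=lambda1,
                locations=tr["env"].to_numpy(),
                seed=int(child_rng(seed, scheme.id, rep).integers(2**31)),
                tol=tol, max_iter=max_iter, cv_folds=cv_folds, cv_path=cv_path,
            )
            X_test = pd.concat(test_blocks, axis=1)
            pred = penalized.predict(model, X_test, locations=te["env"].to_numpy())
            records += _records(pred, te["yield_t_ha"].to_numpy(),
                                te["env"].to_numpy(), scheme, method,
                                predictor_set, rep)
        else:
            z = _zscore_by_env(tab, "yield_t_ha", train_ids)
            y_train = z.loc[train_ids].groupby(tab.loc[train_ids, "line"]).mean()
            y_train = y_train.reindex(grm.line_ids)
            if method == "gblup":
                pred_lines, _ = mixed_models.gblup_fit(y_train, grm)
            else:
                Y = pd.concat([y_train.rename("yield"), comp], axis=1)
                pred_lines, _ = mixed_models.mv_gblup_fit(Y, grm)
            pred = pred_lines.reindex(te["line"]).to_numpy()
            obs = z.loc[test_ids].to_numpy()
            ok = ~np.isnan(pred)
            records += _records(pred[ok], obs[ok], te["env"].to_numpy()[ok],
                                scheme, method, predictor_set, rep)
    return pd.DataFrame.from_records(records)


def _component_scores(data: StudyData, traits, kind: str, k: int) -> pd.DataFrame:
    """Line-level PCO/PLS scores of the trait BLUEs, averaged over
    environments (observed on every line; used as co-responses)."""
    wide = data.blues.groupby("line")[traits].mean()
    y = data.blues.groupby("line")["yield_t_ha"].mean().reindex(wide.index)
    if kind == "pco":
        cs = trait_reduction.select_pco(wide, y.to_numpy(), k=k)
    elif kind == "pls":
        cs = trait_reduction.pls_components(wide, y.to_numpy(), k=k)
    else:
        raise ValueError("co_kind must be 'pco' or 'pls'")
    scores = cs.scores.copy()
    return (scores - scores.mean()) / scores.std(ddof=0)


def aggregate(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of accuracy per (scheme, method, predictor set, target
    environment), plus equal-weight within-year pooled averages when the
    records carry a year mapping."""
    if records.empty:
        raise ValueError("no records to aggregate")
    g = records.groupby(["scheme", "method", "predictor_set", "env"])["accuracy"]
    out = g.agg(mean_accuracy="mean", sd_accuracy="std", n="count").reset_index()
    out["sd_accuracy"] = out["sd_accuracy"].fillna(0.0)
    return out
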