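"""Penalized linear regression for phenomic/genomic yield prediction.

Lasso, elastic net and ridge share one objective,

    (1/2n) ||y - b0 - X b||^2 + lambda1 ||b||_1 + (lambda2/2) ||b||^2,

minimised by cyclic coordinate descent with soft-thresholding on
standardised predictors. The quadratic penalty is fixed by method
convention (0 for lasso, 0.1 for elastic net, 1 for ridge); the L1 strength
is chosen by internal cross-validation over a log-spaced path unless fixed
explicitly. Responses can be standardised per trial location so that
coefficients are comparable across environments and predictions are
returned on the original t/ha scale per location.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._cd import cd_solve
from ._rng import child_rng

__all__ = [
    "PenaltySpec",
    "Standardizer",
    "FittedModel",
    "standardize",
    "elastic_net_cd",
    "ridge_closed_form",
    "fit_predictor",
    "predict",
    "objective",
]


@dataclass(frozen=True)
class PenaltySpec:
    """L1/quadratic penalty weights with a method label."""

    lambda1: float
    lambda2: float
    label: str

    def __post_init__(self):
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ValueError("penalty weights must be non-negative")
        if self.label == "lasso" and self.lambda2 != 0:
            raise ValueError("lasso requires lambda2 = 0")
        if self.label == "ridge" and self.lambda1 != 0:
            raise ValueError("ridge requires lambda1 = 0")
        if self.label not in ("lasso", "elastic_net", "ridge"):
            raise ValueError(f"unknown label {self.label!r}")

    @classmethod
    def lasso(cls, lambda1: float = 0.0) -> "PenaltySpec":
        return cls(lambda1, 0.0, "lasso")

    @classmethod
    def elastic_net(cls, lambda1: float = 0.0, lambda2: float = 0.1) -> "PenaltySpec":
        return cls(lambda1, lambda2, "elastic_net")

    @classmethod
    def ridge(cls, lambda2: float = 1.0) -> "PenaltySpec":
        return cls(0.0, lambda2, "ridge")


@dataclass
class Standardizer:
    """Column standardisation for X and (optionally per-location) y."""

    col_mean: pd.Series
    col_sd: pd.Series
    dropped: list
    y_mean: float | dict = 0.0
    y_sd: float | dict = 1.0
    per_location: bool = False

    def transform_X(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.col_mean.index if c not in X.columns]
        extra = [
            c for c in X.columns
            if c not in self.col_mean.index and c not in self.dropped
        ]
        if missing or extra:
            raise ValueError(
                f"predictor columns do not match training: "
                f"missing={missing[:5]}, extra={extra[:5]}"
            )
        X = X[self.col_mean.index]
        return (X.to_numpy(dtype=float) - self.col_mean.to_numpy()) / self.col_sd.to_numpy()

    def _loc_moments(self, locations):
        # unseen locations (whole-location prediction) fall back to the
        # pooled training moments; accuracy is scale-invariant anyway
        mu0 = float(np.mean(list(self.y_mean.values())))
        sd0 = float(np.mean(list(self.y_sd.values())))
        mu = np.array([self.y_mean.get(loc, mu0) for loc in locations])
        sd = np.array([self.y_sd.get(loc, sd0) for loc in locations])
        return mu, sd

    def transform_y(self, y, locations=None) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        if not self.per_location:
            return (y - self.y_mean) / self.y_sd
        mu, sd = self._loc_moments(np.asarray(locations))
        return (y - mu) / sd

    def inverse_y(self, y_std, locations=None) -> np.ndarray:
        y_std = np.asarray(y_std, dtype=float)
        if not self.per_location:
            return y_std * self.y_sd + self.y_mean
        if locations is None:
            raise ValueError("per-location transform requires location labels")
        mu, sd = self._loc_moments(np.asarray(locations))
        return y_std * sd + mu


def standardize(
    X: pd.DataFrame, y, locations=None
) -> tuple[np.ndarray, np.ndarray, Standardizer]:
    """Center/scale predictors to unit SD (training rows only); optionally
    center/scale the response within each trial location, storing the
    inverse transform. Zero-SD columns are dropped with a warning."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    dropped = list(X.columns[sd == 0])
    if dropped:
        warnings.warn(f"dropping {len(dropped)} zero-variance column(s)", stacklevel=2)
    keep = sd > 0
    std = Standardizer(mean[keep], sd[keep], dropped)
    y = np.asarray(y, dtype=float)
    if locations is not None:
        locations = np.asarray(locations)
        std.per_location = True
        std.y_mean = {loc: float(y[locations == loc].mean()) for loc in np.unique(locations)}
        std.y_sd = {
            loc: float(y[locations == loc].std(ddof=0)) or 1.0
            for loc in np.unique(locations)
        }
    else:
        std.y_mean = float(y.mean())
        std.y_sd = 1.0  # keep response in t/ha; only centered
    return std.transform_X(X), std.transform_y(y, locations), std


@dataclass
class FittedModel:
    """A fitted penalized model plus everything needed to predict."""

    intercept: float
    coef: pd.Series  # on the standardized-predictor scale
    standardizer: Standardizer
    spec: PenaltySpec
    n_iter: int = 0
    converged: bool = True
    predictor_set: str | None = None
    meta: dict = field(default_factory=dict)

    def coef_original_scale(self) -> pd.Series:
        """Coefficients back-transformed to the original predictor units."""
        return self.coef / self.standardizer.col_sd


def objective(X, y, b, lambda1, lambda2, intercept=0.0) -> float:
    """The penalized objective; used by monotonicity and oracle tests."""
    r = y - intercept - X @ b
    n = len(y)
    return float(
        0.5 * r @ r / n + lambda1 * np.abs(b).sum() + 0.5 * lambda2 * b @ b
    )


def elastic_net_cd(
    X_std: np.ndarray,
    y_std: np.ndarray,
    spec: PenaltySpec,
    tol: float = 1e-7,
    max_iter: int = 10000,
    b0: np.ndarray | None = None,
) -> tuple[np.ndarray, float, int, bool]:
    """Coordinate-descent solve on standardized inputs.

    Returns (coefficients, intercept, iterations, converged). Convergence is
    declared when the largest coefficient update in a sweep falls below
    ``tol``; otherwise a warning is raised and the flag set False.
    """
    yc = y_std - y_std.mean()
    b, it, conv = cd_solve(X_std, yc, spec.lambda1, spec.lambda2, b0=b0,
                           tol=tol, max_iter=max_iter)
    if not conv:
        warnings.warn(
            f"coordinate descent did not converge in {max_iter} sweeps", stacklevel=2
        )
    return b, float(y_std.mean()), it, conv


def ridge_closed_form(X_std: np.ndarray, y_std: np.ndarray, lambda2: float):
    """Closed-form ridge b = (X'X/n + lambda2 I)^-1 X'y/n (on centered y);
    the fast path for ridge and the oracle for the CD solver at lambda1=0."""
    n, p = X_std.shape
    yc = y_std - y_std.mean()
    A = X_std.T @ X_std / n + lambda2 * np.eye(p)
    rhs = X_std.T @ yc / n
    try:
        b = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError:  # pragma: no cover
        warnings.warn("singular ridge system; adding jitter", stacklevel=2)
        b = np.linalg.solve(A + 1e-10 * np.eye(p), rhs)
    return b, float(y_std.mean())


def lambda1_max(X_std: np.ndarray, y_std: np.ndarray) -> float:
    """Smallest L1 weight at which all coefficients are exactly zero."""
    yc = y_std - y_std.mean()
    return float(np.abs(X_std.T @ yc).max() / len(yc))


def _cv_lambda1(
    X: np.ndarray,
    y: np.ndarray,
    spec: PenaltySpec,
    n_folds: int,
    n_path: int,
    seed: int,
    tol: float,
    max_iter: int,
) -> float:
    """Internal k-fold CV over a log-spaced L1 path with warm starts."""
    lmax = lambda1_max(X, y)
    if lmax <= 0:
        return 0.0
    path = np.geomspace(lmax, lmax * 1e-3, n_path)
    rng = child_rng(seed, "lambda1-cv")
    folds = rng.permutation(len(y)) % n_folds
    mse = np.zeros(n_path)
    for f in range(n_folds):
        tr, va = folds != f, folds == f
        b = None
        for i, lam in enumerate(path):
            b, _, _ = cd_solve(X[tr], y[tr] - y[tr].mean(), lam, spec.lambda2,
                               b0=b, tol=tol, max_iter=max_iter)
            pred = y[tr].mean() + X[va] @ b
            mse[i] += ((y[va] - pred) ** 2).sum()
    return float(path[int(np.argmin(mse))])


def fit_predictor(
    blocks: dict,
    y,
    predictor_set: str,
    spec: PenaltySpec,
    lambda1_rule: str = "cv",
    lambda1: float | None = None,
    locations=None,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
    cv_folds: int = 5,
    cv_path: int = 50,
) -> FittedModel:
    """Fit yield on traits, markers or both.

    ``blocks`` maps block names ("traits", "markers") to predictor
    DataFrames over the training observations; blocks are standardized
    separately and concatenated for ``predictor_set="combined"``. The
    quadratic penalty comes from ``spec``; the L1 weight is either fixed
    (``lambda1_rule="fixed"`` with ``lambda1``) or chosen by internal
    ``cv_folds``-fold cross-validation over a ``cv_path``-point log path
    minimising validation MSE.
    """
    wanted = {"traits": ["traits"], "markers": ["markers"],
              "combined": ["traits", "markers"]}.get(predictor_set)
    if wanted is None:
        raise ValueError(f"unknown predictor set {predictor_set!r}")
    missing = [w for w in wanted if w not in blocks]
    if missing:
        raise ValueError(f"predictor set {predictor_set!r} needs blocks {missing}")
    X = pd.concat([blocks[w] for w in wanted], axis=1)
    if len(X) < 10:
        raise ValueError("need at least 10 training rows")
    X_std, y_std, std = standardize(X, y, locations)
    if spec.label == "ridge":
        lam1 = 0.0
    elif lambda1_rule == "fixed":
        if lambda1 is None:
            raise ValueError("lambda1_rule='fixed' requires lambda1")
        lam1 = float(lambda1)
    elif lambda1_rule == "cv":
        lam1 = _cv_lambda1(X_std, y_std, spec, cv_folds, cv_path, seed, tol, max_iter)
    else:
        raise ValueError(f"unknown lambda1 rule {lambda1_rule!r}")
    eff_spec = PenaltySpec(lam1, spec.lambda2, spec.label)
    if spec.label == "ridge":
        b, b0 = ridge_closed_form(X_std, y_std, spec.lambda2)
        it, conv = 0, True
    else:
        b, b0, it, conv = elastic_net_cd(X_std, y_std, eff_spec, tol, max_iter)
    return FittedModel(
        intercept=b0,
        coef=pd.Series(b, index=std.col_mean.index),
        standardizer=std,
        spec=eff_spec,
        n_iter=it,
        converged=conv,
        predictor_set=predictor_set,
        meta={"lambda1_rule": lambda1_rule},
    )


def predict(model: FittedModel, X_new: pd.DataFrame, locations=None) -> np.ndarray:
    """Predict on the original yield scale (per-location back-transform when
    the model was trained with per-location response scaling)."""
    X_std = model.standardizer.transform_X(X_new)
    y_std = model.intercept + X_std @ model.coef.to_numpy()
    return model.standardizer.inverse_y(y_std, locations)
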