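"""Mixed linear models for the trial analysis.

Implements, at desk scale and in dense linear algebra:

* EM-REML variance components for the block/sub-block design
  (y = environment + line(fixed) + block(random) + sub-block(random) + e);
* generalized-least-squares line BLUEs per environment given those
  components;
* the VanRaden genomic relationship matrix from (possibly fractional,
  pooled) marker dosages;
* univariate GBLUP via Henderson's mixed-model equations, predicting
  unphenotyped lines, with optional EM-REML estimation of the genetic and
  residual variances;
* multivariate GBLUP in which phenomic component scores act as
  co-responses: trait covariance matrices are estimated on lines with
  complete records (eigen-rotation of the kernel makes the EM cheap) and
  masked yields are predicted conditionally on the observed co-responses.

Relationship information enters only through markers; no pedigree is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simdata import MarkerMatrix

__all__ = [
    "VarianceComponents",
    "GRM",
    "IdentifiabilityError",
    "em_reml",
    "reml_blocks",
    "compute_blues",
    "grm_vanraden",
    "gblup_fit",
    "mv_gblup_fit",
]


class IdentifiabilityError(ValueError):
    """The design cannot separate the requested effects."""


@dataclass
class VarianceComponents:
    """REML variance components; multivariate runs carry trait covariance
    matrices (genetic G_t, residual R_t) instead."""

    sigma2: dict = field(default_factory=dict)  # component name -> variance
    sigma2_e: float = np.nan
    G_t: pd.DataFrame | None = None
    R_t: pd.DataFrame | None = None
    loglik_trace: list = field(default_factory=list)
    converged: bool = True

    def __post_init__(self):
        for k, v in self.sigma2.items():
            if v < 0:
                raise ValueError(f"negative variance for {k}")


# ---------------------------------------------------------------------------
# generic EM-REML for independent random factors
# ---------------------------------------------------------------------------


def _reml_loglik(y, X, Z, d, sigma2_e):
    """REML log-likelihood (up to a constant) for V = sigma2_e I + Z D Z'
    with D = diag(d); computed by Woodbury in the q x q inner space."""
    n, p = X.shape
    sq = np.sqrt(np.clip(d, 0.0, None))
    Zs = Z * sq  # Z D^{1/2}
    q = Z.shape[1]
    K = np.eye(q) + Zs.T @ Zs / sigma2_e
    sign, logdetK = np.linalg.slogdet(K)
    logdetV = n * np.log(sigma2_e) + logdetK

    def vinv(M):
        return (M - Zs @ np.linalg.solve(K, Zs.T @ M) / sigma2_e) / sigma2_e

    ViX = vinv(X)
    Viy = vinv(y[:, None])[:, 0]
    XtViX = X.T @ ViX
    sign2, logdetXVX = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, X.T @ Viy)
    yPy = y @ Viy - (X.T @ Viy) @ beta
    return -0.5 * (logdetV + logdetXVX + yPy)


def em_reml(
    y: np.ndarray,
    X: np.ndarray,
    Z_blocks: dict,
    tol: float = 1e-8,
    max_iter: int = 500,
    init: dict | None = None,
    accelerate: bool = True,
) -> tuple[VarianceComponents, np.ndarray, dict]:
    """EM-REML for y = X beta + sum_i Z_i u_i + e, u_i ~ N(0, sigma2_i I).

    One Cholesky factorisation of the mixed-model-equation matrix per
    iteration yields the solution, the restricted log-likelihood (via
    -2 lR = (n-p-q) ln s2e + sum_i q_i ln s2_i + ln|M| + y'Py / s2e) and the
    traces needed for the EM updates. Plain EM steps are interleaved with
    safeguarded Aitken extrapolations: an extrapolated step is kept only if
    it does not decrease the likelihood, so the recorded trace is
    non-decreasing. Convergence is a successive log-likelihood change below
    ``tol``; otherwise a warning is raised and the last iterate returned.

    Returns (components with log-likelihood trace, fixed-effect solution,
    dict of random-effect BLUPs at the final iterate).
    """
    from scipy import linalg as sla

    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise IdentifiabilityError("fixed-effect design matrix is rank deficient")
    if n <= p:
        raise IdentifiabilityError("no residual degrees of freedom")
    names = list(Z_blocks)
    Zs = [np.asarray(Z_blocks[k], dtype=float) for k in names]
    q = [Z.shape[1] for Z in Zs]
    q_tot = sum(q)
    Z = np.hstack(Zs)
    W = np.hstack([X, Z])
    WtW = W.T @ W
    Wty = W.T @ y
    yty = y @ y
    vary = y.var(ddof=1) or 1.0
    floor = 1e-10 * vary

    def state_eval(sig, sig_e):
        """Factorise the MME at (sig, sig_e): returns loglik, solution and
        per-block inverse traces."""
        lam = np.concatenate(
            [np.zeros(p)] + [np.full(qi, sig_e / max(sig[k], floor))
                             for k, qi in zip(names, q)]
        )
        M = WtW + np.diag(lam)
        c, low = sla.cho_factor(M, lower=True, check_finite=False)
        sol = sla.cho_solve((c, low), Wty, check_finite=False)
        logdetM = 2.0 * np.log(np.diag(c)).sum()
        yPy = (yty - sol @ Wty) / sig_e
        ll = -0.5 * (
            (n - p - q_tot) * np.log(sig_e)
            + sum(qi * np.log(max(sig[k], floor)) for k, qi in zip(names, q))
            + logdetM
            + yPy
        )
        Minv = sla.cho_solve((c, low), np.eye(M.shape[0]), check_finite=False)
        traces = {}
        off = p
        for k, qi in zip(names, q):
            traces[k] = float(np.trace(Minv[off : off + qi, off : off + qi]))
            off += qi
        return ll, sol, traces

    def em_step(sig, sig_e, sol, traces):
        new = {}
        off = p
        for k, qi in zip(names, q):
            u = sol[off : off + qi]
            new[k] = max((u @ u + sig_e * traces[k]) / qi, 0.0)
            off += qi
        sig_e_new = max((yty - sol @ Wty) / (n - p), floor)
        return new, sig_e_new

    sig = {k: (init or {}).get(k, vary / (len(names) + 1)) for k in names}
    sig_e = (init or {}).get("residual", vary / (len(names) + 1))
    trace = []
    converged = False
    prev = None  # previous (sig, sig_e) for Aitken extrapolation
    ll, sol, tr = state_eval(sig, sig_e)
    for it in range(max_iter):
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        new_sig, new_sig_e = em_step(sig, sig_e, sol, tr)
        if accelerate and prev is not None and it % 3 == 2:
            # component-wise Aitken: extrapolate along the EM direction
            acc_sig, ok = {}, True
            for k in names:
                d1 = sig[k] - prev[0][k]
                d2 = new_sig[k] - sig[k]
                r = d2 / d1 if abs(d1) > 1e-300 else 0.0
                if 0 < r < 1:
                    acc_sig[k] = max(sig[k] + d2 / (1 - r), floor)
                else:
                    acc_sig[k] = new_sig[k]
            d1e = sig_e - prev[1]
            d2e = new_sig_e - sig_e
            re_ = d2e / d1e if abs(d1e) > 1e-300 else 0.0
            acc_sig_e = (
                max(sig_e + d2e / (1 - re_), floor) if 0 < re_ < 1 else new_sig_e
            )
            ll_acc, sol_acc, tr_acc = state_eval(acc_sig, acc_sig_e)
            if ll_acc >= ll:  # keep only non-decreasing steps
                prev = (sig, sig_e)
                sig, sig_e = acc_sig, acc_sig_e
                ll, sol, tr = ll_acc, sol_acc, tr_acc
                continue
        prev = (sig, sig_e)
        sig, sig_e = new_sig, new_sig_e
        ll, sol, tr = state_eval(sig, sig_e)
    if not converged:
        warnings.warn("EM-REML did not converge; returning last iterate",
                      stacklevel=2)
    beta = sol[:p]
    blups = {}
    off = p
    for k, qi in zip(names, q):
        blups[k] = sol[off : off + qi]
        off += qi
    vc = VarianceComponents(
        sigma2={k: float(sig[k]) for k in names},
        sigma2_e=float(sig_e),
        loglik_trace=trace,
        converged=converged,
    )
    return vc, beta, blups


# ---------------------------------------------------------------------------
# trial model: blocks and BLUEs
# ---------------------------------------------------------------------------


def _dummies(labels) -> tuple[np.ndarray, list]:
    labels = pd.Series(list(labels))
    levels = list(pd.unique(labels))
    Z = (labels.to_numpy()[:, None] == np.array(levels)[None, :]).astype(float)
    return Z, levels


def reml_blocks(
    plots: pd.DataFrame,
    response: str = "yield_t_ha",
    tol: float = 1e-8,
    max_iter: int = 500,
) -> VarianceComponents:
    """EM-REML for the trial model with environment and line as fixed
    effects and block and sub-block (nested labels) as random effects.

    ``plots`` must carry env/block/sub_block/line columns and the response.
    """
    if plots["block"].groupby(plots["env"]).nunique().min() < 2:
        raise IdentifiabilityError("need at least two blocks per environment")
    y = plots[response].to_numpy(dtype=float)
    env_X, _ = _dummies(plots["env"].astype(str))
    line_X, line_levels = _dummies(plots["line"].astype(str))
    X = np.hstack([env_X, line_X[:, 1:]])  # first line as reference level
    Zb, _ = _dummies(plots["env"].astype(str) + ":" + plots["block"].astype(str))
    Zs, _ = _dummies(plots["env"].astype(str) + ":" + plots["sub_block"].astype(str))
    vc, _, _ = em_reml(y, X, {"block": Zb, "sub_block": Zs}, tol=tol, max_iter=max_iter)
    return vc


def compute_blues(
    plots: pd.DataFrame,
    varcomp: VarianceComponents,
    response: str = "yield_t_ha",
) -> pd.DataFrame:
    """Generalized-least-squares line means per environment.

    For each environment, lines are fixed cell means and V collects the
    block, sub-block and residual variances from ``varcomp``. Lines without
    plots in an environment simply have no row. Returns a tidy frame
    (line, env, blue, se)."""
    s2b = varcomp.sigma2.get("block", 0.0)
    s2s = varcomp.sigma2.get("sub_block", 0.0)
    s2e = varcomp.sigma2_e
    out = []
    for env, sub in plots.groupby("env", sort=False):
        y = sub[response].to_numpy(dtype=float)
        X, lines = _dummies(sub["line"].astype(str))
        Zb, _ = _dummies(sub["block"].astype(str))
        Zs, _ = _dummies(sub["sub_block"].astype(str))
        Z = np.hstack([Zb, Zs])
        d = np.concatenate([np.full(Zb.shape[1], s2b), np.full(Zs.shape[1], s2s)])
        sq = np.sqrt(d)
        Zsc = Z * sq
        K = np.eye(Z.shape[1]) + Zsc.T @ Zsc / s2e

        def vinv(M):
            return (M - Zsc @ np.linalg.solve(K, Zsc.T @ M) / s2e) / s2e

        ViX = vinv(X)
        XtViX = X.T @ ViX
        beta = np.linalg.solve(XtViX, ViX.T @ y)
        se = np.sqrt(np.diag(np.linalg.inv(XtViX)))
        out.append(pd.DataFrame({"line": lines, "env": env, "blue": beta, "se": se}))
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# genomic relationship and GBLUP
# ---------------------------------------------------------------------------


@dataclass
class GRM:
    """Marker-derived line x line relationship matrix (VanRaden scaling)."""

    matrix: pd.DataFrame
    allele_freq: pd.Series

    def __post_init__(self):
        A = self.matrix.to_numpy()
        if not np.allclose(A, A.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")

    @property
    def line_ids(self):
        return list(self.matrix.index)

    def values(self) -> np.ndarray:
        return self.matrix.to_numpy(dtype=float)


def grm_vanraden(matrix: MarkerMatrix) -> GRM:
    """G = Z Z' / (2 sum p(1-p)) with Z = dosage - 2p; monomorphic markers
    are excluded. Valid for fractional pooled dosages (p = mean dosage / 2)."""
    dos = matrix.dosages
    if dos.isna().any().any():
        raise ValueError("GRM requires complete (imputed) dosages")
    p = (dos.mean(axis=0) / 2.0).clip(0.0, 1.0)
    poly = dos.std(axis=0, ddof=0) > 0
    if not poly.any():
        raise ValueError("all markers are monomorphic")
    dos = dos.loc[:, poly]
    p = p[poly]
    Z = dos.to_numpy(dtype=float) - 2.0 * p.to_numpy()
    denom = 2.0 * float((p * (1.0 - p)).sum())
    G = Z @ Z.T / denom
    return GRM(pd.DataFrame(G, index=dos.index, columns=dos.index), p)


def _grm_root(G: np.ndarray) -> np.ndarray:
    """L with G = L L' (eigen square root, small negatives clipped)."""
    w, V = np.linalg.eigh(G)
    w = np.clip(w, 0.0, None)
    keep = w > 1e-10 * w.max() if w.max() > 0 else w > -1
    return V[:, keep] * np.sqrt(w[keep])


def gblup_fit(
    y: pd.Series,
    grm: GRM,
    varcomp: VarianceComponents | tuple | str = "estimate",
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[pd.Series, VarianceComponents]:
    """Univariate GBLUP with prediction of unphenotyped lines.

    ``y`` is indexed by line id; NaN entries (and lines absent from the
    index but present in the GRM) are predicted. With
    ``varcomp="estimate"``, genetic and residual variances are estimated by
    EM-REML on the observed subset using the factorisation u = L a,
    G = L L', which reduces GBLUP to the generic mixed-model machinery.
    Returns (predictions mu + u for every GRM line, variance components).
    """
    lines = grm.line_ids
    y_full = y.reindex(lines)
    obs = y_full.notna().to_numpy()
    if obs.sum() < 1:
        raise ValueError("need at least one observed response")
    G = grm.values()
    L = _grm_root(G)
    y_o = y_full.to_numpy(dtype=float)[obs]
    X_o = np.ones((obs.sum(), 1))
    if isinstance(varcomp, str) and varcomp == "estimate":
        vc, _, _ = em_reml(y_o, X_o, {"genetic": L[obs]}, tol=tol, max_iter=max_iter)
        s2g, s2e = vc.sigma2["genetic"], vc.sigma2_e
    else:
        if isinstance(varcomp, VarianceComponents):
            s2g, s2e = varcomp.sigma2["genetic"], varcomp.sigma2_e
        else:
            s2g, s2e = map(float, varcomp)
        vc = VarianceComponents(sigma2={"genetic": s2g}, sigma2_e=s2e)
    V = s2g * G[np.ix_(obs, obs)] + s2e * np.eye(int(obs.sum()))
    try:
        Vi = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        warnings.warn("singular GBLUP system; adding ridge jitter", stacklevel=2)
        Vi = np.linalg.inv(V + 1e-8 * np.eye(V.shape[0]))
    ones = np.ones(int(obs.sum()))
    mu = float(ones @ Vi @ y_o / (ones @ Vi @ ones))
    u = s2g * G[:, obs] @ (Vi @ (y_o - mu))
    return pd.Series(mu + u, index=lines), vc


# ---------------------------------------------------------------------------
# multivariate GBLUP with co-responses
# ---------------------------------------------------------------------------


def _mv_em(Yt: np.ndarray, d: np.ndarray, tol: float, max_iter: int):
    """ML-EM for rotated multi-trait data: row i ~ N(0, d_i G_t + R_t).

    ``Yt`` is the kernel-eigenrotated, per-trait-centered data of the
    complete-record lines; ``d`` the kernel eigenvalues. Returns
    (G_t, R_t, loglik trace, converged)."""
    n, t = Yt.shape
    S = Yt.T @ Yt / n
    G_t = 0.5 * S + 1e-6 * np.eye(t)
    R_t = 0.5 * S + 1e-6 * np.eye(t)
    trace = []
    converged = False
    for _ in range(max_iter):
        ll = 0.0
        sumG = np.zeros((t, t))
        sumR = np.zeros((t, t))
        for i in range(n):
            C = d[i] * G_t + R_t
            Ci = np.linalg.inv(C)
            yi = Yt[i]
            sign, logdet = np.linalg.slogdet(C)
            ll += -0.5 * (logdet + yi @ Ci @ yi)
            dG = d[i] * G_t
            m_u = dG @ Ci @ yi
            V_u = dG - dG @ Ci @ dG
            if d[i] > 1e-12:
                sumG += (np.outer(m_u, m_u) + V_u) / d[i]
            else:
                sumG += G_t  # no information: keep prior value
            e = yi - m_u
            V_e = R_t - R_t @ Ci @ R_t
            sumR += np.outer(e, e) + V_e
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        G_t = sumG / n
        R_t = sumR / n
    if not converged:
        warnings.warn("multivariate EM did not converge; using last iterate",
                      stacklevel=2)
    return G_t, R_t, trace, converged


def mv_gblup_fit(
    Y: pd.DataFrame,
    grm: GRM,
    covariance: str | tuple = "estimate",
    tol: float = 1e-6,
    max_iter: int = 200,
) -> tuple[pd.Series, VarianceComponents]:
    """Multivariate GBLUP: predict masked yields given observed co-responses.

    ``Y`` is lines x traits with the response ("yield" must be the first
    column) masked (NaN) on validation lines; co-response columns (e.g. PCO
    or PLS scores) are typically observed everywhere. The model places
    genetic covariance G_t (x) G and residual covariance R_t (x) I over the
    cells; with ``covariance="estimate"`` the trait matrices are fitted by
    eigen-rotated EM on the lines with complete records and then held fixed
    for the conditional prediction. Supplying ``(G_t, R_t)`` skips
    estimation (both must be PSD).

    Returns (predicted response for every GRM line, components).
    """
    lines = grm.line_ids
    Y = Y.reindex(lines)
    traits = list(Y.columns)
    t = len(traits)
    resp = traits[0]
    G = grm.values()
    n = len(lines)
    if isinstance(covariance, str) and covariance == "estimate":
        complete = Y.notna().all(axis=1).to_numpy()
        if complete.sum() < t + 2:
            raise ValueError("too few complete records to estimate covariances")
        Gc = G[np.ix_(complete, complete)]
        w, U = np.linalg.eigh(Gc)
        w = np.clip(w, 0.0, None)
        Yc = Y.loc[complete].to_numpy(dtype=float)
        Yc = Yc - Yc.mean(axis=0)
        G_t, R_t, trace, conv = _mv_em(U.T @ Yc, w, tol, max_iter)
    else:
        G_t, R_t = (np.asarray(M, dtype=float) for M in covariance)
        for M, nm in ((G_t, "G_t"), (R_t, "R_t")):
            if M.shape != (t, t) or not np.allclose(M, M.T):
                raise ValueError(f"{nm} must be a symmetric {t}x{t} matrix")
            if np.linalg.eigvalsh(M).min() < -1e-8:
                raise ValueError(f"{nm} must be positive semi-definite")
        trace, conv = [], True
    vc = VarianceComponents(
        G_t=pd.DataFrame(G_t, index=traits, columns=traits),
        R_t=pd.DataFrame(R_t, index=traits, columns=traits),
        loglik_trace=trace,
        converged=conv,
    )

    # conditional prediction over observed cells
    Yv = Y.to_numpy(dtype=float)
    obs_mask = ~np.isnan(Yv)  # n x t
    cells = np.flatnonzero(obs_mask.T.ravel())  # trait-major ordering
    trait_of = np.repeat(np.arange(t), n)
    line_of = np.tile(np.arange(n), t)
    y_o = Yv.T.ravel()[cells]
    lo, to = line_of[cells], trait_of[cells]
    V = G_t[np.ix_(to, to)] * G[np.ix_(lo, lo)] + R_t[np.ix_(to, to)] * (
        lo[:, None] == lo[None, :]
    )
    try:
        Vi = np.linalg.inv(V)
    except np.linalg.LinAlgError:
        warnings.warn("singular multivariate system; adding ridge jitter",
                      stacklevel=2)
        Vi = np.linalg.inv(V + 1e-8 * np.eye(V.shape[0]))
    X = (to[:, None] == np.arange(t)[None, :]).astype(float)  # per-trait means
    XtViX = X.T @ Vi @ X
    mu = np.linalg.solve(XtViX, X.T @ Vi @ y_o)
    r = y_o - X @ mu
    # BLUP of the genetic value of the response for every line, conditional
    # on all observed cells: Cov(u_resp(l), y cell) = G_t[resp, t'] G[l, l']
    C_mo = G_t[0, to][None, :] * G[:, lo]
    pred = mu[0] + C_mo @ (Vi @ r)
    return pd.Series(pred, index=lines, name=resp), vc
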