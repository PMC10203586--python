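"""Marker quality-control chain: mean imputation, PIC filtering, and greedy
correlation pruning of redundant markers.

The chain runs in the order imputation -> PIC filter (> 0.1, strict) ->
pruning of markers with |r| > 0.9 against an already-retained marker, with a
report of counts and decisions at every stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simdata import MarkerMatrix

__all__ = ["QCReport", "impute_mean", "pic", "filter_pic", "prune_correlated", "run_qc"]


@dataclass
class QCReport:
    """Counts and per-marker decisions along the QC chain."""

    n_input: int = 0
    n_post_impute: int = 0
    n_post_pic: int = 0
    n_post_prune: int = 0
    pic_values: pd.Series | None = None
    dropped_all_missing: list = field(default_factory=list)
    dropped_low_pic: list = field(default_factory=list)
    pruned: dict = field(default_factory=dict)  # dropped marker -> retained anchor
    zero_variance_retained: list = field(default_factory=list)

    def counts(self) -> dict:
        return {
            "input": self.n_input,
            "post_imputation": self.n_post_impute,
            "post_pic": self.n_post_pic,
            "post_pruning": self.n_post_prune,
        }


def impute_mean(matrix: MarkerMatrix, report: QCReport | None = None) -> MarkerMatrix:
    """Replace missing dosages by the marker's observed mean (a stand-in for
    model-based imputation). Markers with no observed values are dropped
    with a warning and recorded in the report."""
    dos = matrix.dosages
    all_missing = dos.columns[dos.isna().all(axis=0)]
    if len(all_missing):
        warnings.warn(
            f"dropping {len(all_missing)} fully missing marker(s)", stacklevel=2
        )
        if report is not None:
            report.dropped_all_missing = list(all_missing)
        dos = dos.drop(columns=all_missing)
    dos = dos.fillna(dos.mean(axis=0))
    if report is not None:
        report.n_post_impute = dos.shape[1]
    return MarkerMatrix(dos, matrix.map)


def pic(allele_freq):
    """Polymorphism information content of a biallelic marker:
    PIC = 1 - (p^2 + q^2) - 2 p^2 q^2."""
    p = np.asarray(allele_freq, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequency must be in [0, 1]")
    q = 1.0 - p
    out = 1.0 - (p**2 + q**2) - 2.0 * p**2 * q**2
    return float(out) if np.isscalar(allele_freq) else out


def filter_pic(
    matrix: MarkerMatrix, threshold: float = 0.1, report: QCReport | None = None
) -> tuple[MarkerMatrix, QCReport]:
    """Retain markers with PIC strictly greater than ``threshold``.

    Allele frequency is estimated as mean dosage / 2, which remains valid
    for fractional pooled scores.
    """
    report = report if report is not None else QCReport(n_input=matrix.shape[1])
    dos = matrix.dosages
    p_hat = (dos.mean(axis=0) / 2.0).clip(0.0, 1.0)
    pic_vals = pd.Series(pic(p_hat.to_numpy()), index=dos.columns)
    keep = pic_vals > threshold
    if not keep.any():
        warnings.warn("PIC filter removed every marker", stacklevel=2)
    report.pic_values = pic_vals
    report.dropped_low_pic = list(dos.columns[~keep])
    out = MarkerMatrix(dos.loc[:, keep], matrix.map)
    report.n_post_pic = out.shape[1]
    return out, report


def prune_correlated(
    matrix: MarkerMatrix,
    r_threshold: float = 0.9,
    order: str = "input",
    report: QCReport | None = None,
) -> tuple[MarkerMatrix, QCReport]:
    """Greedy single-pass redundancy pruning.

    Walking markers in ``order`` ("input" = map order, "pic_desc" = most
    informative first), a marker is dropped when its absolute Pearson
    correlation with any already-retained marker exceeds ``r_threshold``;
    the retained anchor of each drop is recorded. Zero-variance markers are
    treated as correlated with nothing, retained, and flagged.
    """
    if matrix.shape[1] < 2:
        raise ValueError("pruning needs at least two markers")
    report = report if report is not None else QCReport(n_input=matrix.shape[1])
    dos = matrix.dosages
    if dos.isna().any().any():
        raise ValueError("prune_correlated requires imputed (complete) dosages")
    cols = list(dos.columns)
    if order == "pic_desc":
        p_hat = (dos.mean(axis=0) / 2.0).clip(0.0, 1.0)
        pic_vals = pd.Series(pic(p_hat.to_numpy()), index=dos.columns)
        cols = list(pic_vals.sort_values(ascending=False, kind="stable").index)
    elif order != "input":
        raise ValueError("order must be 'input' or 'pic_desc'")

    X = dos.to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    zero_var = sd == 0
    Xs = (X - X.mean(axis=0)) / np.where(zero_var, 1.0, sd)
    n = X.shape[0]
    idx = {c: i for i, c in enumerate(dos.columns)}

    retained: list = []
    kept_mat = np.empty((n, 0))
    for c in cols:
        j = idx[c]
        if zero_var[j]:
            report.zero_variance_retained.append(c)
            retained.append(c)
            kept_mat = np.hstack([kept_mat, np.zeros((n, 1))])
            continue
        if kept_mat.shape[1]:
            r = np.abs(kept_mat.T @ Xs[:, j]) / n
            if r.max() > r_threshold:
                report.pruned[c] = retained[int(np.argmax(r))]
                continue
        retained.append(c)
        kept_mat = np.hstack([kept_mat, Xs[:, [j]]])
    keep_in_input_order = [c for c in dos.columns if c in set(retained)]
    out = MarkerMatrix(dos.loc[:, keep_in_input_order], matrix.map)
    report.n_post_prune = out.shape[1]
    return out, report


def run_qc(
    matrix: MarkerMatrix,
    pic_threshold: float = 0.1,
    r_threshold: float = 0.9,
    order: str = "input",
) -> tuple[MarkerMatrix, QCReport]:
    """Full chain: impute -> PIC filter -> correlation pruning."""
    report = QCReport(n_input=matrix.shape[1])
    m = impute_mean(matrix, report)
    m, report = filter_pic(m, pic_threshold, report)
    if m.shape[1] >= 2:
        m, report = prune_correlated(m, r_threshold, order, report)
    else:
        report.n_post_prune = m.shape[1]
    return m, report
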