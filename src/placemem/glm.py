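"""Ordinary-least-squares GLM fitting and single-trial (beta-series) estimates.

Estimation is run-wise: each run's voxel x time matrix is regressed on that
run's design; per-trial t-maps from all runs are concatenated into a
``TrialEstimates`` object that feeds both the univariate ROI analysis
(condition-mean t values) and the multivariate split-half analysis.

No autocorrelation correction is applied: serial correlation in the noise
is treated as unmodeled, as in the standard deconvolution path that
produces the per-trial t-maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix, build_design_matrix, check_collinearity
from .hrf import HRFSpec
from .simulate import TimeSeriesDataset

__all__ = ["TrialEstimates", "percent_signal_change", "fit_glm",
           "single_trial_estimates"]


@dataclass
class TrialEstimates:
    """Per-trial beta and t maps (trial x voxel) with trial metadata."""

    betas: np.ndarray
    t_values: np.ndarray
    info: pd.DataFrame          # columns: condition, stim_id, run_index
    residual_df: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.betas.shape != self.t_values.shape:
            raise ValueError("betas and t_values must have the same shape")
        if len(self.info) != self.betas.shape[0]:
            raise ValueError("metadata rows must match trial count")

    @property
    def n_trials(self) -> int:
        return self.betas.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[1]


def percent_signal_change(series: np.ndarray) -> np.ndarray:
    """Normalize each voxel's series to percent signal change.

    ``100 * (x - mean) / mean`` per voxel; the output has zero temporal
    mean.  Raises if any voxel has zero temporal mean (undefined scaling).
    """
    series = np.asarray(series, dtype=float)
    mean = series.mean(axis=-1, keepdims=True)
    zero = np.flatnonzero(mean.ravel() == 0)
    if zero.size:
        raise ValueError(f"zero-mean voxel(s) at indices {zero.tolist()[:20]}")
    return 100.0 * (series - mean) / mean


def _rank_deficient_columns(X: np.ndarray, names: list[str]) -> list[str]:
    # pivoted QR: columns whose pivot falls past the numerical rank
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    return [names[j] for j in sorted(piv[rank:])]


def fit_glm(
    series: np.ndarray, design: DesignMatrix
) -> tuple[np.ndarray, np.ndarray, int]:
    """OLS fit of every voxel's series on the design.

    Returns ``(betas, t_values, residual_df)`` with betas and t of shape
    voxel x regressor.  ``t = beta / SE`` with the standard error from the
    residual variance and the design Gram inverse;
    ``residual_df = T - rank(X)``.

    Raises on rank deficiency (naming the dependent columns) and on a
    series/design length mismatch.
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    X = design.values
    if series.shape[1] != X.shape[0]:
        raise ValueError(
            f"series has {series.shape[1]} timepoints, design has {X.shape[0]}"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _rank_deficient_columns(X, design.column_names)
        raise ValueError(f"design is rank deficient; dependent columns: {bad}")
    df = X.shape[0] - X.shape[1]
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    gram_inv = np.linalg.inv(X.T @ X)
    betas = series @ X @ gram_inv            # voxel x regressor
    resid = series - betas @ X.T
    sigma2 = (resid**2).sum(axis=1) / df
    se = np.sqrt(np.outer(sigma2, np.diag(gram_inv)))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, betas / se, 0.0)
    return betas, t, df


def single_trial_estimates(
    dataset: TimeSeriesDataset,
    hrf: HRFSpec | None = None,
    poly_order: int = 4,
    motion: dict[int, np.ndarray] | None = None,
    collinearity_warn: float = 0.2,
) -> TrialEstimates:
    """Beta-series estimation: one regressor per trial, fit run by run.

    Every task trial in every run yields one row of betas and t values
    (e.g. 8 runs x 20 trials -> 160 x V).  Cue+mask / novel events are
    modeled as pooled nuisance regressors and excluded from the output.
    A design whose task regressors correlate above ``collinearity_warn``
    triggers a warning, not an error.
    """
    if hrf is None:
        hrf = HRFSpec()
    all_betas, all_t, info_rows = [], [], []
    residual_df: dict[int, int] = {}
    for data, events in dataset.runs:
        run_idx = int(events["run_index"].iloc[0]) if len(events) else 0
        dm = build_design_matrix(
            events, data.shape[1], dataset.tr, hrf=hrf, mode="single_trial",
            poly_order=poly_order,
            motion=None if motion is None else motion.get(run_idx),
        )
        task_cols = dm.columns_with_role("task")
        if task_cols.size >= 2:
            max_r, ok = check_collinearity(dm, "task", collinearity_warn)
            if not ok:
                warnings.warn(
                    f"run {run_idx}: task-regressor collinearity "
                    f"{max_r:.3f} exceeds {collinearity_warn}",
                    stacklevel=2,
                )
        betas, t, df = fit_glm(data, dm)
        residual_df[run_idx] = df
        task = events[~events["trial_type"].isin({"cue_mask", "novel"})]
        all_betas.append(betas[:, task_cols].T)
        all_t.append(t[:, task_cols].T)
        for cond, stim in zip(task["trial_type"], task["stim_id"]):
            info_rows.append(dict(condition=cond, stim_id=stim, run_index=run_idx))
    return TrialEstimates(
        betas=np.vstack(all_betas),
        t_values=np.vstack(all_t),
        info=pd.DataFrame(info_rows),
        residual_df=residual_df,
    )
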