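"""GLM design matrices for event-related runs.

Task regressors are boxcars of the event duration convolved with the gamma
HRF and sampled on the TR grid.  In ``single_trial`` mode every task event
gets its own column (the beta-series setup behind per-trial t-maps); in
``by_condition`` mode events of a condition share one column.  Cue+mask
events are pooled into a single nuisance column per run, as are novel-image
events in recognition runs.  Legendre-style polynomial drift columns
(degrees 0..poly_order, orthonormalized within the run) and optional motion
columns complete the matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import NUISANCE_CONDITIONS
from .hrf import HRFSpec, sample_regressor

__all__ = ["DesignMatrix", "build_design_matrix", "check_collinearity",
           "polynomial_columns"]


@dataclass
class DesignMatrix:
    """Time x regressor matrix with per-column roles.

    Roles are ``task``, ``cue_nuisance``, ``polynomial`` or ``motion``.
    """

    values: np.ndarray
    column_names: list[str]
    column_roles: list[str]
    tr: float
    events: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("design values must be 2-D (time x regressor)")
        if self.values.shape[1] != len(self.column_names) or len(
            self.column_names
        ) != len(self.column_roles):
            raise ValueError("column_names/roles length must match value columns")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    def columns_with_role(self, roles: str | set[str]) -> np.ndarray:
        """Indices of columns whose role is in ``roles``."""
        if isinstance(roles, str):
            roles = {roles}
        return np.array(
            [i for i, r in enumerate(self.column_roles) if r in roles], dtype=int
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names)


def polynomial_columns(n_timepoints: int, poly_order: int) -> np.ndarray:
    """Orthonormal polynomial drift basis, degrees 0..poly_order.

    Built by QR decomposition of the Vandermonde matrix on [-1, 1], so the
    columns are exactly mutually orthogonal on the sampling grid.
    """
    if poly_order < 0:
        raise ValueError("poly_order must be >= 0")
    x = np.linspace(-1.0, 1.0, n_timepoints)
    vander = np.vander(x, poly_order + 1, increasing=True)
    q, r = np.linalg.qr(vander)
    # fix signs so the constant column is positive (QR sign is arbitrary)
    signs = np.sign(np.diag(r))
    signs[signs == 0] = 1.0
    return q * signs


def build_design_matrix(
    events: pd.DataFrame,
    n_timepoints: int,
    tr: float,
    hrf: HRFSpec | None = None,
    mode: str = "single_trial",
    poly_order: int = 4,
    motion: np.ndarray | None = None,
) -> DesignMatrix:
    """Assemble the run design matrix from an event table.

    Parameters
    ----------
    mode : {"single_trial", "by_condition"}
        One column per task event, or one per condition.
    poly_order : int
        Highest polynomial drift degree (4 for the 10 s recall experiment,
        3 for the 2 s recognition experiment).
    motion : array, optional
        time x 6 motion-parameter columns appended with role ``motion``.
    """
    if hrf is None:
        hrf = HRFSpec()
    if mode not in ("single_trial", "by_condition"):
        raise ValueError(f"unknown mode {mode!r}")
    run_end = n_timepoints * tr
    if len(events):
        offsets = events["onset"] + events["duration"]
        late = events[offsets > run_end]
        if len(late):
            bad = late.iloc[0]
            raise ValueError(
                f"event {bad['stim_id']!r} (onset {bad['onset']}, duration "
                f"{bad['duration']}) extends past run end {run_end} s"
            )

    cols: list[np.ndarray] = []
    names: list[str] = []
    roles: list[str] = []

    task = events[~events["trial_type"].isin(NUISANCE_CONDITIONS)] if len(events) else events
    if len(task):
        if mode == "single_trial":
            for onset, dur, stim in zip(
                task["onset"].to_numpy(), task["duration"].to_numpy(),
                task["stim_id"].to_numpy(),
            ):
                cols.append(sample_regressor(onset, dur, n_timepoints, tr, hrf))
                names.append(f"trial_{stim}")
                roles.append("task")
        else:
            for cond in sorted(task["trial_type"].unique()):
                sel = task[task["trial_type"] == cond]
                cols.append(
                    sample_regressor(
                        sel["onset"].to_numpy(), sel["duration"].to_numpy(),
                        n_timepoints, tr, hrf,
                    )
                )
                names.append(f"cond_{cond}")
                roles.append("task")

    if len(events):
        for nuis in sorted(set(events["trial_type"]) & NUISANCE_CONDITIONS):
            sel = events[events["trial_type"] == nuis]
            cols.append(
                sample_regressor(
                    sel["onset"].to_numpy(), sel["duration"].to_numpy(),
                    n_timepoints, tr, hrf,
                )
            )
            names.append(nuis)
            roles.append("cue_nuisance")

    poly = polynomial_columns(n_timepoints, poly_order)
    for d in range(poly.shape[1]):
        cols.append(poly[:, d])
        names.append(f"poly_{d}")
        roles.append("polynomial")

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != n_timepoints:
            raise ValueError("motion parameters must match run length")
        for j in range(motion.shape[1]):
            cols.append(motion[:, j])
            names.append(f"motion_{j}")
            roles.append("motion")

    values = np.column_stack(cols) if cols else np.empty((n_timepoints, 0))
    return DesignMatrix(values, names, roles, tr, events=events)


def check_collinearity(
    design: DesignMatrix,
    roles: str | set[str] = "task",
    threshold: float = 0.2,
) -> tuple[float, bool]:
    """Maximum absolute pairwise Pearson r among selected columns.

    Returns ``(max_abs_r, passed)`` where ``passed`` is ``max_abs_r <
    threshold``.  Raises on constant columns (undefined correlation) or
    fewer than two selected columns.
    """
    idx = design.columns_with_role(roles)
    if idx.size < 2:
        raise ValueError("need at least two columns to assess collinearity")
    sub = design.values[:, idx]
    sd = sub.std(axis=0)
    if (sd == 0).any():
        bad = [design.column_names[idx[j]] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant column(s) in selection: {bad}")
    corr = np.corrcoef(sub, rowvar=False)
    off = np.abs(corr[np.triu_indices_from(corr, k=1)])
    max_r = float(off.max())
    return max_r, max_r < threshold
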