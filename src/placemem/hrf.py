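"""Gamma-variate hemodynamic response function (HRF).

The kernel is the classic gamma-variate

    h(t) = (t / (p*q))**p * exp(p - t/q),   t >= 0

which peaks at ``t = p*q`` with value 1 when peak-normalized.  The defaults
``p = 8.6``, ``q = 0.547`` give the familiar ~4.7 s time-to-peak used by the
standard event-related deconvolution toolchain.  Event regressors are built
by convolving a boxcar of the event duration with this kernel on a fine time
grid and sampling the result on the TR grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = ["HRFSpec", "gamma_hrf", "sample_regressor"]


@dataclass(frozen=True)
class HRFSpec:
    """Shape parameters of the gamma response kernel.

    Parameters
    ----------
    p : float
        Dimensionless shape parameter (> 0).
    q : float
        Time-scale parameter in seconds (> 0).
    dt : float
        Sampling step of the fine grid, seconds (> 0).
    peak_normalize : bool
        If True (default) the kernel maximum is exactly 1.
    """

    p: float = 8.6
    q: float = 0.547
    dt: float = 0.1
    peak_normalize: bool = True

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0 or self.dt <= 0:
            raise ValueError(
                f"HRF parameters must be positive: p={self.p}, q={self.q}, dt={self.dt}"
            )

    @property
    def peak_time(self) -> float:
        """Analytic mode of the kernel, p*q seconds."""
        return self.p * self.q


def gamma_hrf(spec: HRFSpec) -> np.ndarray:
    """Sample the gamma kernel on the fine grid defined by ``spec.dt``.

    The support is truncated where the kernel falls below 1e-6 of its peak
    (past the mode).  Returns a 1-D non-negative array; ``h[0] == 0``.
    """
    # log-kernel avoids overflow of (t/pq)**p for large p
    peak = spec.peak_time
    # find truncation point: h(t)/h(peak) < 1e-6 for t beyond the mode
    t_max = peak
    while True:
        t_max += spec.q
        log_rel = spec.p * np.log(t_max / peak) + (peak - t_max) / spec.q
        if log_rel < np.log(1e-6):
            break
    t = np.arange(0.0, t_max + spec.dt, spec.dt)
    h = np.zeros_like(t)
    pos = t > 0
    h[pos] = np.exp(spec.p * np.log(t[pos] / peak) + (peak - t[pos]) / spec.q)
    if spec.peak_normalize:
        h /= h.max()
    else:
        # un-normalized convention: h(peak) = 1 anyway for this parameterization
        pass
    return h


@lru_cache(maxsize=32)
def _kernel_cumsum(spec: HRFSpec) -> np.ndarray:
    return np.cumsum(gamma_hrf(spec))


def sample_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    n_timepoints: int,
    tr: float,
    spec: HRFSpec,
) -> np.ndarray:
    """Boxcar-convolved HRF regressor sampled on the TR grid.

    Each (onset, duration) contributes a boxcar on the fine ``spec.dt`` grid
    convolved with the gamma kernel and evaluated at t = k*TR.  The discrete
    convolution of a boxcar over fine samples [i0, i1) is the difference of
    kernel cumulative sums, C[n - i0] - C[n - i1], which is evaluated
    directly at the TR samples.  No per-duration rescaling is applied, so
    the regressor for one long event equals the sum of the regressors for
    abutting sub-events exactly (convolution linearity).
    """
    onsets = np.atleast_1d(np.asarray(onsets, dtype=float))
    durations = np.atleast_1d(np.asarray(durations, dtype=float))
    if onsets.shape != durations.shape:
        raise ValueError("onsets and durations must have equal length")
    if (onsets < 0).any():
        raise ValueError("negative onset")
    cum = _kernel_cumsum(spec)
    idx = np.round(np.arange(n_timepoints) * tr / spec.dt).astype(int)

    def lookup(k: np.ndarray) -> np.ndarray:
        k = np.clip(k, -1, cum.size - 1)
        out = np.where(k >= 0, cum[np.maximum(k, 0)], 0.0)
        return out

    reg = np.zeros(n_timepoints)
    for onset, dur in zip(onsets, durations):
        i0 = int(round(onset / spec.dt))
        i1 = int(round((onset + dur) / spec.dt))
        reg += lookup(idx - i0) - lookup(idx - i1)
    return reg * spec.dt
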