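"""Synthetic BOLD data with planted, recoverable effects.

The generator emulates the structure of the recall experiment: 8 runs of 20
imagery trials (10 image / 5 panorama / 5 street, each stimulus cued once
per run), 2 s cue+mask before each 10 s trial, TR = 2 s.  Each voxel's
series is the linear HRF forward model

    y_v(t) = sum_trials [a(ROI_v, cond) + rho_id * P(stim, v)] * x_trial(t)
             + cue_amp * x_cue(t) + drift(t) + AR(1) noise

where ``a`` is the per-ROI condition amplitude profile (percent-signal
units), ``P`` the stimulus-specific multivoxel pattern (zero-mean,
unit-norm within each ROI) and ``rho_id`` the identity-signal strength that
controls across-run pattern reliability.  The output is on the
percent-signal-change scale around a zero baseline — i.e. the
post-preprocessing signal a GLM consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats

from .events import generate_trial_sequence, run_duration, NUISANCE_CONDITIONS
from .hrf import HRFSpec, sample_regressor

__all__ = [
    "GroundTruth",
    "TimeSeriesDataset",
    "make_ground_truth",
    "simulate_run",
    "simulate_dataset",
    "simulate_cohort",
    "simulate_localizer_contrast",
    "RECALL_CONDITION_COUNTS",
]

#: per-run trial counts of the recall experiment (20 studied places)
RECALL_CONDITION_COUNTS = {"image": 10, "panorama": 5, "street": 5}


@dataclass
class GroundTruth:
    """Planted effects for one synthetic subject."""

    n_voxels: int
    roi_voxels: dict[str, np.ndarray]
    amplitudes: dict[str, dict[str, float]]
    identity_patterns: dict[str, np.ndarray]
    rho_id: float
    sigma_white: float = 1.0
    ar1_phi: float = 0.3
    drift_amplitude: float = 0.5
    cue_amplitude: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho_id <= 1.0:
            raise ValueError("rho_id must be in [0, 1]")
        if not 0.0 <= self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must be in [0, 1)")
        all_idx = np.concatenate([v for v in self.roi_voxels.values()]) if self.roi_voxels else np.array([])
        if all_idx.size and (len(np.unique(all_idx)) != all_idx.size):
            raise ValueError("ROIs must be disjoint")
        if all_idx.size and (all_idx.min() < 0 or all_idx.max() >= self.n_voxels):
            raise ValueError("ROI voxel indices out of range")

    def roi_of_voxel(self) -> np.ndarray:
        """Voxel -> ROI-name array ('' outside every ROI)."""
        out = np.array([""] * self.n_voxels, dtype=object)
        for name, idx in self.roi_voxels.items():
            out[idx] = name
        return out


@dataclass
class TimeSeriesDataset:
    """Per-run (voxel x time) matrices with their event tables."""

    runs: list[tuple[np.ndarray, pd.DataFrame]]
    tr: float
    truth: GroundTruth | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n_vox = {d.shape[0] for d, _ in self.runs}
        if len(n_vox) > 1:
            raise ValueError(f"voxel count differs across runs: {sorted(n_vox)}")

    @property
    def n_voxels(self) -> int:
        return self.runs[0][0].shape[0]


def make_ground_truth(
    roi_sizes: Mapping[str, int],
    amplitudes: Mapping[str, Mapping[str, float]],
    stimuli: Sequence[str],
    rho_id: float = 0.0,
    sigma_white: float = 1.0,
    ar1_phi: float = 0.3,
    drift_amplitude: float = 0.5,
    cue_amplitude: float = 0.5,
    n_background: int = 0,
    identity_rois: Sequence[str] | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Lay out disjoint ROIs and draw per-stimulus identity patterns.

    Patterns are drawn i.i.d. normal per stimulus, then within each ROI
    orthonormalized across stimuli (QR) when the ROI has at least as many
    voxels as stimuli, otherwise zero-meaned and unit-normed.  Voxels
    outside every ROI carry no signal; ``n_background`` appends extra
    signal-free voxels after the ROIs.  ``identity_rois`` restricts the
    identity patterns to the named ROIs (default: all ROIs).
    """
    rng = np.random.default_rng(seed)
    roi_voxels: dict[str, np.ndarray] = {}
    start = 0
    for name, size in roi_sizes.items():
        roi_voxels[name] = np.arange(start, start + size)
        start += size
    n_voxels = start + n_background
    stimuli = list(stimuli)
    patterns = {s: np.zeros(n_voxels) for s in stimuli}
    mat = rng.standard_normal((len(stimuli), n_voxels))
    for name, idx in roi_voxels.items():
        if identity_rois is not None and name not in identity_rois:
            continue
        block = mat[:, idx]
        if idx.size >= len(stimuli):
            q, _ = np.linalg.qr(block.T)   # voxels x stimuli, orthonormal cols
            block = q.T
        else:
            block = block - block.mean(axis=1, keepdims=True)
            block /= np.linalg.norm(block, axis=1, keepdims=True)
        for i, s in enumerate(stimuli):
            patterns[s][idx] = block[i]
    return GroundTruth(
        n_voxels=n_voxels,
        roi_voxels=roi_voxels,
        amplitudes={k: dict(v) for k, v in amplitudes.items()},
        identity_patterns=patterns,
        rho_id=rho_id,
        sigma_white=sigma_white,
        ar1_phi=ar1_phi,
        drift_amplitude=drift_amplitude,
        cue_amplitude=cue_amplitude,
        seed=seed,
    )


def _ar1_noise(rng: np.random.Generator, n_voxels: int, n_t: int,
               sigma: float, phi: float) -> np.ndarray:
    """Stationary AR(1) series with marginal SD ``sigma`` and lag-1 corr ``phi``."""
    if sigma == 0:
        return np.zeros((n_voxels, n_t))
    innov_sd = sigma * np.sqrt(1.0 - phi**2)
    w = rng.standard_normal((n_voxels, n_t)) * innov_sd
    # initialize from the stationary distribution
    w[:, 0] = rng.standard_normal(n_voxels) * sigma
    if phi == 0:
        return w
    zi = np.zeros((n_voxels, 1))
    out, _ = sp_signal.lfilter([1.0], [1.0, -phi], w, axis=1, zi=zi)
    return out


def _drift(rng: np.random.Generator, n_voxels: int, n_t: int,
           amplitude: float) -> np.ndarray:
    """Slow cosine drift: three low-frequency components with random phase."""
    if amplitude == 0:
        return np.zeros((n_voxels, n_t))
    t = np.arange(n_t)
    out = np.zeros((n_voxels, n_t))
    for k in (1, 2, 3):
        phase = rng.uniform(0, 2 * np.pi, size=(n_voxels, 1))
        scale = amplitude / k
        out += scale * np.cos(np.pi * k * t[None, :] / n_t + phase)
    return out


def simulate_run(
    events: pd.DataFrame,
    truth: GroundTruth,
    hrf: HRFSpec | None = None,
    n_timepoints: int | None = None,
    tr: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Forward-model one run; returns voxel x time in percent-signal units."""
    if hrf is None:
        hrf = HRFSpec()
    if n_timepoints is None:
        n_timepoints = run_duration(events, tr)
    task = events[~events["trial_type"].isin(NUISANCE_CONDITIONS)]
    unknown = set(task["stim_id"]) - set(truth.identity_patterns)
    if unknown:
        raise ValueError(f"stimulus ids absent from ground truth: {sorted(unknown)}")

    roi_name = truth.roi_of_voxel()
    in_roi = roi_name != ""
    signal = np.zeros((truth.n_voxels, n_timepoints))
    for onset, dur, cond, stim in zip(
        task["onset"].to_numpy(), task["duration"].to_numpy(),
        task["trial_type"].to_numpy(), task["stim_id"].to_numpy(),
    ):
        reg = sample_regressor(onset, dur, n_timepoints, tr, hrf)
        amp = np.zeros(truth.n_voxels)
        for rname, idx in truth.roi_voxels.items():
            amp[idx] = truth.amplitudes.get(rname, {}).get(cond, 0.0)
        amp = amp + truth.rho_id * truth.identity_patterns[stim]
        amp[~in_roi] = 0.0
        signal += np.outer(amp, reg)

    cue = events[events["trial_type"].isin(NUISANCE_CONDITIONS)]
    if len(cue) and truth.cue_amplitude != 0:
        reg = sample_regressor(
            cue["onset"].to_numpy(), cue["duration"].to_numpy(), n_timepoints, tr, hrf
        )
        signal += truth.cue_amplitude * reg[None, :]

    rng = np.random.default_rng(seed)
    signal += _drift(rng, truth.n_voxels, n_timepoints, truth.drift_amplitude)
    signal += _ar1_noise(rng, truth.n_voxels, n_timepoints,
                         truth.sigma_white, truth.ar1_phi)
    return signal


def simulate_dataset(
    truth: GroundTruth,
    n_runs: int = 8,
    tr: float = 2.0,
    hrf: HRFSpec | None = None,
    condition_counts: Mapping[str, int] | None = None,
    stimulus_roster: Mapping[str, Sequence[str]] | None = None,
    trial_duration: float = 10.0,
    cue_duration: float = 2.0,
    seed: int = 0,
) -> TimeSeriesDataset:
    """Simulate a full subject: fresh trial sequence and noise per run."""
    counts = dict(condition_counts or RECALL_CONDITION_COUNTS)
    n_trials = sum(counts.values())
    ss = np.random.SeedSequence(seed)
    seq_seeds, noise_seeds = ss.spawn(2)
    seq_child = seq_seeds.generate_state(n_runs) % (2**31)
    noise_child = noise_seeds.generate_state(n_runs) % (2**31)
    runs = []
    for r in range(n_runs):
        ev = generate_trial_sequence(
            n_trials, counts, trial_duration=trial_duration,
            cue_duration=cue_duration, seed=int(seq_child[r]),
            run_index=r + 1, stimulus_roster=stimulus_roster,
        )
        data = simulate_run(ev, truth, hrf=hrf, tr=tr, seed=int(noise_child[r]))
        runs.append((data, ev))
    return TimeSeriesDataset(runs=runs, tr=tr, truth=truth)


def simulate_cohort(
    n_subjects: int,
    truth_template: GroundTruth,
    between_subject_sd: float = 0.0,
    n_runs: int = 8,
    tr: float = 2.0,
    hrf: HRFSpec | None = None,
    condition_counts: Mapping[str, int] | None = None,
    trial_duration: float = 10.0,
    cue_duration: float = 2.0,
    seed: int = 0,
) -> list[TimeSeriesDataset]:
    """Simulate a cohort around a template ground truth.

    Each subject's per-ROI condition amplitudes are drawn normal around the
    template with SD ``between_subject_sd`` (percent-signal units); identity
    patterns are redrawn per subject.  Default cohort size in the analyses
    this package targets is 17 subjects.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    ss = np.random.SeedSequence(seed)
    subj_seeds = ss.generate_state(2 * n_subjects) % (2**31)
    stimuli = list(truth_template.identity_patterns)
    roi_sizes = {k: len(v) for k, v in truth_template.roi_voxels.items()}
    n_background = truth_template.n_voxels - sum(roi_sizes.values())
    first = stimuli[0] if stimuli else None
    identity_rois = [
        name for name, idx in truth_template.roi_voxels.items()
        if first is not None
        and np.linalg.norm(truth_template.identity_patterns[first][idx]) > 0
    ]
    cohort = []
    for s in range(n_subjects):
        rng = np.random.default_rng(int(subj_seeds[2 * s]))
        amps = {
            roi: {c: a + between_subject_sd * rng.standard_normal()
                  for c, a in conds.items()}
            for roi, conds in truth_template.amplitudes.items()
        }
        truth = make_ground_truth(
            roi_sizes, amps, stimuli,
            rho_id=truth_template.rho_id,
            sigma_white=truth_template.sigma_white,
            ar1_phi=truth_template.ar1_phi,
            drift_amplitude=truth_template.drift_amplitude,
            cue_amplitude=truth_template.cue_amplitude,
            n_background=n_background,
            identity_rois=identity_rois,
            seed=int(subj_seeds[2 * s]),
        )
        cohort.append(
            simulate_dataset(
                truth, n_runs=n_runs, tr=tr, hrf=hrf,
                condition_counts=condition_counts,
                trial_duration=trial_duration, cue_duration=cue_duration,
                seed=int(subj_seeds[2 * s + 1]),
            )
        )
    return cohort


def simulate_localizer_contrast(
    truth: GroundTruth,
    selectivity_z: float,
    n_vertices: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex localizer contrast statistics and two-sided p-values.

    Vertices inside any planted ROI receive standard-normal statistics
    shifted by ``selectivity_z``; all others are centered at 0.  This mimics
    the scene-vs-face (or places-vs-people) general linear test whose map is
    thresholded to draw functional ROIs.
    """
    if n_vertices is None:
        n_vertices = truth.n_voxels
    for name, idx in truth.roi_voxels.items():
        if idx.size and idx.max() >= n_vertices:
            raise ValueError(f"ROI {name!r} exceeds n_vertices={n_vertices}")
    rng = np.random.default_rng(seed)
    stat = rng.standard_normal(n_vertices)
    for idx in truth.roi_voxels.values():
        stat[idx] += selectivity_z
    p = 2.0 * stats.norm.sf(np.abs(stat))
    return stat, p
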