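"""Exhaustive split-half pattern similarity and identity discrimination.

The runs are split into every possible half-pair (all C(n, n/2) ordered
assignments — 70 for 8 runs).  Per split, each stimulus's per-trial t values
are averaged within each half over the mask voxels, and a stimulus x
stimulus Spearman correlation matrix is computed across the halves; the
matrices are averaged over splits.

The identity-discrimination index asks whether a stimulus's pattern is more
similar to itself across independent halves than to the other stimuli of
its own visuospatial-context condition (image with images, panorama with
panoramas, street with streets), so condition-level amplitude differences
cannot masquerade as identity information.  Correlations are Fisher
z-transformed (arctanh) before averaging and differencing by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .glm import TrialEstimates
from .roi import ROIMask
from .univariate import PairedResult

__all__ = [
    "enumerate_half_splits",
    "cross_half_rsm",
    "identity_discrimination_index",
    "group_identity_stats",
    "SimilarityResult",
    "fisher_z",
]

#: correlations are clipped to keep arctanh finite
_CLIP = 1.0 - 1e-7


def fisher_z(rho: np.ndarray | float) -> np.ndarray | float:
    """Fisher z = arctanh(rho), with |rho| clipped to 1 - 1e-7."""
    return np.arctanh(np.clip(rho, -_CLIP, _CLIP))


@dataclass
class SimilarityResult:
    """Cross-half similarity matrix averaged over all splits."""

    stimuli: list[str]
    mean_rsm: np.ndarray
    n_splits: int
    per_split: np.ndarray | None = field(default=None, repr=False)


def enumerate_half_splits(n_runs: int) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All ordered half-splits of runs 0..n_runs-1, lexicographic.

    Both members of each complementary pair are listed (C(8,4) = 70 for 8
    runs); the first split is runs (0,1,2,3) vs (4,5,6,7), the second
    (0,1,2,4) vs (3,5,6,7).
    """
    if n_runs < 2 or n_runs % 2 != 0:
        raise ValueError(f"n_runs must be even and >= 2, got {n_runs}")
    runs = range(n_runs)
    out = []
    for half in combinations(runs, n_runs // 2):
        other = tuple(r for r in runs if r not in half)
        out.append((half, other))
    return out


def _rank_rows(x: np.ndarray) -> np.ndarray:
    """Average ranks along the last axis (Spearman with ties averaged)."""
    return stats.rankdata(x, axis=-1)


def _rank_correlation_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Spearman rho between every row of ``a`` and every row of ``b``."""
    ra, rb = _rank_rows(a), _rank_rows(b)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    na = np.linalg.norm(ra, axis=1, keepdims=True)
    nb = np.linalg.norm(rb, axis=1, keepdims=True)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    return (ra / na) @ (rb / nb).T


def _trial_tensor(
    estimates: TrialEstimates, mask: ROIMask
) -> tuple[np.ndarray, list[str], list[int]]:
    """t values as (run, stimulus, voxel), requiring one trial per stimulus per run."""
    stimuli = sorted(estimates.info["stim_id"].unique())
    runs = sorted(estimates.info["run_index"].unique())
    stim_pos = {s: i for i, s in enumerate(stimuli)}
    run_pos = {r: i for i, r in enumerate(runs)}
    tensor = np.full((len(runs), len(stimuli), mask.size), np.nan)
    vals = estimates.t_values[:, mask.indices]
    for row, (stim, run) in enumerate(
        zip(estimates.info["stim_id"], estimates.info["run_index"])
    ):
        tensor[run_pos[run], stim_pos[stim]] = vals[row]
    if np.isnan(tensor).any():
        missing = [
            (runs[r], stimuli[s])
            for r, s in zip(*np.nonzero(np.isnan(tensor).all(axis=2)))
        ]
        raise ValueError(f"stimulus missing from run(s): {missing[:10]}")
    return tensor, stimuli, runs


def cross_half_rsm(
    estimates: TrialEstimates,
    mask: ROIMask,
    splits: Sequence[tuple[tuple[int, ...], tuple[int, ...]]] | None = None,
    keep_per_split: bool = False,
) -> SimilarityResult:
    """Average cross-half Spearman similarity matrix within an ROI.

    For each split, per-stimulus t patterns are averaged over the runs of
    each half; entry (i, j) of the split matrix is Spearman's rho between
    stimulus i's half-A pattern and stimulus j's half-B pattern.  The
    matrices are averaged over all splits — which, since both orderings of
    every complementary pair are enumerated, yields a symmetric matrix.
    """
    if mask.size < 3:
        raise ValueError("mask must contain at least 3 voxels for rank correlation")
    tensor, stimuli, runs = _trial_tensor(estimates, mask)
    if splits is None:
        splits = enumerate_half_splits(len(runs))
    acc = np.zeros((len(stimuli), len(stimuli)))
    per_split = np.zeros((len(splits), len(stimuli), len(stimuli))) if keep_per_split else None
    for k, (half_a, half_b) in enumerate(splits):
        pat_a = tensor[list(half_a)].mean(axis=0)
        pat_b = tensor[list(half_b)].mean(axis=0)
        rsm = _rank_correlation_matrix(pat_a, pat_b)
        acc += rsm
        if per_split is not None:
            per_split[k] = rsm
    return SimilarityResult(
        stimuli=stimuli, mean_rsm=acc / len(splits),
        n_splits=len(splits), per_split=per_split,
    )


def identity_discrimination_index(
    rsm: np.ndarray,
    stimuli: Sequence[str],
    condition_of: Mapping[str, str],
    transform: str = "z_before_average",
) -> float:
    """Self-similarity minus within-condition other-similarity, Fisher-z units.

    For each stimulus s:  z(rho_self) - mean over same-condition others s'
    of z(rho(s, s')); the index is the mean over stimuli.  Cross-condition
    cells are never used.  ``transform="z_before_average"`` (default)
    Fisher-transforms every correlation first; ``"average_before_z"``
    averages raw correlations within each term and transforms afterwards.
    """
    rsm = np.asarray(rsm, dtype=float)
    stimuli = list(stimuli)
    if rsm.shape != (len(stimuli), len(stimuli)):
        raise ValueError("rsm must be square with one row per stimulus")
    missing = [s for s in stimuli if s not in condition_of]
    if missing:
        raise ValueError(f"stimuli without condition label: {missing}")
    if transform not in ("z_before_average", "average_before_z"):
        raise ValueError(f"unknown transform {transform!r}")
    conds = np.array([condition_of[s] for s in stimuli])
    for c in np.unique(conds):
        if (conds == c).sum() < 2:
            raise ValueError(f"condition {c!r} has a single stimulus")
    per_stim = []
    for i in range(len(stimuli)):
        others = np.flatnonzero((conds == conds[i]) & (np.arange(len(stimuli)) != i))
        if transform == "z_before_average":
            self_term = fisher_z(rsm[i, i])
            cross_term = float(np.mean(fisher_z(rsm[i, others])))
        else:
            self_term = fisher_z(rsm[i, i])
            cross_term = fisher_z(float(np.mean(rsm[i, others])))
        per_stim.append(self_term - cross_term)
    return float(np.mean(per_stim))


def group_identity_stats(
    indices: pd.DataFrame,
    roi_set_comparisons: Sequence[tuple[str, Sequence[str], Sequence[str]]] = (),
    tail: str = "two",
) -> tuple[pd.DataFrame, list[PairedResult]]:
    """Group inference on per-subject, per-ROI identity indices.

    ``indices`` is long-format with columns subject, roi, index.  Each ROI
    gets a one-sample t test of the index against 0 (one- or two-tailed);
    each entry of ``roi_set_comparisons`` is ``(name, rois_a, rois_b)`` and
    yields a paired t test between the subject-wise means of the two ROI
    sets, with Cohen's d on the difference scores.
    """
    if tail not in ("two", "greater"):
        raise ValueError(f"unknown tail {tail!r}")
    wide = indices.pivot_table(index="subject", columns="roi", values="index")
    if wide.isna().any().any():
        raise ValueError("missing subject x roi cells")
    if len(wide) < 2:
        raise ValueError("need at least 2 subjects")
    rows = []
    for roi in wide.columns:
        x = wide[roi].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        n = x.size
        if sd == 0.0:
            t_stat = 0.0
            p = 1.0
            d = 0.0
        else:
            t_stat = x.mean() / (sd / np.sqrt(n))
            p = stats.t.sf(t_stat, n - 1) if tail == "greater" else 2.0 * stats.t.sf(abs(t_stat), n - 1)
            d = x.mean() / sd
        rows.append(dict(roi=roi, mean_index=float(x.mean()), t=float(t_stat),
                         df=n - 1, p=float(p), cohens_d=float(d)))
    roi_table = pd.DataFrame(rows)

    comparisons = []
    m = max(len(roi_set_comparisons), 1)
    for name, rois_a, rois_b in roi_set_comparisons:
        a = wide[list(rois_a)].mean(axis=1).to_numpy(dtype=float)
        b = wide[list(rois_b)].mean(axis=1).to_numpy(dtype=float)
        diff = a - b
        sd = diff.std(ddof=1)
        n = diff.size
        if sd == 0.0:
            t_stat, p, d = 0.0, 1.0, 0.0
        else:
            t_stat = diff.mean() / (sd / np.sqrt(n))
            p = stats.t.sf(t_stat, n - 1) if tail == "greater" else 2.0 * stats.t.sf(abs(t_stat), n - 1)
            d = diff.mean() / sd
        comparisons.append(
            PairedResult(name=name, t=float(t_stat), df=n - 1, p=float(p),
                         p_corrected=float(min(1.0, m * p)),
                         cohens_d=float(d), mean_diff=float(diff.mean()))
        )
    return roi_table, comparisons
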