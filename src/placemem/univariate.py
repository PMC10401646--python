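"""ROI-level univariate statistics.

Covers the condition-mean extraction of per-trial t values, classical
repeated-measures ANOVA (each within-subject effect tested against its own
effect-by-subject error stratum), Bonferroni-corrected paired post hocs
(including difference-of-differences contrasts), Benjamini–Hochberg FDR
thresholding of vertex-wise p maps, and the noncentral-t sample-size
calculation for a one-sample design.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .glm import TrialEstimates
from .roi import ROIMask

__all__ = [
    "extract_roi_condition_means",
    "build_cohort_table",
    "rm_anova",
    "paired_posthoc",
    "PairedResult",
    "fdr_threshold",
    "required_sample_size",
]


def extract_roi_condition_means(
    estimates: TrialEstimates,
    masks: Sequence[ROIMask],
    value: str = "t",
    collapse_hemisphere: bool = False,
) -> pd.DataFrame:
    """Average per-trial statistics over trials, runs and mask voxels.

    Returns one row per (roi, hemisphere, condition) cell with the mean of
    the chosen statistic (``t`` or ``beta``) over all trials of that
    condition in all runs and all voxels in the mask.
    """
    data = estimates.t_values if value == "t" else estimates.betas
    rows = []
    for mask in masks:
        if mask.size == 0:
            raise ValueError(f"empty mask {mask.name!r}")
        if mask.indices.max() >= estimates.n_voxels:
            raise ValueError(f"mask {mask.name!r} exceeds voxel range")
        roi_vals = data[:, mask.indices].mean(axis=1)
        for cond, grp in estimates.info.groupby("condition", sort=True):
            rows.append(
                dict(roi=mask.name, hemisphere=mask.hemisphere,
                     condition=cond, mean_t=float(roi_vals[grp.index].mean()))
            )
    table = pd.DataFrame(rows)
    if collapse_hemisphere:
        table = (
            table.groupby(["roi", "condition"], as_index=False)["mean_t"]
            .mean()
            .assign(hemisphere="both")
        )
    return table


def build_cohort_table(
    per_subject: Mapping[object, pd.DataFrame]
) -> pd.DataFrame:
    """Stack per-subject ROI/condition tables, adding a ``subject`` column."""
    out = []
    for subject, tab in per_subject.items():
        out.append(tab.assign(subject=subject))
    return pd.concat(out, ignore_index=True)


@dataclass
class AnovaEffect:
    name: str
    F: float
    df_num: int
    df_den: int
    p: float


def _effect_arrays(data: np.ndarray) -> dict[frozenset, np.ndarray]:
    """Factorial effect decomposition of a balanced full-factorial array.

    For every subset S of axes, the effect array is the inclusion-exclusion
    combination of marginal means; broadcasting it back to the full shape
    and summing squares gives that term's sum of squares.
    """
    ndim = data.ndim
    axes = list(range(ndim))
    marginals: dict[frozenset, np.ndarray] = {}
    for r in range(ndim + 1):
        for S in combinations(axes, r):
            other = tuple(a for a in axes if a not in S)
            marginals[frozenset(S)] = data.mean(axis=other, keepdims=True)
    effects: dict[frozenset, np.ndarray] = {}
    for S in marginals:
        e = np.zeros_like(marginals[S])
        for T in marginals:
            if T <= S:
                sign = (-1) ** (len(S) - len(T))
                e = e + sign * marginals[T]
        effects[S] = e
    return effects


def rm_anova(
    table: pd.DataFrame,
    dv: str = "mean_t",
    within: Sequence[str] = ("condition",),
    subject: str = "subject",
) -> pd.DataFrame:
    """Classical repeated-measures ANOVA on a balanced long-format table.

    Supports one to three within-subject factors; every effect (main or
    interaction) is tested against its own interaction-with-subject error
    stratum:  F = MS_effect / MS_(effect x subject).  No sphericity
    correction is applied.  Unbalanced tables (missing or duplicated cells)
    raise rather than being imputed.
    """
    within = list(within)
    if not 1 <= len(within) <= 3:
        raise ValueError("supports 1-3 within factors")
    subjects = sorted(table[subject].unique())
    if len(subjects) < 2:
        raise ValueError("need at least 2 subjects")
    levels = {f: sorted(table[f].unique()) for f in within}
    pivot = table.pivot_table(
        index=subject, columns=within, values=dv, aggfunc="count", dropna=False
    )
    counts = pivot.to_numpy(dtype=float)
    if np.isnan(counts).any() or (counts != 1).any():
        raise ValueError("design must be balanced with exactly one value per cell")
    wide = table.pivot_table(index=subject, columns=within, values=dv, sort=True)
    shape = (len(subjects),) + tuple(len(levels[f]) for f in within)
    data = wide.to_numpy(dtype=float).reshape(shape)

    effects = _effect_arrays(data)
    sizes = data.shape
    total = data.size
    rows = []
    subj_axis = 0
    factor_axis = {f: i + 1 for i, f in enumerate(within)}
    for r in range(1, len(within) + 1):
        for combo in combinations(within, r):
            S = frozenset(factor_axis[f] for f in combo)
            S_err = S | {subj_axis}
            e = effects[S]
            e_err = effects[S_err]
            ss = float((e**2).sum() * total / e.size)
            ss_err = float((e_err**2).sum() * total / e_err.size)
            df_num = int(np.prod([sizes[a] - 1 for a in S]))
            df_den = int(df_num * (sizes[subj_axis] - 1))
            ms, ms_err = ss / df_num, ss_err / df_den
            if ss == 0.0:
                F, p = 0.0, 1.0
            elif ms_err == 0.0:
                F, p = np.inf, 0.0
            else:
                F = ms / ms_err
                p = float(stats.f.sf(F, df_num, df_den))
            rows.append(
                dict(effect=" x ".join(combo), F=float(F), df_num=df_num,
                     df_den=df_den, p=p, ss=ss, ss_error=ss_err)
            )
    return pd.DataFrame(rows)


@dataclass
class PairedResult:
    name: str
    t: float
    df: int
    p: float
    p_corrected: float
    cohens_d: float
    mean_diff: float


def _cell_values(table: pd.DataFrame, selector, dv: str, subject: str) -> np.ndarray:
    """Subject-ordered cell means for a selector dict, or a difference of two."""
    if isinstance(selector, tuple):
        a, b = selector
        return _cell_values(table, a, dv, subject) - _cell_values(table, b, dv, subject)
    sub = table
    for col, val in selector.items():
        sub = sub[sub[col] == val]
    grp = sub.groupby(subject)[dv].mean().sort_index()
    return grp.to_numpy(dtype=float)


def paired_posthoc(
    table: pd.DataFrame,
    contrasts: Sequence[tuple],
    dv: str = "mean_t",
    subject: str = "subject",
    correction: str = "bonferroni",
) -> list[PairedResult]:
    """Paired t tests on subject-level cell (or difference) contrasts.

    Each contrast is ``(name, selector_a, selector_b)`` where a selector is
    a dict of column -> value restricting the table (cells matching the
    selector are averaged per subject), or a ``(sel_x, sel_y)`` tuple
    denoting a per-subject difference — which makes difference-of-differences
    contrasts (e.g. a condition effect compared across two ROIs) a paired t
    test on the doubly-differenced scores.

    ``p_corrected = min(1, m * p)`` under Bonferroni with m = number of
    contrasts; Cohen's d is the mean of the paired differences over their SD.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    m = len(contrasts)
    results = []
    for name, sel_a, sel_b in contrasts:
        a = _cell_values(table, sel_a, dv, subject)
        b = _cell_values(table, sel_b, dv, subject)
        if a.size != b.size or a.size < 2:
            raise ValueError(f"contrast {name!r}: need >= 2 complete pairs")
        d = a - b
        sd = d.std(ddof=1)
        n = d.size
        if sd == 0.0:
            t_stat, p, cohens_d = 0.0, 1.0, 0.0
        else:
            t_stat = d.mean() / (sd / np.sqrt(n))
            p = 2.0 * stats.t.sf(abs(t_stat), n - 1)
            cohens_d = d.mean() / sd
        p_corr = min(1.0, m * p) if correction == "bonferroni" else p
        results.append(
            PairedResult(name=name, t=float(t_stat), df=n - 1, p=float(p),
                         p_corrected=float(p_corr), cohens_d=float(cohens_d),
                         mean_diff=float(d.mean()))
        )
    return results


def fdr_threshold(
    p_values: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, float]:
    """Benjamini–Hochberg step-up over a vector of p-values.

    Returns ``(mask, critical_p)``: the significance mask is True where
    ``p <= critical_p``, the largest p(k) satisfying p(k) <= k/m * q.
    When nothing passes, ``critical_p`` is 0 and the mask all-False.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p)
    ranked = p[order]
    thresh = q * np.arange(1, m + 1) / m
    passing = np.flatnonzero(ranked <= thresh)
    crit = float(ranked[passing[-1]]) if passing.size else 0.0
    return p <= crit if passing.size else np.zeros(m, dtype=bool), crit


def _one_sample_power(n: int, d: float, alpha: float) -> float:
    df = n - 1
    tcrit = stats.t.isf(alpha / 2.0, df)
    nc = d * np.sqrt(n)
    return float(stats.nct.sf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))


def required_sample_size(
    effect_size_d: float,
    power: float = 0.80,
    alpha: float = 0.05,
    test: str = "one_sample_two_sided",
    n_max: int = 100_000,
) -> int:
    """Smallest n with a one-sample two-sided t test power >= target.

    Power uses the noncentral t distribution with noncentrality d*sqrt(n)
    and df = n - 1 (the paired-difference design is the one-sample test on
    difference scores).  E.g. d = 0.76 at 80% power, alpha = 0.05 -> n = 16.
    """
    if test != "one_sample_two_sided":
        raise ValueError(f"unsupported test {test!r}")
    if effect_size_d <= 0:
        raise ValueError("effect size must be > 0")
    if not (0 < power < 1 and 0 < alpha < 1):
        raise ValueError("power and alpha must lie in (0, 1)")
    for n in range(2, n_max + 1):
        if _one_sample_power(n, effect_size_d, alpha) >= power:
            return n
    raise ValueError(f"target power {power} unreachable below n = {n_max}")
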