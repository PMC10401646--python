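"""Trial sequences for event-related recall / recognition runs.

An event table is a pandas DataFrame with columns ``onset`` (s), ``duration``
(s), ``trial_type`` (condition label), ``stim_id`` and ``run_index``.  Recall
runs cue each of the 20 studied places once (10 image, 5 panorama, 5 street),
each 10 s imagery trial preceded by a 2 s cue+mask event, with the
inter-trial interval jittered uniformly over whole seconds in [4, 8] and no
condition repeating more than twice in a row.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_COLUMNS",
    "NUISANCE_CONDITIONS",
    "InfeasibleSequenceError",
    "default_stimulus_roster",
    "generate_trial_sequence",
    "validate_events",
    "run_duration",
]

EVENT_COLUMNS = ["onset", "duration", "trial_type", "stim_id", "run_index"]

#: conditions modeled as regressors of no interest, never as task trials
NUISANCE_CONDITIONS = frozenset({"cue_mask", "novel"})

#: seconds of rest appended after the final event so the HRF tail is sampled
RUN_PADDING = 16.0

#: rest before the first trial onset
INITIAL_REST = 4.0

_MAX_ATTEMPTS = 100_000


class InfeasibleSequenceError(ValueError):
    """No ordering satisfies the condition-repetition constraint."""


def default_stimulus_roster(
    condition_counts: Mapping[str, int],
) -> dict[str, list[str]]:
    """Stimulus ids per condition, e.g. image_01..image_10."""
    return {
        cond: [f"{cond}_{i + 1:02d}" for i in range(n)]
        for cond, n in condition_counts.items()
    }


def _max_count_feasible(counts: Mapping[str, int], max_consecutive: int) -> bool:
    # pigeonhole: a condition with n_c of n slots can avoid runs longer than m
    # only if n_c <= m * (n - n_c + 1)
    n = sum(counts.values())
    return all(c <= max_consecutive * (n - c + 1) for c in counts.values())


def _longest_run(seq: Sequence[str]) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if seq else 0


def generate_trial_sequence(
    n_trials: int,
    condition_counts: Mapping[str, int],
    max_consecutive: int = 2,
    isi_range: tuple[float, float] = (4.0, 8.0),
    trial_duration: float = 10.0,
    cue_duration: float = 2.0,
    seed: int = 0,
    run_index: int = 1,
    stimulus_roster: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Pseudo-randomized trial sequence for one run.

    Conditions are shuffled by rejection sampling until no condition repeats
    more than ``max_consecutive`` times; stimulus ids are drawn once each
    within their condition.  Each trial is a ``cue_mask`` event of
    ``cue_duration`` seconds immediately followed by the recall event of
    ``trial_duration`` seconds; trials are separated by an ISI drawn from a
    discrete uniform over whole seconds in ``isi_range``.  ``cue_duration=0``
    omits the cue events (recognition-style runs).

    Raises
    ------
    InfeasibleSequenceError
        If the constraint set admits no ordering, or none is found within
        the attempt budget.
    """
    counts = dict(condition_counts)
    if sum(counts.values()) != n_trials:
        raise ValueError(
            f"condition_counts sums to {sum(counts.values())}, expected {n_trials}"
        )
    if max_consecutive < 1:
        raise ValueError("max_consecutive must be >= 1")
    if not _max_count_feasible(counts, max_consecutive):
        raise InfeasibleSequenceError(
            f"no ordering of {counts} avoids more than {max_consecutive} "
            "consecutive repeats"
        )
    rng = np.random.default_rng(seed)
    pool = [c for c, n in sorted(counts.items()) for _ in range(n)]
    order: list[str] | None = None
    for _ in range(_MAX_ATTEMPTS):
        cand = list(rng.permutation(pool))
        if _longest_run(cand) <= max_consecutive:
            order = cand
            break
    if order is None:
        raise InfeasibleSequenceError(
            f"no valid ordering found within {_MAX_ATTEMPTS} attempts"
        )

    roster = (
        {c: list(v) for c, v in stimulus_roster.items()}
        if stimulus_roster is not None
        else default_stimulus_roster(counts)
    )
    remaining = {c: list(rng.permutation(v)) for c, v in roster.items()}

    isi_lo, isi_hi = isi_range
    isi_choices = np.arange(np.ceil(isi_lo), np.floor(isi_hi) + 1)
    rows: list[dict] = []
    t = INITIAL_REST
    for cond in order:
        if not remaining[cond]:
            raise ValueError(f"stimulus roster exhausted for condition {cond!r}")
        stim = remaining[cond].pop(0)
        if cue_duration > 0:
            rows.append(
                dict(onset=t, duration=cue_duration, trial_type="cue_mask",
                     stim_id=stim, run_index=run_index)
            )
            t += cue_duration
        rows.append(
            dict(onset=t, duration=trial_duration, trial_type=cond,
                 stim_id=stim, run_index=run_index)
        )
        t += trial_duration + float(rng.choice(isi_choices))
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    validate_events(events)
    return events


def validate_events(events: pd.DataFrame) -> None:
    """Check event-table invariants; raise ValueError on violation."""
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"event table missing columns: {missing}")
    if len(events) == 0:
        return
    for run, grp in events.groupby("run_index"):
        onsets = grp["onset"].to_numpy(dtype=float)
        durs = grp["duration"].to_numpy(dtype=float)
        if (onsets < 0).any() or (durs <= 0).any():
            raise ValueError(f"run {run}: onsets must be >= 0, durations > 0")
        if not (np.diff(onsets) > 0).all():
            raise ValueError(f"run {run}: onsets must be strictly increasing")
        if (onsets[:-1] + durs[:-1] > onsets[1:] + 1e-9).any():
            raise ValueError(f"run {run}: overlapping events")


def run_duration(events: pd.DataFrame, tr: float) -> int:
    """Number of TRs covering the run plus the HRF-tail padding."""
    end = float((events["onset"] + events["duration"]).max()) if len(events) else 0.0
    return int(np.ceil((end + RUN_PADDING) / tr))
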