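"""End-to-end synthetic pipeline: simulate -> fit -> ROIs -> stats -> report.

``run_pipeline`` drives the whole two-stage analysis on a simulated cohort:
per-subject beta-series GLMs, functional ROI definition from a simulated
localizer contrast, the ROI x condition repeated-measures ANOVA with
Bonferroni post hocs, and the split-half identity-discrimination analysis
with group inference.  Every output is stamped with a hash of the effective
configuration and the seed, so a rerun with the same config is reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .events import default_stimulus_roster
from .glm import single_trial_estimates
from .hrf import HRFSpec
from .mvpa import (cross_half_rsm, group_identity_stats,
                   identity_discrimination_index)
from .roi import ROIMask, define_functional_roi
from .simulate import (RECALL_CONDITION_COUNTS, make_ground_truth,
                       simulate_cohort, simulate_localizer_contrast)
from .univariate import (build_cohort_table, extract_roi_condition_means,
                         paired_posthoc, rm_anova)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("placemem")


@dataclass
class PipelineConfig:
    """Effective parameters of a synthetic recall / recognition analysis."""

    experiment: str = "recall"          # or "recognition"
    n_subjects: int = 17
    n_runs: int = 8
    tr: float = 2.0
    hrf_p: float = 8.6
    hrf_q: float = 0.547
    poly_order: int | None = None       # default: 4 recall, 3 recognition
    condition_counts: dict = field(
        default_factory=lambda: dict(RECALL_CONDITION_COUNTS))
    roi_sizes: dict = field(
        default_factory=lambda: {"memory": 300, "perception": 300})
    amplitudes: dict = field(default_factory=lambda: {
        "memory": {"image": 0.5, "panorama": 1.0, "street": 1.5},
        "perception": {"image": 1.0, "panorama": 1.0, "street": 1.0},
    })
    rho_id: float = 0.5
    sigma_white: float = 1.0
    ar1_phi: float = 0.3
    drift_amplitude: float = 0.5
    between_subject_sd: float = 0.15
    n_background: int = 200
    selectivity_z: float = 6.0
    top_n: int = 300
    p_threshold: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment not in ("recall", "recognition"):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.poly_order is None:
            self.poly_order = 4 if self.experiment == "recall" else 3
        if self.poly_order < 0:
            raise ValueError("poly_order must be >= 0")
        total = sum(self.condition_counts.values())
        if total <= 0:
            raise ValueError("condition_counts must be non-empty")

    @property
    def trial_duration(self) -> float:
        return 10.0 if self.experiment == "recall" else 2.0

    @property
    def cue_duration(self) -> float:
        return 2.0 if self.experiment == "recall" else 0.0

    @property
    def hrf(self) -> HRFSpec:
        return HRFSpec(p=self.hrf_p, q=self.hrf_q)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_mapping(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**mapping)


def _condition_of(stimuli: list[str]) -> dict[str, str]:
    return {s: s.rsplit("_", 1)[0] for s in stimuli}


def run_pipeline(config: PipelineConfig, out_dir: str | Path,
                 make_figure: bool = True) -> dict:
    """Run the full synthetic analysis; returns the result bundle.

    Writes to ``out_dir``: the cohort cell-mean table, the ANOVA table,
    post hoc tests, per-subject identity indices with group stats, the mean
    similarity matrix per ROI (TSV + heatmap figure) and a log of all
    effective parameters.
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(config, out, make_figure, t0)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path, make_figure: bool, t0: float) -> dict:
    log.info("config %s: %s", config.config_hash(),
             json.dumps(dataclasses.asdict(config), sort_keys=True))
    roster = default_stimulus_roster(config.condition_counts)
    stimuli = [s for v in roster.values() for s in v]
    cond_of = _condition_of(stimuli)

    template = make_ground_truth(
        config.roi_sizes, config.amplitudes, stimuli,
        rho_id=config.rho_id, sigma_white=config.sigma_white,
        ar1_phi=config.ar1_phi, drift_amplitude=config.drift_amplitude,
        n_background=config.n_background, seed=config.seed,
    )
    log.info("simulating cohort: %d subjects x %d runs", config.n_subjects,
             config.n_runs)
    cohort = simulate_cohort(
        config.n_subjects, template,
        between_subject_sd=config.between_subject_sd,
        n_runs=config.n_runs, tr=config.tr, hrf=config.hrf,
        condition_counts=config.condition_counts,
        trial_duration=config.trial_duration,
        cue_duration=config.cue_duration, seed=config.seed,
    )

    ss = np.random.SeedSequence([config.seed, 0xA0])  # localizer substream
    loc_seeds = ss.generate_state(config.n_subjects) % (2**31)

    per_subject_tables = {}
    idx_rows = []
    rsm_acc: dict[str, np.ndarray] = {}
    rsm_stimuli: list[str] | None = None
    n_splits = 0
    for s, dataset in enumerate(cohort):
        truth = dataset.truth
        stat, p = simulate_localizer_contrast(
            truth, config.selectivity_z, seed=int(loc_seeds[s]))
        background = np.arange(
            truth.n_voxels - config.n_background, truth.n_voxels)
        masks = []
        for name, planted in truth.roi_voxels.items():
            constraint = np.concatenate([planted, background])
            masks.append(define_functional_roi(
                stat, p, constraint, p_threshold=config.p_threshold,
                top_n=config.top_n, name=name, signed=True,
            ))
        estimates = single_trial_estimates(
            dataset, hrf=config.hrf, poly_order=config.poly_order)
        per_subject_tables[s] = extract_roi_condition_means(estimates, masks)
        for mask in masks:
            res = cross_half_rsm(estimates, mask)
            rsm_stimuli = res.stimuli
            n_splits = res.n_splits
            rsm_acc.setdefault(mask.name, np.zeros_like(res.mean_rsm))
            rsm_acc[mask.name] += res.mean_rsm
            idx_rows.append(dict(
                subject=s, roi=mask.name,
                index=identity_discrimination_index(
                    res.mean_rsm, res.stimuli, cond_of),
            ))
        log.info("subject %d done (%.1f s elapsed)", s, time.time() - t0)

    cohort_table = build_cohort_table(per_subject_tables)
    anova = rm_anova(cohort_table, within=["condition", "roi"])
    conds = sorted({c for a in config.amplitudes.values() for c in a})
    rois = list(config.roi_sizes)
    contrasts = []
    for roi in rois:
        for i, a in enumerate(conds):
            for b in conds[i + 1:]:
                contrasts.append((
                    f"{roi}:{b}-{a}",
                    dict(roi=roi, condition=b), dict(roi=roi, condition=a),
                ))
    if len(rois) >= 2:
        a, b = rois[0], rois[1]
        hi, lo = conds[-1], conds[0]
        contrasts.append((
            f"({hi}-{lo}):{a}-{b}",
            (dict(roi=a, condition=hi), dict(roi=a, condition=lo)),
            (dict(roi=b, condition=hi), dict(roi=b, condition=lo)),
        ))
    posthocs = paired_posthoc(cohort_table, contrasts)

    indices = pd.DataFrame(idx_rows)
    roi_stats, comparisons = group_identity_stats(
        indices,
        roi_set_comparisons=[("memory_vs_perception", [rois[0]], [rois[1]])]
        if len(rois) >= 2 else [],
    )

    mean_rsms = {k: v / config.n_subjects for k, v in rsm_acc.items()}
    _write_outputs(out, config, cohort_table, anova, posthocs, indices,
                   roi_stats, comparisons, mean_rsms, rsm_stimuli, cond_of,
                   make_figure)
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return dict(
        config=config, cell_means=cohort_table, anova=anova,
        posthocs=posthocs, identity_indices=indices,
        identity_roi_stats=roi_stats, identity_comparisons=comparisons,
        mean_rsms=mean_rsms, rsm_stimuli=rsm_stimuli, n_splits=n_splits,
    )


def _write_outputs(out, config, cohort_table, anova, posthocs, indices,
                   roi_stats, comparisons, mean_rsms, stimuli, cond_of,
                   make_figure) -> None:
    stamp = dict(config_hash=config.config_hash(), seed=config.seed)
    (out / "config.json").write_text(
        json.dumps({**dataclasses.asdict(config), **stamp}, indent=2))
    cohort_table.to_csv(out / "cell_means.tsv", sep="\t", index=False)
    anova.to_csv(out / "anova.tsv", sep="\t", index=False)
    pd.DataFrame([dataclasses.asdict(r) for r in posthocs]).to_csv(
        out / "posthocs.tsv", sep="\t", index=False)
    indices.to_csv(out / "identity_indices.tsv", sep="\t", index=False)
    roi_stats.to_csv(out / "identity_roi_stats.tsv", sep="\t", index=False)
    pd.DataFrame([dataclasses.asdict(r) for r in comparisons]).to_csv(
        out / "identity_comparisons.tsv", sep="\t", index=False)
    for name, rsm in mean_rsms.items():
        pd.DataFrame(rsm, index=stimuli, columns=stimuli).to_csv(
            out / f"rsm_{name}.tsv", sep="\t")
    if make_figure and mean_rsms:
        _rsm_figure(out, mean_rsms, stimuli, cond_of)


def _rsm_figure(out, mean_rsms, stimuli, cond_of) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    # group stimuli by condition along both axes
    order = sorted(range(len(stimuli)), key=lambda i: (cond_of[stimuli[i]], stimuli[i]))
    fig, axes = plt.subplots(1, len(mean_rsms), figsize=(5 * len(mean_rsms), 4.4),
                             squeeze=False)
    for ax, (name, rsm) in zip(axes[0], sorted(mean_rsms.items())):
        im = ax.imshow(rsm[np.ix_(order, order)], vmin=-0.5, vmax=0.5,
                       cmap="RdBu_r")
        ax.set_title(f"{name}: cross-half similarity")
        ax.set_xticks(range(len(order)))
        ax.set_xticklabels([stimuli[i] for i in order], rotation=90, fontsize=5)
        ax.set_yticks(range(len(order)))
        ax.set_yticklabels([stimuli[i] for i in order], fontsize=5)
        fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(out / "rsm_heatmap.png", dpi=150)
    plt.close(fig)
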