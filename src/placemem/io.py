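"""Readers and writers for the package's on-disk formats.

Event tables use the BIDS events dialect: tab-separated, header row, columns
``onset duration trial_type stim_id`` (plus ``run_index`` when present),
"." as the decimal mark.  Images are NIfTI-1 via nibabel; masks and design
matrices round-trip as TSV.  Configuration is YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .design import DesignMatrix
from .events import EVENT_COLUMNS, validate_events
from .glm import TrialEstimates
from .roi import ROIMask

__all__ = [
    "read_events", "write_events",
    "read_image", "write_image",
    "read_mask", "write_mask",
    "write_design", "write_trial_estimates", "read_trial_estimates",
    "load_config",
]

_REQUIRED_EVENT_COLS = ["onset", "duration", "trial_type", "stim_id"]


class FormatError(ValueError):
    """Malformed on-disk input (carries the offending line when known)."""


def read_events(path: str | Path) -> pd.DataFrame:
    """Read a BIDS-style events TSV; strict about dialect.

    Numeric columns must use "." as the decimal mark; a comma decimal (or
    any unparseable number) raises :class:`FormatError` naming the line.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED_EVENT_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    for col in ("onset", "duration"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy() & df[col].notna().to_numpy())
        if bad.size:
            line = int(bad[0]) + 2  # header is line 1
            raise FormatError(
                f"{path}, line {line}: cannot parse {col}={df[col].iloc[bad[0]]!r} "
                "(use '.' as the decimal mark)"
            )
        df[col] = vals
    if "run_index" not in df.columns:
        df["run_index"] = 1
    df["run_index"] = pd.to_numeric(df["run_index"]).astype(int)
    df = df[EVENT_COLUMNS]
    validate_events(df)
    return df


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    events.to_csv(path, sep="\t", index=False, float_format="%g")


def read_image(path: str | Path) -> np.ndarray:
    """Load a NIfTI run as a flat voxel x time matrix (C-order voxels)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 4:
        return data.reshape(-1, data.shape[-1])
    return data


def write_image(
    data: np.ndarray, path: str | Path, grid_shape: tuple[int, int, int] | None = None,
    tr: float | None = None,
) -> None:
    """Write a voxel x time matrix as 4-D NIfTI (flat voxels on an x-axis grid)."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 2:
        raise ValueError("expected voxel x time matrix")
    if grid_shape is None:
        grid_shape = (data.shape[0], 1, 1)
    if int(np.prod(grid_shape)) != data.shape[0]:
        raise ValueError("grid_shape does not match voxel count")
    vol = data.reshape(*grid_shape, data.shape[1])
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    if tr is not None:
        img.header.set_zooms((*img.header.get_zooms()[:3], float(tr)))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))


def write_mask(mask: ROIMask, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"index": mask.indices}).to_csv(path, sep="\t", index=False)
    meta = Path(path).with_suffix(".json")
    meta.write_text(json.dumps(
        dict(name=mask.name, hemisphere=mask.hemisphere, provenance=mask.provenance),
        indent=2, default=str,
    ))


def read_mask(path: str | Path) -> ROIMask:
    idx = pd.read_csv(path, sep="\t")["index"].to_numpy(dtype=int)
    meta_path = Path(path).with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return ROIMask(
        name=meta.get("name", Path(path).stem),
        indices=idx,
        hemisphere=meta.get("hemisphere", "both"),
        provenance=meta.get("provenance", {}),
    )


def write_design(design: DesignMatrix, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame = design.to_frame()
    frame.to_csv(path, sep="\t", index=False)


def write_trial_estimates(estimates: TrialEstimates, prefix: str | Path) -> None:
    """Persist as <prefix>_t.tsv, <prefix>_beta.tsv and <prefix>_trials.tsv."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(estimates.t_values).to_csv(
        f"{prefix}_t.tsv", sep="\t", index=False)
    pd.DataFrame(estimates.betas).to_csv(
        f"{prefix}_beta.tsv", sep="\t", index=False)
    info = estimates.info.copy()
    info.to_csv(f"{prefix}_trials.tsv", sep="\t", index=False)


def read_trial_estimates(prefix: str | Path) -> TrialEstimates:
    prefix = Path(prefix)
    t = pd.read_csv(f"{prefix}_t.tsv", sep="\t").to_numpy(dtype=float)
    b = pd.read_csv(f"{prefix}_beta.tsv", sep="\t").to_numpy(dtype=float)
    info = pd.read_csv(f"{prefix}_trials.tsv", sep="\t")
    return TrialEstimates(betas=b, t_values=t, info=info)


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON — valid YAML) configuration mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg
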