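"""Functional and anatomical regions of interest.

Functional ROIs are drawn from a localizer contrast map: vertices inside an
anatomical constraint that pass a vertex-wise significance threshold
(p < 0.001 by default) form the candidate set, which is then restricted to
a fixed size — the top-N most selective vertices (N = 300 by default), or
the N vertices nearest the candidate centroid.  Fixing N makes ROIs
comparable in size across regions and subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ROIMask", "define_functional_roi", "load_anatomical_roi"]


@dataclass
class ROIMask:
    """A named set of vertex/voxel indices."""

    name: str
    indices: np.ndarray
    hemisphere: str = "both"
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        if len(np.unique(self.indices)) != self.indices.size:
            raise ValueError(f"ROI {self.name!r} has duplicate indices")
        if self.hemisphere not in ("left", "right", "both"):
            raise ValueError(f"bad hemisphere tag {self.hemisphere!r}")

    @property
    def size(self) -> int:
        return self.indices.size


def define_functional_roi(
    stat_map: np.ndarray,
    p_map: np.ndarray,
    anatomical_constraint: np.ndarray,
    p_threshold: float = 0.001,
    top_n: int = 300,
    variant: str = "most_selective",
    name: str = "roi",
    hemisphere: str = "both",
    signed: bool = False,
    grid_shape: tuple[int, ...] | None = None,
) -> ROIMask:
    """Threshold a contrast map and keep a fixed number of vertices.

    Parameters
    ----------
    signed : bool
        If True, "most selective" means largest statistic in the positive
        (preferred) direction; if False (default), largest ``|statistic|``.
    grid_shape : tuple, optional
        3-D shape for the ``center_of_mass`` variant's Euclidean distances;
        flat 1-D positions are used when omitted.

    Candidates are ``{v in constraint : p(v) < p_threshold}``; ties in the
    selection score at the top-N boundary are broken toward the lower
    vertex index, making the output deterministic.
    """
    stat_map = np.asarray(stat_map, dtype=float)
    p_map = np.asarray(p_map, dtype=float)
    if stat_map.shape != p_map.shape:
        raise ValueError("stat_map and p_map must be aligned")
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must be in (0, 1)")
    constraint = np.asarray(anatomical_constraint, dtype=int)
    cand = constraint[p_map[constraint] < p_threshold]
    if cand.size == 0:
        raise ValueError(
            f"no suprathreshold vertices for ROI {name!r} at p < {p_threshold}"
        )
    if cand.size < top_n:
        warnings.warn(
            f"ROI {name!r}: only {cand.size} suprathreshold vertices "
            f"(requested top {top_n})",
            stacklevel=2,
        )
    n_keep = min(top_n, cand.size)

    if variant == "most_selective":
        score = stat_map[cand] if signed else np.abs(stat_map[cand])
        # sort by (-score, index): highest score first, lower index on ties
        order = np.lexsort((cand, -score))
    elif variant == "center_of_mass":
        if grid_shape is not None:
            pos = np.column_stack(np.unravel_index(cand, grid_shape)).astype(float)
        else:
            pos = cand[:, None].astype(float)
        centroid = pos.mean(axis=0)
        dist = np.linalg.norm(pos - centroid, axis=1)
        order = np.lexsort((cand, dist))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    keep = np.sort(cand[order[:n_keep]])
    return ROIMask(
        name=name,
        indices=keep,
        hemisphere=hemisphere,
        provenance=dict(
            p_threshold=p_threshold, top_n=top_n, variant=variant,
            n_candidates=int(cand.size), signed=signed,
        ),
    )


def load_anatomical_roi(
    label_volume: np.ndarray,
    label_ids: int | list[int],
    name: str = "anatomical",
    hemisphere_of_label: dict[int, str] | None = None,
) -> ROIMask:
    """Flat voxel indices matching segmentation label id(s).

    ``label_volume`` may be any integer array (e.g. the data of a
    segmentation NIfTI); it is flattened in C order.  Raises if a requested
    label is absent.
    """
    labels = np.atleast_1d(np.asarray(label_ids, dtype=int))
    flat = np.asarray(label_volume).ravel()
    idx_parts = []
    hemis = set()
    for lab in labels:
        hit = np.flatnonzero(flat == lab)
        if hit.size == 0:
            raise ValueError(f"label {int(lab)} not present in volume")
        idx_parts.append(hit)
        if hemisphere_of_label:
            hemis.add(hemisphere_of_label.get(int(lab), "both"))
    hemi = hemis.pop() if len(hemis) == 1 else "both"
    return ROIMask(
        name=name,
        indices=np.unique(np.concatenate(idx_parts)),
        hemisphere=hemi,
        provenance=dict(labels=[int(v) for v in labels]),
    )
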