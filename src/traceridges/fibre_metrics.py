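"""Per-fibre morphology and inter-fibre gap analysis.

Morphological descriptors (length, width, orientation, eccentricity,
mean intensity) are computed per trace from the second central moments
of its pixel set.  Gaps are the enclosed background regions between
fibres: connected components of the trace-mask complement that do not
touch the image border.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .imagetools import GrayImage, InputError
from .trace_ridges import TraceSet, _component_axes, _EIGHT

__all__ = ["FibreRecord", "GapReport", "fibre_properties", "gap_analysis",
           "records_to_csv", "gap_report_to_json"]


@dataclass(frozen=True)
class FibreRecord:
    """Morphology of a single traced fibre.

    length is the ellipse-equivalent major axis (px); width is the mean
    local thickness of the pre-thinning support where available, else
    1 px for a thinned line; orientation is degrees in (-90, 90] with 0
    horizontal and positive angles rotating counter-clockwise (upward in
    image coordinates).
    """

    trace_id: int
    length: float
    width: float
    orientation: float
    eccentricity: float
    mean_intensity: float
    pixel_count: int


@dataclass(frozen=True)
class GapReport:
    """Areas of the enclosed background regions between fibres."""

    gap_areas: tuple[int, ...]
    largest_gap: int
    gap_count: int


def _orientation_deg(coords: np.ndarray) -> float:
    """Major-axis angle from horizontal, degrees in (-90, 90].

    Works in (x, y) = (col, -row) so angles are counter-clockwise in
    the usual mathematical sense despite rows increasing downward.
    """
    xy = np.column_stack([coords[:, 1], -coords[:, 0]]).astype(float)
    d = xy - xy.mean(axis=0)
    cov = d.T @ d / len(xy)
    theta = 0.5 * np.arctan2(2.0 * cov[0, 1], cov[0, 0] - cov[1, 1])
    deg = np.degrees(theta)
    if deg <= -90.0:
        deg += 180.0
    elif deg > 90.0:
        deg -= 180.0
    return float(deg)


def _eccentricity(coords: np.ndarray) -> float:
    major, minor = _component_axes(coords)
    if major == 0:
        return 0.0
    return float(np.sqrt(max(0.0, 1.0 - (minor / major) ** 2)))


def _mean_width(coords: np.ndarray, support: np.ndarray) -> float:
    """Mean local thickness along the trace from the support's distance
    transform: twice the distance from the centreline to the support
    boundary, clipped below at 1 px."""
    dt = ndi.distance_transform_edt(support)
    vals = dt[coords[:, 0], coords[:, 1]]
    w = 2.0 * float(vals.mean()) - 1.0
    return max(1.0, w)


def fibre_properties(
    traces: TraceSet, img: GrayImage
) -> list[FibreRecord]:
    """One FibreRecord per trace, in trace order (ids are 1-based)."""
    if traces.shape != img.shape:
        raise InputError("trace set and image shapes differ")
    records: list[FibreRecord] = []
    support = traces.support
    for i, t in enumerate(traces.traces, start=1):
        coords = np.array(sorted(t.pixel_coords))
        width = 1.0
        if support is not None and support.any():
            comp_support = _component_support(coords, support)
            if comp_support is not None:
                width = _mean_width(coords, comp_support)
        records.append(
            FibreRecord(
                trace_id=i,
                length=t.major_axis_length,
                width=width,
                orientation=_orientation_deg(coords),
                eccentricity=_eccentricity(coords),
                mean_intensity=t.mean_intensity,
                pixel_count=len(coords),
            )
        )
    return records


def _component_support(
    coords: np.ndarray, support: np.ndarray
) -> np.ndarray | None:
    """Support component(s) overlapping the trace pixels, if any."""
    lab, n = ndi.label(support, structure=_EIGHT)
    ids = np.unique(lab[coords[:, 0], coords[:, 1]])
    ids = ids[ids > 0]
    if ids.size == 0:
        return None
    return np.isin(lab, ids)


def gap_analysis(traces: TraceSet) -> GapReport:
    """Areas of enclosed background regions between traces.

    Components of the complement touching the image border are open
    background, not gaps, and are excluded.
    """
    bg = ~traces.mask() if len(traces) else np.ones(traces.shape, dtype=bool)
    lab, n = ndi.label(bg, structure=_EIGHT)
    if n == 0:
        return GapReport(gap_areas=(), largest_gap=0, gap_count=0)
    border = np.unique(
        np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
    )
    areas = ndi.sum_labels(bg, lab, np.arange(1, n + 1)).astype(int)
    gaps = tuple(
        int(a) for i, a in enumerate(areas, start=1) if i not in border and a > 0
    )
    return GapReport(
        gap_areas=gaps,
        largest_gap=max(gaps) if gaps else 0,
        gap_count=len(gaps),
    )


def records_to_csv(records: list[FibreRecord], path: str | Path) -> None:
    pd.DataFrame([asdict(r) for r in records]).to_csv(path, index=False)


def gap_report_to_json(report: GapReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(report), indent=2))
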