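"""Distance-map comparison of a trace set against ground truth.

Pixel-wise overlap metrics cannot tell how far a mis-placed trace lies
from the truth: two delineations crossing the ground truth at a single
pixel score identically whether they hug it or diverge wildly.  The
distance-map metrics used here do: the Euclidean distance transform of
one trace set is sampled at the pixels of the other (the "product map"),
and its sum, per-trace mean and maximum quantify the separation in both
directions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .imagetools import InputError
from .trace_ridges import TraceSet

__all__ = [
    "DistanceMap",
    "DirectedError",
    "DistanceErrorReport",
    "EvaluationError",
    "distance_map",
    "directed_error",
    "compare",
    "report_to_json",
    "report_to_csv",
]


class EvaluationError(ValueError):
    """Raised when a comparison is undefined (e.g. an empty trace set)."""


@dataclass(frozen=True)
class DistanceMap:
    """Per-pixel exact Euclidean distance to the nearest trace pixel."""

    values: np.ndarray


@dataclass(frozen=True)
class DirectedError:
    """Error of one trace set measured on the other's distance map."""

    total: float
    mean_per_trace: float
    max: float
    n_traces: int


@dataclass(frozen=True)
class DistanceErrorReport:
    """Both directed errors plus symmetric summaries.

    ``total`` sums both directions; ``mean_per_trace`` divides the
    combined total by the combined trace count; ``max`` is the larger
    directed maximum.
    """

    gt_to_result: DirectedError
    result_to_gt: DirectedError

    @property
    def total(self) -> float:
        return self.gt_to_result.total + self.result_to_gt.total

    @property
    def mean_per_trace(self) -> float:
        n = self.gt_to_result.n_traces + self.result_to_gt.n_traces
        return self.total / n if n else 0.0

    @property
    def max(self) -> float:
        return max(self.gt_to_result.max, self.result_to_gt.max)


def distance_map(traces: TraceSet) -> DistanceMap:
    """Exact Euclidean distance transform of the trace-mask complement."""
    mask = traces.mask()
    if not mask.any():
        raise EvaluationError("distance map undefined for an empty trace set")
    return DistanceMap(values=ndi.distance_transform_edt(~mask))


def directed_error(source: TraceSet, target_map: DistanceMap) -> DirectedError:
    """Product-map statistics of ``source`` on ``target_map``.

    The product map is the target distance map restricted to the source
    trace pixels; total/max are its sum and maximum, and the mean is
    the total divided by the source trace count.
    """
    if source.shape != target_map.values.shape:
        raise InputError("source and distance map shapes differ")
    mask = source.mask()
    if not mask.any():
        raise EvaluationError("directed error undefined for an empty trace set")
    product = target_map.values[mask]
    n = len(source)
    total = float(product.sum())
    return DirectedError(
        total=total,
        mean_per_trace=total / n,
        max=float(product.max()),
        n_traces=n,
    )


def compare(result: TraceSet, gt: TraceSet) -> DistanceErrorReport:
    """Distance errors between a traced result and the ground truth.

    Computes both directions — ground truth on the result's distance
    map and vice versa — so the combined total is symmetric under
    argument swap.
    """
    if result.shape != gt.shape:
        raise InputError("result and ground truth shapes differ")
    if len(result) == 0:
        raise EvaluationError("cannot evaluate an empty result trace set")
    if len(gt) == 0:
        raise EvaluationError("cannot evaluate against an empty ground truth")
    gt_err = directed_error(gt, distance_map(result))
    res_err = directed_error(result, distance_map(gt))
    return DistanceErrorReport(gt_to_result=gt_err, result_to_gt=res_err)


def _report_dict(report: DistanceErrorReport) -> dict:
    return {
        "total": report.total,
        "mean_per_trace": report.mean_per_trace,
        "max": report.max,
        "gt_to_result": asdict(report.gt_to_result),
        "result_to_gt": asdict(report.result_to_gt),
    }


def report_to_json(report: DistanceErrorReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_report_dict(report), indent=2))


def report_to_csv(report: DistanceErrorReport, path: str | Path) -> None:
    d = _report_dict(report)
    row = {
        "total": d["total"],
        "mean_per_trace": d["mean_per_trace"],
        "max": d["max"],
    }
    for direction in ("gt_to_result", "result_to_gt"):
        for k, v in d[direction].items():
            row[f"{direction}_{k}"] = v
    pd.DataFrame([row]).to_csv(path, index=False)
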