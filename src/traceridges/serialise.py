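"""On-disk forms of trace sets and configuration.

A TraceSet round-trips through two representations: a 16-bit label
image (0 background, k for trace k) and a CSV of pixel coordinates with
a JSON sidecar of per-trace fields.  Configuration files are flat
``key=value`` text.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi

from .imagetools import GrayImage, InputError, load_image
from .trace_ridges import Trace, TraceRidgesConfig, TraceSet, _make_trace, _EIGHT

__all__ = [
    "save_traceset",
    "load_traceset_csv",
    "traceset_from_mask",
    "load_gt",
    "read_config_file",
    "config_from_mapping",
]


def save_traceset(traces: TraceSet, stem: str | Path) -> dict[str, Path]:
    """Write label TIFF, coordinate CSV and per-trace JSON sidecar.

    Returns the paths written, keyed by kind (labels/coords/fields).
    """
    stem = Path(stem)
    paths = {
        "labels": stem.with_suffix(".tif"),
        "coords": stem.with_suffix(".csv"),
        "fields": stem.with_suffix(".json"),
    }
    tifffile.imwrite(paths["labels"], traces.label_image())
    rows = []
    fields = []
    for i, t in enumerate(traces.traces, start=1):
        for r, c in sorted(t.pixel_coords):
            rows.append((i, r, c, t.source_tag))
        fields.append(
            {
                "trace_id": i,
                "source_tag": t.source_tag,
                "mean_intensity": t.mean_intensity,
                "major_axis_length": t.major_axis_length,
                "minor_axis_length": t.minor_axis_length,
            }
        )
    pd.DataFrame(rows, columns=["trace_id", "row", "col", "source_tag"]).to_csv(
        paths["coords"], index=False
    )
    paths["fields"].write_text(
        json.dumps({"shape": list(traces.shape), "traces": fields}, indent=2)
    )
    return paths


def load_traceset_csv(
    coords_path: str | Path, img: GrayImage | None = None,
    shape: tuple[int, int] | None = None,
) -> TraceSet:
    """Rebuild a TraceSet from its coordinate CSV (+JSON sidecar shape)."""
    coords_path = Path(coords_path)
    df = pd.read_csv(coords_path)
    sidecar = coords_path.with_suffix(".json")
    if shape is None:
        if sidecar.exists():
            shape = tuple(json.loads(sidecar.read_text())["shape"])
        elif img is not None:
            shape = img.shape
        else:
            shape = (int(df["row"].max()) + 1, int(df["col"].max()) + 1)
    ref = img if img is not None else GrayImage(np.zeros(shape))
    traces = []
    for tid, grp in df.groupby("trace_id"):
        coords = grp[["row", "col"]].to_numpy()
        tag = str(grp["source_tag"].iloc[0])
        traces.append(_make_trace(coords, ref, tag))
    return TraceSet(traces=tuple(traces), shape=shape)


def traceset_from_mask(
    mask: np.ndarray, img: GrayImage | None = None, tag: str = "main_ridge"
) -> TraceSet:
    """TraceSet from a binary mask: one trace per 8-connected component."""
    mask = np.asarray(mask).astype(bool)
    ref = img if img is not None else GrayImage(np.zeros(mask.shape))
    lab, n = ndi.label(mask, structure=_EIGHT)
    traces = tuple(
        _make_trace(np.argwhere(lab == i), ref, tag) for i in range(1, n + 1)
    )
    return TraceSet(traces=traces, shape=mask.shape, support=mask)


def load_gt(path: str | Path, img: GrayImage | None = None) -> TraceSet:
    """Ground truth from a binary mask image (TIFF/PNG) or TraceSet CSV."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        return load_traceset_csv(path, img=img)
    loaded = load_image(path)
    if not isinstance(loaded, GrayImage):
        raise InputError("ground-truth mask must be a single 2-D image")
    return traceset_from_mask(loaded.pixels > 0.5, img=img)


def read_config_file(path: str | Path) -> dict[str, str]:
    """Parse a flat key=value config file; '#' starts a comment."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise InputError(f"malformed config line: {line!r}")
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out


_CFG_FIELDS = {f.name: f.type for f in dataclasses.fields(TraceRidgesConfig)}


def config_from_mapping(mapping: dict[str, str]) -> TraceRidgesConfig:
    """Build a TraceRidgesConfig from string key=value pairs."""
    kwargs = {}
    for k, v in mapping.items():
        if k not in _CFG_FIELDS:
            raise InputError(f"unknown config key {k!r}")
        if k in ("recovered_count_switch", "max_hole_area"):
            kwargs[k] = int(v)
        elif k == "dark_threshold_mode":
            kwargs[k] = v
        elif k in ("canny_low", "canny_high"):
            kwargs[k] = v if v == "auto" else float(v)
        else:
            kwargs[k] = float(v)
    return TraceRidgesConfig(**kwargs)
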