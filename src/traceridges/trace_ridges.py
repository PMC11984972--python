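"""Fibre tracing by watershed ridge lines fused with Canny edges.

The watershed transform of the intensity landscape places its divide
lines on ridges — the bright centrelines of fibres — but it
over-segments: spurious *minor* ridges run down the fibre flanks between
noise-induced basins.  Canny edges flank the strong ridges on both sides
and cross those minor ridges, so removing the pixels where edges and
watershed lines overlap breaks the minor ridges off the main ones.  The
detached fragments are then removed by size and by brightness, double
ridge lines enclosing slim holes are collapsed via their Euler
characteristic, and ridges the watershed missed (both flanks draining to
one basin) are recovered from edge pairs by closing the space between
the edges and thinning it to a centre line.  Main and recovered ridges
are finally fused into a set of one-pixel-wide traces, giving priority
to longer and brighter fibres where they conflict.

All masks are boolean arrays with 0-based (row, col) indexing; traces
use 8-connectivity throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import canny
from skimage.filters import threshold_otsu
from skimage.morphology import disk, local_minima, thin
from skimage.segmentation import watershed

from .imagetools import GrayImage, InputError

__all__ = [
    "Trace",
    "TraceSet",
    "TraceRidgesConfig",
    "watershed_ridge_lines",
    "canny_edges",
    "break_minor_ridges",
    "remove_small_segments",
    "remove_dark_segments",
    "repair_double_ridges",
    "recover_missed_ridges",
    "fuse",
    "trace_ridges",
]

log = logging.getLogger("traceridges")

_EIGHT = np.ones((3, 3), dtype=int)  # 8-connectivity structuring element


@dataclass(frozen=True)
class Trace:
    """A single one-pixel-wide fibre trace.

    ``pixel_coords`` is a frozenset of 0-based (row, col) pairs forming
    one 8-connected component.  ``source_tag`` records provenance:
    ``main_ridge`` for watershed-derived traces, ``recovered_edge`` for
    traces reconstructed from edge pairs.  Axis lengths come from the
    ellipse with the same normalised second central moments as the
    pixel set.
    """

    pixel_coords: frozenset[tuple[int, int]]
    source_tag: Literal["main_ridge", "recovered_edge"]
    mean_intensity: float
    major_axis_length: float
    minor_axis_length: float

    def __post_init__(self) -> None:
        if not self.pixel_coords:
            raise InputError("Trace cannot be empty")
        if self.major_axis_length < self.minor_axis_length:
            raise InputError("major axis must be >= minor axis")

    def __len__(self) -> int:
        return len(self.pixel_coords)


@dataclass(frozen=True)
class TraceSet:
    """A labelled collection of pairwise disjoint thin traces.

    ``support`` optionally carries the pre-thinning foreground so that
    downstream width estimation can recover local thickness.
    """

    traces: tuple[Trace, ...]
    shape: tuple[int, int]
    support: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.traces)

    def mask(self) -> np.ndarray:
        """Boolean mask of all trace pixels."""
        m = np.zeros(self.shape, dtype=bool)
        for t in self.traces:
            rows, cols = zip(*t.pixel_coords)
            m[list(rows), list(cols)] = True
        return m

    def label_image(self) -> np.ndarray:
        """uint16 label image: 0 background, k for trace k (1-based)."""
        lab = np.zeros(self.shape, dtype=np.uint16)
        for i, t in enumerate(self.traces, start=1):
            rows, cols = zip(*t.pixel_coords)
            lab[list(rows), list(cols)] = i
        return lab


@dataclass(frozen=True)
class TraceRidgesConfig:
    """Every threshold the tracing pipeline uses.

    min_segment_major_axis:
        segments with ellipse major axis below this (px) are discarded.
    recovered_count_switch:
        if fewer recovered-ridge candidates than this survive the
        two-edge filter, the relaxed axis rule applies; otherwise the
        strict rule.
    relaxed_min_major / strict_min_major:
        major-axis thresholds (px) for recovered candidates under the
        relaxed and strict rules.
    recovered_max_minor:
        recovered candidates must have minor axis below this (px).
    max_hole_area:
        holes up to this area (px^2) between double ridge lines are
        filled before re-thinning.
    dark_threshold_mode / dark_threshold_value:
        segments whose mean underlying intensity falls below the Otsu
        threshold of the image (or a fixed value) are discarded.
    canny_sigma, canny_low, canny_high:
        Gaussian scale and hysteresis fractions for the internal edge
        stage; "auto" derives the thresholds from the gradient
        magnitude.
    """

    min_segment_major_axis: float = 5.0
    recovered_count_switch: int = 100
    relaxed_min_major: float = 15.0
    strict_min_major: float = 25.0
    recovered_max_minor: float = 10.0
    max_hole_area: int = 5
    dark_threshold_mode: Literal["otsu", "fixed"] = "otsu"
    dark_threshold_value: float = 0.5
    canny_sigma: float = 1.0
    canny_low: float | str = "auto"
    canny_high: float | str = "auto"

    def __post_init__(self) -> None:
        for name in (
            "min_segment_major_axis",
            "relaxed_min_major",
            "strict_min_major",
            "recovered_max_minor",
        ):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.strict_min_major <= self.relaxed_min_major:
            raise InputError("strict_min_major must exceed relaxed_min_major")
        if self.dark_threshold_mode not in ("otsu", "fixed"):
            raise InputError("dark_threshold_mode must be 'otsu' or 'fixed'")


# ---------------------------------------------------------------------------
# Stage 1: watershed ridge lines and Canny edges
# ---------------------------------------------------------------------------

def watershed_ridge_lines(img: GrayImage) -> np.ndarray:
    """Watershed divide lines of the intensity landscape.

    The image is flooded from its regional minima (dark background
    pockets), so the divide lines between catchment basins fall on the
    intensity ridges — the bright fibre crests.  Returns a boolean mask
    of the divide pixels.  A constant image has no relief and yields an
    empty mask.
    """
    px = img.pixels
    if px.max() == px.min():
        log.warning("constant image: no ridges to delineate")
        return np.zeros(px.shape, dtype=bool)
    markers, n = ndi.label(local_minima(px, connectivity=2), structure=_EIGHT)
    if n == 0:
        return np.zeros(px.shape, dtype=bool)
    labels = watershed(px, markers=markers, connectivity=2, watershed_line=True)
    return labels == 0


def canny_edges(
    img: GrayImage,
    sigma: float = 1.0,
    low: float | str = "auto",
    high: float | str = "auto",
) -> np.ndarray:
    """Canny edge mask: smoothing, gradient, non-maximum suppression,
    hysteresis.  ``low``/``high`` are fractions of the maximum gradient
    magnitude; "auto" lets the detector derive them."""
    lo = None if low == "auto" else float(low)
    hi = None if high == "auto" else float(high)
    if lo is not None and hi is not None and not (0 <= lo < hi <= 1):
        raise InputError("require 0 <= low < high <= 1")
    return canny(
        img.pixels,
        sigma=sigma,
        low_threshold=lo,
        high_threshold=hi,
        use_quantiles=False,
    )


# ---------------------------------------------------------------------------
# Stage 2: breaking and refinement of the watershed network
# ---------------------------------------------------------------------------

def break_minor_ridges(ridges: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Remove from the ridge mask every pixel shared with the edge mask.

    The overlap pixels are where edges cross the minor ridges running
    down the fibre flanks; deleting them detaches the minor ridges from
    the main divide network.  Two 8-connected curves can also cross
    between pixel centres — a diagonal ridge pair threaded by the
    opposite diagonal edge pair shares no pixel — so those crossings
    are cut as well by removing one ridge pixel of the pair
    (deterministically the lower one).
    """
    if ridges.shape != edges.shape:
        raise InputError(f"shape mismatch: {ridges.shape} vs {edges.shape}")
    out = ridges & ~edges
    # diagonal crossing: ridge on (r,c)-(r+1,c+1), edge on (r+1,c)-(r,c+1)
    cross = out[:-1, :-1] & out[1:, 1:] & edges[1:, :-1] & edges[:-1, 1:]
    out[1:, 1:] &= ~cross
    # anti-diagonal crossing: ridge on (r,c+1)-(r+1,c), edge on (r,c)-(r+1,c+1)
    across = out[:-1, 1:] & out[1:, :-1] & edges[:-1, :-1] & edges[1:, 1:]
    out[1:, :-1] &= ~across
    return out


def _component_axes(coords: np.ndarray) -> tuple[float, float]:
    """Ellipse-equivalent (major, minor) axis lengths of a pixel set.

    Standard region-properties definition: four times the square root
    of the eigenvalues of the normalised second central moment matrix
    (with the 1/12 pixel self-variance term).
    """
    rc = coords.astype(float)
    mu = rc.mean(axis=0)
    d = rc - mu
    cov = d.T @ d / len(rc) + np.eye(2) / 12.0
    ev = np.linalg.eigvalsh(cov)
    ev = np.clip(ev, 0.0, None)
    minor, major = 4.0 * np.sqrt(ev)
    return float(major), float(minor)


def remove_small_segments(mask: np.ndarray, min_major: float) -> np.ndarray:
    """Delete 8-connected components with ellipse major axis < min_major."""
    if min_major < 0:
        raise InputError("min_major must be >= 0")
    if min_major == 0:
        return mask.copy()
    lab, n = ndi.label(mask, structure=_EIGHT)
    if n == 0:
        return mask.copy()
    out = mask.copy()
    for sl, idx in zip(ndi.find_objects(lab), range(1, n + 1)):
        comp = lab[sl] == idx
        major, _ = _component_axes(np.argwhere(comp))
        if major < min_major:
            out[sl][comp] = False
    return out


def _dark_threshold(img: GrayImage, cfg: TraceRidgesConfig) -> float:
    if cfg.dark_threshold_mode == "fixed":
        return cfg.dark_threshold_value
    px = img.pixels
    if px.max() == px.min():
        return float(px.max())
    return float(threshold_otsu(px))


def remove_dark_segments(
    mask: np.ndarray, img: GrayImage, cfg: TraceRidgesConfig
) -> np.ndarray:
    """Delete components whose mean underlying intensity is below the
    dark threshold — watershed lines in dark regions delineate basins
    of the background, not fibres."""
    if mask.shape != img.shape:
        raise InputError("mask and image shapes differ")
    thr = _dark_threshold(img, cfg)
    lab, n = ndi.label(mask, structure=_EIGHT)
    if n == 0:
        return mask.copy()
    means = ndi.labeled_comprehension(
        img.pixels, lab, np.arange(1, n + 1), np.mean, float, 0.0
    )
    keep = np.concatenate(([False], means >= thr))
    return keep[lab]


def repair_double_ridges(mask: np.ndarray, cfg: TraceRidgesConfig) -> np.ndarray:
    """Collapse double ridge lines enclosing very small holes.

    Components with Euler characteristic < 1 contain holes; holes of
    area <= max_hole_area are filled and the component re-thinned to a
    single centre line.  Larger holes (genuine loops in the fibre
    network) are left untouched, as are all hole-free components.
    """
    lab, n = ndi.label(mask, structure=_EIGHT)
    out = mask.copy()
    for sl, idx in zip(ndi.find_objects(lab), range(1, n + 1)):
        # pad so hole filling sees the outside of the component
        comp = np.pad(lab[sl] == idx, 1)
        filled = ndi.binary_fill_holes(comp)
        holes = filled & ~comp
        if not holes.any():
            continue
        hlab, hn = ndi.label(holes, structure=np.array(
            [[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        sizes = ndi.sum_labels(holes, hlab, np.arange(1, hn + 1))
        small = np.concatenate(([False], sizes <= cfg.max_hole_area))
        patched = comp | small[hlab]
        if patched.sum() == comp.sum():
            continue  # every hole too large: leave untouched
        skel = thin(patched)[1:-1, 1:-1]
        region = out[sl]
        region[lab[sl] == idx] = False
        region |= skel
    return out


# ---------------------------------------------------------------------------
# Stage 3: recovery of ridges the watershed missed
# ---------------------------------------------------------------------------

def _neighbour_count(mask: np.ndarray) -> np.ndarray:
    return ndi.convolve(mask.astype(int), _EIGHT, mode="constant") - mask


def _prune_spurs(skel: np.ndarray, max_len: int) -> np.ndarray:
    """Remove side branches of length <= max_len from a thin skeleton.

    Thinning a closed band leaves short diagonal spurs at its corners;
    these are artefacts of the band shape, not ridge structure.  A spur
    is a path from an endpoint to a junction pixel; free ends of an
    unbranched curve are never pruned.
    """
    nb = _neighbour_count(skel)
    endpoints = np.argwhere(skel & (nb == 1))
    # spurs are identified against the frozen skeleton so that pruning
    # one tine of a fork cannot disguise its sibling as a plain bend
    to_remove: list[tuple[int, int]] = []
    for r, c in endpoints:
        path = [(int(r), int(c))]
        prev: tuple[int, int] | None = None
        cur = (int(r), int(c))
        while len(path) <= max_len:
            rr, cc = cur
            neigh = [
                (rr + dr, cc + dc)
                for dr in (-1, 0, 1)
                for dc in (-1, 0, 1)
                if (dr or dc)
                and 0 <= rr + dr < skel.shape[0]
                and 0 <= cc + dc < skel.shape[1]
                and skel[rr + dr, cc + dc]
                and (rr + dr, cc + dc) != prev
            ]
            if len(neigh) != 1:
                break  # junction (or isolated end) reached
            nxt = neigh[0]
            if nb[nxt] > 2:
                # nxt is a junction: the walked path is a spur
                to_remove.extend(path)
                break
            prev, cur = cur, nxt
            path.append(nxt)
    out = skel.copy()
    for pr, pc in to_remove:
        out[pr, pc] = False
    return out

def recover_missed_ridges(
    edges: np.ndarray,
    main: np.ndarray,
    img: GrayImage,
    cfg: TraceRidgesConfig,
) -> np.ndarray:
    """Reconstruct ridges absent from the watershed output.

    A ridge whose two flanks drain into a single basin produces no
    divide line, but its two Canny edges are still there.  The space
    between edge pairs is closed and filled, then thinned to a centre
    line.  Candidates supported by only one edge are discarded as noise,
    as are candidates flanking a ridge already present in ``main``.
    The survivors pass an axis filter: with fewer candidates than
    ``recovered_count_switch`` the relaxed rule applies (major axis >
    relaxed_min_major), otherwise the strict rule (major axis >=
    strict_min_major); in both cases the minor axis must stay below
    recovered_max_minor.
    """
    if edges.shape != main.shape:
        raise InputError("edge and main masks differ in shape")
    if not edges.any():
        return np.zeros_like(edges)

    radius = max(1, int(round(cfg.recovered_max_minor / 2)))
    # edges flanking a ridge the watershed already traced belong to that
    # ridge: only the remaining "orphan" edges can support a missed one
    if main.any():
        near_main = ndi.distance_transform_edt(~main) <= radius
        free_edges = edges & ~near_main
    else:
        near_main = np.zeros_like(main)
        free_edges = edges
    # pad so closing is not eroded at the image border
    pad = 2 * radius
    closed = ndi.binary_closing(
        np.pad(free_edges, pad), structure=disk(radius).astype(bool)
    )
    filled = ndi.binary_fill_holes(closed)[pad:-pad, pad:-pad]

    cand_lab, n = ndi.label(filled, structure=_EIGHT)
    candidates: list[np.ndarray] = []
    for sl, idx in zip(ndi.find_objects(cand_lab), range(1, n + 1)):
        comp = cand_lab[sl] == idx
        # the ridge is not missed if the watershed already traced it
        if (main[sl] & comp).any():
            continue
        skel = _prune_spurs(thin(comp), max_len=radius + 1)
        if not skel.any():
            continue
        # two-edge support: after discounting the centre line's own
        # vicinity, flanking edge material must remain on >= 2 sides.
        # A one-sided edge thickens into a band whose centre line is the
        # edge itself, so nothing survives the discount and it is
        # discarded as a low-level ridge or noise.
        flank = edges[sl] & comp & ~ndi.binary_dilation(skel, structure=_EIGHT)
        flank_lab, fn = ndi.label(flank, structure=_EIGHT)
        if fn:
            sizes = ndi.sum_labels(flank, flank_lab, np.arange(1, fn + 1))
            n_sides = int((sizes >= 3).sum())
        else:
            n_sides = 0
        if n_sides < 2:
            continue
        full = np.zeros_like(edges)
        full[sl][skel] = True
        candidates.append(full)

    strict = len(candidates) >= cfg.recovered_count_switch
    if strict:
        log.info(
            "%d recovered candidates: applying strict axis rule", len(candidates)
        )
    out = np.zeros_like(edges)
    for cand in candidates:
        major, minor = _component_axes(np.argwhere(cand))
        if minor >= cfg.recovered_max_minor:
            continue
        if strict:
            if major >= cfg.strict_min_major:
                out |= cand
        else:
            if major > cfg.relaxed_min_major:
                out |= cand
    return out


# ---------------------------------------------------------------------------
# Stage 4: fusion into a TraceSet
# ---------------------------------------------------------------------------

def _make_trace(
    coords: np.ndarray, img: GrayImage, tag: str
) -> Trace:
    major, minor = _component_axes(coords)
    inten = float(img.pixels[coords[:, 0], coords[:, 1]].mean())
    return Trace(
        pixel_coords=frozenset((int(r), int(c)) for r, c in coords),
        source_tag=tag,  # type: ignore[arg-type]
        mean_intensity=inten,
        major_axis_length=major,
        minor_axis_length=minor,
    )


def fuse(
    main: np.ndarray,
    recovered: np.ndarray,
    img: GrayImage,
    support: np.ndarray | None = None,
) -> TraceSet:
    """Fuse main and recovered ridge masks into disjoint thin traces.

    Each mask is thinned and split into 8-connected components.  Where
    components from the two masks share pixels, the component with the
    greater priority — major axis length times mean intensity, i.e.
    longer and brighter — keeps the shared pixels and the other is
    broken there, possibly splitting into several traces.
    """
    if main.shape != recovered.shape:
        raise InputError("mask shapes differ")
    pieces: list[tuple[np.ndarray, str]] = []
    for mask, tag in ((main, "main_ridge"), (recovered, "recovered_edge")):
        if not mask.any():
            continue
        skel = thin(mask)
        lab, n = ndi.label(skel, structure=_EIGHT)
        for idx in range(1, n + 1):
            pieces.append((lab == idx, tag))

    def priority(item: tuple[np.ndarray, str]) -> float:
        coords = np.argwhere(item[0])
        major, _ = _component_axes(coords)
        inten = float(img.pixels[coords[:, 0], coords[:, 1]].mean())
        return major * inten

    pieces.sort(key=priority, reverse=True)

    occupied = np.zeros(main.shape, dtype=bool)
    traces: list[Trace] = []
    for comp, tag in pieces:
        free = comp & ~occupied
        if not free.any():
            continue
        occupied |= free
        # losing a conflict pixel may split the component
        sub_lab, sn = ndi.label(free, structure=_EIGHT)
        for s in range(1, sn + 1):
            part = thin(sub_lab == s)
            if part.any():
                traces.append(_make_trace(np.argwhere(part), img, tag))

    if support is None:
        support = main | recovered
    return TraceSet(traces=tuple(traces), shape=main.shape, support=support)


# ---------------------------------------------------------------------------
# The full pipeline
# ---------------------------------------------------------------------------

def trace_ridges(
    img: GrayImage, cfg: TraceRidgesConfig | None = None
) -> TraceSet:
    """Run the full tracing pipeline on a normalised 2-D image.

    Stages: watershed ridge lines, Canny edges, overlap breaking of
    minor ridges, small-segment removal, dark-segment removal,
    double-ridge repair, missed-ridge recovery, and priority fusion.
    Deterministic for fixed input and configuration.
    """
    cfg = cfg or TraceRidgesConfig()
    if img.height < 8 or img.width < 8:
        raise InputError("tracing requires images of at least 8x8 pixels")
    img = img.normalised()

    ridges = watershed_ridge_lines(img)
    if not ridges.any():
        log.warning("no ridges found: returning empty trace set")
        return TraceSet(traces=(), shape=img.shape,
                        support=np.zeros(img.shape, dtype=bool))

    edges = canny_edges(img, cfg.canny_sigma, cfg.canny_low, cfg.canny_high)
    broken = break_minor_ridges(ridges, edges)
    sized = remove_small_segments(broken, cfg.min_segment_major_axis)
    bright = remove_dark_segments(sized, img, cfg)
    repaired = repair_double_ridges(bright, cfg)
    recovered = recover_missed_ridges(edges, repaired, img, cfg)
    return fuse(repaired, recovered, img, support=repaired | recovered)
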