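"""Image I/O, grayscale conversion, projection and pre-filtering.

All tracing operates on a :class:`GrayImage`: a 2-D float array normalised
to [0, 1].  Three-dimensional stacks are collapsed to 2-D with a maximum
intensity projection before tracing.  Pre-filtering is either a small
Gaussian low-pass (3x3 kernel by default) or a user-registered denoiser
plug-in; both are optional.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal

import imageio.v3 as iio
import numpy as np
import tifffile
from scipy import ndimage as ndi

__all__ = [
    "GrayImage",
    "VolumeImage",
    "FilterSpec",
    "FormatError",
    "InputError",
    "ConfigError",
    "load_image",
    "save_image",
    "max_intensity_project",
    "gaussian_prefilter",
    "apply_denoiser",
    "register_denoiser",
    "prefilter",
]

# ITU-R BT.601 luminance weights for RGB -> gray.
_LUMA = np.array([0.299, 0.587, 0.114])


class FormatError(ValueError):
    """Raised when a file cannot be read as an image."""


class InputError(ValueError):
    """Raised when image data violates a precondition."""


class ConfigError(ValueError):
    """Raised for invalid filter or tracing configuration."""


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale image with intensities in [0, 1].

    Parameters
    ----------
    pixels:
        2-D float array.  Values must be finite; ``normalise`` rescales
        them to [0, 1].
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise InputError(f"GrayImage requires a 2-D array, got shape {px.shape}")
        if px.size == 0:
            raise InputError("GrayImage cannot be empty")
        if not np.all(np.isfinite(px)):
            raise InputError("GrayImage contains non-finite values")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def normalised(self) -> "GrayImage":
        """Min-max rescale to [0, 1]; constant images map to zeros."""
        px = self.pixels
        lo, hi = float(px.min()), float(px.max())
        if hi - lo == 0.0:
            return GrayImage(np.zeros_like(px))
        return GrayImage((px - lo) / (hi - lo))


@dataclass(frozen=True)
class VolumeImage:
    """An ordered stack of equally shaped grayscale slices."""

    slices: tuple[GrayImage, ...]

    def __post_init__(self) -> None:
        if len(self.slices) < 1:
            raise InputError("VolumeImage requires at least one slice")
        shapes = {s.shape for s in self.slices}
        if len(shapes) != 1:
            raise InputError(f"VolumeImage slices differ in shape: {shapes}")

    @property
    def depth(self) -> int:
        return len(self.slices)

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices[0].shape


@dataclass(frozen=True)
class FilterSpec:
    """Pre-filter configuration.

    mode ``none`` passes the image through, ``gaussian`` applies a small
    normalised Gaussian kernel (default 3x3, sigma 0.5 px) and ``plugin``
    dispatches to a registered denoiser.
    """

    mode: Literal["none", "gaussian", "plugin"] = "none"
    gaussian_kernel: int = 3
    gaussian_sigma: float = 0.5
    plugin_name: str | None = None
    border: str = "reflect"

    def __post_init__(self) -> None:
        if self.mode not in ("none", "gaussian", "plugin"):
            raise ConfigError(f"unknown filter mode {self.mode!r}")
        if self.gaussian_kernel % 2 == 0 or self.gaussian_kernel < 3:
            raise ConfigError("gaussian_kernel must be odd and >= 3")
        if self.gaussian_sigma <= 0:
            raise ConfigError("gaussian_sigma must be positive")
        if self.mode == "plugin" and not self.plugin_name:
            raise ConfigError("plugin mode requires plugin_name")


def _to_unit_float(arr: np.ndarray) -> np.ndarray:
    """Convert an integer or float image array to float in [0, 1].

    Integer arrays are divided by their maximum value so the brightest
    recorded pixel maps to 1.0 regardless of bit depth headroom.
    """
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        arr = arr[..., :3] @ _LUMA
    arr = arr.astype(float)
    mx = arr.max() if arr.size else 0.0
    if mx > 0:
        arr = arr / mx
    return np.clip(arr, 0.0, 1.0)


def load_image(path: str | Path) -> GrayImage | VolumeImage:
    """Read a TIFF or PNG file as a grayscale image or volume.

    RGB data is converted to luminance; integer intensities are rescaled
    to [0, 1] by the image maximum.  Multi-page TIFFs return a
    :class:`VolumeImage` with one slice per page.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            pages = tifffile.imread(path)
        else:
            pages = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - wrap any reader failure
        raise FormatError(f"cannot read {path}: {exc}") from exc
    pages = np.asarray(pages)
    if pages.size == 0:
        raise InputError(f"zero-sized image: {path}")
    # A 3-D array is a stack unless the last axis is an RGB(A) channel axis.
    if pages.ndim == 3 and pages.shape[-1] not in (3, 4):
        return VolumeImage(tuple(GrayImage(_to_unit_float(p)) for p in pages))
    if pages.ndim == 4:  # multi-page RGB
        return VolumeImage(tuple(GrayImage(_to_unit_float(p)) for p in pages))
    return GrayImage(_to_unit_float(pages))


def save_image(img: GrayImage, path: str | Path) -> None:
    """Write a GrayImage as 16-bit TIFF or PNG depending on the suffix."""
    path = Path(path)
    data = np.clip(img.pixels, 0.0, 1.0)
    u16 = np.round(data * 65535).astype(np.uint16)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, u16)
    else:
        iio.imwrite(path, u16)


def max_intensity_project(vol: VolumeImage) -> GrayImage:
    """Collapse a stack to 2-D by the per-pixel maximum across slices."""
    stack = np.stack([s.pixels for s in vol.slices])
    return GrayImage(stack.max(axis=0))


def _gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    """Normalised 2-D Gaussian kernel truncated to ``size`` x ``size``."""
    r = size // 2
    ax = np.arange(-r, r + 1, dtype=float)
    g1 = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g1, g1)
    return k / k.sum()


def gaussian_prefilter(img: GrayImage, spec: FilterSpec) -> GrayImage:
    """Low-pass filter with a normalised truncated Gaussian kernel.

    The kernel integrates to one so constant regions are preserved;
    borders use reflective padding by default.
    """
    if spec.mode != "gaussian":
        raise ConfigError("gaussian_prefilter requires FilterSpec(mode='gaussian')")
    k = _gaussian_kernel(spec.gaussian_kernel, spec.gaussian_sigma)
    out = ndi.convolve(img.pixels, k, mode=spec.border)
    return GrayImage(np.clip(out, 0.0, 1.0))


# Registry of denoiser plug-ins: name -> callable(GrayImage) -> GrayImage.
_DENOISERS: dict[str, Callable[[GrayImage], GrayImage]] = {}


def register_denoiser(name: str, fn: Callable[[GrayImage], GrayImage]) -> None:
    """Register a denoiser plug-in under ``name``.

    The callable must map a GrayImage to a GrayImage of identical shape;
    this is how learned denoisers are slotted into the pipeline without
    the package depending on any particular model.
    """
    _DENOISERS[name] = fn


def apply_denoiser(img: GrayImage, plugin_name: str) -> GrayImage:
    """Run a registered denoiser plug-in; output is clipped to [0, 1]."""
    try:
        fn = _DENOISERS[plugin_name]
    except KeyError:
        raise ConfigError(f"no denoiser registered under {plugin_name!r}") from None
    out = fn(img)
    if not isinstance(out, GrayImage):
        out = GrayImage(np.asarray(out, dtype=float))
    if out.shape != img.shape:
        raise InputError(
            f"denoiser {plugin_name!r} changed shape {img.shape} -> {out.shape}"
        )
    return GrayImage(np.clip(out.pixels, 0.0, 1.0))


def prefilter(img: GrayImage, spec: FilterSpec) -> GrayImage:
    """Dispatch on FilterSpec.mode: none, gaussian or plugin."""
    if spec.mode == "none":
        return img
    if spec.mode == "gaussian":
        return gaussian_prefilter(img, spec)
    return apply_denoiser(img, spec.plugin_name)


def _identity(img: GrayImage) -> GrayImage:
    return img


def _median3(img: GrayImage) -> GrayImage:
    return GrayImage(ndi.median_filter(img.pixels, size=3, mode="reflect"))


register_denoiser("identity", _identity)
register_denoiser("median3", _median3)
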