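"""Reading, writing and basic screening of strip images.

A lateral-flow strip photographed through an emission filter is a
single-channel capture; colour files therefore have to be collapsed to one
analysis channel before quantification.  This module wraps imageio/tifffile
behind a small :class:`RasterImage` container that tracks bit depth and
channel identity, and flags detector saturation (pixels pinned at the
maximum representable value), which produces flat-topped band profiles and
biased AUCs downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import ImageFormatError, ImageReadError, UsageError

logger = logging.getLogger(__name__)

CHANNEL_LABELS = ("green", "red", "gray")

#: RGB -> channel collapse rules accepted by :func:`load_image`.
CHANNEL_RULES = ("select_red", "select_green", "select_blue", "luminance",
                 "native_gray")

# ITU-R BT.601 luma coefficients, fixed for reproducibility.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

#: Default fraction of saturated pixels above which an image is flagged.
SATURATION_FRACTION_THRESHOLD = 0.001


@dataclass(frozen=True)
class RasterImage:
    """One channel's strip photograph as an integer pixel matrix.

    Parameters
    ----------
    pixels
        2-D array of non-negative integers, row 0 at the top.  The flow
        axis of the strip runs along the rows (top to bottom).
    bit_depth
        8 or 16; every pixel must be ``<= 2**bit_depth - 1``.
    channel_label
        ``"green"``, ``"red"`` or ``"gray"`` — which emission channel the
        capture represents.
    source_id
        File path or simulator tag identifying where the pixels came from.
    """

    pixels: np.ndarray
    bit_depth: int
    channel_label: str = "gray"
    source_id: str = ""

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise UsageError(
                f"pixels must be a 2-D matrix with at least one row and "
                f"column, got shape {px.shape}")
        if self.bit_depth not in (8, 16):
            raise ImageFormatError(
                f"bit depth must be 8 or 16, got {self.bit_depth}")
        if self.channel_label not in CHANNEL_LABELS:
            raise UsageError(
                f"channel_label must be one of {CHANNEL_LABELS}, "
                f"got {self.channel_label!r}")
        if not np.issubdtype(px.dtype, np.integer):
            raise ImageFormatError(
                f"pixels must be integers, got dtype {px.dtype}")
        if px.min() < 0 or px.max() > self.max_value:
            raise ImageFormatError(
                f"pixel values must lie in [0, {self.max_value}] for "
                f"bit depth {self.bit_depth}")
        object.__setattr__(self, "pixels", px)

    @property
    def max_value(self) -> int:
        """Largest representable pixel value (``2**bit_depth - 1``)."""
        return 2 ** self.bit_depth - 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, *,
                    source_suffix: str = "") -> "RasterImage":
        """Copy of this image with new pixels (same depth and channel)."""
        return replace(self, pixels=pixels,
                       source_id=self.source_id + source_suffix)


def _bit_depth_from_dtype(dtype: np.dtype, path: Path) -> int:
    if dtype == np.uint8:
        return 8
    if dtype == np.uint16:
        return 16
    raise ImageFormatError(
        f"{path}: unsupported pixel type {dtype}; only 8- and 16-bit "
        f"integer images are handled")


def luminance(rgb: np.ndarray) -> np.ndarray:
    """Integer BT.601 luminance of an ``(H, W, 3)`` array.

    Weights 0.299/0.587/0.114, rounded to the nearest integer, so the
    result stays within ``[min(R,G,B), max(R,G,B)]`` per pixel.
    """
    y = np.tensordot(rgb.astype(np.float64), _LUMA_WEIGHTS, axes=([-1], [0]))
    return np.rint(y).astype(rgb.dtype)


def load_image(path: str | Path, channel_rule: str = "native_gray",
               channel_label: str | None = None) -> RasterImage:
    """Read a PNG/TIFF (or JPEG, with a warning) strip image.

    ``channel_rule`` collapses RGB input to one plane: ``select_red`` /
    ``select_green`` / ``select_blue`` pick a channel, ``luminance``
    computes the BT.601 weighted sum, and ``native_gray`` asserts the file
    is already single-channel.  ``channel_label`` defaults to the colour
    implied by the rule (``select_green`` → green, ``select_red`` → red,
    otherwise gray).
    """
    path = Path(path)
    if channel_rule not in CHANNEL_RULES:
        raise UsageError(
            f"channel_rule must be one of {CHANNEL_RULES}, "
            f"got {channel_rule!r}")
    if not path.exists():
        raise ImageReadError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    if suffix in (".jpg", ".jpeg"):
        logger.warning(
            "%s: JPEG is lossy; compression artifacts can bias band AUCs. "
            "Prefer PNG or TIFF captures.", path)
    try:
        if suffix in (".tif", ".tiff"):
            raw = tifffile.imread(path)
        else:
            raw = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - normalise reader errors
        raise ImageReadError(f"could not read image {path}: {exc}") from exc

    raw = np.asarray(raw)
    if raw.dtype == bool or np.issubdtype(raw.dtype, np.floating):
        raise ImageFormatError(
            f"{path}: unsupported pixel type {raw.dtype}; only 8- and "
            f"16-bit integer images are handled")
    bit_depth = _bit_depth_from_dtype(raw.dtype, path)

    if raw.ndim == 3 and raw.shape[-1] == 4:
        logger.warning("%s: dropping alpha channel", path)
        raw = raw[..., :3]

    if raw.ndim == 2:
        plane = raw
        if channel_label is None:
            channel_label = "gray"
    elif raw.ndim == 3 and raw.shape[-1] == 3:
        if channel_rule == "native_gray":
            raise UsageError(
                f"{path} is RGB; channel_rule='native_gray' only applies "
                f"to grayscale files")
        if channel_rule == "luminance":
            plane = luminance(raw)
        else:
            idx = {"select_red": 0, "select_green": 1, "select_blue": 2}
            plane = raw[..., idx[channel_rule]]
        if channel_label is None:
            channel_label = {"select_green": "green",
                             "select_red": "red"}.get(channel_rule, "gray")
    else:
        raise ImageFormatError(
            f"{path}: unsupported image layout with shape {raw.shape}")

    return RasterImage(pixels=plane, bit_depth=bit_depth,
                       channel_label=channel_label, source_id=str(path))


def save_image(image: RasterImage, path: str | Path) -> Path:
    """Write a grayscale image; the file suffix selects PNG or TIFF."""
    path = Path(path)
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    px = image.pixels.astype(dtype)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, px)
    elif suffix == ".png":
        iio.imwrite(path, px)
    else:
        raise UsageError(
            f"unsupported output format {suffix!r}; use .png or .tif(f)")
    return path


def detect_saturation(image: RasterImage,
                      threshold: float = SATURATION_FRACTION_THRESHOLD,
                      ) -> tuple[float, bool]:
    """Fraction of pixels pinned at the detector maximum, plus a flag.

    The flag is true iff the fraction strictly exceeds ``threshold``
    (default 0.1% of pixels).  Saturated captures produce flat-topped
    band peaks whose AUC under-reports the true signal.
    """
    saturated = np.count_nonzero(image.pixels == image.max_value)
    fraction = saturated / image.pixels.size
    return float(fraction), bool(fraction > threshold)
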