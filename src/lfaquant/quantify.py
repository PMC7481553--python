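"""Densitometric quantification of strip images.

The pipeline is: crop the batch photograph, split it into equal-width
lanes (one per strip), reduce each lane to a flow-axis intensity profile
(mean intensity per row), locate up to six bands as the most prominent
profile peaks, and for each band compute a background-corrected AUC.  The
background is estimated locally per band by Otsu's threshold on the pixels
of the band window plus a flanking margin: pixels below the threshold are
membrane background, their mean is subtracted row-wise (floored at zero)
before summation.  Applying Otsu per band rather than per lane keeps a
bright control line from inflating the background estimate under a faint
test line.

Conventions: the flow axis is the image row axis (bands horizontal,
top→bottom); all geometry is 0-based with half-open intervals; AUC is the
plain sum of per-row mean intensities over the window (rectangle rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import (DegenerateInputError, DetectionError, GeometryError,
                     UsageError)
from .image_io import RasterImage

logger = logging.getLogger(__name__)

MAX_BANDS = 6  # LFAs in practice carry at most six lines

BAND_KINDS = ("test", "control", "unknown")

#: CSV column order for exported band measurements.
MEASUREMENT_COLUMNS = ["image_id", "lane_id", "band_index", "kind",
                       "channel", "raw_auc", "background_level",
                       "corrected_auc", "saturated"]


@dataclass(frozen=True)
class CropRegion:
    """Axis-aligned rectangle, 0-based, half-open on both axes."""

    top: int
    left: int
    height: int
    width: int

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise UsageError(
                f"crop region must have positive size, got "
                f"{self.height}x{self.width}")


@dataclass(frozen=True)
class IntensityProfile:
    """Per-row mean intensity along the flow axis of one lane."""

    values: np.ndarray
    lane_id: str
    channel_label: str = "gray"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 1:
            raise UsageError("profile must be a non-empty 1-D sequence")
        if np.any(v < 0):
            raise UsageError("profile values must be non-negative")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class BandWindow:
    """Half-open row interval ``[start, end)`` covering one band."""

    start: int
    end: int
    band_index: int
    kind: str = "unknown"

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise UsageError(
                f"band window needs 0 <= start < end, got "
                f"[{self.start}, {self.end})")
        if not 1 <= self.band_index <= MAX_BANDS:
            raise UsageError(
                f"band_index must be 1..{MAX_BANDS}, got {self.band_index}")
        if self.kind not in BAND_KINDS:
            raise UsageError(f"kind must be one of {BAND_KINDS}")


@dataclass(frozen=True)
class BandMeasurement:
    """Background-corrected densitometric readout of one band."""

    lane_id: str
    band_index: int
    channel_label: str
    raw_auc: float
    background_level: float
    corrected_auc: float
    saturated: bool
    kind: str = "unknown"


def crop(image: RasterImage, region: CropRegion) -> RasterImage:
    """Extract ``region`` from ``image``; depth and channel are kept."""
    rows, cols = image.shape
    bottom = region.top + region.height
    right = region.left + region.width
    if region.top < 0 or region.left < 0 or bottom > rows or right > cols:
        raise GeometryError(
            f"crop region [{region.top},{bottom})x[{region.left},{right}) "
            f"falls outside image [0,{rows})x[0,{cols})")
    sub = image.pixels[region.top:bottom, region.left:right]
    return image.with_pixels(sub, source_suffix=f"[crop@{region.top},"
                             f"{region.left}+{region.height}x{region.width}]")


def split_lanes(image: RasterImage, n_lanes: int) -> list[RasterImage]:
    """Partition the image into ``n_lanes`` vertical equal-width lanes.

    When the width is not divisible, the leftmost ``width % n_lanes``
    lanes receive one extra column, so the lanes tile the input exactly.
    """
    rows, cols = image.shape
    if n_lanes < 1:
        raise UsageError(f"n_lanes must be >= 1, got {n_lanes}")
    if n_lanes > cols:
        raise UsageError(
            f"cannot split width {cols} into {n_lanes} lanes")
    base, extra = divmod(cols, n_lanes)
    lanes = []
    left = 0
    for i in range(n_lanes):
        w = base + (1 if i < extra else 0)
        lanes.append(image.with_pixels(
            image.pixels[:, left:left + w], source_suffix=f"[lane{i}]"))
        left += w
    return lanes


def lane_profile(lane: RasterImage, lane_id: str = "lane0"
                 ) -> IntensityProfile:
    """Mean pixel intensity of each row — the flow-axis profile."""
    return IntensityProfile(values=lane.pixels.mean(axis=1),
                            lane_id=lane_id,
                            channel_label=lane.channel_label)


def otsu_threshold(values: Sequence[int] | np.ndarray) -> int:
    """Otsu's threshold over the exact value histogram.

    Returns the integer ``t`` maximizing the between-class variance of the
    split background ``< t`` / foreground ``>= t``; ties are broken toward
    the smallest threshold.  Requires at least two distinct values.
    """
    v = np.asarray(values).ravel()
    if v.size == 0:
        raise DegenerateInputError("otsu_threshold: empty input")
    levels, counts = np.unique(v, return_counts=True)
    if levels.size < 2:
        raise DegenerateInputError(
            "otsu_threshold: all values identical; no threshold separates "
            "background from foreground")
    # Candidate thresholds are the observed levels above the minimum: the
    # split background < t vs foreground >= t is then always non-trivial.
    counts = counts.astype(np.float64)
    levels_f = levels.astype(np.float64)
    n = counts.sum()
    w0 = np.cumsum(counts)[:-1]            # mass strictly below levels[1:]
    m0 = np.cumsum(counts * levels_f)[:-1]  # first moment below levels[1:]
    w1 = n - w0
    mu0 = m0 / w0
    mu1 = (counts @ levels_f - m0) / w1
    between = w0 * w1 * (mu0 - mu1) ** 2   # ∝ between-class variance
    best = int(np.argmax(between))         # argmax takes the first maximum
    return int(levels[1:][best])


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with reflected edges (odd window)."""
    if window <= 1:
        return values.astype(float)
    pad = window // 2
    padded = np.pad(values.astype(float), pad, mode="reflect")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def locate_bands(profile: IntensityProfile, expected_n: int,
                 min_prominence: float = 0.0,
                 smoothing_window: int = 5,
                 boundary_fraction: float = 0.10,
                 control_band: str = "last") -> list[BandWindow]:
    """Find the ``expected_n`` most prominent bands in a lane profile.

    The profile is smoothed with a centred moving average (odd window,
    default 5 rows), local maxima are ranked by peak prominence, and each
    retained peak is grown outward until the smoothed profile drops below
    ``baseline + boundary_fraction * (peak - baseline)``.  The baseline
    under the peak is interpolated linearly between the two prominence
    bases — the band-local level even on a tilted membrane background —
    and growth never crosses the bases.  Windows are returned disjoint
    and sorted top→bottom; by default the bottom-most band is labelled
    ``control`` and the others ``test``.
    """
    if not 1 <= expected_n <= MAX_BANDS:
        raise UsageError(
            f"expected_n must be 1..{MAX_BANDS}, got {expected_n}")
    if smoothing_window % 2 == 0:
        raise UsageError("smoothing_window must be odd")
    if len(profile) <= smoothing_window:
        raise UsageError(
            f"profile of length {len(profile)} is too short for "
            f"smoothing window {smoothing_window}")

    smoothed = _moving_average(profile.values, smoothing_window)
    # prominence=0 keeps every local maximum but still computes the
    # prominences and bases used for ranking and window growth
    peaks, props = find_peaks(smoothed, prominence=max(min_prominence, 0.0))
    if peaks.size < expected_n:
        raise DetectionError(
            f"found {peaks.size} peak(s) above prominence "
            f"{min_prominence} at rows {peaks.tolist()}, "
            f"expected {expected_n}")
    # Most prominent first; equal prominence -> topmost retained first.
    order = np.lexsort((peaks, -props["prominences"]))
    chosen = np.sort(order[:expected_n])  # ascending row position

    windows: list[tuple[int, int, int]] = []
    for pos in chosen:
        peak = int(peaks[pos])
        lb = int(props["left_bases"][pos])
        rb = int(props["right_bases"][pos])
        # local baseline under the peak: linear interpolation between the
        # prominence bases, so a tilted membrane background (gradient)
        # yields the band-local level rather than the ramp's low end
        if rb > lb:
            background = smoothed[lb] + (smoothed[rb] - smoothed[lb]) \
                * (peak - lb) / (rb - lb)
        else:
            background = smoothed[lb]
        cut = background + boundary_fraction * (smoothed[peak] - background)
        # growth is clamped to the prominence bases so a rising membrane
        # background (gradient) cannot drag the window past the band
        start = peak
        while start > lb and smoothed[start - 1] >= cut:
            start -= 1
        end = peak + 1
        while end < min(rb + 1, smoothed.size) and smoothed[end] >= cut:
            end += 1
        windows.append((start, end, peak))

    # Enforce disjointness: clip overlapping neighbours at the midpoint
    # between their peaks.
    for i in range(len(windows) - 1):
        s0, e0, p0 = windows[i]
        s1, e1, p1 = windows[i + 1]
        if e0 > s1:
            mid = (p0 + p1 + 1) // 2
            windows[i] = (s0, max(mid, s0 + 1), p0)
            windows[i + 1] = (min(mid, e1 - 1), e1, p1)

    out = []
    for i, (start, end, _) in enumerate(windows):
        if control_band == "last":
            kind = "control" if i == len(windows) - 1 else "test"
        elif control_band == "first":
            kind = "control" if i == 0 else "test"
        else:
            kind = "unknown"
        out.append(BandWindow(start=start, end=end, band_index=i + 1,
                              kind=kind))
    return out


def measure_band(lane: RasterImage, window: BandWindow,
                 lane_id: str = "lane0",
                 margin_factor: float = 2.0,
                 background_stat: str = "median") -> BandMeasurement:
    """Otsu-background-corrected AUC of one band.

    The background is estimated from the pixels of the band window plus a
    flanking margin (``margin_factor`` × window length on each side,
    clipped to the lane): Otsu's threshold splits them and the median
    (default) or mean of the sub-threshold pixels is the local background
    level.  The median is preferred because the sub-threshold class still
    contains band tail pixels and, under noise, is truncated from above
    by the threshold — both of which bias the class mean while leaving
    its median at the membrane level.  The corrected AUC sums
    ``max(row_mean - background, 0)`` over the window; negative residuals
    are floored so noise cannot cancel a faint band.
    """
    if background_stat not in ("median", "mean"):
        raise UsageError("background_stat must be 'median' or 'mean'")
    rows = lane.shape[0]
    if window.end > rows:
        raise GeometryError(
            f"band window [{window.start},{window.end}) exceeds lane "
            f"height {rows}")
    margin = int(round(margin_factor * (window.end - window.start)))
    ctx_start = max(0, window.start - margin)
    ctx_end = min(rows, window.end + margin)
    context = lane.pixels[ctx_start:ctx_end]

    try:
        threshold = otsu_threshold(context)
        below = context[context < threshold]
        # With foreground >= t the background class is always non-empty.
        background = float(np.median(below) if background_stat == "median"
                           else below.mean())
    except DegenerateInputError:
        logger.warning(
            "%s band %d: context pixels all identical; treating the whole "
            "window as background", lane_id, window.band_index)
        background = float(context.mean())

    profile = lane.pixels[window.start:window.end].mean(axis=1)
    raw_auc = float(profile.sum())
    corrected = float(np.maximum(profile - background, 0.0).sum())
    saturated = bool(
        (lane.pixels[window.start:window.end] == lane.max_value).any())
    return BandMeasurement(lane_id=lane_id, band_index=window.band_index,
                           channel_label=lane.channel_label,
                           raw_auc=raw_auc, background_level=background,
                           corrected_auc=corrected, saturated=saturated,
                           kind=window.kind)


def quantify_lane(lane: RasterImage, expected_n: int,
                  lane_id: str = "lane0", **locate_kwargs
                  ) -> list[BandMeasurement]:
    """Profile → band location → per-band measurement for one lane."""
    profile = lane_profile(lane, lane_id=lane_id)
    windows = locate_bands(profile, expected_n, **locate_kwargs)
    return [measure_band(lane, w, lane_id=lane_id) for w in windows]


def consensus_windows(profiles: Sequence[IntensityProfile],
                      expected_n: int, **locate_kwargs) -> list[BandWindow]:
    """Band windows from the mean profile of aligned lanes.

    Strips of one batch are well aligned, so averaging the flow-axis
    profiles across lanes before peak detection makes band location
    robust for lanes where a band is faint or absent (blanks): the
    calibrant lanes dominate the mean profile and pin the windows.
    """
    lengths = {len(p) for p in profiles}
    if len(lengths) != 1:
        raise UsageError(
            f"consensus windows need equally long profiles, got lengths "
            f"{sorted(lengths)}")
    mean = np.mean([p.values for p in profiles], axis=0)
    pooled = IntensityProfile(values=mean, lane_id="consensus",
                              channel_label=profiles[0].channel_label)
    return locate_bands(pooled, expected_n, **locate_kwargs)


def _measurement_row(image_id: str, m: BandMeasurement) -> dict:
    if m.saturated:
        logger.warning(
            "%s %s band %d: saturated pixels inside the band window; "
            "AUC is biased low (flat-topped peak)",
            image_id, m.lane_id, m.band_index)
    return {"image_id": image_id, "lane_id": m.lane_id,
            "band_index": m.band_index, "kind": m.kind,
            "channel": m.channel_label, "raw_auc": m.raw_auc,
            "background_level": m.background_level,
            "corrected_auc": m.corrected_auc, "saturated": m.saturated}


def quantify_batch(images: Sequence[tuple[str, RasterImage]],
                   n_lanes: int, expected_n: int,
                   region: CropRegion | None = None,
                   band_location: str = "consensus",
                   **locate_kwargs) -> pd.DataFrame:
    """Quantify a batch of aligned images, one row per band.

    ``band_location="consensus"`` (default) pools the flow-axis profiles
    of all lanes of one channel, locates the bands once on the mean
    profile, and measures every lane at those shared windows;
    ``"per_lane"`` detects bands independently in each lane.
    """
    if band_location not in ("consensus", "per_lane"):
        raise UsageError("band_location must be 'consensus' or 'per_lane'")
    lanes: list[tuple[str, str, RasterImage]] = []
    for image_id, image in images:
        if region is not None:
            image = crop(image, region)
        for i, lane in enumerate(split_lanes(image, n_lanes)):
            lanes.append((image_id, f"lane{i}", lane))

    rows = []
    if band_location == "per_lane":
        for image_id, lane_id, lane in lanes:
            for m in quantify_lane(lane, expected_n, lane_id=lane_id,
                                   **locate_kwargs):
                rows.append(_measurement_row(image_id, m))
    else:
        by_channel: dict[str, list[tuple[str, str, RasterImage]]] = {}
        for entry in lanes:
            by_channel.setdefault(entry[2].channel_label, []).append(entry)
        for channel, entries in by_channel.items():
            profiles = [lane_profile(lane, lane_id=lane_id)
                        for _, lane_id, lane in entries]
            windows = consensus_windows(profiles, expected_n,
                                        **locate_kwargs)
            for image_id, lane_id, lane in entries:
                for w in windows:
                    m = measure_band(lane, w, lane_id=lane_id)
                    rows.append(_measurement_row(image_id, m))
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def quantify_image(image: RasterImage, n_lanes: int, expected_n: int,
                   image_id: str | None = None,
                   region: CropRegion | None = None,
                   band_location: str = "consensus",
                   **locate_kwargs) -> pd.DataFrame:
    """Quantify every lane of one (optionally cropped) batch image.

    Returns a tidy frame with one row per band in the exported CSV schema
    (:data:`MEASUREMENT_COLUMNS`).  See :func:`quantify_batch` for the
    ``band_location`` strategies.
    """
    if image_id is None:
        image_id = image.source_id
    return quantify_batch([(image_id, image)], n_lanes, expected_n,
                          region=region, band_location=band_location,
                          **locate_kwargs)


def write_measurements(frame: pd.DataFrame, path) -> None:
    """Write band measurements as UTF-8 CSV with a header row."""
    frame.to_csv(path, index=False, columns=MEASUREMENT_COLUMNS)
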