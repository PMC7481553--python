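"""Ground-truthed synthetic strip images.

Emulates emission-filtered captures of lateral-flow strips: horizontal
bands modelled as Gaussian stripes along the flow axis (uniform across the
strip width), membrane background with an optional linear gradient,
additive Gaussian read noise, optional optical blur, and optional
saturation clipping at the detector maximum.  A duplex experiment pairs a
green and a red capture of each strip: one analyte reads out per channel,
the shared test line's amplitude follows the analyte's response function,
and the control line has a fixed amplitude.

The generator is fully deterministic: a master seed yields per-capture
seeds (``master + 2*strip_index`` for green, ``+1`` for red), so the two
photographs of one strip carry independent but reproducible noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import PixelRangeError, UsageError
from .image_io import RasterImage, save_image
from .quantify import MAX_BANDS, BandWindow

#: Window half-width, in units of band sigma, used for ground-truth windows.
TRUTH_WINDOW_SIGMAS = 4.0


@dataclass(frozen=True)
class StripSpec:
    """Geometry and imaging model of one synthetic strip capture.

    Defaults give a compact 8-bit strip (120 rows of 24 px) with a test
    line at row 40 and a control line at row 90, low membrane background
    and mild read noise; experiment presets override depth and levels.
    """

    height_px: int = 120
    width_px: int = 24
    bit_depth: int = 8
    band_centers: tuple[int, ...] = (40, 90)
    band_sigma_px: float = 3.0
    background_level: float = 20.0
    background_gradient: float = 0.0
    noise_sd: float = 2.0
    blur_sigma_px: float = 0.0
    clip_saturation: bool = False

    def __post_init__(self):
        if self.height_px < 1 or self.width_px < 1:
            raise UsageError("strip must be at least 1x1 pixels")
        if self.bit_depth not in (8, 16):
            raise UsageError("bit_depth must be 8 or 16")
        centers = tuple(int(c) for c in self.band_centers)
        if len(centers) > MAX_BANDS:
            raise UsageError(f"at most {MAX_BANDS} bands per strip")
        if any(not 0 <= c < self.height_px for c in centers):
            raise UsageError("band centers must lie inside the strip")
        if any(b - a <= 0 for a, b in zip(centers, centers[1:])):
            raise UsageError("band centers must be strictly increasing")
        if self.band_sigma_px <= 0:
            raise UsageError("band_sigma_px must be positive")
        if self.background_level < 0 or self.noise_sd < 0 \
                or self.blur_sigma_px < 0:
            raise UsageError("background, noise and blur must be >= 0")
        top = self.background_level
        bottom = self.background_level \
            + self.background_gradient * (self.height_px - 1)
        if min(top, bottom) < 0 or max(top, bottom) > 2 ** self.bit_depth - 1:
            raise UsageError("background ramp leaves the representable "
                             "pixel range")
        object.__setattr__(self, "band_centers", centers)

    @property
    def max_value(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass(frozen=True)
class StripTruth:
    """Ground truth attached to one generated capture."""

    windows: tuple[BandWindow, ...]
    centers: tuple[int, ...]
    amplitudes: tuple[float, ...]
    band_sigma_px: float
    background_level: float
    background_gradient: float
    noise_sd: float
    seed: int

    def expected_corrected_auc(self, band: int) -> float:
        """Analytic background-free AUC of band ``band`` (0-based): the
        Gaussian profile summed over all rows of the strip."""
        c = self.centers[band]
        w = self.windows[band]
        # Sum over a generous window; outside ±4σ the tail contributes
        # < 0.01% and matches what quantification can recover.
        rows = np.arange(w.start, w.end)
        return float(self.amplitudes[band] * np.exp(
            -((rows - c) ** 2) / (2 * self.band_sigma_px ** 2)).sum())


def _truth_windows(spec: StripSpec, kinds: Sequence[str]
                   ) -> tuple[BandWindow, ...]:
    half = int(round(TRUTH_WINDOW_SIGMAS * spec.band_sigma_px))
    windows = []
    for i, c in enumerate(spec.band_centers):
        start = max(0, c - half)
        end = min(spec.height_px, c + half + 1)
        windows.append(BandWindow(start=start, end=end, band_index=i + 1,
                                  kind=kinds[i]))
    return tuple(windows)


def generate_strip(spec: StripSpec, band_amplitudes: Sequence[float],
                   seed: int, channel_label: str = "gray",
                   source_id: str | None = None
                   ) -> tuple[RasterImage, StripTruth]:
    """Render one strip capture and its ground truth.

    The noise-free signal at row ``r`` is ``background + gradient*r +
    Σ_i amplitude_i * exp(-(r - center_i)² / (2σ²))``, uniform across
    columns; optional Gaussian blur is applied before seeded Gaussian
    noise.  Pixels are rounded to integers; values below 0 are floored;
    values above the representable maximum are clipped when
    ``clip_saturation`` is set and raise :class:`PixelRangeError`
    otherwise.  Identical (spec, amplitudes, seed) give a bit-identical
    image.
    """
    amplitudes = tuple(float(a) for a in band_amplitudes)
    if len(amplitudes) != len(spec.band_centers):
        raise UsageError(
            f"{len(amplitudes)} amplitudes for {len(spec.band_centers)} "
            f"band centers")
    if any(a < 0 for a in amplitudes):
        raise UsageError("band amplitudes must be >= 0")

    rows = np.arange(spec.height_px, dtype=float)
    profile = spec.background_level + spec.background_gradient * rows
    for c, a in zip(spec.band_centers, amplitudes):
        profile = profile + a * np.exp(
            -((rows - c) ** 2) / (2 * spec.band_sigma_px ** 2))
    signal = np.tile(profile[:, None], (1, spec.width_px))
    if spec.blur_sigma_px > 0:
        signal = gaussian_filter(signal, spec.blur_sigma_px, mode="nearest")
    rng = np.random.default_rng(seed)
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0.0, spec.noise_sd, signal.shape)
    pixels = np.rint(signal)
    if pixels.max() > spec.max_value:
        if spec.clip_saturation:
            pixels = np.minimum(pixels, spec.max_value)
        else:
            raise PixelRangeError(
                f"signal peaks at {pixels.max():.0f} > representable "
                f"maximum {spec.max_value}; enable clip_saturation to "
                f"emulate an oversaturated capture")
    pixels = np.maximum(pixels, 0)
    dtype = np.uint8 if spec.bit_depth == 8 else np.uint16
    kinds = ["test"] * len(spec.band_centers)
    if kinds:
        kinds[-1] = "control"
    image = RasterImage(
        pixels=pixels.astype(dtype), bit_depth=spec.bit_depth,
        channel_label=channel_label,
        source_id=source_id or f"synthetic:seed={seed}")
    truth = StripTruth(windows=_truth_windows(spec, kinds),
                       centers=spec.band_centers, amplitudes=amplitudes,
                       band_sigma_px=spec.band_sigma_px,
                       background_level=spec.background_level,
                       background_gradient=spec.background_gradient,
                       noise_sd=spec.noise_sd, seed=seed)
    return image, truth


def saturate(image: RasterImage, ceiling: int) -> RasterImage:
    """Clip every pixel at ``ceiling`` — a flat-topped, oversaturated
    capture when the ceiling sits below the band peaks."""
    if not 0 < ceiling <= image.max_value:
        raise UsageError(
            f"ceiling must lie in (0, {image.max_value}], got {ceiling}")
    return image.with_pixels(np.minimum(image.pixels, ceiling),
                             source_suffix=f"[sat@{ceiling}]")


# --------------------------------------------------------------------------
# Response functions and duplex experiment designs


@dataclass(frozen=True)
class LinearResponse:
    """Test-line amplitude proportional to concentration."""

    slope: float

    def __call__(self, concentration: float) -> float:
        return self.slope * concentration


@dataclass(frozen=True)
class LangmuirResponse:
    """Saturating binding-isotherm response ``amax·c / (k_half + c)``."""

    amax: float
    k_half: float

    def __call__(self, concentration: float) -> float:
        return self.amax * concentration / (self.k_half + concentration)


@dataclass(frozen=True)
class AnalyteSpec:
    """One analyte of a duplex design: name, calibration levels with a
    unit, response function, and the channel it reads out in."""

    name: str
    concentrations: tuple[float, ...]
    unit: str
    response: Callable[[float], float]
    channel: str

    def __post_init__(self):
        conc = tuple(float(c) for c in self.concentrations)
        if not conc:
            raise UsageError(f"{self.name}: concentration list is empty")
        if any(c < 0 for c in conc):
            raise UsageError(f"{self.name}: concentrations must be >= 0")
        object.__setattr__(self, "concentrations", conc)


@dataclass(frozen=True)
class DuplexDesign:
    """A full two-channel calibration experiment.

    Strip ``i`` of level ``l`` carries ``analyte_a.concentrations[l]``
    and ``analyte_b.concentrations[l]`` simultaneously; the two lists
    must be equally long.  ``crosstalk`` is the fraction of the other
    channel's test-line amplitude leaking into a capture (0 = perfectly
    separated emission filters).
    """

    analyte_a: AnalyteSpec
    analyte_b: AnalyteSpec
    control_amplitude: float
    replicates: int
    strip_spec: StripSpec
    crosstalk: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise UsageError("replicates must be >= 1")
        if not 0 <= self.crosstalk <= 1:
            raise UsageError("crosstalk must lie in [0, 1]")
        if self.control_amplitude <= 0:
            raise UsageError("control_amplitude must be positive")
        if len(self.analyte_a.concentrations) \
                != len(self.analyte_b.concentrations):
            raise UsageError(
                "duplex analytes need concentration lists of equal "
                "length (levels are paired per strip)")
        if len(self.strip_spec.band_centers) != 2:
            raise UsageError(
                "duplex strips carry exactly one test and one control "
                "band")

    @property
    def n_levels(self) -> int:
        return len(self.analyte_a.concentrations)

    @property
    def n_strips(self) -> int:
        return self.n_levels * self.replicates


@dataclass(frozen=True)
class SimulatedStrip:
    """One strip of a duplex experiment: both captures plus truths."""

    strip_index: int
    image_id: str
    level: int
    replicate: int
    green: RasterImage
    red: RasterImage
    green_truth: StripTruth
    red_truth: StripTruth


@dataclass(frozen=True)
class SimulatedExperiment:
    """All captures of a duplex design plus design/truth tables in the
    calibration module's CSV schema."""

    design: DuplexDesign
    strips: tuple[SimulatedStrip, ...]
    design_table: pd.DataFrame
    truth_table: pd.DataFrame


def generate_duplex_experiment(design: DuplexDesign) -> SimulatedExperiment:
    """Render every strip (levels × replicates) of a duplex design.

    Each strip yields a green and a red capture with independent,
    seed-derived noise; the test-line amplitude in a channel is that
    channel's response at its analyte's concentration plus
    ``crosstalk`` times the other channel's response.
    """
    a, b = design.analyte_a, design.analyte_b
    strips = []
    design_rows = []
    truth_rows = []
    strip_index = 0
    for level in range(design.n_levels):
        ca = a.concentrations[level]
        cb = b.concentrations[level]
        amp_a = a.response(ca)
        amp_b = b.response(cb)
        for rep in range(design.replicates):
            image_id = f"strip{strip_index:03d}"
            seed_g = design.seed + 2 * strip_index
            seed_r = design.seed + 2 * strip_index + 1
            test_g = amp_a + design.crosstalk * amp_b
            test_r = amp_b + design.crosstalk * amp_a
            green, truth_g = generate_strip(
                design.strip_spec, [test_g, design.control_amplitude],
                seed_g, channel_label=a.channel,
                source_id=f"synthetic:{image_id}:{a.channel}")
            red, truth_r = generate_strip(
                design.strip_spec, [test_r, design.control_amplitude],
                seed_r, channel_label=b.channel,
                source_id=f"synthetic:{image_id}:{b.channel}")
            strips.append(SimulatedStrip(
                strip_index=strip_index, image_id=image_id, level=level,
                replicate=rep, green=green, red=red,
                green_truth=truth_g, red_truth=truth_r))
            for spec_, conc, truth in ((a, ca, truth_g), (b, cb, truth_r)):
                design_rows.append({
                    "image_id": image_id, "lane_id": "lane0",
                    "channel": spec_.channel, "analyte": spec_.name,
                    "concentration": conc, "unit": spec_.unit,
                    "replicate_group": f"{spec_.name}_L{level}",
                    "role": "blank" if conc == 0 else "calibrant"})
                for w, amp in zip(truth.windows, truth.amplitudes):
                    truth_rows.append({
                        "image_id": image_id, "lane_id": "lane0",
                        "channel": spec_.channel, "band_index": w.band_index,
                        "kind": w.kind, "center": truth.centers[
                            w.band_index - 1],
                        "amplitude": amp,
                        "window_start": w.start, "window_end": w.end,
                        "background_level": truth.background_level,
                        "noise_sd": truth.noise_sd, "seed": truth.seed})
            strip_index += 1
    return SimulatedExperiment(
        design=design, strips=tuple(strips),
        design_table=pd.DataFrame(design_rows),
        truth_table=pd.DataFrame(truth_rows))


def write_experiment(experiment: SimulatedExperiment, out_dir: str | Path,
                     image_format: str = "tif") -> list[Path]:
    """Write captures, design.csv, truth.csv and a manifest to a
    directory; returns every path written (manifest last)."""
    if image_format not in ("tif", "png"):
        raise UsageError("image_format must be 'tif' or 'png'")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for strip in experiment.strips:
        for channel, image in (("green", strip.green), ("red", strip.red)):
            path = out_dir / f"{strip.image_id}_{channel}.{image_format}"
            save_image(image, path)
            written.append(path)
    design_path = out_dir / "design.csv"
    experiment.design_table.to_csv(design_path, index=False)
    written.append(design_path)
    truth_path = out_dir / "truth.csv"
    experiment.truth_table.to_csv(truth_path, index=False)
    written.append(truth_path)
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps(
        {"artifacts": [p.name for p in written],
         "n_strips": experiment.design.n_strips,
         "seed": experiment.design.seed}, indent=2) + "\n")
    written.append(manifest)
    return written


# --------------------------------------------------------------------------
# Presets


def sandwich_preset(seed: int = 0, replicates: int = 3,
                    noise_fraction: float = 0.02,
                    crosstalk: float = 0.0) -> DuplexDesign:
    """Equal-range duplex design: both analytes span 0–20 concentration
    units over 5 levels with linear responses, emulating a sandwich-format
    calibration where the two channels are developed at comparable
    intensities.  ``noise_fraction`` sets the read noise as a fraction of
    the largest test-line amplitude."""
    slope_a, slope_b = 8.0, 6.0
    levels = (0.0, 5.0, 10.0, 15.0, 20.0)
    max_amp = max(slope_a, slope_b) * max(levels)
    spec = StripSpec(bit_depth=16, background_level=200.0,
                     noise_sd=noise_fraction * max_amp)
    return DuplexDesign(
        analyte_a=AnalyteSpec("analyteA", levels, "nM",
                              LinearResponse(slope_a), "green"),
        analyte_b=AnalyteSpec("analyteB", levels, "nM",
                              LinearResponse(slope_b), "red"),
        control_amplitude=150.0, replicates=replicates,
        strip_spec=spec, crosstalk=crosstalk, seed=seed)


def clinical_preset(seed: int = 0, replicates: int = 3,
                    crosstalk: float = 0.0) -> DuplexDesign:
    """Clinically motivated duplex design: analyte A spans 0–1000 nM
    (CRP-like acute-phase range) in the green channel and analyte B spans
    0–60 pM (IL-6-like cytokine range) in the red channel, with
    saturating Langmuir responses."""
    levels_a = (0.0, 50.0, 100.0, 250.0, 500.0, 1000.0)
    levels_b = (0.0, 5.0, 15.0, 30.0, 45.0, 60.0)
    spec = StripSpec(bit_depth=16, background_level=300.0, noise_sd=25.0)
    return DuplexDesign(
        analyte_a=AnalyteSpec("CRP", levels_a, "nM",
                              LangmuirResponse(amax=3000.0, k_half=400.0),
                              "green"),
        analyte_b=AnalyteSpec("IL-6", levels_b, "pM",
                              LangmuirResponse(amax=2500.0, k_half=30.0),
                              "red"),
        control_amplitude=800.0, replicates=replicates,
        strip_spec=spec, crosstalk=crosstalk, seed=seed)
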