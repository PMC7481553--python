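"""Calibration analysis: join, replicate averaging, linear fits, limits.

Band AUCs become concentrations in three steps.  Measurements are joined
to the experiment design (analyte, concentration, replicate group, role)
on the key ``(image_id, lane_id, channel)``; technical replicates are
averaged; and an ordinary least squares line ``signal = intercept +
slope * concentration`` is fitted per analyte/channel on the replicate
means.  Assay sensitivity is summarised by the blank-based key measures

* LOB (limit of blank)          = mean_blank + 1.645 * sd_blank
* LOD (limit of detection)      = LOB + 1.645 * sd_low
* LOQ (limit of quantification) = mean_blank + 10 * sd_blank

computed in signal units and converted to concentration by inverse
prediction through the fitted line; ``sd_low`` is the standard deviation
of the lowest non-blank calibrant (falling back to the blank SD when
absent).  A limit that maps below zero concentration is reported as the
label ``"Negative"`` rather than a negative number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import (DegenerateDesignError, DegenerateFitError,
                     InsufficientDataError, IntegrityError, SchemaError,
                     TableParseError, UsageError)

logger = logging.getLogger(__name__)

NEGATIVE_LABEL = "Negative"

#: Identifier of the default LOB/LOD/LOQ formula set (see module docstring).
DEFAULT_DEFINITIONS_ID = "blank_1645_10sd"

JOIN_KEYS = ["image_id", "lane_id", "channel"]

DESIGN_COLUMNS = JOIN_KEYS + ["analyte", "concentration", "unit",
                              "replicate_group", "role"]

ROLES = ("calibrant", "blank", "unknown")

#: Synonyms accepted for the AUC column of externally produced tables.
_AUC_ALIASES = ("corrected_auc", "auc", "AUC", "intensity", "signal")


@dataclass(frozen=True)
class CalibrationFit:
    """Fitted line ``signal = intercept + slope * concentration``."""

    analyte: str
    channel_label: str
    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    n_points: int
    concentration_unit: str = ""
    slope_se: float = float("nan")

    def predict(self, concentration: float) -> float:
        """Forward prediction: expected signal at a concentration."""
        return self.intercept + self.slope * concentration


@dataclass(frozen=True)
class KeyMeasures:
    """LOB/LOD/LOQ in concentration units; ``"Negative"`` when a limit
    maps below zero concentration."""

    lob: float | str
    lod: float | str
    loq: float | str
    unit: str
    definitions_id: str = DEFAULT_DEFINITIONS_ID

    def as_dict(self) -> dict:
        return {"lob": self.lob, "lod": self.lod, "loq": self.loq,
                "unit": self.unit, "definitions_id": self.definitions_id}


def read_design(path: str | Path) -> pd.DataFrame:
    """Read and validate an experiment-design CSV.

    Schema: image_id, lane_id, channel, analyte, concentration, unit,
    replicate_group, role (calibrant/blank/unknown).  Keys must be unique,
    calibrants need finite concentrations, and blanks concentration 0.
    """
    design = pd.read_csv(path, dtype={"image_id": str, "lane_id": str})
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise SchemaError(
            f"design table {path} lacks mandatory column(s): "
            f"{', '.join(missing)}")
    bad_roles = set(design["role"]) - set(ROLES)
    if bad_roles:
        raise SchemaError(
            f"design table {path}: unknown role(s) {sorted(bad_roles)}")
    _check_design_integrity(design)
    return design


def _check_design_integrity(design: pd.DataFrame) -> None:
    dup = design.duplicated(subset=JOIN_KEYS)
    if dup.any():
        keys = design.loc[dup, JOIN_KEYS].to_records(index=False).tolist()
        raise IntegrityError(
            f"design contains duplicated (image_id, lane_id, channel) "
            f"key(s): {keys}")
    cal = design[design["role"] == "calibrant"]
    if not np.isfinite(cal["concentration"].to_numpy(dtype=float)).all():
        raise IntegrityError(
            "every calibrant row needs a finite concentration")
    blanks = design[design["role"] == "blank"]
    if (blanks["concentration"].to_numpy(dtype=float) != 0).any():
        raise IntegrityError("blank rows must have concentration 0")


def import_intensity_table(path: str | Path) -> pd.DataFrame:
    """Import an intensity CSV produced elsewhere (e.g. densitometry
    exports), normalising the AUC column name to ``corrected_auc``.

    Needs at least ``lane_id`` and one numeric AUC column; missing
    optional columns (image_id, channel, saturated, ...) are filled with
    defaults and logged.  A non-numeric AUC cell raises with its 1-based
    file line number (header = line 1).
    """
    table = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if "lane_id" not in table.columns:
        raise SchemaError(f"intensity table {path} lacks column 'lane_id'")
    auc_col = next((c for c in _AUC_ALIASES if c in table.columns), None)
    if auc_col is None:
        raise SchemaError(
            f"intensity table {path} lacks an AUC column (one of "
            f"{_AUC_ALIASES})")

    values = pd.to_numeric(table[auc_col], errors="coerce")
    bad = values.isna() & table[auc_col].notna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise TableParseError(
            f"{path} line {row + 2}: AUC value "
            f"{table[auc_col].iloc[row]!r} is not numeric", line=row + 2)
    out = pd.DataFrame({"lane_id": table["lane_id"],
                        "corrected_auc": values.astype(float)})
    for col, default in (("image_id", ""), ("channel", "gray"),
                         ("band_index", 1), ("kind", "unknown"),
                         ("saturated", False)):
        if col in table.columns:
            out[col] = table[col]
        else:
            logger.info("%s: column %r absent, filled with %r",
                        path, col, default)
            out[col] = default
    out["saturated"] = out["saturated"].map(
        lambda v: str(v).strip().lower() in ("true", "1", "yes"))
    out["band_index"] = pd.to_numeric(out["band_index"]).astype(int)
    return out


def merge_with_design(measurements: pd.DataFrame, design: pd.DataFrame,
                      ) -> tuple[pd.DataFrame, dict]:
    """Inner-join measurements to the design on (image, lane, channel).

    Returns the merged records and a reconciliation summary listing the
    keys left unmatched on either side; duplicated design keys raise.
    """
    _check_design_integrity(design)
    merged = measurements.merge(design, on=JOIN_KEYS, how="inner")
    mk = set(map(tuple, measurements[JOIN_KEYS].to_numpy()))
    dk = set(map(tuple, design[JOIN_KEYS].to_numpy()))
    summary = {"unmatched_measurements": sorted(mk - dk),
               "unmatched_design": sorted(dk - mk)}
    for side, keys in summary.items():
        if keys:
            logger.warning("merge_with_design: %d %s: %s",
                           len(keys), side.replace("_", " "), keys)
    return merged, summary


def average_replicates(records: pd.DataFrame) -> pd.DataFrame:
    """Mean and sample SD of corrected AUC per technical-replicate group.

    Groups are keyed by (analyte, channel, replicate_group); the SD uses
    the n−1 denominator and singleton groups get sd 0 with a flag.
    """
    required = ["analyte", "channel", "replicate_group", "concentration",
                "corrected_auc"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise SchemaError(
            f"records lack column(s) {', '.join(missing)}; merge with a "
            f"design table first")
    rows = []
    for (analyte, channel, group), sub in records.groupby(
            ["analyte", "channel", "replicate_group"], sort=True):
        conc = sub["concentration"].unique()
        if conc.size > 1:
            raise IntegrityError(
                f"replicate group {group!r} mixes concentrations "
                f"{conc.tolist()}")
        auc = sub["corrected_auc"].to_numpy(dtype=float)
        n = auc.size
        singleton = n == 1
        if singleton:
            logger.warning(
                "replicate group %r has a single measurement; sd set to 0",
                group)
        rows.append({"analyte": analyte, "channel": channel,
                     "replicate_group": group,
                     "concentration": float(conc[0]),
                     "mean_auc": float(auc.mean()),
                     "sd_auc": 0.0 if singleton else float(auc.std(ddof=1)),
                     "n": int(n), "singleton": singleton})
    return pd.DataFrame(rows)


def fit_calibration(averaged: pd.DataFrame, analyte: str, channel: str,
                    unit: str = "", weights: str | None = None
                    ) -> CalibrationFit:
    """OLS line of mean signal on concentration for one analyte/channel.

    ``weights="1/concentration"`` switches to WLS with inverse-
    concentration weights (blank rows get the smallest non-zero
    concentration's weight).  Needs at least three distinct concentration
    levels.
    """
    sub = averaged[(averaged["analyte"] == analyte)
                   & (averaged["channel"] == channel)]
    conc = sub["concentration"].to_numpy(dtype=float)
    signal = sub["mean_auc"].to_numpy(dtype=float)
    levels = np.unique(conc)
    if levels.size < 3:
        raise InsufficientDataError(
            f"{analyte}/{channel}: {levels.size} concentration level(s); "
            f"a linear calibration needs at least 3")
    if np.ptp(levels) == 0:
        raise DegenerateDesignError(
            f"{analyte}/{channel}: concentrations have zero variance")

    X = sm.add_constant(conc)
    if weights is None:
        res = sm.OLS(signal, X).fit()
    elif weights == "1/concentration":
        w = np.where(conc > 0, 1.0 / np.where(conc > 0, conc, 1.0),
                     1.0 / levels[levels > 0].min())
        res = sm.WLS(signal, X, weights=w).fit()
    else:
        raise UsageError(f"unknown weighting scheme {weights!r}")

    n = conc.size
    ss_res = float(res.ssr)
    residual_sd = float(np.sqrt(ss_res / (n - 2))) if n > 2 else 0.0
    return CalibrationFit(analyte=analyte, channel_label=channel,
                          slope=float(res.params[1]),
                          intercept=float(res.params[0]),
                          r_squared=float(np.clip(res.rsquared, 0.0, 1.0)),
                          residual_sd=residual_sd, n_points=int(n),
                          concentration_unit=unit,
                          slope_se=float(res.bse[1]))


def inverse_predict(fit: CalibrationFit, signal: float) -> float:
    """Concentration whose predicted signal equals ``signal``.

    May be negative; interpreting negative estimates (e.g. as the
    ``"Negative"`` label for detection limits) is the caller's job.
    """
    if fit.slope == 0:
        raise DegenerateFitError(
            f"{fit.analyte}/{fit.channel_label}: zero slope cannot be "
            f"inverted")
    return (signal - fit.intercept) / fit.slope


def key_measures_from_stats(fit: CalibrationFit, mean_blank: float,
                            sd_blank: float, sd_low: float | None = None,
                            definitions_id: str = DEFAULT_DEFINITIONS_ID
                            ) -> KeyMeasures:
    """LOB/LOD/LOQ from blank summary statistics.

    Same formula set as :func:`key_measures` but starting from the blank
    mean/SD (and optionally the lowest calibrant's SD) — the entry point
    when only replicate-averaged data are available.
    """
    if definitions_id != DEFAULT_DEFINITIONS_ID:
        raise UsageError(
            f"unknown key-measure definitions {definitions_id!r}")
    if fit.slope == 0:
        raise DegenerateFitError("zero slope: key measures undefined")
    if sd_blank < 0:
        raise UsageError("sd_blank must be >= 0")
    if sd_low is None:
        logger.info("no low-concentration sd; using blank sd for the LOD "
                    "term")
        sd_low = sd_blank

    lob_s = mean_blank + 1.645 * sd_blank
    lod_s = lob_s + 1.645 * sd_low
    loq_s = mean_blank + 10.0 * sd_blank

    def to_conc(signal: float) -> float | str:
        conc = inverse_predict(fit, signal)
        return NEGATIVE_LABEL if conc < 0 else float(conc)

    return KeyMeasures(lob=to_conc(lob_s), lod=to_conc(lod_s),
                       loq=to_conc(loq_s), unit=fit.concentration_unit,
                       definitions_id=definitions_id)


def key_measures(fit: CalibrationFit, blank_signals: Iterable[float],
                 low_conc_signals: Iterable[float] | None = None,
                 definitions_id: str = DEFAULT_DEFINITIONS_ID
                 ) -> KeyMeasures:
    """LOB/LOD/LOQ in concentration units from blank replicate signals.

    See the module docstring for the formula set.  ``low_conc_signals``
    are the replicate signals of the lowest non-blank calibrant; when
    absent the blank SD is reused for the LOD term (logged).
    """
    blanks = np.asarray(list(blank_signals), dtype=float)
    if blanks.size < 2:
        raise InsufficientDataError(
            f"key measures need >= 2 blank replicates, got {blanks.size}")
    if low_conc_signals is not None:
        low = np.asarray(list(low_conc_signals), dtype=float)
    else:
        low = np.empty(0)
    sd_low = float(low.std(ddof=1)) if low.size >= 2 else None
    return key_measures_from_stats(fit, float(blanks.mean()),
                                   float(blanks.std(ddof=1)), sd_low,
                                   definitions_id=definitions_id)


@dataclass(frozen=True)
class CalibrationResult:
    """Everything calibrate_experiment derives for one analyte/channel."""

    fit: CalibrationFit
    measures: KeyMeasures
    averaged: pd.DataFrame
    n_excluded_saturated: int


def calibrate_experiment(records: pd.DataFrame,
                         include_saturated: bool = False,
                         weights: str | None = None,
                         definitions_id: str = DEFAULT_DEFINITIONS_ID
                         ) -> dict[tuple[str, str], CalibrationResult]:
    """Full calibration of merged measurement records.

    Saturated measurements are excluded from fitting by default (their
    flat-topped peaks under-report the AUC); pass
    ``include_saturated=True`` to keep them.  Returns one
    :class:`CalibrationResult` per (analyte, channel).
    """
    usable = records[records["role"].isin(("blank", "calibrant"))]
    n_sat = 0
    if not include_saturated and "saturated" in usable.columns:
        sat_mask = usable["saturated"].astype(bool)
        n_sat = int(sat_mask.sum())
        if n_sat:
            logger.warning(
                "excluding %d saturated measurement(s) from calibration",
                n_sat)
        usable = usable[~sat_mask]

    results: dict[tuple[str, str], CalibrationResult] = {}
    for (analyte, channel), sub in usable.groupby(["analyte", "channel"],
                                                  sort=True):
        unit = str(sub["unit"].iloc[0]) if "unit" in sub.columns else ""
        averaged = average_replicates(sub)
        fit = fit_calibration(averaged, analyte, channel, unit=unit,
                              weights=weights)
        blanks = sub.loc[sub["concentration"] == 0, "corrected_auc"]
        nonzero = sub[sub["concentration"] > 0]
        if len(nonzero):
            low_level = nonzero["concentration"].min()
            low = nonzero.loc[nonzero["concentration"] == low_level,
                              "corrected_auc"]
        else:
            low = None
        measures = key_measures(fit, blanks.to_numpy(dtype=float),
                                None if low is None
                                else low.to_numpy(dtype=float),
                                definitions_id=definitions_id)
        results[(analyte, channel)] = CalibrationResult(
            fit=fit, measures=measures, averaged=averaged,
            n_excluded_saturated=n_sat)
    return results


def results_table(results: dict[tuple[str, str], CalibrationResult]
                  ) -> pd.DataFrame:
    """Flat per-analyte/channel summary of fits and key measures."""
    rows = []
    for (analyte, channel), r in sorted(results.items()):
        rows.append({"analyte": analyte, "channel": channel,
                     "slope": r.fit.slope, "intercept": r.fit.intercept,
                     "r_squared": r.fit.r_squared,
                     "residual_sd": r.fit.residual_sd,
                     "n_points": r.fit.n_points,
                     "unit": r.fit.concentration_unit,
                     "lob": r.measures.lob, "lod": r.measures.lod,
                     "loq": r.measures.loq,
                     "definitions_id": r.measures.definitions_id})
    return pd.DataFrame(rows)
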