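"""Deterministic calibration reports (self-contained HTML + Markdown).

The report mirrors what an assay developer wants on one page per
analyte/channel: the calibration table (slope, intercept, R², residual
SD, n), the key-measures table with ``"Negative"`` labels where a limit
maps below zero concentration, a scatter-plus-line calibration plot
(embedded as base64 PNG in the HTML), and the run configuration.  No
timestamps or hostnames appear in the body, so identical inputs render
byte-identical documents.
"""

from __future__ import annotations

import base64
import html
import io
from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from . import __version__
from .calibrate import CalibrationResult
from .errors import UsageError

_CSS = """
body { font-family: sans-serif; margin: 2em auto; max-width: 60em; }
table { border-collapse: collapse; margin: 1em 0; }
th, td { border: 1px solid #999; padding: 0.3em 0.8em; text-align: right; }
th { background: #eee; }
td.label, th.label { text-align: left; }
img { max-width: 28em; }
"""

_CHANNEL_COLORS = {"green": "#2a7e2a", "red": "#b03030", "gray": "#555555"}


def _fmt(x, digits: int = 4) -> str:
    if isinstance(x, str):
        return x
    return f"{x:.{digits}g}"


def _calibration_plot_png(result: CalibrationResult) -> bytes:
    """Scatter of replicate means ± SD with the fitted line, as PNG."""
    fit = result.fit
    avg = result.averaged.sort_values("concentration")
    conc = avg["concentration"].to_numpy(dtype=float)
    mean = avg["mean_auc"].to_numpy(dtype=float)
    sd = avg["sd_auc"].to_numpy(dtype=float)
    color = _CHANNEL_COLORS.get(fit.channel_label, "#333333")

    fig, ax = plt.subplots(figsize=(4.2, 3.2), dpi=100)
    ax.errorbar(conc, mean, yerr=sd, fmt="o", color=color, capsize=3,
                label="replicate means")
    grid = np.linspace(conc.min(), conc.max(), 50)
    ax.plot(grid, fit.intercept + fit.slope * grid, "-", color="#333333",
            label=f"fit (R²={fit.r_squared:.3f})")
    unit = fit.concentration_unit or "a.u."
    ax.set_xlabel(f"concentration ({unit})")
    ax.set_ylabel("corrected AUC")
    ax.set_title(f"{fit.analyte} / {fit.channel_label}")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    buf = io.BytesIO()
    # Fixed Software tag: default embeds the library version, which would
    # break byte-identical reruns across environments.
    fig.savefig(buf, format="png", metadata={"Software": "lfaquant"})
    plt.close(fig)
    return buf.getvalue()


def _fit_rows(results: Mapping[tuple[str, str], CalibrationResult]):
    for (analyte, channel), r in sorted(results.items()):
        yield analyte, channel, r


def render_report(results: Mapping[tuple[str, str], CalibrationResult],
                  out_path: str | Path,
                  config: Mapping | None = None,
                  include_plots: bool = True) -> tuple[Path, Path]:
    """Write the HTML report and its Markdown twin.

    ``out_path`` names the HTML file; the Markdown twin gets the same
    stem with ``.md``.  ``config`` (a flat mapping) is echoed verbatim in
    a run-configuration section.  Returns both paths.
    """
    if not results:
        raise UsageError("render_report needs at least one calibration fit")
    out_path = Path(out_path)
    md_path = out_path.with_suffix(".md")

    fit_header = ["analyte", "channel", "slope", "intercept", "R²",
                  "residual SD", "n"]
    fit_rows = [[a, c, _fmt(r.fit.slope), _fmt(r.fit.intercept),
                 _fmt(r.fit.r_squared), _fmt(r.fit.residual_sd),
                 str(r.fit.n_points)]
                for a, c, r in _fit_rows(results)]
    km_header = ["analyte", "channel", "LOB", "LOD", "LOQ", "unit",
                 "definitions"]
    km_rows = [[a, c, _fmt(r.measures.lob), _fmt(r.measures.lod),
                _fmt(r.measures.loq), r.measures.unit or "a.u.",
                r.measures.definitions_id]
               for a, c, r in _fit_rows(results)]
    config = dict(config or {})

    # ---- HTML ----
    def html_table(header, rows):
        head = "".join(f"<th class=\"label\">{html.escape(h)}</th>"
                       for h in header)
        body = []
        for row in rows:
            cells = [f"<td class=\"label\">{html.escape(row[0])}</td>",
                     f"<td class=\"label\">{html.escape(row[1])}</td>"]
            cells += [f"<td>{html.escape(str(v))}</td>" for v in row[2:]]
            body.append("<tr>" + "".join(cells) + "</tr>")
        return (f"<table><thead><tr>{head}</tr></thead>"
                f"<tbody>{''.join(body)}</tbody></table>")

    parts = [
        "<!DOCTYPE html>",
        "<html><head><meta charset=\"utf-8\">",
        "<title>LFA calibration report</title>",
        f"<style>{_CSS}</style></head><body>",
        "<h1>LFA calibration report</h1>",
        f"<p>Generated by lfaquant {html.escape(__version__)}.</p>",
        "<h2>Calibration fits</h2>",
        html_table(fit_header, fit_rows),
        "<h2>Key measures</h2>",
        "<p>Blank-based detection limits, inverse-predicted to "
        "concentration units; limits below zero concentration are "
        "reported as <em>Negative</em>.</p>",
        html_table(km_header, km_rows),
    ]
    if include_plots:
        parts.append("<h2>Calibration curves</h2>")
        for a, c, r in _fit_rows(results):
            png = base64.b64encode(_calibration_plot_png(r)).decode("ascii")
            parts.append(
                f"<h3>{html.escape(a)} / {html.escape(c)}</h3>"
                f"<img alt=\"calibration curve {html.escape(a)} "
                f"{html.escape(c)}\" "
                f"src=\"data:image/png;base64,{png}\">")
    if config:
        parts.append("<h2>Run configuration</h2><table><tbody>")
        for key in sorted(config):
            parts.append(
                f"<tr><td class=\"label\">{html.escape(str(key))}</td>"
                f"<td class=\"label\">{html.escape(str(config[key]))}"
                f"</td></tr>")
        parts.append("</tbody></table>")
    parts.append("</body></html>")
    out_path.write_text("\n".join(parts) + "\n", encoding="utf-8")

    # ---- Markdown twin ----
    def md_table(header, rows):
        lines = ["| " + " | ".join(header) + " |",
                 "|" + "|".join("---" for _ in header) + "|"]
        lines += ["| " + " | ".join(str(v) for v in row) + " |"
                  for row in rows]
        return "\n".join(lines)

    md = [
        "# LFA calibration report",
        f"Generated by lfaquant {__version__}.",
        "",
        "## Calibration fits",
        md_table(fit_header, fit_rows),
        "",
        "## Key measures",
        md_table(km_header, km_rows),
    ]
    if config:
        md += ["", "## Run configuration",
               md_table(["key", "value"],
                        [[k, config[k]] for k in sorted(config)])]
    md_path.write_text("\n".join(md) + "\n", encoding="utf-8")
    return out_path, md_path
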