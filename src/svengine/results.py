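"""Result-file writers.

A completed session populates one fresh output directory with exactly:

* ``screenshot.bmp``      -- rendered report image (data+fit, residuals,
  distribution, info text; optional residual histogram)
* ``RInoise.dat``         -- scan time vs. radial-invariant offset
* ``TInoise.dat``         -- radius vs. time-invariant offset
* ``ScanRMSD.dat``        -- scan number vs. per-scan rmsd
* ``distribution.dat``    -- grid s-value vs. c(s)
* ``dfr.dat``             -- matrix of noise profiles and per-scan
  radius/raw/fit columns for recreating the fit overlay
* ``ResultParameters.xml``-- the request echoed (post-fit values) plus all
  additional output parameters

All numeric text files are tab-delimited ASCII with at least 6 significant
digits.  The bitmap name ``screenshot.bmp`` is kept for drop-in compatibility
with downstream software keying on that path, although the content is a
rendered plot rather than a window capture.
"""

from __future__ import annotations

import io
import threading
from dataclasses import dataclass
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np

from .distribution import DistributionResult, fold_noise
from .fitstats import FitStatistics
from .protocol import ROOT_TAG, _PARAM_SPEC, _scan_number, _scan_slices
from .scan_io import MetadataAggregate, ScanSet

__all__ = [
    "AnalysisResult",
    "write_all",
    "write_dfr",
    "write_result_xml",
    "render_report_image",
    "OUTPUT_FILES",
]

OUTPUT_FILES = (
    "screenshot.bmp",
    "RInoise.dat",
    "TInoise.dat",
    "ScanRMSD.dat",
    "distribution.dat",
    "dfr.dat",
    "ResultParameters.xml",
)


@dataclass
class AnalysisResult:
    """Everything the results XML reports: the post-fit request echo plus
    engine metadata, fit statistics, and (after write_all) output paths."""

    request: object
    engine_version: str
    scan_files_loaded: list[Path]
    metadata: MetadataAggregate
    stats: FitStatistics
    frictional_ratio: float
    fitting_steps_text: str
    screenshot_path: Path | None = None
    cofs_data_path: Path | None = None
    ti_noise_path: Path | None = None
    ri_noise_path: Path | None = None
    scan_rmsd_path: Path | None = None


def write_all(
    result: AnalysisResult,
    dist: DistributionResult,
    scanset: ScanSet,
    out_dir: str | Path,
) -> list[Path]:
    """Write the complete output-file set into ``out_dir`` and return the
    paths.  The protocol layer writes the completion flag only after this
    returns, so a failure here leaves no flag file."""
    out_dir = Path(out_dir)
    if not out_dir.is_dir():
        raise FileNotFoundError(f"output directory missing: {out_dir}")

    ti_text, ri_text = fold_noise(dist, scanset)
    ti_path = out_dir / "TInoise.dat"
    ti_path.write_text(ti_text, encoding="ascii")
    ri_path = out_dir / "RInoise.dat"
    ri_path.write_text(ri_text, encoding="ascii")

    rmsd_path = out_dir / "ScanRMSD.dat"
    rmsd_path.write_text(
        "".join(f"{sid}\t{v:.6e}\n" for sid, v in result.stats.per_scan_rmsd),
        encoding="ascii",
    )

    dist_path = out_dir / "distribution.dat"
    dist_path.write_text(
        "".join(f"{s:.6e}\t{c:.6e}\n" for s, c in zip(dist.grid.values, dist.c)),
        encoding="ascii",
    )

    dfr_path = write_dfr(scanset, dist, out_dir / "dfr.dat")

    shot_path = render_report_image(
        scanset,
        dist,
        result,
        options={
            "subtract_noise": bool(result.request.AutoSubtractSystematicNoise),
            "show_histogram": bool(result.request.ShowResidualsHistogram),
        },
        path=out_dir / "screenshot.bmp",
    )

    result.screenshot_path = shot_path
    result.cofs_data_path = dist_path
    result.ti_noise_path = ti_path
    result.ri_noise_path = ri_path
    result.scan_rmsd_path = rmsd_path
    xml_path = write_result_xml(result, out_dir / "ResultParameters.xml")
    return [shot_path, ri_path, ti_path, rmsd_path, dist_path, dfr_path, xml_path]


def write_dfr(scanset: ScanSet, dist: DistributionResult, path: str | Path) -> Path:
    """Tab-delimited fit matrix: radius (TI), TI noise, RI noise, then per
    scan the triple (radius, raw data, fit value).  Columns of unequal length
    are padded with empty fields."""
    slices = _scan_slices(scanset)
    columns: list[list[str]] = [
        [f"{r:.6f}" for r in dist.ti_radii],
        [f"{v:.6e}" for v in dist.ti_noise],
        [f"{v:.6e}" for v in dist.ri_noise],
    ]
    for sc, sl in zip(scanset.scans, slices):
        columns.append([f"{r:.6f}" for r in sc.radii])
        columns.append([f"{y:.6e}" for y in sc.signal])
        columns.append([f"{v:.6e}" for v in dist.fitted[sl]])
    n_rows = max(len(col) for col in columns)
    lines = []
    for i in range(n_rows):
        lines.append("\t".join(col[i] if i < len(col) else "" for col in columns))
    Path(path).write_text("\n".join(lines) + "\n", encoding="ascii")
    return Path(path)


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "TRUE" if value else "FALSE"
    if isinstance(value, float):  # includes numpy scalars; repr round-trips
        return repr(float(value))
    return str(value)


def write_result_xml(result: AnalysisResult, path: str | Path) -> Path:
    """Results XML: same root and element conventions as the request, echoing
    every input parameter at its post-fit value, followed by the additional
    output parameters."""
    req = result.request
    lines = ['<?xml version="1.0" encoding="UTF-8"?>', f"<{ROOT_TAG}>"]

    def add(name: str, value) -> None:
        lines.append(f"  <{name}>{escape(_fmt(value))}</{name}>")

    def add_raw(name: str, raw: str) -> None:
        # PassThrough may itself be XML-formatted; keep markup verbatim when
        # it re-parses as a fragment, escape otherwise
        try:
            import xml.etree.ElementTree as ET

            ET.fromstring(f"<{name}>{raw}</{name}>")
            lines.append(f"  <{name}>{raw}</{name}>")
        except ET.ParseError:
            lines.append(f"  <{name}>{escape(raw)}</{name}>")

    for name, _typ, _default in _PARAM_SPEC:
        value = getattr(req, name)
        if value is None:
            continue
        if name == "PassThrough":
            add_raw(name, value)
        else:
            add(name, value)

    add("SEDFITVersion", result.engine_version)
    add("ScreenShotPath", result.screenshot_path)
    add("CofsDataPath", result.cofs_data_path)
    add("TINoisePath", result.ti_noise_path)
    add("RINoisePath", result.ri_noise_path)
    add("ScanRMSDpath", result.scan_rmsd_path)
    lines.append("  <ScanDataFilesLoaded>")
    for p in result.scan_files_loaded:
        lines.append(f"    <File>{escape(str(p))}</File>")
    lines.append("  </ScanDataFilesLoaded>")
    meta = result.metadata
    add("CheckTimeStamps", meta.CheckTimeStamps)
    add("RotorSpeed", int(meta.RotorSpeed))
    add("Wavelength", float(meta.Wavelength))
    add("w2tLastScan", float(meta.w2tLastScan))
    add("tLastScan", float(meta.tLastScan))
    add("TemperatureStart", float(meta.TemperatureStart))
    add("TemperatureEnd", float(meta.TemperatureEnd))
    add("TemperatureAverage", float(meta.TemperatureAverage))
    add("TemperatureDiffMax-Min", float(meta.TemperatureDiffMaxMin))
    add("FittingStepsText", result.fitting_steps_text)
    stats = result.stats
    add("RMSD", float(stats.RMSD))
    add("RMSD-points", int(stats.RMSD_points))
    add("RMSD-SSR", float(stats.RMSD_SSR))
    add("RunsTestZ", float(stats.RunsTestZ))
    add("HistogramH", float(stats.HistogramH))
    add("FrictionalRatio", float(result.frictional_ratio))
    lines.append(f"</{ROOT_TAG}>")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    return Path(path)


def render_report_image(
    scanset: ScanSet,
    dist: DistributionResult,
    result: AnalysisResult,
    options: dict,
    path: str | Path,
) -> Path:
    """Render the report bitmap: scan data with fit overlay, residuals
    overlay, the distribution, and an informational text block.  Degrades to
    a text-only placeholder image if plotting fails."""
    path = Path(path)
    try:
        with _RENDER_LOCK:
            _render(scanset, dist, result, options, path)
    except Exception:  # plotting must never abort a session
        _placeholder(result, path)
    return path


# matplotlib's pyplot state machine is not thread-safe; sessions may run
# concurrently, so rendering is serialized
_RENDER_LOCK = threading.Lock()


def _render(scanset, dist, result, options, path):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    show_hist = bool(options.get("show_histogram"))
    subtract = bool(options.get("subtract_noise"))
    slices = _scan_slices(scanset)
    fig = plt.figure(figsize=(9, 8), dpi=100)
    gs = fig.add_gridspec(3, 2, height_ratios=[2.2, 1.2, 1.6])
    ax_data = fig.add_subplot(gs[0, :])
    ax_res = fig.add_subplot(gs[1, :] if not show_hist else gs[1, 0])
    ax_dist = fig.add_subplot(gs[2, 0])
    ax_text = fig.add_subplot(gs[2, 1])
    if show_hist:
        ax_hist = fig.add_subplot(gs[1, 1])
        ax_hist.hist(dist.residuals, bins=40, color="0.4")
        ax_hist.set_title("residuals histogram", fontsize=8)

    cmap = plt.get_cmap("rainbow")
    n = len(scanset)
    for k, (sc, sl) in enumerate(zip(scanset.scans, slices)):
        color = cmap(k / max(n - 1, 1))
        y = sc.signal
        fit = dist.fitted[sl]
        if subtract:
            systematic = np.zeros(sc.n_points)
            systematic += np.interp(sc.radii, dist.ti_radii, dist.ti_noise)
            systematic += dist.ri_noise[k] + dist.baseline
            y = y - systematic
            fit = fit - systematic
        ax_data.plot(sc.radii, y, ".", ms=1.5, color=color)
        ax_data.plot(sc.radii, fit, "-", lw=0.7, color="k", alpha=0.6)
        ax_res.plot(sc.radii, dist.residuals[sl], "-", lw=0.4, color=color)
    ax_data.set_xlabel("radius (cm)")
    ax_data.set_ylabel("signal")
    ax_res.axhline(0, color="k", lw=0.5)
    ax_res.set_ylabel("residuals")
    ax_dist.plot(dist.grid.values, dist.c, "-", color="tab:blue")
    ax_dist.set_xlabel("s (S)")
    ax_dist.set_ylabel("c(s)")
    ax_text.axis("off")
    ax_text.text(
        0.0, 1.0, _info_text(result), fontsize=7, family="monospace",
        va="top", ha="left", transform=ax_text.transAxes,
    )
    fig.tight_layout()
    _save_bmp(fig, path)
    plt.close(fig)


def _info_text(result: AnalysisResult) -> str:
    req = result.request
    files = [Path(p).name for p in result.scan_files_loaded]
    shown = ", ".join(files[:4]) + (" ..." if len(files) > 4 else "")
    return "\n".join(
        [
            f"engine {result.engine_version}",
            f"data: {req.DataDirectory}",
            f"scans: {shown} ({len(files)} files)",
            f"model: {req.Model}  grid {req.Smin}-{req.Smax} S",
            f"rmsd: {result.stats.RMSD:.6f}",
            f"f/f0: {result.frictional_ratio:.4f}",
            f"meniscus: {req.Meniscus:.4f} cm",
            result.fitting_steps_text,
        ]
    )


def _placeholder(result: AnalysisResult, path: Path) -> None:
    from PIL import Image, ImageDraw

    img = Image.new("RGB", (640, 240), "white")
    draw = ImageDraw.Draw(img)
    draw.text((10, 10), "report rendering failed\n" + _info_text(result), fill="black")
    img.save(path, format="BMP")


def _save_bmp(fig, path: Path) -> None:
    from PIL import Image

    buf = io.BytesIO()
    fig.savefig(buf, format="png")
    buf.seek(0)
    Image.open(buf).convert("RGB").save(path, format="BMP")
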