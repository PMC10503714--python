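"""Command-line/XML control protocol.

A session is driven by exactly three command-line tokens -- an operation
mode, an opaque handshake string, and the path of an XML request file -- and
ends by writing a flag file whose sole content is the handshake.  The flag
file is written strictly after every other output, so its existence certifies
that the result set is complete.

The request file is UTF-8 XML with root ``cGMPSedfitCall`` and one child
element per parameter, ``<Name>value</Name>``.  Parameter names are
case-sensitive; unknown elements are ignored with a warning; parameters left
unset take the documented defaults.  Mode 111 accepts the full parameter set;
mode 112 is a restricted validation profile that rejects non-standard options
(custom grid files, log-spaced grids, bottom fitting).
"""

from __future__ import annotations

import logging
import os
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from . import __version__
from .distribution import (
    RegularizationSpec,
    build_grid,
    fold_noise,
    grid_from_file,
    write_sdist,
)
from .fitting import FitSpec, optimize, seed_from_handshake
from .fitstats import histogram_h, rmsd_stats, runs_test_z
from .lamm import CellGeometry, SolutionConditions
from .scan_io import aggregate_metadata, filter_spikes_set, load_scanset, restrict_fit_range

logger = logging.getLogger(__name__)

__all__ = [
    "CommandLine",
    "AnalysisRequest",
    "UsageError",
    "RequestFormatError",
    "RequestValidationError",
    "FlagFileExistsError",
    "parse_command_line",
    "read_request",
    "validate_request",
    "run_session",
    "ROOT_TAG",
    "SUPPORTED_MODES",
]

ROOT_TAG = "cGMPSedfitCall"
SUPPORTED_MODES = (111, 112)
DEFAULT_SPIKE_THRESHOLD = 0.4
# radial grid size of the Lamm kernels used during analysis; converged for
# typical 12 mm columns (see docs/methods.md)
ANALYSIS_N_RADIAL = 300


class UsageError(ValueError):
    """Wrong command-line arity or an unsupported operation mode."""


class RequestFormatError(ValueError):
    """Malformed XML or wrong root element."""


class FlagFileExistsError(RuntimeError):
    """The completion flag file already exists; refusing to run."""


class RequestValidationError(ValueError):
    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("invalid request:\n  " + "\n  ".join(violations))


@dataclass(frozen=True)
class CommandLine:
    mode: int
    handshake: str
    input_path: Path

    @property
    def restricted(self) -> bool:
        return self.mode == 112


def parse_command_line(argv: list[str]) -> CommandLine:
    """Parse the three tokens following the program name: mode, handshake,
    request-file path."""
    if len(argv) != 3:
        raise UsageError(
            f"expected 3 arguments (mode, handshake, input file), got {len(argv)}"
        )
    mode_str, handshake, raw_path = argv
    try:
        mode = int(mode_str)
    except ValueError as exc:
        raise UsageError(f"mode must be an integer, got {mode_str!r}") from exc
    if mode not in SUPPORTED_MODES:
        raise UsageError(f"unsupported mode {mode}; supported: {SUPPORTED_MODES}")
    if not handshake.strip():
        raise UsageError("handshake string must be non-empty")
    path = _normalize_path(raw_path)
    if not path.is_file() or not os.access(path, os.R_OK):
        raise OSError(f"input file not readable: {raw_path}")
    return CommandLine(mode=mode, handshake=handshake, input_path=path)


def _normalize_path(raw: str) -> Path:
    # requests written on Windows hosts use backslash separators
    if os.sep != "\\":
        raw = raw.replace("\\", os.sep)
    return Path(raw)


# (name, python type, default); None default means the parameter is required.
_PARAM_SPEC: list[tuple[str, type, object]] = [
    ("AllDoneFlagFile", Path, None),
    ("OutputResultsDirectory", Path, None),
    ("PassThrough", str, ""),
    ("DataDirectory", Path, None),
    ("Channel", str, None),
    ("FirstScan", int, None),
    ("LastScan", int, None),
    ("ScanInterval", int, 1),
    ("FilterDataSpikes", bool, True),
    ("DataSpikeThreshold", float, DEFAULT_SPIKE_THRESHOLD),
    ("Meniscus", float, None),
    ("MeniscusLowerLimit", float, None),
    ("MeniscusUpperLimit", float, None),
    ("Bottom", float, None),
    ("BottomLowerLimit", float, None),
    ("BottomUpperLimit", float, None),
    ("LeftFitLimit", float, None),
    ("RightFitLimit", float, None),
    ("AutoRun", bool, False),
    ("AutoFit", bool, False),
    ("AutoSubtractSystematicNoise", bool, False),
    ("ShowResidualsHistogram", bool, False),
    ("Model", str, "cofs"),
    ("Resolution", int, 50),
    ("Smin", float, 1.0),
    ("Smax", float, 20.0),
    ("GridfromFile", bool, False),
    ("UseLogSpaceSgrid", bool, False),
    ("RegularizationType", str, "Tikhonov"),
    ("RegularizationPvalue", float, 0.68),
    ("SuppressBaselineCorrelation", bool, False),
    ("NumberComputationThreads", int, 2),
    ("FittingAlgorithm", str, "Simplex"),
    ("StartingFrictionalRatio", float, 1.2),
    ("FrictionalRatioFitted", bool, False),
    ("MeniscusFitted", bool, False),
    ("BottomFitted", bool, False),
    ("BaselineFitted", bool, False),
    ("RINoiseFitted", bool, True),
    ("TINoiseFitted", bool, True),
    ("Vbar", float, 0.73),
    ("BufferDensity", float, 0.99823),
    ("BufferViscosity", float, 0.01002),
]
_PARAM_TYPES = {name: typ for name, typ, _ in _PARAM_SPEC}


def _make_request_dataclass():
    # all fields optional at construction; required ones default to None and
    # are enforced by validate_request
    ns = {"__annotations__": {}}
    for name, typ, default in _PARAM_SPEC:
        ns["__annotations__"][name] = object
        ns[name] = default
    return dataclass(type("AnalysisRequest", (), ns))


AnalysisRequest = _make_request_dataclass()
AnalysisRequest.__doc__ = (
    "The complete input parameter set controlling one analysis session; "
    "one attribute per XML request parameter."
)


def _parse_value(name: str, typ: type, text: str):
    text = (text or "").strip()
    try:
        if typ is bool:
            up = text.upper()
            if up in ("TRUE", "FALSE"):
                return up == "TRUE"
            raise ValueError("expected TRUE or FALSE")
        if typ is int:
            return int(text)
        if typ is float:
            return float(text)
        if typ is Path:
            return _normalize_path(text)
        return text
    except ValueError as exc:
        raise ValueError(f"parameter {name}: cannot parse {text!r} ({exc})") from exc


def _inner_xml(elem: ET.Element) -> str:
    parts = [elem.text or ""]
    for child in elem:
        parts.append(ET.tostring(child, encoding="unicode"))
    return "".join(parts).strip()


def read_request(path: str | Path) -> "AnalysisRequest":
    """Parse the XML request file into an :class:`AnalysisRequest`.

    Parameter names are case-sensitive; element order is irrelevant; unknown
    elements are ignored with a warning.  ``PassThrough`` is captured
    verbatim, including any nested markup.
    """
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise RequestFormatError(f"{path}: malformed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != ROOT_TAG:
        raise RequestFormatError(
            f"{path}: root element must be <{ROOT_TAG}>, found <{root.tag}>"
        )
    req = AnalysisRequest()
    for elem in root:
        name = elem.tag
        if name == "PassThrough":
            req.PassThrough = _inner_xml(elem)
            continue
        if name not in _PARAM_TYPES:
            logger.warning("ignoring unknown request parameter <%s>", name)
            continue
        setattr(req, name, _parse_value(name, _PARAM_TYPES[name], elem.text))
    return req


def validate_request(req: "AnalysisRequest", restricted: bool = False) -> list[str]:
    """Check every request invariant; returns a list of human-readable
    violations (empty iff the request is valid)."""
    v: list[str] = []

    def need(name):
        if getattr(req, name) is None:
            v.append(f"{name}: required parameter is unset")
            return False
        return True

    required = [
        "AllDoneFlagFile", "OutputResultsDirectory", "DataDirectory", "Channel",
        "FirstScan", "LastScan", "Meniscus", "Bottom", "LeftFitLimit", "RightFitLimit",
    ]
    ok = all([need(n) for n in required])

    # default meniscus/bottom brackets collapse onto the value itself
    if req.Meniscus is not None:
        if req.MeniscusLowerLimit is None:
            req.MeniscusLowerLimit = req.Meniscus
        if req.MeniscusUpperLimit is None:
            req.MeniscusUpperLimit = req.Meniscus
    if req.Bottom is not None:
        if req.BottomLowerLimit is None:
            req.BottomLowerLimit = req.Bottom
        if req.BottomUpperLimit is None:
            req.BottomUpperLimit = req.Bottom

    if ok:
        if not (req.FirstScan <= req.LastScan):
            v.append("FirstScan/LastScan: FirstScan must be <= LastScan")
        if req.FirstScan < 1:
            v.append("FirstScan: must be >= 1")
        if not (req.MeniscusLowerLimit <= req.Meniscus <= req.MeniscusUpperLimit):
            v.append("Meniscus: must lie within [MeniscusLowerLimit, MeniscusUpperLimit]")
        if not (req.MeniscusUpperLimit < req.LeftFitLimit):
            v.append("MeniscusUpperLimit: must be smaller than LeftFitLimit")
        if not (req.LeftFitLimit < req.RightFitLimit):
            v.append("LeftFitLimit: must be smaller than RightFitLimit")
        if not (req.BottomLowerLimit <= req.Bottom <= req.BottomUpperLimit):
            v.append("Bottom: must lie within [BottomLowerLimit, BottomUpperLimit]")
        if not (req.RightFitLimit < req.Bottom):
            v.append("RightFitLimit: must be smaller than Bottom")
        flag = Path(req.AllDoneFlagFile)
        if flag.exists():
            v.append("AllDoneFlagFile: file already exists")
        if not flag.parent.is_dir():
            v.append("AllDoneFlagFile: parent directory does not exist")
        out = Path(req.OutputResultsDirectory)
        if out.exists():
            v.append("OutputResultsDirectory: directory already exists")
        if not out.parent.is_dir():
            v.append("OutputResultsDirectory: parent directory does not exist")
        if not Path(req.DataDirectory).is_dir():
            v.append("DataDirectory: not an existing directory")
    if req.ScanInterval < 1:
        v.append("ScanInterval: must be >= 1")
    if req.FilterDataSpikes and req.DataSpikeThreshold <= 0:
        v.append("DataSpikeThreshold: must be positive")
    if req.Model not in ("cofs", "lsgofs"):
        v.append("Model: must be 'cofs' or 'lsgofs'")
    if not (0 < req.Smin < req.Smax):
        v.append("Smin/Smax: require 0 < Smin < Smax")
    if req.Resolution < 2:
        v.append("Resolution: must be >= 2")
    if req.RegularizationType not in ("maxent", "Tikhonov"):
        v.append("RegularizationType: must be 'maxent' or 'Tikhonov'")
    if not (0.5 <= req.RegularizationPvalue <= 1.0):
        v.append("RegularizationPvalue: must lie between 0.5 and 1.0")
    if req.NumberComputationThreads < 1:
        v.append("NumberComputationThreads: must be >= 1")
    if req.FittingAlgorithm not in ("Simplex", "Levenberg-Marquardt"):
        v.append("FittingAlgorithm: must be 'Simplex' or 'Levenberg-Marquardt'")
    if req.StartingFrictionalRatio < 1.0 and req.Model == "cofs":
        v.append("StartingFrictionalRatio: must be >= 1")
    if req.Vbar <= 0:
        v.append("Vbar: must be positive")
    if req.BufferDensity <= 0:
        v.append("BufferDensity: must be positive")
    if req.BufferViscosity <= 0:
        v.append("BufferViscosity: must be positive")
    if req.Vbar > 0 and req.BufferDensity > 0 and 1.0 - req.Vbar * req.BufferDensity == 0:
        v.append("Vbar/BufferDensity: buoyancy factor 1 - Vbar*BufferDensity is zero")
    if restricted:
        for name, val in (
            ("GridfromFile", req.GridfromFile),
            ("UseLogSpaceSgrid", req.UseLogSpaceSgrid),
            ("BottomFitted", req.BottomFitted),
        ):
            if val:
                v.append(f"{name}: not available in restricted mode 112")
    return v


def run_session(cmd: CommandLine, engine_seed: int | None = None):
    """Execute one full analysis session and return the
    :class:`~svengine.results.AnalysisResult`.

    Lifecycle: read and validate the request, load and preprocess the scans,
    build the s-grid, run the (optionally nonlinear) fit, write every result
    file into the freshly created output directory, and finally write the
    completion flag file.  Any failure before the last step leaves no flag
    file behind.
    """
    from .results import AnalysisResult, write_all  # deferred: avoids import cycle

    req = read_request(cmd.input_path)
    violations = validate_request(req, restricted=cmd.restricted)
    if violations:
        raise RequestValidationError(violations)
    flag_path = Path(req.AllDoneFlagFile)
    if flag_path.exists():
        raise FlagFileExistsError(str(flag_path))

    scanset = load_scanset(
        req.DataDirectory, req.Channel, req.FirstScan, req.LastScan, req.ScanInterval
    )
    loaded_paths = list(scanset.source_paths)
    if req.FilterDataSpikes:
        scanset, n_removed = filter_spikes_set(scanset, req.DataSpikeThreshold)
        if n_removed:
            logger.info("spike filter removed %d points", n_removed)
    scanset = restrict_fit_range(scanset, req.LeftFitLimit, req.RightFitLimit)

    meta = aggregate_metadata(scanset)
    cond = SolutionConditions(
        vbar=req.Vbar,
        density=req.BufferDensity,
        viscosity=req.BufferViscosity,
        temperature=meta.TemperatureAverage + 273.15,
    )
    geom = CellGeometry(meniscus=req.Meniscus, bottom=req.Bottom)

    if req.GridfromFile:
        grid = grid_from_file(Path(req.DataDirectory) / f"sdist.{scanset.channel}")
    else:
        grid = build_grid(req.Smin, req.Smax, req.Resolution, req.UseLogSpaceSgrid)

    seed = seed_from_handshake(cmd.handshake) if engine_seed is None else engine_seed
    do_fit = bool(req.AutoFit)
    spec = FitSpec(
        fit_meniscus=do_fit and req.MeniscusFitted,
        fit_bottom=do_fit and req.BottomFitted,
        fit_ffr=do_fit and req.FrictionalRatioFitted and req.Model == "cofs",
        meniscus_bounds=(req.MeniscusLowerLimit, req.MeniscusUpperLimit),
        bottom_bounds=(req.BottomLowerLimit, req.BottomUpperLimit),
        algorithm=req.FittingAlgorithm,
        seed=seed,
    )
    reg = RegularizationSpec(
        kind=req.RegularizationType,
        p_value=req.RegularizationPvalue,
        suppress_baseline=req.SuppressBaselineCorrelation,
    )
    noise_flags = {
        "ti": req.TINoiseFitted,
        "ri": req.RINoiseFitted,
        "baseline": req.BaselineFitted,
    }
    best, dist, trace = optimize(
        scanset, grid, req.Model, cond, geom, meta.RotorSpeed,
        req.StartingFrictionalRatio, spec, reg, noise_flags,
        n_radial=ANALYSIS_N_RADIAL,
    )

    residual_vectors = [dist.residuals[sl] for sl in _scan_slices(scanset)]
    scan_ids = [_scan_number(p) for p in loaded_paths]
    stats = rmsd_stats(residual_vectors, scan_ids)
    stats.RunsTestZ = runs_test_z(dist.residuals)
    stats.HistogramH = histogram_h(dist.residuals)

    # side-effect files in the data directory (grid template + session log)
    write_sdist(grid, Path(req.DataDirectory) / f"sdist.{scanset.channel}")
    _write_session_log(req, cmd, best, stats, Path(req.DataDirectory))

    # echo best-fit values back into the request state
    req.Meniscus = best["meniscus"]
    req.Bottom = best["bottom"]

    out_dir = Path(req.OutputResultsDirectory)
    out_dir.mkdir(parents=False, exist_ok=False)
    result = AnalysisResult(
        request=req,
        engine_version=f"engine:{__version__}",
        scan_files_loaded=loaded_paths,
        metadata=meta,
        stats=stats,
        frictional_ratio=best["ffr"],
        fitting_steps_text=trace.text,
    )
    write_all(result, dist, scanset, out_dir)

    # the flag file is written last: its existence certifies completeness
    with open(flag_path, "w", encoding="ascii", newline="\n") as fh:
        fh.write(cmd.handshake + "\n")
    return result


def _scan_slices(scanset):
    slices, start = [], 0
    for sc in scanset.scans:
        slices.append(slice(start, start + sc.n_points))
        start += sc.n_points
    return slices


def _scan_number(path: Path) -> int:
    try:
        return int(Path(path).stem)
    except ValueError:
        return -1


def _write_session_log(req, cmd, best, stats, data_dir: Path) -> None:
    """JSON session log (this engine's replacement for a GUI session-restore
    file): enough to re-run or audit the analysis, clearly non-binary.  The
    filename carries a handshake digest so concurrent sessions sharing one
    data directory never collide."""
    import json

    payload = {
        "engine_version": __version__,
        "mode": cmd.mode,
        "handshake": cmd.handshake,
        "best_fit": {k: float(v) for k, v in best.items()},
        "rmsd": stats.RMSD,
        "model": req.Model,
    }
    name = f"session_log_{seed_from_handshake(cmd.handshake):08x}.json"
    with open(data_dir / name, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
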