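"""Automated-vs-operator equivalence study on a synthetic antibody analog.

Runs the same simulated dataset through two complete protocol sessions:

* **Path A** -- one fully automated session (AutoRun + AutoFit, meniscus and
  frictional ratio floated).
* **Path B** -- an operator-style workflow: a Run-only session first, then a
  second fitting session whose starting meniscus and frictional ratio are
  perturbed by +/-0.5%, emulating an analyst restarting a fit from slightly
  different estimates.

Both paths integrate the same three principal peaks (monomer, dimer,
aggregates) over fixed s-windows; the study reports the maximum absolute
difference in peak sedimentation coefficients and in peak population
fractions between the paths.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .distribution import integrate_distribution
from .protocol import CommandLine, run_session
from .simulate import generate_dataset, nistmab_like_preset

__all__ = ["EquivalenceReport", "PEAK_WINDOWS", "run_equivalence_study", "write_request_xml"]

# integration windows (svedberg) bracketing the monomer, dimer and aggregate
# peaks of the antibody-analog preset
PEAK_WINDOWS = ((5.0, 8.0), (8.0, 12.0), (12.0, 30.0))


@dataclass
class EquivalenceReport:
    peak_s_a: list[float]
    peak_s_b: list[float]
    fraction_a: list[float]
    fraction_b: list[float]
    max_delta_s: float  # svedberg
    max_delta_fraction: float  # percentage points
    n_points: int


def write_request_xml(path: Path, params: dict) -> Path:
    """Write a minimal protocol request file from a name->value mapping."""
    lines = ['<?xml version="1.0" encoding="UTF-8"?>', "<cGMPSedfitCall>"]
    for name, value in params.items():
        if isinstance(value, bool):
            value = "TRUE" if value else "FALSE"
        lines.append(f"  <{name}>{value}</{name}>")
    lines.append("</cGMPSedfitCall>")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def _base_params(data_dir: Path, work: Path, tag: str) -> dict:
    return {
        "AllDoneFlagFile": work / f"done_{tag}.txt",
        "OutputResultsDirectory": work / f"results_{tag}",
        "DataDirectory": data_dir,
        "Channel": "ra2",
        "FirstScan": 1,
        "LastScan": 20,
        "ScanInterval": 1,
        "Meniscus": 6.005,
        "MeniscusLowerLimit": 5.96,
        "MeniscusUpperLimit": 6.045,
        "Bottom": 7.2,
        "LeftFitLimit": 6.05,
        "RightFitLimit": 7.15,
        "Model": "cofs",
        "Resolution": 57,
        "Smin": 2.0,
        "Smax": 30.0,
        "RegularizationType": "Tikhonov",
        "RegularizationPvalue": 0.68,
        "StartingFrictionalRatio": 1.2,
        "TINoiseFitted": True,
        "RINoiseFitted": True,
        "Vbar": 0.73,
        "BufferDensity": 0.99823,
        "BufferViscosity": 0.01002,
    }


def _session(work: Path, params: dict, tag: str, handshake: str):
    xml = write_request_xml(work / f"request_{tag}.xml", params)
    cmd = CommandLine(mode=111, handshake=handshake, input_path=xml)
    return run_session(cmd)


def _integrate(out_dir: Path):
    """Read the written distribution back and integrate the peak windows --
    the same post-processing a spawning program would do."""
    import numpy as np

    from .distribution import DistributionResult, SGrid

    data = np.loadtxt(out_dir / "distribution.dat")
    result = DistributionResult(
        grid=SGrid(data[:, 0]), c=data[:, 1], ti_noise=np.zeros(1),
        ti_radii=np.zeros(1), ri_noise=np.zeros(1), baseline=0.0, ssr=0.0, lam=0.0,
    )
    peaks, fractions = [], []
    for lo, hi in PEAK_WINDOWS:
        frac, sw, _load = integrate_distribution(result, lo, hi)
        peaks.append(sw)
        fractions.append(frac)
    return peaks, fractions


def run_equivalence_study(seed: int, workdir: str | Path) -> EquivalenceReport:
    """Generate the antibody-analog dataset and compare the fully automated
    analysis path with the operator-style stepwise path (see module doc)."""
    work = Path(workdir)
    data_dir = work / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    spec = nistmab_like_preset(seed=seed)
    generate_dataset(spec, data_dir)

    # Path A: single fully automated session
    params_a = _base_params(data_dir, work, "a")
    params_a.update(
        {"AutoRun": True, "AutoFit": True, "MeniscusFitted": True, "FrictionalRatioFitted": True}
    )
    result_a = _session(work, params_a, "a", f"pathA-{seed}")
    peaks_a, frac_a = _integrate(work / "results_a")

    # Path B, step 1: Run-only session (operator inspects the raw fit first)
    params_b1 = _base_params(data_dir, work, "b1")
    params_b1.update({"AutoRun": True, "AutoFit": False})
    _session(work, params_b1, "b1", f"pathB1-{seed}")

    # Path B, step 2: fitting session restarted from perturbed estimates
    params_b2 = _base_params(data_dir, work, "b2")
    params_b2.update(
        {"AutoRun": True, "AutoFit": True, "MeniscusFitted": True, "FrictionalRatioFitted": True}
    )
    params_b2["Meniscus"] = round(params_a["Meniscus"] * 1.005, 6)
    params_b2["StartingFrictionalRatio"] = round(params_a["StartingFrictionalRatio"] * 0.995, 6)
    result_b = _session(work, params_b2, "b2", f"pathB2-{seed}")
    peaks_b, frac_b = _integrate(work / "results_b2")

    return EquivalenceReport(
        peak_s_a=peaks_a,
        peak_s_b=peaks_b,
        fraction_a=frac_a,
        fraction_b=frac_b,
        max_delta_s=max(abs(a - b) for a, b in zip(peaks_a, peaks_b)),
        max_delta_fraction=max(abs(a - b) for a, b in zip(frac_a, frac_b)),
        n_points=result_a.stats.RMSD_points,
    )
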