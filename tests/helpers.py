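"""Helper builders shared by fixtures and test modules."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from svengine.lamm import CellGeometry, SolutionConditions
from svengine.simulate import SimulationSpec, Species

WATER = dict(vbar=0.73, density=0.99823, viscosity=0.01002, temperature=293.15)


def make_small_spec(seed: int = 7, **overrides) -> SimulationSpec:
    """Two-species mixture in a standard column, sized for fast tests."""
    kwargs = dict(
        species=[Species(s=5.0, ffr=1.3, loading=0.5), Species(s=8.0, ffr=1.3, loading=0.3)],
        geometry=CellGeometry(meniscus=6.0, bottom=7.2),
        rpm=50000.0,
        scan_times=np.linspace(600.0, 5400.0, 8),
        conditions=SolutionConditions(**WATER),
        radial_step=0.008,
        noise_sigma=0.005,
        ti_amplitude=0.01,
        ri_amplitude=0.005,
        seed=seed,
        n_radial=200,
    )
    kwargs.update(overrides)
    return SimulationSpec(**kwargs)


def base_request_params(data_dir: Path, work: Path, tag: str = "t") -> dict:
    """Request parameters matching the small_dataset fixture."""
    return {
        "AllDoneFlagFile": work / f"done_{tag}.txt",
        "OutputResultsDirectory": work / f"results_{tag}",
        "DataDirectory": data_dir,
        "Channel": "ra2",
        "FirstScan": 1,
        "LastScan": 8,
        "ScanInterval": 1,
        "Meniscus": 6.0,
        "MeniscusLowerLimit": 5.97,
        "MeniscusUpperLimit": 6.03,
        "Bottom": 7.2,
        "LeftFitLimit": 6.04,
        "RightFitLimit": 7.15,
        "Model": "cofs",
        "Resolution": 21,
        "Smin": 2.0,
        "Smax": 12.0,
        "StartingFrictionalRatio": 1.3,
        "AutoRun": True,
    }
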