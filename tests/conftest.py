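"""Shared fixtures: a small simulated sedimentation experiment reused across
the protocol, distribution and results tests."""

from __future__ import annotations

from pathlib import Path

import pytest

from svengine.distribution import (
    RegularizationSpec,
    build_design_matrix,
    build_grid,
    fit_linear,
)
from svengine.scan_io import load_scanset, restrict_fit_range
from svengine.simulate import SimulationSpec, generate_dataset

from helpers import make_small_spec


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory) -> tuple[Path, SimulationSpec, object]:
    data_dir = tmp_path_factory.mktemp("scandata")
    spec = make_small_spec()
    _paths, truth = generate_dataset(spec, data_dir)
    return data_dir, spec, truth


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """A complete linear fit of the small dataset (library level, no session
    machinery): (scanset, design matrix, regularized distribution result)."""
    data_dir, spec, _truth = small_dataset
    scanset = restrict_fit_range(load_scanset(data_dir, "ra2", 1, 8, 1), 6.04, 7.15)
    grid = build_grid(2.0, 12.0, 21)
    dm = build_design_matrix(
        grid, "cofs", 1.3, spec.conditions, spec.geometry, spec.rpm, scanset, n_radial=200
    )
    flags = {"ti": True, "ri": True, "baseline": False}
    dist = fit_linear(scanset, dm, RegularizationSpec("Tikhonov", 0.68), flags)
    return scanset, dm, dist
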