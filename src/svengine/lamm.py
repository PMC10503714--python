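"""Single-species sedimentation boundaries in a sector-shaped cell.

Two kernels underlie the distribution models: finite-element solutions of the
Lamm equation (diffusing species, used by c(s)) and the closed-form
non-diffusing step boundary (used by ls-g*(s)).  Diffusion coefficients are
tied to sedimentation coefficients through the constant frictional-ratio
scaling law, so a single shape parameter f/f0 maps the whole s-grid to D(s).

All internal computation is in CGS units; sedimentation coefficients enter in
svedberg (1 S = 1e-13 s) and are converted on entry.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "SolutionConditions",
    "CellGeometry",
    "LammSolution",
    "diffusion_from_s",
    "solve_lamm",
    "nondiffusing_profile",
    "SVEDBERG",
    "BOLTZMANN_CGS",
]

SVEDBERG = 1e-13  # s
BOLTZMANN_CGS = 1.380649e-16  # erg/K


@dataclass(frozen=True)
class SolutionConditions:
    """Solvent and solute properties entering the hydrodynamic scaling law."""

    vbar: float  # partial specific volume, mL/g
    density: float  # solvent density, g/mL
    viscosity: float  # solvent viscosity, poise
    temperature: float  # K

    def __post_init__(self) -> None:
        if min(self.vbar, self.density, self.viscosity, self.temperature) <= 0:
            raise ValueError("solution conditions must all be positive")
        if self.buoyancy == 0:
            raise ValueError("buoyancy factor (1 - vbar*density) must be nonzero")

    @property
    def buoyancy(self) -> float:
        return 1.0 - self.vbar * self.density


@dataclass(frozen=True)
class CellGeometry:
    """Solution column limits, cm from the center of rotation."""

    meniscus: float
    bottom: float

    def __post_init__(self) -> None:
        if not 0 < self.meniscus < self.bottom:
            raise ValueError("require 0 < meniscus < bottom")


@dataclass
class LammSolution:
    """Concentration evolution c(t, r) normalized to unit loading."""

    radii: np.ndarray  # cm
    times: np.ndarray  # s
    concentration: np.ndarray  # shape (n_times, n_radii)


def diffusion_from_s(s: float, ffr: float, cond: SolutionConditions) -> float:
    """Diffusion coefficient (cm^2/s) for sedimentation coefficient ``s``
    (svedberg) under the constant frictional-ratio scaling law

        D = (sqrt(2)/18 pi) kT s^(-1/2) (eta f/f0)^(-3/2) ((1 - vbar rho)/vbar)^(1/2)

    which assumes all species share one f/f0 and partial-specific volume.
    """
    if s <= 0:
        raise ValueError("scaling law requires s > 0 (floating species rejected)")
    if ffr < 1:
        raise ValueError("frictional ratio must be >= 1")
    if cond.buoyancy <= 0:
        raise ValueError("buoyancy factor must be positive for sedimenting species")
    s_sec = s * SVEDBERG
    kT = BOLTZMANN_CGS * cond.temperature
    return (
        (np.sqrt(2.0) / (18.0 * np.pi))
        * kT
        * s_sec ** (-0.5)
        * (cond.viscosity * ffr) ** (-1.5)
        * (cond.buoyancy / cond.vbar) ** 0.5
    )


def _omega(rpm: float) -> float:
    return rpm * np.pi / 30.0


@lru_cache(maxsize=512)
def _lamm_grid_solution(
    s_sec: float,
    D: float,
    meniscus: float,
    bottom: float,
    rpm: float,
    times: tuple[float, ...],
    n_radial: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Cached core solver; returns (radii, concentration[time, radius])."""
    w2 = _omega(rpm) ** 2
    r = np.geomspace(meniscus, bottom, n_radial)
    h = np.diff(r)
    rl = r[:-1]

    # element matrices for linear finite elements with radial weight r:
    #   M = int phi_a phi_b r dr   (mass)
    #   S = int phi_a' phi_b' r dr (diffusion stiffness)
    #   G = int phi_a' phi_b r^2 dr (sedimentation flux)
    m11 = h * (rl / 3.0 + h / 12.0)
    m12 = h * (rl / 6.0 + h / 12.0)
    m22 = h * (rl / 3.0 + h / 4.0)
    s_el = (rl + h / 2.0) / h
    g1 = h * (rl**2 / 2.0 + rl * h / 3.0 + h**2 / 12.0)  # int phi_1 r^2 dr
    g2 = h * (rl**2 / 2.0 + 2.0 * rl * h / 3.0 + h**2 / 4.0)  # int phi_2 r^2 dr

    # Sedimentation is advection-dominated for small D; plain Galerkin
    # oscillates there.  Add the classic optimal 1-D artificial diffusion
    # per element, D_art = (v h / 2)(coth(Pe) - 1/Pe) with Pe = v h / (2 D),
    # which vanishes as O(Pe) for resolved elements and tends to full
    # upwinding for sharp boundaries.
    sw2 = s_sec * w2
    v_el = sw2 * (rl + h / 2.0)
    if D > 0:
        pe = v_el * h / (2.0 * D)
        small = pe < 1e-4
        with np.errstate(over="ignore"):
            d_art = np.where(
                small,
                0.5 * v_el * h * pe / 3.0,
                0.5 * v_el * h * (1.0 / np.tanh(np.maximum(pe, 1e-12)) - 1.0 / np.maximum(pe, 1e-12)),
            )
    else:
        d_art = 0.5 * v_el * h
    d_eff = D + d_art  # per-element effective diffusion

    n = n_radial
    # K = D_eff*S - s w^2 G, assembled tridiagonally (G is non-symmetric).
    def assemble(diag11, diag12, diag21, diag22):
        lower = np.zeros(n)
        diag = np.zeros(n)
        upper = np.zeros(n)
        diag[:-1] += diag11
        diag[1:] += diag22
        upper[1:] += diag12  # entry (i, i+1)
        lower[:-1] += diag21  # entry (i+1, i)
        return lower, diag, upper

    k11 = d_eff * s_el - sw2 * (-g1 / h)
    k12 = d_eff * (-s_el) - sw2 * (-g2 / h)
    k21 = d_eff * (-s_el) - sw2 * (g1 / h)
    k22 = d_eff * s_el - sw2 * (g2 / h)
    kl, kd, ku = assemble(k11, k12, k21, k22)
    ml, md, mu = assemble(m11, m12, m12, m22)

    t_max = float(times[-1]) if times else 0.0
    if t_max <= 0:
        c = np.ones((len(times), n))
        return r, c

    # Time step: boundary movement per step at most one radial cell, and at
    # least 200 steps over the run for temporal accuracy.
    v_max = sw2 * bottom
    dt_cells = np.min(h) / v_max if v_max > 0 else np.inf
    dt = min(dt_cells, t_max / 200.0)
    n_steps = int(np.ceil(t_max / dt))
    dt = t_max / n_steps

    # Crank-Nicolson: (M + dt/2 K) c+ = (M - dt/2 K) c
    a_l, a_d, a_u = ml + 0.5 * dt * kl, md + 0.5 * dt * kd, mu + 0.5 * dt * ku
    b_l, b_d, b_u = ml - 0.5 * dt * kl, md - 0.5 * dt * kd, mu - 0.5 * dt * ku
    ab = np.vstack([a_u, a_d, a_l])  # banded storage for solve_banded((1,1), ...)

    c = np.ones(n)
    step_times = np.arange(n_steps + 1) * dt
    want = np.asarray(times, dtype=float)
    out = np.empty((want.size, n))
    # indices of steps bracketing each requested time (linear interpolation)
    lo_idx = np.clip(np.searchsorted(step_times, want, side="right") - 1, 0, n_steps)
    states: dict[int, np.ndarray] = {}
    needed = set(lo_idx.tolist()) | set(np.minimum(lo_idx + 1, n_steps).tolist())
    if 0 in needed:
        states[0] = c.copy()
    for k in range(1, n_steps + 1):
        rhs = b_d * c
        rhs[:-1] += b_u[1:] * c[1:]
        rhs[1:] += b_l[:-1] * c[:-1]
        c = solve_banded((1, 1), ab, rhs, overwrite_b=True, check_finite=False)
        if k in needed:
            states[k] = c.copy()
    for i, t in enumerate(want):
        k0 = int(lo_idx[i])
        k1 = min(k0 + 1, n_steps)
        if k1 == k0 or step_times[k1] == step_times[k0]:
            out[i] = states[k0]
        else:
            w = (t - step_times[k0]) / (step_times[k1] - step_times[k0])
            out[i] = (1.0 - w) * states[k0] + w * states[k1]
    return r, out


def solve_lamm(
    s: float,
    D: float,
    geom: CellGeometry,
    rpm: float,
    times: np.ndarray,
    n_radial: int = 150,
) -> LammSolution:
    """Solve the Lamm equation

        dc/dt = (1/r) d/dr [ r D dc/dr - s w^2 r^2 c ]

    on [meniscus, bottom] with zero-flux boundaries and uniform unit initial
    concentration, using Crank-Nicolson time stepping of a linear
    finite-element discretization on a log-spaced radial grid.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0 or np.any(times < 0) or np.any(np.diff(times) <= 0):
        raise ValueError("times must be a non-empty increasing non-negative vector")
    if n_radial < 50:
        raise ValueError("n_radial must be at least 50")
    if D < 0 or s < 0:
        raise ValueError("s and D must be non-negative")
    r, conc = _lamm_grid_solution(
        s * SVEDBERG, float(D), geom.meniscus, geom.bottom, float(rpm),
        tuple(times.tolist()), int(n_radial),
    )
    return LammSolution(radii=r.copy(), times=times, concentration=conc.copy())


def nondiffusing_profile(
    s: float, geom: CellGeometry, rpm: float, time: float, radii: np.ndarray
) -> np.ndarray:
    """Closed-form boundary of a non-diffusing species at unit loading:
    a step at r_b = meniscus * exp(s w^2 t) with plateau exp(-2 s w^2 t)
    (radial dilution).  Once the boundary passes the bottom the cell is
    cleared and the profile is zero everywhere."""
    if s < 0:
        raise ValueError("s must be non-negative")
    radii = np.asarray(radii, dtype=float)
    swt = s * SVEDBERG * _omega(rpm) ** 2 * time
    r_boundary = geom.meniscus * np.exp(swt)
    if r_boundary > geom.bottom:
        return np.zeros_like(radii)
    plateau = np.exp(-2.0 * swt)
    return np.where(radii >= r_boundary, plateau, 0.0)
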