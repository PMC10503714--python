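"""Outer nonlinear regression over meniscus, bottom and frictional ratio.

The objective wraps the linear distribution fit: at each trial parameter
vector the kernel matrix is rebuilt and the non-negative least-squares
problem solved (unregularized -- the regularization weight is recomputed once
at the converged parameters, since its F-statistics target depends only on
the final SSR).  Two optimizers are provided with the contracts the protocol
exposes: a bound-projected Nelder-Mead simplex with seeded random
initialization and a bound-projected Levenberg-Marquardt.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .distribution import (
    DistributionResult,
    NoiseProjector,
    RegularizationSpec,
    SGrid,
    build_design_matrix,
    fit_linear,
)
from .lamm import CellGeometry, SolutionConditions
from .scan_io import ScanSet

__all__ = ["FitSpec", "FitTrace", "optimize", "simplex_minimize", "lm_minimize", "seed_from_handshake"]

PENALTY_SSR = 1e30  # objective value assigned to failed trial points


@dataclass
class FitSpec:
    """Which nonlinear parameters float, their bounds, and the algorithm."""

    fit_meniscus: bool = False
    fit_bottom: bool = False
    fit_ffr: bool = False
    meniscus_bounds: tuple[float, float] = (0.0, 0.0)
    bottom_bounds: tuple[float, float] = (0.0, 0.0)
    ffr_bounds: tuple[float, float] = (1.0, 4.0)
    algorithm: str = "Simplex"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ("Simplex", "Levenberg-Marquardt"):
            raise ValueError(f"unknown fitting algorithm {self.algorithm!r}")


@dataclass
class FitTrace:
    steps: list[tuple[np.ndarray, float]] = field(default_factory=list)
    converged: bool = True
    text: str = ""

    @property
    def best_ssr(self) -> float:
        return min(s for _, s in self.steps) if self.steps else float("nan")


def seed_from_handshake(handshake: str) -> int:
    """Deterministic simplex-initialization seed derived from the handshake
    string (stable across platforms and runs)."""
    digest = hashlib.sha256(handshake.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _project(x: np.ndarray, bounds: list[tuple[float, float]]) -> np.ndarray:
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return np.clip(x, lo, hi)


def simplex_minimize(
    objective,
    x0: np.ndarray,
    bounds: list[tuple[float, float]],
    seed: int = 0,
    max_iter: int = 200,
    ftol: float = 1e-6,
) -> tuple[np.ndarray, FitTrace]:
    """Nelder-Mead with bound projection.

    The initial simplex perturbs x0 by a seeded random +/-2% of each bound
    span (one dominant coordinate per vertex, keeping the simplex
    non-degenerate).  Convergence: relative best-SSR improvement < ftol over
    5 consecutive iterations, or the iteration cap.  A degenerate simplex is
    restarted once before non-convergence is reported.
    """
    x0 = np.asarray(x0, dtype=float)
    n = x0.size
    rng = np.random.default_rng(seed)
    span = np.array([hi - lo for lo, hi in bounds], dtype=float)
    span = np.where(span > 0, span, np.maximum(np.abs(x0), 1.0))

    def build_simplex():
        verts = [_project(x0, bounds)]
        for j in range(n):
            v = x0.copy()
            v[j] += 0.02 * span[j] * rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0])
            v += 0.002 * span * rng.uniform(-1.0, 1.0, size=n)
            v[j] = v[j]  # dominant perturbation on coordinate j
            verts.append(_project(v, bounds))
        return np.array(verts)

    def run(verts):
        fv = np.array([objective(v) for v in verts])
        trace = FitTrace()
        stall = 0
        best_prev = fv.min()
        trace.steps.append((verts[np.argmin(fv)].copy(), float(fv.min())))
        for it in range(max_iter):
            order = np.argsort(fv)
            verts, fv = verts[order], fv[order]
            centroid = verts[:-1].mean(axis=0)
            xr = _project(centroid + (centroid - verts[-1]), bounds)
            fr = objective(xr)
            if fr < fv[0]:
                xe = _project(centroid + 2.0 * (centroid - verts[-1]), bounds)
                fe = objective(xe)
                verts[-1], fv[-1] = (xe, fe) if fe < fr else (xr, fr)
            elif fr < fv[-2]:
                verts[-1], fv[-1] = xr, fr
            else:
                xc = _project(centroid + 0.5 * (verts[-1] - centroid), bounds)
                fc = objective(xc)
                if fc < fv[-1]:
                    verts[-1], fv[-1] = xc, fc
                else:  # shrink toward best vertex
                    for k in range(1, n + 1):
                        verts[k] = _project(verts[0] + 0.5 * (verts[k] - verts[0]), bounds)
                        fv[k] = objective(verts[k])
            best = fv.min()
            trace.steps.append((verts[np.argmin(fv)].copy(), float(best)))
            if best_prev - best <= ftol * max(abs(best_prev), 1e-30):
                stall += 1
                if stall >= 5:
                    trace.converged = True
                    return verts[np.argmin(fv)], fv.min(), trace, it + 1
            else:
                stall = 0
            best_prev = min(best_prev, best)
            if np.max(np.abs(verts - verts[0])) < 1e-14:
                return None, fv.min(), trace, it + 1  # degenerate
        trace.converged = False
        order = np.argsort(fv)
        return verts[order][0], fv[order][0], trace, max_iter

    best_x, best_f, trace, n_it = run(build_simplex())
    if best_x is None:  # degenerate simplex: restart once
        best_x, best_f, trace, n_it = run(build_simplex())
        if best_x is None:
            trace.converged = False
            best_x = trace.steps[int(np.argmin([s for _, s in trace.steps]))][0]
    trace.text = (
        f"Simplex: {n_it} iterations, final SSR {trace.best_ssr:.6e}, "
        f"converged={trace.converged}"
    )
    return np.asarray(best_x), trace


def lm_minimize(
    residual_fn,
    x0: np.ndarray,
    bounds: list[tuple[float, float]],
    max_iter: int = 200,
    ftol: float = 1e-6,
) -> tuple[np.ndarray, FitTrace]:
    """Levenberg-Marquardt on a residual vector with forward-difference
    Jacobian (relative step 1e-4 of the bound span), multiplicative damping
    adaptation, and bound projection of every trial point."""
    x = _project(np.asarray(x0, dtype=float), bounds)
    n = x.size
    span = np.array([hi - lo for lo, hi in bounds], dtype=float)
    span = np.where(span > 0, span, np.maximum(np.abs(x), 1.0))
    step = 1e-4 * span
    r = np.asarray(residual_fn(x))
    ssr = float(r @ r)
    trace = FitTrace(steps=[(x.copy(), ssr)])
    mu = 1e-3
    stall = 0
    n_it = 0
    for n_it in range(1, max_iter + 1):
        J = np.empty((r.size, n))
        for j in range(n):
            xj = x.copy()
            xj[j] = min(xj[j] + step[j], bounds[j][1])
            dx = xj[j] - x[j]
            if dx == 0:  # at the upper bound: step backwards
                xj[j] = x[j] - step[j]
                dx = -step[j]
            J[:, j] = (np.asarray(residual_fn(xj)) - r) / dx
        JtJ = J.T @ J
        g = J.T @ r
        accepted = False
        for _ in range(20):
            try:
                delta = np.linalg.solve(JtJ + mu * np.diag(np.diag(JtJ)) + 1e-30 * np.eye(n), -g)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            x_new = _project(x + delta, bounds)
            r_new = np.asarray(residual_fn(x_new))
            ssr_new = float(r_new @ r_new)
            if ssr_new < ssr:
                mu = max(mu / 10.0, 1e-12)
                accepted = True
                break
            mu *= 10.0
        if not accepted:
            trace.converged = True  # no descent direction: local optimum
            break
        improvement = (ssr - ssr_new) / max(ssr, 1e-30)
        x, r, ssr = x_new, r_new, ssr_new
        trace.steps.append((x.copy(), ssr))
        if improvement < ftol:
            stall += 1
            if stall >= 5:
                break
        else:
            stall = 0
    else:
        trace.converged = False
    trace.text = (
        f"Levenberg-Marquardt: {n_it} iterations, final SSR {ssr:.6e}, "
        f"converged={trace.converged}"
    )
    return x, trace


def optimize(
    scanset: ScanSet,
    grid: SGrid,
    model: str,
    cond: SolutionConditions,
    geom: CellGeometry,
    rpm: float,
    ffr: float,
    spec: FitSpec,
    reg: RegularizationSpec | None,
    noise_flags: dict,
    n_radial: int = 150,
) -> tuple[dict, DistributionResult, FitTrace]:
    """Minimize the linear-fit SSR over the floated parameters.

    Returns the best parameters (dict with 'meniscus', 'bottom', 'ffr'),
    the final regularized distribution at those parameters, and the trace.
    With all fit flags off this performs a single linear fit at the initial
    parameters (the Run-only behavior).
    """
    names, x0, bounds = [], [], []
    if spec.fit_meniscus:
        names.append("meniscus")
        x0.append(geom.meniscus)
        bounds.append(spec.meniscus_bounds)
    if spec.fit_bottom:
        names.append("bottom")
        x0.append(geom.bottom)
        bounds.append(spec.bottom_bounds)
    if spec.fit_ffr:
        names.append("ffr")
        x0.append(ffr)
        bounds.append(spec.ffr_bounds)
    for v, (lo, hi) in zip(x0, bounds):
        if not lo <= v <= hi:
            raise ValueError("initial parameter outside its bounds")

    slices, start = [], 0
    for sc in scanset.scans:
        slices.append(slice(start, start + sc.n_points))
        start += sc.n_points
    projector = NoiseProjector(
        np.concatenate([sc.radii for sc in scanset.scans]),
        slices,
        bool(noise_flags.get("ti")),
        bool(noise_flags.get("ri")),
        bool(noise_flags.get("baseline")),
    )

    def params_of(x):
        p = {"meniscus": geom.meniscus, "bottom": geom.bottom, "ffr": ffr}
        p.update({k: float(v) for k, v in zip(names, x)})
        return p

    def linear_fit(x, regularization):
        p = params_of(x)
        g = CellGeometry(meniscus=p["meniscus"], bottom=p["bottom"])
        dm = build_design_matrix(
            grid, model, p["ffr"], cond, g, rpm, scanset, n_radial=n_radial
        )
        return fit_linear(scanset, dm, regularization, noise_flags, projector=projector)

    def objective(x):
        try:
            return linear_fit(x, None).ssr
        except Exception:
            return PENALTY_SSR

    def residual_fn(x):
        try:
            return linear_fit(x, None).residuals
        except Exception:
            return np.full(scanset.n_points, np.sqrt(PENALTY_SSR / scanset.n_points))

    if not names:
        result = linear_fit(np.array([]), reg)
        trace = FitTrace(steps=[(np.array([]), result.ssr)], converged=True)
        trace.text = f"Run: single linear fit, SSR {result.ssr:.6e}"
        return params_of(np.array([])), result, trace

    if spec.algorithm == "Simplex":
        best_x, trace = simplex_minimize(objective, np.array(x0), bounds, seed=spec.seed)
    else:
        best_x, trace = lm_minimize(residual_fn, np.array(x0), bounds)
    result = linear_fit(best_x, reg)
    return params_of(best_x), result, trace
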