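"""Sedimentation-coefficient distribution inversion.

Builds the s-grid and the kernel design matrix (Lamm solutions for c(s),
non-diffusing step boundaries for ls-g*(s)), eliminates time-invariant (TI)
and radial-invariant (RI) systematic noise by orthogonal projection, and
solves the regularized non-negative least-squares problem

    min_{c >= 0} || y - X c - T(r) - R(t) - b ||^2 + penalty(c)

The regularization weight is chosen on the F-statistics criterion: the
largest weight whose sum of squared residuals does not exceed
SSR_min * F(p; nu, nu), found by bisection on log(lambda).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import f as f_dist

from .lamm import CellGeometry, SolutionConditions, diffusion_from_s, nondiffusing_profile, solve_lamm
from .scan_io import ScanSet

__all__ = [
    "SGrid",
    "RegularizationSpec",
    "DesignMatrix",
    "DistributionResult",
    "build_grid",
    "grid_from_file",
    "write_sdist",
    "build_design_matrix",
    "NoiseProjector",
    "nnls",
    "fit_linear",
    "fold_noise",
    "integrate_distribution",
]

# Multiplier applied to the prior weight of the smallest grid node when the
# Bayesian baseline-correlation suppression is enabled.
BASELINE_SUPPRESSION_WEIGHT = 1.0e3


@dataclass(frozen=True)
class SGrid:
    """Strictly ascending grid of positive sedimentation coefficients (svedberg)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.size < 2:
            raise ValueError("s-grid needs at least 2 nodes")
        if v[0] <= 0 or np.any(np.diff(v) <= 0):
            raise ValueError("s-grid must be strictly ascending and positive")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class RegularizationSpec:
    kind: str  # 'maxent' or 'Tikhonov'
    p_value: float
    suppress_baseline: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("maxent", "Tikhonov"):
            raise ValueError(f"unknown regularization kind {self.kind!r}")
        if not 0.5 <= self.p_value <= 1.0:
            raise ValueError("regularization p-value must lie in [0.5, 1.0]")


@dataclass
class DesignMatrix:
    """Kernel columns on the concatenated (scan, radius) data grid."""

    X: np.ndarray  # (n_points, n_grid)
    grid: SGrid
    scan_slices: list[slice]  # rows belonging to each scan
    radii: np.ndarray  # concatenated radii, len n_points
    times: np.ndarray  # scan times, len n_scans

    @property
    def n_points(self) -> int:
        return int(self.X.shape[0])


@dataclass
class DistributionResult:
    grid: SGrid
    c: np.ndarray  # non-negative, signal per svedberg
    ti_noise: np.ndarray  # over distinct radii
    ti_radii: np.ndarray
    ri_noise: np.ndarray  # per scan
    baseline: float
    ssr: float
    lam: float
    fitted: np.ndarray = field(default=None, repr=False)  # per-point fit values
    residuals: np.ndarray = field(default=None, repr=False)
    warnings_: list[str] = field(default_factory=list)


def build_grid(smin: float, smax: float, resolution: int, log_spaced: bool = False) -> SGrid:
    """Linear or logarithmic s-grid inclusive of both endpoints."""
    if not 0 < smin < smax:
        raise ValueError("require 0 < smin < smax")
    if resolution < 2:
        raise ValueError("resolution must be >= 2")
    if log_spaced:
        return SGrid(np.geomspace(smin, smax, resolution))
    return SGrid(np.linspace(smin, smax, resolution))


def grid_from_file(path: str | Path) -> SGrid:
    """Read a single-column ASCII grid file (one s-value per line)."""
    values = []
    with open(path, "r", encoding="ascii") as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                values.append(float(line))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-numeric grid entry") from exc
    arr = np.array(values)
    if arr.size < 2 or np.any(np.diff(arr) <= 0):
        raise ValueError(f"{path}: grid values must be strictly ascending")
    return SGrid(arr)


def write_sdist(grid: SGrid, path: str | Path) -> Path:
    """Write the grid as a single-column file (re-readable by grid_from_file).

    The write is atomic (temp file + rename) so concurrent sessions sharing a
    data directory never observe a half-written grid."""
    import os
    import tempfile

    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".sdist.tmp")
    with os.fdopen(fd, "w", encoding="ascii", newline="\n") as fh:
        for s in grid.values:
            fh.write(f"{s:.8g}\n")
    os.replace(tmp, path)
    return path


def build_design_matrix(
    grid: SGrid,
    model: str,
    ffr: float,
    cond: SolutionConditions,
    geom: CellGeometry,
    rpm: float,
    scanset: ScanSet,
    n_radial: int = 150,
) -> DesignMatrix:
    """Evaluate one unit-loading kernel per grid s-value on every retained
    (scan, radius) point.  ``model`` is 'cofs' (Lamm kernels with D(s) from the
    frictional-ratio scaling law) or 'lsgofs' (non-diffusing step kernels)."""
    if model not in ("cofs", "lsgofs"):
        raise ValueError(f"unknown model {model!r}")
    times = scanset.times
    slices, radii_parts, start = [], [], 0
    for sc in scanset.scans:
        slices.append(slice(start, start + sc.n_points))
        radii_parts.append(sc.radii)
        start += sc.n_points
    radii_concat = np.concatenate(radii_parts)
    n_points = radii_concat.size
    X = np.empty((n_points, len(grid)))
    for j, s in enumerate(grid.values):
        if model == "cofs":
            if ffr < 1:
                raise ValueError("c(s) requires frictional ratio >= 1")
            D = diffusion_from_s(s, ffr, cond)
            sol = solve_lamm(s, D, geom, rpm, times, n_radial=n_radial)
            for k, sl in enumerate(slices):
                X[sl, j] = np.interp(radii_concat[sl], sol.radii, sol.concentration[k])
        else:
            for k, sl in enumerate(slices):
                X[sl, j] = nondiffusing_profile(s, geom, rpm, times[k], radii_concat[sl])
    return DesignMatrix(X=X, grid=grid, scan_slices=slices, radii=radii_concat, times=times)


class NoiseProjector:
    """Orthogonal projector onto the complement of the systematic-noise
    subspace (TI per distinct radius, RI per scan, uniform baseline).

    The three families are mutually collinear (each sums to the constant
    vector), so the projector is built from an orthonormal basis of the
    column space via SVD; noise coefficients are later recovered as the
    minimum-norm least-squares solution, which fixes the gauge.
    """

    def __init__(
        self,
        radii: np.ndarray,
        scan_slices: list[slice],
        ti: bool,
        ri: bool,
        baseline: bool,
    ):
        self.ti, self.ri, self.baseline = ti, ri, baseline
        radii = np.asarray(radii, dtype=float)
        n = radii.size
        # distinct radii across all scans (exact match; radii come from a
        # fixed-precision file format)
        self.distinct_radii, radius_idx = np.unique(radii, return_inverse=True)
        self.radius_idx = radius_idx
        self.scan_slices = list(scan_slices)
        self.n_scans = len(self.scan_slices)
        blocks = []
        if ti:
            Q_ti = np.zeros((n, self.distinct_radii.size))
            Q_ti[np.arange(n), radius_idx] = 1.0
            blocks.append(Q_ti)
        if ri:
            Q_ri = np.zeros((n, self.n_scans))
            for k, sl in enumerate(self.scan_slices):
                Q_ri[sl, k] = 1.0
            blocks.append(Q_ri)
        if baseline:
            blocks.append(np.ones((n, 1)))
        if blocks:
            self.Q = np.hstack(blocks)
            u, sv, _ = np.linalg.svd(self.Q, full_matrices=False)
            tol = sv.max() * max(self.Q.shape) * np.finfo(float).eps
            self.rank = int(np.count_nonzero(sv > tol))
            self.U = u[:, : self.rank]
        else:
            self.Q = np.zeros((n, 0))
            self.U = np.zeros((n, 0))
            self.rank = 0

    def project(self, a: np.ndarray) -> np.ndarray:
        """Remove the noise-subspace component of vector/matrix ``a``."""
        if self.rank == 0:
            return a
        return a - self.U @ (self.U.T @ a)

    def solve_noise(self, residual: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        """Minimum-norm noise decomposition of ``residual`` into
        (ti over distinct radii, ri per scan, baseline scalar)."""
        ti = np.zeros(self.distinct_radii.size)
        ri = np.zeros(self.n_scans)
        b = 0.0
        if self.rank == 0:
            return ti, ri, b
        coef, *_ = np.linalg.lstsq(self.Q, residual, rcond=None)
        pos = 0
        if self.ti:
            ti = coef[pos : pos + ti.size]
            pos += ti.size
        if self.ri:
            ri = coef[pos : pos + ri.size]
            pos += ri.size
        if self.baseline:
            b = float(coef[pos])
        return ti, ri, b


def nnls(G: np.ndarray, h: np.ndarray, max_iter: int | None = None) -> np.ndarray:
    """Non-negative least squares via the Lawson-Hanson active-set method,
    operating on the normal equations: minimizes ||A x - b||^2 for x >= 0
    given the Gram matrix G = A'A and h = A'b.

    The Gram formulation lets one kernel matrix serve many regularization
    weights cheaply (G is augmented, not restacked).
    """
    G = np.asarray(G, dtype=float)
    h = np.asarray(h, dtype=float)
    m = h.size
    if max_iter is None:
        max_iter = 3 * m + 30
    x = np.zeros(m)
    passive = np.zeros(m, dtype=bool)
    w = h.copy()  # negative gradient = h - G x
    tol = 10 * np.finfo(float).eps * np.linalg.norm(G, 1) * max(m, 1)
    for _ in range(max_iter):
        if passive.all() or np.max(np.where(passive, -np.inf, w)) <= tol:
            break
        passive[int(np.argmax(np.where(passive, -np.inf, w)))] = True
        for _inner in range(m + 1):
            idx = np.flatnonzero(passive)
            Gpp = G[np.ix_(idx, idx)]
            try:
                z = np.linalg.solve(Gpp, h[idx])
            except np.linalg.LinAlgError:
                z, *_ = np.linalg.lstsq(Gpp, h[idx], rcond=None)
            if np.all(z > 0):
                x = np.zeros(m)
                x[idx] = z
                break
            # step toward z, stopping at the first variable hitting zero
            xp = x[idx]
            neg = z <= 0
            alpha = np.min(xp[neg] / (xp[neg] - z[neg]))
            x[idx] = xp + alpha * (z - xp)
            passive[idx[x[idx] <= tol]] = False
            x[~passive] = 0.0
        w = h - G @ x
    return x


def _trapezoid_weights(s: np.ndarray) -> np.ndarray:
    """Quadrature weights such that sum(c * w) == trapezoid(c, s)."""
    w = np.empty_like(s)
    w[0] = (s[1] - s[0]) / 2.0
    w[-1] = (s[-1] - s[-2]) / 2.0
    w[1:-1] = (s[2:] - s[:-2]) / 2.0
    return w


def _second_difference(n: int) -> np.ndarray:
    """Second-difference operator with natural ends, (n-2) x n."""
    L = np.zeros((max(n - 2, 0), n))
    for i in range(n - 2):
        L[i, i : i + 3] = (1.0, -2.0, 1.0)
    return L


def _ssr_of(c, Gram, h, yty):
    return float(yty - 2.0 * h @ c + c @ Gram @ c)


def fit_linear(
    data: ScanSet,
    dm: DesignMatrix,
    reg: RegularizationSpec | None,
    noise_flags: dict | None = None,
    projector: NoiseProjector | None = None,
) -> DistributionResult:
    """Regularized non-negative inversion with algebraic TI/RI/baseline
    elimination.

    ``noise_flags`` holds booleans 'ti', 'ri', 'baseline'.  Passing
    ``reg=None`` solves the unregularized problem (lambda -> 0), which is the
    objective used inside the nonlinear parameter search.
    """
    noise_flags = noise_flags or {}
    flags = {k: bool(noise_flags.get(k, False)) for k in ("ti", "ri", "baseline")}
    y = np.concatenate([sc.signal for sc in data.scans])
    if y.size != dm.n_points:
        raise ValueError("design matrix rows do not match retained data points")
    proj = projector or NoiseProjector(
        dm.radii, dm.scan_slices, flags["ti"], flags["ri"], flags["baseline"]
    )
    Py = proj.project(y)
    PX = proj.project(dm.X)
    n_grid = len(dm.grid)
    warn_list: list[str] = []

    # c(s) is a signal density per svedberg: the model is
    # y ~ sum_j c_j w_j K_j with trapezoidal quadrature weights w_j, so the
    # solved coefficients integrate (trapezoidally) to the total loading.
    w_quad = _trapezoid_weights(dm.grid.values)
    PXw = PX * w_quad

    yty = float(Py @ Py)
    Gram = PXw.T @ PXw
    h = PXw.T @ Py

    if np.sqrt(yty / max(y.size, 1)) < 1e-12:
        warn_list.append("data is all-zero after systematic-noise elimination")
        warnings.warn(warn_list[-1], stacklevel=2)
        c = np.zeros(n_grid)
        lam = 0.0
    elif reg is None:
        c = nnls(Gram, h)
        lam = 0.0
    else:
        c, lam, reg_warn = _solve_regularized(Gram, h, yty, dm.grid, reg, y.size, proj.rank)
        warn_list.extend(reg_warn)

    fitted_model = dm.X @ (c * w_quad)
    ti, ri, b = proj.solve_noise(y - fitted_model)
    noise = np.zeros_like(y)
    if proj.ti:
        noise += ti[proj.radius_idx]
    if proj.ri:
        for k, sl in enumerate(dm.scan_slices):
            noise[sl] += ri[k]
    noise += b
    fitted = fitted_model + noise
    residuals = y - fitted
    return DistributionResult(
        grid=dm.grid,
        c=c,
        ti_noise=ti,
        ti_radii=proj.distinct_radii,
        ri_noise=ri,
        baseline=b,
        ssr=float(residuals @ residuals),
        lam=lam,
        fitted=fitted,
        residuals=residuals,
        warnings_=warn_list,
    )


def _solve_regularized(Gram, h, yty, grid, reg, n_points, n_noise_params):
    """Choose lambda by bisection on log(lambda) against the F-statistics
    target SSR_min * F(p; nu, nu), nu = points - model parameters."""
    n_grid = len(grid)
    c_min = nnls(Gram, h)
    ssr_min = _ssr_of(c_min, Gram, h, yty)
    nu = max(n_points - (n_grid + n_noise_params), 1)
    f_ratio = float(f_dist.ppf(reg.p_value, nu, nu))
    target = ssr_min * f_ratio
    warn_list: list[str] = []

    L = _second_difference(n_grid)
    if reg.suppress_baseline:
        e0 = np.zeros((1, n_grid))
        e0[0, 0] = np.sqrt(BASELINE_SUPPRESSION_WEIGHT)
        L = np.vstack([L, e0])
    LtL = L.T @ L
    # normalized penalty scale so the bisection bracket is dimensionless
    scale = np.sqrt(np.trace(Gram)) / max(np.sqrt(np.trace(LtL)), 1e-30)

    mean_level = None
    if reg.kind == "maxent":
        total = np.trapezoid(np.maximum(c_min, 0.0), grid.values)
        span = grid.values[-1] - grid.values[0]
        mean_level = max(total / span, 1e-12)

    def solve_at(lam: float) -> tuple[np.ndarray, float]:
        lam_eff2 = (lam * scale) ** 2
        if reg.kind == "Tikhonov":
            c = nnls(Gram + lam_eff2 * LtL, h)
        else:
            c = _maxent_solve(Gram, h, lam_eff2, mean_level, reg, n_grid)
        return c, _ssr_of(c, Gram, h, yty)

    lo, hi = 1e-6, 1e6
    c_lo, ssr_lo = solve_at(lo)
    if ssr_lo >= target:
        return c_lo, lo, warn_list
    c_hi, ssr_hi = solve_at(hi)
    if ssr_hi <= target:
        warn_list.append("regularization target SSR unreachable; returning bracket end")
        warnings.warn(warn_list[-1], stacklevel=3)
        return c_hi, hi, warn_list
    best = (c_lo, lo)
    for _ in range(60):
        mid = np.sqrt(lo * hi)
        c_mid, ssr_mid = solve_at(mid)
        if ssr_mid <= target:
            best = (c_mid, mid)
            lo = mid
            if ssr_mid >= target * 0.999:
                break
        else:
            hi = mid
        if hi / lo < 1.0 + 1e-4:
            break
    return best[0], best[1], warn_list


def _maxent_solve(Gram, h, lam_eff2, mean_level, reg, n_grid, max_iter=30, tol=1e-4):
    """Maximum-entropy penalty lam * sum c ln(c/prior) via iterated local
    quadratic approximation; each inner step is an NNLS solve.  The prior is
    uniform at the mean signal level; Bayesian baseline-correlation
    suppression lowers the prior expectation of the smallest grid node."""
    prior = np.full(n_grid, mean_level)
    if reg.suppress_baseline:
        prior[0] /= BASELINE_SUPPRESSION_WEIGHT
    c = prior.copy()
    for _ in range(max_iter):
        c_safe = np.maximum(c, 1e-8 * mean_level)
        # entropy ~ const + g.(c - c0) + (c - c0)^2 / (2 c0); complete the square
        g = np.log(c_safe / prior)
        d = lam_eff2 / (2.0 * c_safe)
        target = c_safe - c_safe * g
        c_new = nnls(Gram + np.diag(2.0 * d), h + 2.0 * d * target)
        if np.max(np.abs(c_new - c)) <= tol * (np.max(np.abs(c)) + 1e-12):
            return c_new
        c = c_new
    return c


def fold_noise(result: DistributionResult, scanset: ScanSet) -> tuple[str, str]:
    """Render the systematic-noise estimates as two-column file contents:
    TI as (radius, value) rows and RI as (scan time, value) rows."""
    ti_lines = [f"{r:.6f}\t{v:.6e}" for r, v in zip(result.ti_radii, result.ti_noise)]
    ri_lines = [
        f"{t:.2f}\t{v:.6e}" for t, v in zip(scanset.times, result.ri_noise)
    ]
    return "\n".join(ti_lines) + "\n", "\n".join(ri_lines) + "\n"


def integrate_distribution(
    result: DistributionResult, s_lo: float, s_hi: float
) -> tuple[float, float, float]:
    """Trapezoidal integration of c(s) over [s_lo, s_hi].

    Returns (fraction of total signal in percent, signal-weighted mean s over
    the window, integrated signal).  The weighted mean is NaN when the window
    contains no mass.
    """
    s = result.grid.values
    if s_lo >= s_hi:
        raise ValueError("empty integration window")
    if s_hi < s[0] or s_lo > s[-1]:
        raise ValueError("integration window outside the grid span")
    lo = max(s_lo, s[0])
    hi = min(s_hi, s[-1])
    inner = s[(s > lo) & (s < hi)]
    sw_nodes = np.concatenate([[lo], inner, [hi]])
    cw = np.interp(sw_nodes, s, result.c)
    load = float(np.trapezoid(cw, sw_nodes))
    total = float(np.trapezoid(result.c, s))
    fraction = 100.0 * load / total if total > 0 else 0.0
    if load > 0:
        sw = float(np.trapezoid(cw * sw_nodes, sw_nodes) / load)
    else:
        sw = float("nan")
    return fraction, sw, load
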