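"""Fit-quality statistics: global and per-scan rmsd, Wald-Wolfowitz runs-test
Z for residual randomness, and a Gaussianity score for the residual
histogram.

The histogram score H is defined here as the root-mean-square deviation
between the unit-area histogram of the *standardized* residuals (Scott's-rule
bins) and the standard normal density at the bin centers.  H = 0 means exact
agreement; larger values mean a less Gaussian residual distribution.  This is
a documented convention of this engine, not a published formula, so only its
qualitative behavior (ordering, scale invariance) is guaranteed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FitStatistics", "rmsd_stats", "runs_test_z", "histogram_h", "UNDEFINED"]

UNDEFINED = float("nan")


@dataclass
class FitStatistics:
    RMSD: float
    RMSD_points: int
    RMSD_SSR: float
    RunsTestZ: float = UNDEFINED
    HistogramH: float = UNDEFINED
    per_scan_rmsd: list[tuple[int, float]] = None


def rmsd_stats(residuals: list[np.ndarray], scan_ids: list[int] | None = None) -> FitStatistics:
    """Global and per-scan root-mean-square deviations.

    ``residuals`` holds one residual vector per scan; ``scan_ids`` optionally
    labels them (defaults to 1-based position).
    """
    if not residuals:
        raise ValueError("no residuals")
    if scan_ids is None:
        scan_ids = list(range(1, len(residuals) + 1))
    per_scan = []
    ssr_total, n_total = 0.0, 0
    for sid, r in zip(scan_ids, residuals):
        r = np.asarray(r, dtype=float)
        ssr = float(r @ r)
        per_scan.append((sid, float(np.sqrt(ssr / r.size))))
        ssr_total += ssr
        n_total += r.size
    return FitStatistics(
        RMSD=float(np.sqrt(ssr_total / n_total)),
        RMSD_points=n_total,
        RMSD_SSR=ssr_total,
        per_scan_rmsd=per_scan,
    )


def runs_test_z(residuals: np.ndarray) -> float:
    """Wald-Wolfowitz runs test on the residual sign sequence.

    Z = (R - mu) / sigma with mu = 2 n+ n- / n + 1 and
    sigma^2 = 2 n+ n- (2 n+ n- - n) / (n^2 (n - 1)), where R is the number of
    runs.  Zeros are excluded.  The caller fixes the ordering (scan by scan,
    ascending radius within each scan).  Returns NaN for single-sign
    sequences, where the statistic is undefined.
    """
    r = np.asarray(residuals, dtype=float)
    signs = np.sign(r[r != 0.0])
    n_pos = int(np.count_nonzero(signs > 0))
    n_neg = int(np.count_nonzero(signs < 0))
    n = n_pos + n_neg
    if n_pos == 0 or n_neg == 0 or n < 2:
        return UNDEFINED
    runs = 1 + int(np.count_nonzero(signs[1:] != signs[:-1]))
    mu = 2.0 * n_pos * n_neg / n + 1.0
    var = 2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return UNDEFINED
    return float((runs - mu) / np.sqrt(var))


def histogram_h(residuals: np.ndarray) -> float:
    """Gaussianity score of the pooled residual histogram (see module doc).

    Residuals are standardized first, making H invariant under positive
    rescaling.  Requires at least 30 residuals; returns NaN otherwise.
    """
    r = np.asarray(residuals, dtype=float).ravel()
    if r.size < 30:
        return UNDEFINED
    sd = np.std(r)
    if sd == 0:
        return UNDEFINED
    z = (r - np.mean(r)) / sd
    edges = np.histogram_bin_edges(z, bins="scott")
    if edges.size < 3:
        return UNDEFINED
    hist, edges = np.histogram(z, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    gauss = np.exp(-0.5 * centers**2) / np.sqrt(2.0 * np.pi)
    return float(np.sqrt(np.mean((hist - gauss) ** 2)))
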