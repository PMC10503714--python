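"""Reading, writing and preprocessing of SV-AUC scan files.

Scan files follow the customary analytical-ultracentrifuge ASCII layout:
a free-text description line, a header line with acquisition metadata, and
radius/signal pairs, one per line.  Files are numbered ``NNNNN.<ext>`` with
five-digit zero padding; the extension identifies cell and optical channel.

Dialect (version 1)::

    line 1:  free-text description
    line 2:  <type char> <cell> <temperature C> <rpm> <time s> <w2t 1/s> <wavelength> <replicates>
    line 3+: <radius cm> <signal>

Radii are written with 5 decimals, signals with 6.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "Scan",
    "ScanSet",
    "MetadataAggregate",
    "ScanFormatError",
    "ScanDataError",
    "MissingScanError",
    "enumerate_scan_paths",
    "read_scan",
    "write_scan",
    "load_scanset",
    "filter_spikes",
    "restrict_fit_range",
    "aggregate_metadata",
]


class ScanFormatError(ValueError):
    """Raised when a scan file header or body cannot be parsed."""


class ScanDataError(ValueError):
    """Raised when parsed scan data violates basic expectations."""


class MissingScanError(FileNotFoundError):
    """Raised when enumerated scan files are absent, listing the missing names."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__("missing scan files: " + ", ".join(self.missing))


@dataclass
class Scan:
    """One radial scan: header metadata plus the radius/signal trace."""

    description: str
    data_type: str
    cell: int
    temperature: float  # degC
    rpm: float
    time_s: float
    w2t: float  # accumulated omega^2 t, 1/s
    wavelength: float
    radii: np.ndarray  # cm, strictly increasing
    signal: np.ndarray
    replicates: int = 1

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.radii.size != self.signal.size:
            raise ScanDataError("radius and signal vectors differ in length")
        if self.radii.size < 2:
            raise ScanDataError("scan holds fewer than 2 data points")
        if not np.all(np.diff(self.radii) > 0):
            raise ScanDataError("radii are not strictly increasing")
        if self.rpm <= 0:
            raise ScanDataError("rotor speed must be positive")
        if self.time_s < 0 or self.w2t < 0:
            raise ScanDataError("scan time and w2t must be non-negative")

    @property
    def n_points(self) -> int:
        return int(self.radii.size)


@dataclass
class ScanSet:
    """Time-ordered collection of scans from one channel."""

    scans: list[Scan]
    channel: str
    source_paths: list[Path] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.scans:
            raise ScanDataError("empty scan set")
        times = [sc.time_s for sc in self.scans]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ScanDataError("scan times are not strictly increasing")
        w2ts = [sc.w2t for sc in self.scans]
        if any(b < a for a, b in zip(w2ts, w2ts[1:])):
            raise ScanDataError("w2t decreases across the time-ordered scan set")
        rpms = {sc.rpm for sc in self.scans}
        if len(rpms) > 1:
            warnings.warn(
                "rotor speed differs between scan headers; "
                f"using first scan's value {self.scans[0].rpm}",
                stacklevel=2,
            )
        dtypes = {sc.data_type for sc in self.scans}
        if len(dtypes) > 1:
            raise ScanDataError("scans mix data types: " + ", ".join(sorted(dtypes)))

    def __len__(self) -> int:
        return len(self.scans)

    @property
    def times(self) -> np.ndarray:
        return np.array([sc.time_s for sc in self.scans])

    @property
    def n_points(self) -> int:
        return sum(sc.n_points for sc in self.scans)


@dataclass
class MetadataAggregate:
    """Per-run header summary reported alongside the fit results."""

    RotorSpeed: float
    Wavelength: float
    tLastScan: float
    w2tLastScan: float
    TemperatureStart: float
    TemperatureEnd: float
    TemperatureAverage: float
    TemperatureDiffMaxMin: float
    CheckTimeStamps: bool


def enumerate_scan_paths(
    directory: str | Path, channel: str, first: int, last: int, interval: int
) -> list[Path]:
    """Build the list of scan-file paths ``NNNNN.<channel>`` for the requested range.

    Numbers run ``first, first+interval, ...`` up to ``last`` inclusive.  All
    enumerated files must exist; otherwise :class:`MissingScanError` is raised
    naming every absent file.
    """
    if first < 1 or last < first or interval < 1:
        raise ValueError("scan range requires first >= 1, last >= first, interval >= 1")
    directory = Path(directory)
    ext = channel.lower().lstrip(".")
    paths = [directory / f"{n:05d}.{ext}" for n in range(first, last + 1, interval)]
    missing = [p.name for p in paths if not p.is_file()]
    if missing:
        raise MissingScanError(missing)
    return paths


def read_scan(path: str | Path) -> Scan:
    """Parse one scan file in the dialect documented in the module header."""
    path = Path(path)
    with open(path, "r", encoding="ascii") as fh:
        lines = fh.read().splitlines()
    if len(lines) < 4:
        raise ScanFormatError(f"{path.name}: too short to be a scan file")
    description = lines[0]
    tokens = lines[1].split()
    if len(tokens) != 8:
        raise ScanFormatError(
            f"{path.name}: header line must hold 8 fields, found {len(tokens)}"
        )
    try:
        data_type = tokens[0]
        cell = int(tokens[1])
        temperature = float(tokens[2])
        rpm = float(tokens[3])
        time_s = float(tokens[4])
        w2t = float(tokens[5])
        wavelength = float(tokens[6])
        replicates = int(tokens[7])
    except ValueError as exc:
        raise ScanFormatError(f"{path.name}: unparseable header field: {exc}") from exc
    radii, signal = [], []
    for ln, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ScanFormatError(f"{path.name}:{ln}: expected radius/signal pair")
        try:
            radii.append(float(parts[0]))
            signal.append(float(parts[1]))
        except ValueError as exc:
            raise ScanFormatError(f"{path.name}:{ln}: non-numeric data") from exc
    return Scan(
        description=description,
        data_type=data_type,
        cell=cell,
        temperature=temperature,
        rpm=rpm,
        time_s=time_s,
        w2t=w2t,
        wavelength=wavelength,
        radii=np.array(radii),
        signal=np.array(signal),
        replicates=replicates,
    )


def write_scan(scan: Scan, path: str | Path) -> Path:
    """Write a scan in the dialect read by :func:`read_scan` (round-trip exact
    at the written precision)."""
    path = Path(path)
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        fh.write(scan.description + "\n")
        fh.write(
            f"{scan.data_type} {scan.cell} {scan.temperature:.2f} {scan.rpm:g} "
            f"{scan.time_s:.1f} {scan.w2t:.6e} {scan.wavelength:.1f} {scan.replicates}\n"
        )
        for r, y in zip(scan.radii, scan.signal):
            fh.write(f"{r:.5f} {y:.6f}\n")
    return path


def load_scanset(
    directory: str | Path, channel: str, first: int, last: int, interval: int
) -> ScanSet:
    """Enumerate and read a scan range into a :class:`ScanSet` (ordered by
    scan number)."""
    paths = enumerate_scan_paths(directory, channel, first, last, interval)
    scans = [read_scan(p) for p in paths]
    return ScanSet(scans=scans, channel=channel.lower().lstrip("."), source_paths=paths)


def filter_spikes(scan: Scan, threshold: float) -> tuple[Scan, int]:
    """Remove isolated data spikes from a scan.

    An interior point is a spike when it deviates from *both* neighbours in
    the same direction by more than ``threshold`` signal units.  Spike points
    are deleted together with their radii; endpoints are never removed.  The
    rule is applied to a fixed point (removal can expose new isolated
    outliers), which makes the filter idempotent.  Returns the filtered scan
    and the total number of points removed.
    """
    if threshold <= 0:
        raise ValueError("spike threshold must be positive")
    removed = 0
    current = scan
    while True:
        y = current.signal
        d_prev = y[1:-1] - y[:-2]
        d_next = y[1:-1] - y[2:]
        spike = (np.sign(d_prev) == np.sign(d_next)) & (
            (np.abs(d_prev) > threshold) & (np.abs(d_next) > threshold)
        )
        n = int(np.count_nonzero(spike))
        if n == 0:
            return current, removed
        keep = np.ones(y.size, dtype=bool)
        keep[1:-1] = ~spike
        current = replace(current, radii=current.radii[keep], signal=current.signal[keep])
        removed += n


def filter_spikes_set(scanset: ScanSet, threshold: float) -> tuple[ScanSet, int]:
    """Apply :func:`filter_spikes` to every scan of a set."""
    out, total = [], 0
    for sc in scanset.scans:
        fsc, n = filter_spikes(sc, threshold)
        out.append(fsc)
        total += n
    return (
        ScanSet(scans=out, channel=scanset.channel, source_paths=scanset.source_paths),
        total,
    )


def restrict_fit_range(scanset: ScanSet, left: float, right: float) -> ScanSet:
    """Keep, in every scan, exactly the points with ``left <= radius <= right``."""
    if left >= right:
        raise ValueError("left fit limit must be smaller than right fit limit")
    out = []
    for sc in scanset.scans:
        mask = (sc.radii >= left) & (sc.radii <= right)
        if np.count_nonzero(mask) < 2:
            raise ScanDataError(
                f"fit range [{left}, {right}] leaves fewer than 2 points "
                f"in scan at t={sc.time_s} s"
            )
        out.append(replace(sc, radii=sc.radii[mask], signal=sc.signal[mask]))
    return ScanSet(scans=out, channel=scanset.channel, source_paths=scanset.source_paths)


def aggregate_metadata(scanset: ScanSet) -> MetadataAggregate:
    """Summarize header metadata across the set: rotor speed and wavelength
    from the first scan, temperature statistics over all scans, time and
    w2t of the last scan, and whether filesystem timestamps were readable."""
    temps = np.array([sc.temperature for sc in scanset.scans])
    check = bool(scanset.source_paths) and all(
        _mtime_readable(p) for p in scanset.source_paths
    )
    first, last = scanset.scans[0], scanset.scans[-1]
    return MetadataAggregate(
        RotorSpeed=first.rpm,
        Wavelength=first.wavelength,
        tLastScan=last.time_s,
        w2tLastScan=last.w2t,
        TemperatureStart=first.temperature,
        TemperatureEnd=last.temperature,
        TemperatureAverage=float(np.mean(temps)),
        TemperatureDiffMaxMin=float(np.max(temps) - np.min(temps)),
        CheckTimeStamps=check,
    )


def _mtime_readable(path: Path) -> bool:
    try:
        os.path.getmtime(path)
        return True
    except OSError:
        return False
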