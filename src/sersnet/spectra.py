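"""Spectrum data model, preprocessing, peak statistics, and file I/O.

SERS (surface-enhanced Raman) spectra are intensity series on a uniform
wavenumber grid. The portable-spectrometer acquisition range used throughout
this package is 300-1800 cm^-1; the default grid discretises it at 2 cm^-1
(751 points), which is typical for a 785 nm portable instrument.

Intensities are in arbitrary units (a.u.). Raw spectra are non-negative;
normalisation for network input (min-max or unit vector) may be applied via
:func:`normalize`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavenumberGrid",
    "RamanSpectrum",
    "PeakQuery",
    "DEFAULT_GRID",
    "DegenerateSpectrumError",
    "SpectrumParseError",
    "resample",
    "normalize",
    "peak_intensity",
    "rsd",
    "read_spectra",
    "write_spectra",
    "read_manifest",
    "write_manifest",
]


class DegenerateSpectrumError(ValueError):
    """Raised when an operation is undefined on a constant spectrum."""


class SpectrumParseError(ValueError):
    """Raised when a spectrum file is malformed; names the offending record."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform wavenumber axis in cm^-1, from ``start`` to ``stop`` inclusive."""

    start: float = 300.0
    stop: float = 1800.0
    n_points: int = 751

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError(f"grid start ({self.start}) must be < stop ({self.stop})")
        if self.n_points < 2:
            raise ValueError("grid needs at least 2 points")

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.n_points)

    @property
    def spacing(self) -> float:
        return (self.stop - self.start) / (self.n_points - 1)

    def index_of(self, wavenumber: float) -> int:
        """Index of the grid point nearest to ``wavenumber``."""
        return int(round((wavenumber - self.start) / self.spacing))


#: 300-1800 cm^-1 at 2 cm^-1 spacing.
DEFAULT_GRID = WavenumberGrid(300.0, 1800.0, 751)


@dataclass
class RamanSpectrum:
    """One spectrum: intensities (a.u.) on a :class:`WavenumberGrid`.

    ``label`` is the mixture-class identifier (``None`` for unlabelled data);
    ``sample_id``/``replicate_id`` identify the physical sample and the
    repeated acquisition.
    """

    grid: WavenumberGrid
    intensities: np.ndarray
    label: str | None = None
    sample_id: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1 or len(self.intensities) != self.grid.n_points:
            raise ValueError(
                f"intensity length {self.intensities.shape} does not match grid "
                f"({self.grid.n_points} points)"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")


@dataclass(frozen=True)
class PeakQuery:
    """A characteristic-peak window: ``center`` +/- ``window_half_width`` cm^-1."""

    center: float
    window_half_width: float = 10.0

    def __post_init__(self) -> None:
        if self.window_half_width <= 0:
            raise ValueError("window_half_width must be positive")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def resample(spectrum: RamanSpectrum, target: WavenumberGrid) -> RamanSpectrum:
    """Linearly interpolate onto ``target``; outside the source range the
    nearest edge value is held (clamped).

    Raises ``ValueError`` if the two ranges are disjoint.
    """
    src = spectrum.grid
    if src.stop < target.start or target.stop < src.start:
        raise ValueError(
            f"incompatible grids: source [{src.start}, {src.stop}] and "
            f"target [{target.start}, {target.stop}] do not overlap"
        )
    values = np.interp(target.wavenumbers, src.wavenumbers, spectrum.intensities)
    return replace(spectrum, grid=target, intensities=values)


def normalize(spectrum: RamanSpectrum, method: str = "minmax") -> RamanSpectrum:
    """Per-spectrum intensity scaling: ``minmax`` to [0, 1], ``vector`` to unit
    Euclidean norm, or ``none``.

    A constant spectrum carries no peak pattern, so minmax/vector raise
    :class:`DegenerateSpectrumError`.
    """
    x = spectrum.intensities
    if method == "none":
        return replace(spectrum, intensities=x.copy())
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise DegenerateSpectrumError(
            f"constant spectrum (value {lo}) cannot be normalized with '{method}'"
        )
    if method == "minmax":
        return replace(spectrum, intensities=(x - lo) / (hi - lo))
    if method == "vector":
        return replace(spectrum, intensities=x / np.linalg.norm(x))
    raise ValueError(f"unknown normalization method: {method!r}")


# ---------------------------------------------------------------------------
# Peak statistics
# ---------------------------------------------------------------------------

def peak_intensity(spectrum: RamanSpectrum, query: PeakQuery) -> float:
    """Maximum raw intensity within the query window (no baseline correction)."""
    grid = spectrum.grid
    lo = query.center - query.window_half_width
    hi = query.center + query.window_half_width
    if lo < grid.start or hi > grid.stop:
        raise ValueError(
            f"peak window [{lo}, {hi}] cm^-1 extends outside grid "
            f"[{grid.start}, {grid.stop}]"
        )
    w = grid.wavenumbers
    mask = (w >= lo) & (w <= hi)
    return float(spectrum.intensities[mask].max())


def rsd(values: Sequence[float]) -> float:
    """Relative standard deviation in percent: 100 * sd / mean.

    Uses the sample (n-1) standard deviation; this is the replicate-stability
    statistic reported for characteristic-peak intensities.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("RSD needs at least 2 values")
    mean = x.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / mean)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_LONG_COLUMNS = ["sample_id", "replicate_id", "label", "wavenumber_cm1", "intensity"]


def write_spectra(spectra: Iterable[RamanSpectrum], path: str | Path) -> None:
    """Write spectra as long-format CSV (one row per grid point per spectrum)."""
    frames = []
    for s in spectra:
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": s.sample_id,
                    "replicate_id": s.replicate_id,
                    "label": s.label if s.label is not None else "",
                    "wavenumber_cm1": s.grid.wavenumbers,
                    "intensity": s.intensities,
                }
            )
        )
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=_LONG_COLUMNS)
    df.to_csv(path, index=False, float_format="%.9g")


def read_spectra(path: str | Path) -> list[RamanSpectrum]:
    """Read spectra from CSV.

    Accepts the long format written by :func:`write_spectra` and, as a
    convenience, a wide matrix (first column wavenumber, one column per
    spectrum; column headers become sample ids).
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "replicate_id": str, "label": str})
    if set(_LONG_COLUMNS).issubset(df.columns):
        return _read_long(df, path)
    return _read_wide(df, path)


def _grid_from_wavenumbers(w: np.ndarray, record: str, path: str | Path) -> WavenumberGrid:
    if len(w) < 2:
        raise SpectrumParseError(f"{path}: record {record!r} has fewer than 2 points")
    dw = np.diff(w)
    if np.any(dw <= 0):
        raise SpectrumParseError(
            f"{path}: record {record!r} has non-monotone wavenumbers"
        )
    if not np.allclose(dw, dw[0], rtol=1e-6, atol=1e-9):
        raise SpectrumParseError(
            f"{path}: record {record!r} has non-uniform wavenumber spacing"
        )
    return WavenumberGrid(float(w[0]), float(w[-1]), len(w))


def _read_long(df: pd.DataFrame, path: str | Path) -> list[RamanSpectrum]:
    spectra: list[RamanSpectrum] = []
    if df.empty:
        return spectra
    expected_len: int | None = None
    for (sid, rid), group in df.groupby(["sample_id", "replicate_id"], sort=False):
        record = f"{sid}/{rid}"
        w = group["wavenumber_cm1"].to_numpy(dtype=float)
        y = group["intensity"].to_numpy(dtype=float)
        if np.any(~np.isfinite(y)):
            raise SpectrumParseError(f"{path}: record {record!r} has non-finite intensity")
        grid = _grid_from_wavenumbers(w, record, path)
        if expected_len is None:
            expected_len = len(w)
        elif len(w) != expected_len:
            raise SpectrumParseError(
                f"{path}: record {record!r} has {len(w)} points, expected {expected_len}"
            )
        labels = group["label"].fillna("")
        label = str(labels.iloc[0]) or None
        spectra.append(
            RamanSpectrum(grid=grid, intensities=y, label=label,
                          sample_id=str(sid), replicate_id=str(rid))
        )
    return spectra


def _read_wide(df: pd.DataFrame, path: str | Path) -> list[RamanSpectrum]:
    if df.shape[1] < 2:
        raise SpectrumParseError(
            f"{path}: expected long columns {_LONG_COLUMNS} or a wide matrix "
            "with a wavenumber column plus one column per spectrum"
        )
    w = df.iloc[:, 0].to_numpy(dtype=float)
    grid = _grid_from_wavenumbers(w, df.columns[0], path)
    spectra = []
    for col in df.columns[1:]:
        y = df[col].to_numpy(dtype=float)
        if np.any(~np.isfinite(y)):
            raise SpectrumParseError(f"{path}: record {col!r} has non-finite intensity")
        spectra.append(
            RamanSpectrum(grid=grid, intensities=y, sample_id=str(col), replicate_id="r0")
        )
    return spectra


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
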