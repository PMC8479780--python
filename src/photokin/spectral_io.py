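"""Containers and I/O for spectra and time–wavelength absorbance matrices.

The on-disk dialect for matrices is plain tab-separated text: the first row
holds the wavelength grid (nm), the first column holds the time grid, and the
corner cell carries a ``<time_unit>:<value_unit>`` tag (e.g. ``s:OD`` or
``ps:mOD``).  Spectra are two-column TSV with a one-line ``#`` header.  Both
formats round-trip losslessly at >= 9 significant digits and diff cleanly.

Also hosts the small measurement-protocol utilities used around the raw data:
pixel binning along the wavelength axis, logarithmic binning along the time
axis, Beer–Lambert concentration checks, and mixing arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

__all__ = [
    "Spectrum",
    "TimeResolvedMatrix",
    "MatrixFormatError",
    "read_spectrum",
    "write_spectrum",
    "read_matrix",
    "write_matrix",
    "bin_wavelength",
    "bin_time_log",
    "concentration_from_absorbance",
    "MixingResult",
    "mixing_concentrations",
]

_FMT = "%.17g"  # full float64 round-trip precision


class MatrixFormatError(ValueError):
    """Raised when a delimited matrix/spectrum file violates the dialect."""


@dataclass
class Spectrum:
    """A single spectrum: absorbance (OD) or difference absorbance (mOD) vs nm.

    ``wavelengths`` must be strictly increasing and the same length as
    ``values``.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    label: str = ""
    units: str = "OD"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.ndim != 1 or self.values.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D")
        if self.wavelengths.size != self.values.size:
            raise ValueError(
                f"length mismatch: {self.wavelengths.size} wavelengths vs "
                f"{self.values.size} values"
            )
        if self.wavelengths.size and np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    def at(self, wavelength: float) -> float:
        """Linearly interpolated value at an arbitrary wavelength (nm)."""
        return float(np.interp(wavelength, self.wavelengths, self.values))

    def __eq__(self, other: object) -> bool:  # value semantics for tests
        if not isinstance(other, Spectrum):
            return NotImplemented
        return (
            np.array_equal(self.wavelengths, other.wavelengths)
            and np.array_equal(self.values, other.values)
            and self.units == other.units
        )


@dataclass
class TimeResolvedMatrix:
    """Time x wavelength matrix of (difference) absorbance.

    ``times`` (s or ps, see ``time_unit``) and ``wavelengths`` (nm) are
    strictly increasing; ``values`` has shape ``(len(times),
    len(wavelengths))``.
    """

    times: np.ndarray
    wavelengths: np.ndarray
    values: np.ndarray
    time_unit: str = "s"
    value_unit: str = "OD"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.wavelengths.ndim != 1:
            raise ValueError("times and wavelengths must be 1-D")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.values.shape != (self.times.size, self.wavelengths.size):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{self.times.size} times x {self.wavelengths.size} wavelengths"
            )
        if not self.time_unit or not self.value_unit:
            raise ValueError("unit tags must be non-empty")

    def slice_at_time(self, t: float) -> Spectrum:
        """Spectrum at the grid time nearest to ``t`` (no interpolation)."""
        i = int(np.argmin(np.abs(self.times - t)))
        return Spectrum(
            self.wavelengths,
            self.values[i].copy(),
            label=f"t={self.times[i]:g} {self.time_unit}",
            units=self.value_unit,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TimeResolvedMatrix):
            return NotImplemented
        return (
            np.array_equal(self.times, other.times)
            and np.array_equal(self.wavelengths, other.wavelengths)
            and np.array_equal(self.values, other.values)
            and self.time_unit == other.time_unit
            and self.value_unit == other.value_unit
        )


# ---------------------------------------------------------------------------
# file I/O


def write_spectrum(spectrum: Spectrum, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# wavelength_nm\t{spectrum.units}\t{spectrum.label}\n")
        for wl, v in zip(spectrum.wavelengths, spectrum.values):
            fh.write(f"{_FMT % wl}\t{_FMT % v}\n")


def read_spectrum(path) -> Spectrum:
    units, label = "OD", ""
    wls, vals = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                parts = line.lstrip("# ").split("\t")
                if len(parts) >= 2:
                    units = parts[1]
                if len(parts) >= 3:
                    label = parts[2]
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise MatrixFormatError(
                    f"{path}: line {lineno} has {len(parts)} columns, expected 2"
                )
            wls.append(float(parts[0]))
            vals.append(float(parts[1]))
    try:
        return Spectrum(np.array(wls), np.array(vals), label=label, units=units)
    except ValueError as exc:
        raise MatrixFormatError(f"{path}: {exc}") from exc


def write_matrix(matrix: TimeResolvedMatrix, path) -> None:
    """Write a matrix in the documented TSV dialect (corner = unit tag)."""
    with open(path, "w") as fh:
        corner = f"{matrix.time_unit}:{matrix.value_unit}"
        fh.write(corner + "\t" + "\t".join(_FMT % w for w in matrix.wavelengths) + "\n")
        for t, row in zip(matrix.times, matrix.values):
            fh.write(_FMT % t + "\t" + "\t".join(_FMT % v for v in row) + "\n")


def read_matrix(path) -> TimeResolvedMatrix:
    """Read a matrix written by :func:`write_matrix`.

    Raises :class:`MatrixFormatError` naming the offending row/column for
    ragged rows or non-monotonic axes.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise MatrixFormatError(f"{path}: empty file")
    header = lines[0].split("\t")
    corner = header[0]
    if ":" not in corner:
        raise MatrixFormatError(
            f"{path}: corner cell {corner!r} is not a 'time_unit:value_unit' tag"
        )
    time_unit, value_unit = corner.split(":", 1)
    try:
        wavelengths = np.array([float(x) for x in header[1:]])
    except ValueError as exc:
        raise MatrixFormatError(f"{path}: bad wavelength header: {exc}") from exc
    if np.any(np.diff(wavelengths) <= 0):
        j = int(np.argmax(np.diff(wavelengths) <= 0)) + 1
        raise MatrixFormatError(
            f"{path}: wavelength header not strictly increasing at column {j + 1}"
        )
    ncol = wavelengths.size
    times, rows = [], []
    for i, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != ncol + 1:
            raise MatrixFormatError(
                f"{path}: row {i} has {len(parts)} cells, expected {ncol + 1}"
            )
        times.append(float(parts[0]))
        rows.append([float(x) for x in parts[1:]])
    times = np.array(times)
    if np.any(np.diff(times) <= 0):
        i = int(np.argmax(np.diff(times) <= 0)) + 2
        raise MatrixFormatError(
            f"{path}: time column not strictly increasing at row {i}"
        )
    return TimeResolvedMatrix(
        times, wavelengths, np.array(rows), time_unit=time_unit, value_unit=value_unit
    )


# ---------------------------------------------------------------------------
# binning


def bin_wavelength(matrix: TimeResolvedMatrix, n_pixels: int) -> TimeResolvedMatrix:
    """Average consecutive non-overlapping groups of ``n_pixels`` wavelengths.

    Detector pixels are binned to improve S/N at the cost of spectral
    resolution.  A trailing remainder group shorter than ``n_pixels`` is
    averaged as-is rather than dropped.
    """
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    nwl = matrix.wavelengths.size
    if n_pixels > nwl:
        raise ValueError(f"n_pixels={n_pixels} exceeds grid size {nwl}")
    if n_pixels == 1:
        return replace(matrix)
    edges = np.arange(0, nwl + n_pixels, n_pixels)
    edges[-1] = min(edges[-1], nwl)
    edges = np.unique(edges)
    new_wl = np.array(
        [matrix.wavelengths[a:b].mean() for a, b in zip(edges[:-1], edges[1:])]
    )
    new_vals = np.column_stack(
        [matrix.values[:, a:b].mean(axis=1) for a, b in zip(edges[:-1], edges[1:])]
    )
    return TimeResolvedMatrix(
        matrix.times,
        new_wl,
        new_vals,
        time_unit=matrix.time_unit,
        value_unit=matrix.value_unit,
        metadata={**matrix.metadata, "wl_bin": n_pixels},
    )


def bin_time_log(
    matrix: TimeResolvedMatrix, points_per_decade: int
) -> TimeResolvedMatrix:
    """Re-bin rows onto a logarithmic time grid.

    Rows are grouped by log-spaced bin edges (``points_per_decade`` bins per
    decade); each bin's value is the mean of its member rows and its
    representative time is the geometric mean of the member times, which is
    the natural centre on a log axis.  Empty bins are dropped.
    """
    if points_per_decade < 1:
        raise ValueError("points_per_decade must be >= 1")
    if np.any(matrix.times <= 0):
        raise ValueError("logarithmic time binning requires strictly positive times")
    logt = np.log10(matrix.times)
    lo = np.floor(logt[0] * points_per_decade) / points_per_decade
    hi = np.ceil(logt[-1] * points_per_decade) / points_per_decade
    nbins = max(1, int(round((hi - lo) * points_per_decade)))
    edges = lo + np.arange(nbins + 1) / points_per_decade
    idx = np.clip(np.digitize(logt, edges) - 1, 0, nbins - 1)
    new_t, new_rows = [], []
    for b in range(nbins):
        mask = idx == b
        if not mask.any():
            continue
        new_t.append(float(np.exp(np.mean(np.log(matrix.times[mask])))))
        new_rows.append(matrix.values[mask].mean(axis=0))
    return TimeResolvedMatrix(
        np.array(new_t),
        matrix.wavelengths,
        np.array(new_rows),
        time_unit=matrix.time_unit,
        value_unit=matrix.value_unit,
        metadata={**matrix.metadata, "time_log_bin": points_per_decade},
    )


# ---------------------------------------------------------------------------
# Beer–Lambert and mixing arithmetic


def concentration_from_absorbance(
    absorbance: float, epsilon: float, pathlength: float = 1.0
) -> float:
    """Concentration (uM) from absorbance via Beer–Lambert.

    Parameters
    ----------
    absorbance : OD at the band maximum.
    epsilon : extinction coefficient in mM^-1 cm^-1.
    pathlength : cuvette pathlength in cm.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if pathlength <= 0:
        raise ValueError("pathlength must be positive")
    return 1000.0 * absorbance / (epsilon * pathlength)


class MixingResult(NamedTuple):
    final_a: float  # uM after mixing
    final_b: float  # uM after mixing
    excess_ratio: float  # final_a / final_b, full precision
    excess_ratio_2sf: float  # same, rounded to 2 significant figures


def mixing_concentrations(
    vol_a: float, conc_a: float, vol_b: float, conc_b: float
) -> MixingResult:
    """Final concentrations after mixing two stock solutions.

    Volumes in mL (any common unit), concentrations in uM.  The molar excess
    ratio a/b is reported both at full precision and rounded to two
    significant figures, the precision at which such protocols are quoted.
    """
    if vol_a <= 0 or vol_b <= 0:
        raise ValueError("volumes must be positive")
    total = vol_a + vol_b
    final_a = conc_a * vol_a / total
    final_b = conc_b * vol_b / total
    ratio = final_a / final_b
    if ratio == 0:
        r2 = 0.0
    else:
        ndigits = 1 - int(np.floor(np.log10(abs(ratio))))
        r2 = round(ratio, ndigits)
    return MixingResult(final_a, final_b, ratio, r2)
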