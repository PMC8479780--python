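"""Gaussian band composites used as species spectra.

Bilin absorption bands (Soret and Q) are modelled as sums of Gaussians in
wavelength.  Each band is parameterised by centre (nm), full width at half
maximum (nm) and a signed peak amplitude: extinction-scale (mM^-1 cm^-1) for
species spectra, mOD-scale for transient-absorption components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral_io import Spectrum

__all__ = ["GaussianBand", "SpeciesSpectrum", "gaussian_spectrum"]

_FOUR_LN2 = 4.0 * np.log(2.0)

# species that represent physical absorbers: evaluation must be non-negative
ABSORBING_SPECIES = {"free_bilin", "noncovalent", "covalent", "dark_state", "photoproduct"}


@dataclass(frozen=True)
class GaussianBand:
    """One Gaussian absorption band: center/fwhm in nm, signed amplitude."""

    center: float
    fwhm: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if not (250.0 <= self.center <= 900.0):
            raise ValueError("band center must lie within [250, 900] nm")

    def __call__(self, grid: np.ndarray) -> np.ndarray:
        grid = np.asarray(grid, dtype=float)
        return self.amplitude * np.exp(
            -_FOUR_LN2 * (grid - self.center) ** 2 / self.fwhm**2
        )


@dataclass
class SpeciesSpectrum:
    """Named band composite, e.g. the extinction spectrum of one species."""

    name: str
    bands: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError(f"species {self.name!r} needs at least one band")
        self.bands = [
            b if isinstance(b, GaussianBand) else GaussianBand(*b) for b in self.bands
        ]

    def evaluate(self, grid: np.ndarray) -> np.ndarray:
        vals = gaussian_spectrum(self.bands, grid).values
        if self.name in ABSORBING_SPECIES and np.any(vals < 0):
            raise ValueError(
                f"absorbing species {self.name!r} evaluates negative on the grid"
            )
        return vals

    def spectrum(self, grid: np.ndarray, units: str = "mM-1cm-1") -> Spectrum:
        return Spectrum(np.asarray(grid, float), self.evaluate(grid),
                        label=self.name, units=units)


def gaussian_spectrum(bands, grid) -> Spectrum:
    """Evaluate a sum of Gaussian bands on a wavelength grid.

    value(lambda) = sum_b amplitude_b * exp(-4 ln2 (lambda - center_b)^2 / fwhm_b^2)
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("wavelength grid is empty")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("wavelength grid must be strictly increasing")
    values = np.zeros_like(grid)
    for b in bands:
        if not isinstance(b, GaussianBand):
            b = GaussianBand(*b)
        values += b(grid)
    return Spectrum(grid, values)
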