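"""Decomposition of photostationary spectra into dark state and photoproduct.

Under continuous illumination a bistable photoreceptor settles into a
photostationary mixture; the measured equilibrium spectrum ``S_equil``
contains a residual dark-state contribution.  The pure photoproduct spectrum
is exposed by ``S_phot = S_equil - s * S_dark`` with the subtraction factor
``s`` chosen to (1) remove the dark state completely at its prominent marker
band, and (2) avoid over-subtraction, which shows up as negative or sharp
features in ``S_phot``.

The same factor, rescaled by the spectra's ratio at the pump wavelength,
propagates to the subtraction of whole pump-probe datasets measured on the
equilibrium mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectral_io import Spectrum, TimeResolvedMatrix

__all__ = [
    "DecompositionResult",
    "determine_subtraction_factor",
    "scale_factor_for_pump",
    "subtract_ta_datasets",
]


@dataclass
class DecompositionResult:
    """Outcome of :func:`determine_subtraction_factor`.

    ``constrained`` is True when the negativity/sharpness constraints forced
    ``s`` below the marker-determined starting value ``s0``.
    """

    s: float
    s0: float
    S_phot: Spectrum
    marker_wavelength: float
    residual_at_marker: float
    negativity_metric: float
    constrained: bool
    trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0 <= self.s <= 1):
            raise ValueError("subtraction factor must lie in [0, 1]")


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(values, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad:pad + values.size]
    return out


def determine_subtraction_factor(
    S_equil: Spectrum,
    S_dark: Spectrum,
    marker: float,
    noise_floor: float,
    step: float = 0.005,
    negativity_mult: float = 3.0,
    sharpness_mult: float = 5.0,
    smooth_window: int = 9,
) -> DecompositionResult:
    """Iteratively determine the subtraction factor ``s``.

    Starting from the marker-band ratio ``s0 = S_equil(marker) /
    S_dark(marker)`` (complete removal of the dark state at the marker), the
    factor is lowered on a grid of ``step`` until the extracted spectrum
    satisfies both acceptance criteria:

    * no negative feature below ``-negativity_mult * noise_floor``;
    * the second difference around the marker stays within
      ``sharpness_mult`` times the median absolute second difference of
      ``S_equil`` (no sharp subtraction artifact at the marker).

    Both criteria are evaluated on a lightly smoothed copy (moving average of
    ``smooth_window`` points) so that single-pixel noise excursions do not
    masquerade as over-subtraction features.

    ``S_dark`` is resampled onto the grid of ``S_equil`` by linear
    interpolation if the grids differ.
    """
    grid = S_equil.wavelengths
    dark = S_dark.values
    if not np.array_equal(grid, S_dark.wavelengths):
        dark = np.interp(grid, S_dark.wavelengths, S_dark.values)
    dark_marker = float(np.interp(marker, grid, dark))
    if dark_marker <= 10.0 * noise_floor:
        raise ValueError(
            f"S_dark({marker} nm) = {dark_marker:g} is too small relative to "
            f"the noise floor {noise_floor:g} to anchor the subtraction"
        )
    equil_marker = float(np.interp(marker, grid, S_equil.values))
    s0 = equil_marker / dark_marker
    if s0 > 1.0 + 1e-9:
        raise ValueError(
            f"marker ratio s0 = {s0:.3f} exceeds 1: mixture inconsistent with "
            "S_equil = f*S_dark + (1-f)*S_phot"
        )
    s0 = min(s0, 1.0)

    # sharpness reference from the (smoothed) equilibrium spectrum; a
    # subtraction artifact must stand out both against the spectrum's global
    # curvature scale and against the curvature already present at the marker
    ref = _smooth(S_equil.values, smooth_window)
    ref_d2 = np.abs(np.diff(ref, 2))
    neg_bound = -negativity_mult * noise_floor
    imark = int(np.argmin(np.abs(grid - marker)))
    window = slice(max(imark - 3, 1), min(imark + 4, grid.size - 1))
    local_ref = ref_d2[window.start - 1:window.stop - 1]
    local_sharp = float(local_ref.max()) if local_ref.size else 0.0
    sharp_bound = max(
        sharpness_mult * max(float(np.median(ref_d2)), 1e-15),
        2.0 * local_sharp,
    )

    trace = []
    chosen = None
    s = s0
    while s >= -1e-12:
        s_eff = max(s, 0.0)
        phot = S_equil.values - s_eff * dark
        sm = _smooth(phot, smooth_window)
        most_negative = float(sm.min())
        d2 = np.abs(np.diff(sm, 2))[window.start - 1:window.stop - 1]
        sharp = float(d2.max()) if d2.size else 0.0
        ok = most_negative >= neg_bound and sharp <= sharp_bound
        trace.append({"s": s_eff, "min": most_negative, "sharpness": sharp,
                      "accepted": ok})
        if ok:
            chosen = s_eff
            break
        s -= step
    if chosen is None:
        chosen = 0.0  # no admissible factor: report the unsubtracted spectrum
    phot = S_equil.values - chosen * dark
    return DecompositionResult(
        s=chosen,
        s0=s0,
        S_phot=Spectrum(grid, phot, label="S_phot", units=S_equil.units),
        marker_wavelength=marker,
        residual_at_marker=float(np.interp(marker, grid, phot)),
        negativity_metric=float(phot.min()),
        constrained=chosen < s0 - 1e-12,
        trace=trace,
    )


def scale_factor_for_pump(
    s: float,
    S_dark: Spectrum,
    S_equil: Spectrum,
    pump_wavelength: float,
    reference: str = "equil",
) -> float:
    """Rescale the subtraction factor to the pump wavelength.

    For pump-probe subtraction the relevant quantity is the dark-state share
    of the *absorbed pump photons*, so ``s`` is multiplied by the ratio of
    the spectra evaluated at the pump wavelength:
    ``s_ta = s * S_dark(l_pump) / S_ref(l_pump)`` with the equilibrium
    spectrum as the default reference (``reference='equil'``); pass
    ``reference='phot'`` together with a photoproduct spectrum in place of
    ``S_equil`` for the dark/photoproduct convention.
    """
    dark_p = S_dark.at(pump_wavelength)
    ref_p = S_equil.at(pump_wavelength)
    if ref_p <= 0:
        raise ValueError(
            f"reference spectrum non-positive at the pump wavelength "
            f"({pump_wavelength} nm): {ref_p:g}"
        )
    return s * dark_p / ref_p


def subtract_ta_datasets(
    ta_equil: TimeResolvedMatrix,
    ta_dark: TimeResolvedMatrix,
    s_ta: float,
) -> TimeResolvedMatrix:
    """Remove the dark-state contribution from an equilibrium pump-probe set.

    Both matrices must sit on identical time and wavelength grids — mixed
    calibrations produce spectral artifacts, so mismatches are an error
    (re-bin onto a common grid first) rather than silently interpolated.
    """
    if not np.array_equal(ta_equil.times, ta_dark.times) or not np.array_equal(
        ta_equil.wavelengths, ta_dark.wavelengths
    ):
        raise ValueError(
            "pump-probe grids differ; re-bin both datasets onto a common "
            "time/wavelength grid before subtracting"
        )
    if ta_equil.value_unit != ta_dark.value_unit:
        raise ValueError("value units differ between the two datasets")
    return TimeResolvedMatrix(
        ta_equil.times,
        ta_equil.wavelengths,
        ta_equil.values - s_ta * ta_dark.values,
        time_unit=ta_equil.time_unit,
        value_unit=ta_equil.value_unit,
        metadata={**ta_equil.metadata, "subtracted_s_ta": s_ta},
    )
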