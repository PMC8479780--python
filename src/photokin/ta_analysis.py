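"""Pump-probe (transient absorption) analysis and quantum-yield estimation.

A pump-probe matrix over the 10 ps - 20 ns window is fitted globally with
two exponentials plus a non-decaying component.  The offset spectrum of that
fit is the spectrum of the primary ground-state photoproduct (Lumi); the
photochemical quantum yield of its formation is approximated by the
ground-state-bleach (GSB) ratio

    Phi = dA_inf(l*) / dA_model(t0, l*),

evaluated from the fitted model at the Lumi GSB minimum l* and the early
reference delay t0 (first observed point, 10 ps).  Overlapping product
absorption can only fill in the bleach, so the ratio is a lower bound on the
true yield; a large shift of the Lumi GSB minimum relative to the
steady-state absorption maximum signals exactly this situation and is
reported as a diagnostic flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .global_fitting import (
    GlobalExpModel,
    GlobalFitResult,
    evaluate_model,
    global_exp_fit,
)
from .spectral_io import Spectrum, TimeResolvedMatrix

__all__ = [
    "QYEstimate",
    "TAStateResult",
    "fit_ta",
    "estimate_qy",
    "gsb_shift_diagnostic",
]


@dataclass
class QYEstimate:
    """GSB-ratio quantum-yield estimate with its diagnostics."""

    phi: float
    lumi_gsb_min: float  # nm
    t0: float  # ps, early reference delay
    gsb_shift: float | None = None  # nm, negative = downshift
    quality_flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if not (0 <= self.phi <= 1):
            raise ValueError("phi must lie in [0, 1]")


@dataclass
class TAStateResult:
    """Global fit of one photochemical state's pump-probe data."""

    label: str
    fit: GlobalFitResult
    data: TimeResolvedMatrix
    qy: QYEstimate | None = None

    @property
    def lumi(self) -> Spectrum:
        return self.fit.offset

    @property
    def taus(self) -> np.ndarray:
        return self.fit.taus


def fit_ta(data: TimeResolvedMatrix, label: str = "", n_starts: int = 5) -> TAStateResult:
    """Globally fit a pump-probe matrix: 2 exponentials + offset.

    The exponential basis is referenced to the first observed delay, so the
    fitted amplitudes describe the earliest spectrum directly and the offset
    spectrum is the Lumi spectrum.
    """
    if data.time_unit != "ps":
        raise ValueError("pump-probe data must carry times in ps")
    model = GlobalExpModel(
        n_exp=2, with_offset=True, t_ref=float(data.times[0]), n_starts=n_starts
    )
    fit = global_exp_fit(data, model)
    return TAStateResult(label=label or str(data.metadata.get("label", "")),
                         fit=fit, data=data)


def _parabolic_min(wl: np.ndarray, y: np.ndarray):
    """Index-refined minimum of y(wl): returns (wavelength, index, delta)."""
    j = int(np.argmin(y))
    if j == 0 or j == y.size - 1:
        return float(wl[j]), j, 0.0
    denom = y[j - 1] - 2 * y[j] + y[j + 1]
    if denom <= 0:
        return float(wl[j]), j, 0.0
    delta = 0.5 * (y[j - 1] - y[j + 1]) / denom
    step = 0.5 * (wl[j + 1] - wl[j - 1])
    return float(wl[j] + delta * step), j, float(delta)


def _parabola_eval(y: np.ndarray, j: int, delta: float) -> float:
    """Evaluate the 3-point parabola around index j at fractional offset delta."""
    if j == 0 or j == y.size - 1 or delta == 0.0:
        return float(y[j])
    return float(
        y[j]
        + 0.5 * (y[j + 1] - y[j - 1]) * delta
        + 0.5 * (y[j - 1] - 2 * y[j] + y[j + 1]) * delta**2
    )


def estimate_qy(result: TAStateResult, t0: float | None = None) -> QYEstimate:
    """Estimate the photochemical quantum yield from the GSB ratio.

    ``l*`` is the (parabolically refined) minimum of the offset (Lumi)
    spectrum; Phi is the ratio of the fitted model's value at ``l*`` between
    t -> infinity (the offset) and the early reference ``t0`` (default: the
    first observed delay).  Both values are negative in a bleach; the ratio
    is clipped to [0, 1] with a quality flag if clipping occurred.
    """
    offset = result.lumi
    if offset is None:
        raise ValueError("fit has no non-decaying component")
    if t0 is None:
        t0 = float(result.data.times[0])
    flags: set = set()
    if np.all(offset.values == 0.0):
        return QYEstimate(phi=0.0, lumi_gsb_min=np.nan, t0=t0,
                          quality_flags={"zero_offset"})
    if offset.values.min() >= 0:
        raise ValueError("no Lumi GSB found: offset spectrum is non-negative")
    wl_star, j, delta = _parabolic_min(offset.wavelengths, offset.values)
    off_star = _parabola_eval(offset.values, j, delta)

    early = evaluate_model(result.fit, [t0]).values[0]
    # evaluate the early model spectrum at the same refined minimum, with the
    # same local parabolic interpolation as the numerator
    early_star = _parabola_eval(early, j, delta)
    if early_star >= 0:
        raise ValueError(
            f"early model spectrum non-negative at the Lumi GSB minimum "
            f"({wl_star:.1f} nm); cannot form a GSB ratio"
        )
    phi = off_star / early_star
    if phi < 0 or phi > 1:
        flags.add("phi_clipped")
        phi = float(np.clip(phi, 0.0, 1.0))
    est = QYEstimate(phi=float(phi), lumi_gsb_min=wl_star, t0=t0,
                     quality_flags=flags)
    result.qy = est
    return est


def gsb_shift_diagnostic(
    result: TAStateResult,
    steady_state: Spectrum,
    band_window: tuple[float, float] | None = None,
    flag_threshold: float = 10.0,
):
    """Shift of the Lumi GSB minimum against the steady-state maximum.

    ``shift = l*(Lumi GSB min) - l(steady-state max)`` within the band
    window (default: +/- 60 nm around the Lumi minimum).  A shift larger
    than ``flag_threshold`` (nm) in magnitude indicates strong overlap of
    photoproduct absorption with the bleach and therefore a likely
    underestimated quantum yield (flag ``gsb_shift_large``); it is stored on
    the result's quantum-yield estimate when present.

    Returns ``(shift_nm, flags)``.
    """
    est = result.qy if result.qy is not None else estimate_qy(result)
    wl_star = est.lumi_gsb_min
    if band_window is None:
        band_window = (wl_star - 60.0, wl_star + 60.0)
    lo, hi = band_window
    mask = (steady_state.wavelengths >= lo) & (steady_state.wavelengths <= hi)
    if mask.sum() < 3:
        raise ValueError(
            f"steady-state spectrum has no coverage in the band window {band_window}"
        )
    wl = steady_state.wavelengths[mask]
    vals = steady_state.values[mask]
    if np.ptp(vals) == 0:
        raise ValueError("steady-state spectrum is flat in the band window")
    wl_ss, _, _ = _parabolic_min(wl, -vals)  # max via negated minimum
    shift = float(wl_star - wl_ss)
    flags = set()
    if abs(shift) > flag_threshold:
        flags.add("gsb_shift_large")
    est.gsb_shift = shift
    est.quality_flags |= flags
    return shift, flags
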