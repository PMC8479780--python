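"""Global multiexponential fitting with per-wavelength amplitude spectra.

All wavelength channels share the same time constants; each exponential gets
its own amplitude spectrum (decay-associated spectrum, DAS — or DADS for
difference data) and an optional non-decaying offset spectrum (the
final-state / Lumi spectrum).

The fit uses variable projection (separable least squares): for any trial set
of time constants the linear amplitudes are solved exactly by linear least
squares across all channels at once, and the nonlinear search runs only over
the time constants.  A multi-start strategy over a log-spaced grid of initial
time constants guards against local minima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .spectral_io import Spectrum, TimeResolvedMatrix

__all__ = [
    "GlobalExpModel",
    "GlobalFitResult",
    "GlobalFitError",
    "global_exp_fit",
    "evaluate_model",
]


class GlobalFitError(RuntimeError):
    """Raised when no optimizer start converges; carries the best attempt."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


@dataclass
class GlobalExpModel:
    """Configuration of a global exponential fit.

    Parameters
    ----------
    n_exp : number of exponential components (1 or 2).
    with_offset : include a non-decaying component (offset spectrum).
    tau_bounds : optional per-exponential (lower, upper) bounds in the data's
        time unit; a single pair is broadcast to all exponentials.  Defaults
        span from 5e-4 to 10x the observed time span.
    tau_init : optional explicit initial guesses (overrides the multi-start
        grid).
    t_ref : time origin of the exponential basis, exp(-(t - t_ref)/tau).
        Default 0 (absolute time axis); pump-probe fits use the first
        observed delay so that amplitudes refer to the earliest spectrum.
    n_starts : number of log-spaced initial values per time constant.
    """

    n_exp: int = 1
    with_offset: bool = True
    tau_bounds: tuple | list | None = None
    tau_init: list | None = None
    t_ref: float = 0.0
    n_starts: int = 5

    def __post_init__(self) -> None:
        if self.n_exp not in (1, 2):
            raise ValueError("n_exp must be 1 or 2")

    def resolved_bounds(self, times: np.ndarray) -> np.ndarray:
        span = float(times[-1] - times[0])
        if span <= 0:
            raise ValueError("need a non-degenerate time span")
        default = (5e-4 * span, 10.0 * span)
        if self.tau_bounds is None:
            b = [default] * self.n_exp
        else:
            tb = np.asarray(self.tau_bounds, dtype=float)
            if tb.ndim == 1:
                b = [tuple(tb)] * self.n_exp
            else:
                b = [tuple(row) for row in tb]
        for lo, hi in b:
            if not (0 < lo < hi):
                raise ValueError(f"invalid tau bounds ({lo}, {hi})")
        return np.asarray(b, dtype=float)


@dataclass
class GlobalFitResult:
    """Outcome of :func:`global_exp_fit`.

    ``taus`` are sorted ascending and the DAS are permuted accordingly.
    ``amplitudes`` has one row per basis function (exponentials first, then
    the offset if present) and one column per wavelength.
    """

    taus: np.ndarray
    tau_stderr: np.ndarray
    das: list  # list[Spectrum], one per exponential
    offset: Spectrum | None
    amplitudes: np.ndarray
    residual_rms: float
    model_eval: TimeResolvedMatrix
    t_ref: float
    with_offset: bool
    metadata: dict = field(default_factory=dict)


def _design(times: np.ndarray, taus: np.ndarray, with_offset: bool, t_ref: float):
    t = times[:, None] - t_ref
    cols = np.exp(-t / taus[None, :])
    if with_offset:
        cols = np.hstack([cols, np.ones((times.size, 1))])
    return cols


def _solve_amplitudes(C: np.ndarray, Y: np.ndarray):
    amps, *_ = np.linalg.lstsq(C, Y, rcond=None)
    return amps


def global_exp_fit(
    data: TimeResolvedMatrix, model: GlobalExpModel
) -> GlobalFitResult:
    """Fit ``data`` with shared time constants and free amplitude spectra.

    Minimises ``sum_{t,l} [A(t,l) - sum_i D_i(l) exp(-(t-t_ref)/tau_i)
    - D_inf(l)]^2``.  Amplitudes are profiled out exactly for each trial of
    the time constants; the nonlinear search (trust-region least squares on
    log tau) is restarted from a log-spaced grid of initial values and the
    best start wins.
    """
    times = data.times
    Y = data.values
    n_par = model.n_exp + (1 if model.with_offset else 0)
    if times.size < 2 * model.n_exp + 2:
        raise ValueError(
            f"need at least {2 * model.n_exp + 2} time points, got {times.size}"
        )
    bounds = model.resolved_bounds(times)
    log_lo, log_hi = np.log(bounds[:, 0]), np.log(bounds[:, 1])

    def residual(log_taus: np.ndarray) -> np.ndarray:
        taus = np.sort(np.exp(log_taus))
        C = _design(times, taus, model.with_offset, model.t_ref)
        amps = _solve_amplitudes(C, Y)
        return (Y - C @ amps).ravel()

    starts = _start_grid(model, bounds)
    best = None
    n_converged = 0
    for x0 in starts:
        try:
            res = least_squares(
                residual,
                np.log(x0),
                bounds=(log_lo, log_hi),
                xtol=1e-10,
                ftol=1e-12,
                gtol=1e-10,
                max_nfev=500 * (model.n_exp + 1),
            )
        except Exception:  # singular design etc.: try the next start
            continue
        if res.success or res.cost < np.inf:
            n_converged += int(res.success)
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise GlobalFitError("global exponential fit failed from every start")
    if n_converged == 0:
        raise GlobalFitError(
            "global exponential fit did not converge from any start", best=best
        )

    order = np.argsort(np.exp(best.x))
    taus = np.sort(np.exp(best.x))
    C = _design(times, taus, model.with_offset, model.t_ref)
    amps = _solve_amplitudes(C, Y)
    R = Y - C @ amps
    rms = float(np.sqrt(np.mean(R**2)))

    meta = {"n_starts": len(starts), "n_converged": n_converged,
            "cost": float(best.cost), "success": bool(best.success)}
    if model.n_exp == 2 and taus[1] / taus[0] < 1.5:
        meta["degenerate_tau_pair"] = True
        warnings.warn(
            f"fitted time constants nearly degenerate (ratio "
            f"{taus[1] / taus[0]:.2f} < 1.5)", stacklevel=2)

    # approximate standard errors from the variable-projection Jacobian
    tau_stderr = _tau_stderr(best, taus, order, Y.size, n_par * Y.shape[1])

    das = [
        Spectrum(data.wavelengths, amps[i].copy(),
                 label=f"DAS tau={taus[i]:g} {data.time_unit}",
                 units=data.value_unit)
        for i in range(model.n_exp)
    ]
    offset = None
    if model.with_offset:
        offset = Spectrum(data.wavelengths, amps[-1].copy(),
                          label="offset", units=data.value_unit)
    model_eval = TimeResolvedMatrix(
        times, data.wavelengths, C @ amps,
        time_unit=data.time_unit, value_unit=data.value_unit,
        metadata={"fit": "global_exp", **meta},
    )
    return GlobalFitResult(
        taus=taus, tau_stderr=tau_stderr, das=das, offset=offset,
        amplitudes=amps, residual_rms=rms, model_eval=model_eval,
        t_ref=model.t_ref, with_offset=model.with_offset, metadata=meta,
    )


def _start_grid(model: GlobalExpModel, bounds: np.ndarray):
    if model.tau_init is not None:
        init = np.asarray(model.tau_init, dtype=float)
        if init.size != model.n_exp:
            raise ValueError("tau_init length must equal n_exp")
        return [init]
    grids = [
        np.exp(np.linspace(np.log(lo * 1.01), np.log(hi * 0.99), model.n_starts))
        for lo, hi in bounds
    ]
    if model.n_exp == 1:
        return [np.array([g]) for g in grids[0]]
    starts = []
    for i, t1 in enumerate(grids[0]):
        for t2 in grids[1][i + 1:]:
            starts.append(np.array([t1, t2]))
    return starts


def _tau_stderr(res, taus, order, n_obs, n_lin):
    try:
        J = res.jac
        dof = max(n_obs - (taus.size + n_lin), 1)
        s2 = 2.0 * res.cost / dof
        cov_log = s2 * np.linalg.inv(J.T @ J)
        err_log = np.sqrt(np.clip(np.diag(cov_log), 0, np.inf))[order]
        return taus * err_log  # delta method: tau = exp(theta)
    except np.linalg.LinAlgError:
        return np.full_like(taus, np.nan)


def evaluate_model(result: GlobalFitResult, times) -> TimeResolvedMatrix:
    """Evaluate the fitted closed-form model on an arbitrary time grid.

    Used e.g. to extrapolate a pump-probe fit to the early reference time in
    quantum-yield estimation; the t -> infinity limit is the offset spectrum.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    C = _design(times, result.taus, result.with_offset, result.t_ref)
    src = result.model_eval
    return TimeResolvedMatrix(
        times, src.wavelengths, C @ result.amplitudes,
        time_unit=src.time_unit, value_unit=src.value_unit,
        metadata={"evaluated": True},
    )
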