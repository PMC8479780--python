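"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from photokin.spectral_io import TimeResolvedMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_matrix(times, wavelengths, values, **kw) -> TimeResolvedMatrix:
    return TimeResolvedMatrix(
        np.asarray(times, float), np.asarray(wavelengths, float),
        np.asarray(values, float), **kw
    )


def exp_matrix(times, wavelengths, taus, das, offset=None, t_ref=0.0):
    """Closed-form multiexponential matrix used to generate fit targets."""
    times = np.asarray(times, float)
    values = np.zeros((times.size, len(wavelengths)))
    for tau, d in zip(taus, das):
        values += np.exp(-(times - t_ref) / tau)[:, None] * np.asarray(d)[None, :]
    if offset is not None:
        values += np.asarray(offset)[None, :]
    return make_matrix(times, wavelengths, values)


def profiled_rss(times, Y, taus, with_offset, t_ref=0.0):
    """Residual sum of squares with amplitudes profiled out (oracle)."""
    cols = [np.exp(-(times - t_ref) / tau) for tau in taus]
    if with_offset:
        cols.append(np.ones_like(times))
    C = np.column_stack(cols)
    amps, *_ = np.linalg.lstsq(C, Y, rcond=None)
    return float(np.sum((Y - C @ amps) ** 2))


def grid_search_taus(data, n_exp, with_offset, bounds, t_ref=0.0,
                     n_coarse=40, n_zoom=6):
    """Brute-force grid search over time constants, iteratively refined.

    Independent oracle for the variable-projection optimum: scans a dense
    log grid of tau (or ordered tau pairs) and zooms around the best cell
    until the grid resolution is below 0.1 % of the value.
    """
    times, Y = data.times, data.values
    intervals = [list(bounds) for _ in range(n_exp)]
    best = None
    for _ in range(n_zoom):
        grids = [np.geomspace(lo, hi, n_coarse) for lo, hi in intervals]
        if n_exp == 1:
            candidates = [(t,) for t in grids[0]]
        else:
            candidates = [
                (t1, t2)
                for t1, t2 in itertools.product(grids[0], grids[1])
                if t1 < t2
            ]
        best = min(
            candidates,
            key=lambda taus: profiled_rss(times, Y, np.array(taus), with_offset, t_ref),
        )
        ratios = [
            (hi / lo) ** (1.0 / (n_coarse - 1)) for lo, hi in intervals
        ]
        if max(ratios) - 1 < 1e-3:
            break
        intervals = [
            [t / r**2, t * r**2] for t, r in zip(best, ratios)
        ]
    return np.array(best)
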