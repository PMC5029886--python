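"""Hemodynamic response model shared by the simulator and every GLM.

Arterial gas tensions, and the vascular responses they drive, follow the
inspired-gas schedule with a lag of tens of seconds.  All block regressors in
this package use a single impulse response: a gamma density whose mode
(time-to-peak) is 20 s and whose full width at half maximum is 40 s, which
produces near-exponential transitions at block edges.  Block responses are
evaluated analytically through the gamma CDF, so they are exact at arbitrary
(irregular) sample times and identical wherever they are used.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Iterable, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

DEFAULT_TIME_TO_PEAK = 20.0  # s, mode of the gamma density
DEFAULT_FWHM = 40.0  # s, full width at half maximum

# dense-grid resolution used only to locate response maxima for normalization
_GRID_DT = 0.05


@lru_cache(maxsize=None)
def gamma_hrf_params(
    time_to_peak: float = DEFAULT_TIME_TO_PEAK, fwhm: float = DEFAULT_FWHM
) -> Tuple[float, float]:
    """Solve for the (shape, scale) of the gamma HRF.

    The mode of a gamma density with shape k > 1 and scale s is (k - 1) * s;
    the FWHM has no closed form and is found numerically.
    """
    if time_to_peak <= 0 or fwhm <= 0:
        raise ValueError("time_to_peak and fwhm must be positive")

    def width(shape: float) -> float:
        scale = time_to_peak / (shape - 1.0)
        dist = stats.gamma(shape, scale=scale)
        half = dist.pdf(time_to_peak) / 2.0
        lo = optimize.brentq(lambda t: dist.pdf(t) - half, 1e-9, time_to_peak)
        hi_end = 2.0 * time_to_peak
        while dist.pdf(hi_end) > half:
            hi_end *= 2.0
        hi = optimize.brentq(lambda t: dist.pdf(t) - half, time_to_peak, hi_end)
        return hi - lo

    shape = optimize.brentq(lambda k: width(k) - fwhm, 1.2, 80.0, xtol=1e-12)
    return shape, time_to_peak / (shape - 1.0)


def hrf_kernel(
    times: np.ndarray,
    time_to_peak: float = DEFAULT_TIME_TO_PEAK,
    fwhm: float = DEFAULT_FWHM,
) -> np.ndarray:
    """Peak-normalized gamma HRF sampled at ``times`` (seconds)."""
    shape, scale = gamma_hrf_params(time_to_peak, fwhm)
    dist = stats.gamma(shape, scale=scale)
    t = np.asarray(times, dtype=float)
    return dist.pdf(np.clip(t, 0.0, None)) / dist.pdf(time_to_peak)


def block_response(
    times: np.ndarray | float,
    blocks: Sequence[Tuple[float, float]] | Iterable[Tuple[float, float]],
    time_to_peak: float = DEFAULT_TIME_TO_PEAK,
    fwhm: float = DEFAULT_FWHM,
) -> np.ndarray:
    """HRF-convolved response of (onset, duration) blocks, peak-normalized.

    The convolution of a unit block with the gamma density is the difference
    of two gamma CDFs, evaluated exactly.  The result is rescaled so its
    global maximum is 1, making a fitted effect size directly interpretable
    as the plateau amplitude.
    """
    blocks = tuple(tuple(map(float, b)) for b in blocks)
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if not blocks:
        return np.zeros_like(t)
    shape, scale = gamma_hrf_params(time_to_peak, fwhm)
    dist = stats.gamma(shape, scale=scale)

    def raw(x: np.ndarray) -> np.ndarray:
        out = np.zeros_like(x, dtype=float)
        for onset, dur in blocks:
            out += dist.cdf(x - onset) - dist.cdf(x - onset - dur)
        return out

    peak = _response_peak(blocks, time_to_peak, fwhm)
    return raw(t) / peak


@lru_cache(maxsize=None)
def _response_peak(
    blocks: Tuple[Tuple[float, float], ...], time_to_peak: float, fwhm: float
) -> float:
    shape, scale = gamma_hrf_params(time_to_peak, fwhm)
    dist = stats.gamma(shape, scale=scale)
    t0 = min(on for on, _ in blocks)
    t1 = max(on + dur for on, dur in blocks) + 6.0 * fwhm
    grid = np.arange(t0, t1, _GRID_DT)
    out = np.zeros_like(grid)
    for onset, dur in blocks:
        out += dist.cdf(grid - onset) - dist.cdf(grid - onset - dur)
    peak = float(out.max())
    if peak <= 0:
        raise ValueError("block response has non-positive peak")
    return peak
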