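"""End-tidal analysis of continuous O2/CO2 respiratory traces.

The analyzer samples gas through a long line and bacterial filter that
low-pass the breathing waveform, shrinking its peak-to-peak amplitude
symmetrically about the breath mean: observed end-tidal (ET) values are
pulled toward the fixed-inspired (FI) level and vice versa.  Because the
delivered FI schedule is known exactly, the FI error of neighbouring breaths
measures the attenuation and is added back to each ET point.  ET pressures
are then rescaled from dry-analyzer to alveolar values (expired water vapor
47 mmHg) before baseline and per-block gas responses are estimated with a
third-degree-polynomial plus four-block-regressor linear model evaluated at
the irregular breath times.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .hrf import block_response
from .paradigm import GasParadigm

WATER_VAPOR_MMHG = 47.0


@dataclass
class RespiratoryTrace:
    """Continuous O2 and CO2 partial-pressure recordings (dry analyzer units)."""

    time: np.ndarray  # s, strictly increasing
    po2: np.ndarray  # mmHg
    pco2: np.ndarray  # mmHg
    sampling_rate: float  # Hz

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.po2 = np.asarray(self.po2, dtype=float)
        self.pco2 = np.asarray(self.pco2, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.po2 < 0) or np.any(self.pco2 < 0):
            raise ValueError("pressures must be non-negative")

    def channel(self, gas: str) -> np.ndarray:
        if gas == "o2":
            return self.po2
        if gas == "co2":
            return self.pco2
        raise ValueError("gas must be 'o2' or 'co2'")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "po2": self.po2, "pco2": self.pco2})


@dataclass
class BreathPoints:
    """Per-breath end-tidal and fixed-inspired samples of one gas channel."""

    gas: str
    et_times: np.ndarray
    et_values: np.ndarray  # mmHg
    fi_times: np.ndarray
    fi_values: np.ndarray  # mmHg
    expected_fi: Optional[Callable[[np.ndarray], np.ndarray]] = None

    def __post_init__(self) -> None:
        for name in ("et_times", "et_values", "fi_times", "fi_values"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if np.any(np.diff(self.et_times) <= 0) or np.any(np.diff(self.fi_times) <= 0):
            raise ValueError("breath points must be strictly time-ordered")


@dataclass(frozen=True)
class EndTidalSummary:
    """Baseline end-tidal pressures and gas-induced changes (mmHg, alveolar)."""

    eto2_0: float
    etco2_0: float
    d_eto2_hc: float
    d_eto2_ho: float
    d_etco2_hc: float
    d_etco2_ho: float


def extract_breath_points(
    trace: RespiratoryTrace,
    gas: str,
    expected_fi: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    breath_period: float = 4.0,
) -> BreathPoints:
    """Locate one ET and one FI point per breath cycle.

    Breath windows are delimited by upward zero-crossings of the
    mean-subtracted, low-passed channel; each window contributes its maximum
    and minimum.  For CO2 the ET is always the maximum.  For O2 the ET is
    the minimum while breathing a constant mixture, but during return from
    hyperoxia the decaying ET can exceed the freshly lowered FI; when the
    expected FI schedule is supplied, the extremum closer to it is labelled
    FI and the other ET, which resolves those crossings.
    """
    x = trace.channel(gas)
    fs = trace.sampling_rate
    if fs < 4.0 / breath_period:
        raise ValueError("sampling rate below 4x breath frequency")
    win = max(3, int(round(breath_period * fs)))
    if x.size < 2 * win:
        raise ValueError("trace too short: fewer than 2 breaths")
    resid = x - uniform_filter1d(x, size=win, mode="nearest")
    if np.max(np.abs(resid)) < 1e-9 * max(1.0, float(np.max(np.abs(x)))):
        raise ValueError("no breaths detected")

    up = np.nonzero((resid[:-1] <= 0) & (resid[1:] > 0))[0]
    if up.size == 0:
        raise ValueError("no breaths detected")
    bounds = list(up)
    if x.size - 1 - up[-1] >= 0.5 * breath_period * fs:
        bounds.append(x.size - 1)
    if up[0] >= 0.5 * breath_period * fs:
        bounds.insert(0, 0)
    if len(bounds) < 3:
        raise ValueError("trace too short: fewer than 2 breaths")

    et_t, et_v, fi_t, fi_v = [], [], [], []
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi - lo < 0.5 * breath_period * fs:
            continue
        if expected_fi is not None:
            # a breath spanning a delivered-gas switch has no well-defined
            # FI/ET pair, and the low-pass detrender leaks the step into the
            # neighbouring breath; drop windows within half a smoothing
            # window of an FI change rather than mislabel their extrema
            guard_lo = max(lo - win // 2, 0)
            guard_hi = min(hi + win // 2, x.size - 1)
            efi = np.asarray(expected_fi(trace.time[guard_lo : guard_hi + 1]))
            if np.ptp(efi) > 1e-9:
                continue
        seg = slice(lo, hi)  # half-open: the boundary sample belongs to the next window
        # locate the breath-phase extrema on the detrended residual (the raw
        # trace extrema drift with the gas transitions), read raw values there
        imax = lo + int(np.argmax(resid[seg]))
        imin = lo + int(np.argmin(resid[seg]))
        if x[imax] - x[imin] < 1e-12:
            continue
        if gas == "co2":
            i_et, i_fi = imax, imin
        elif expected_fi is not None:
            d_max = abs(x[imax] - float(np.asarray(expected_fi(trace.time[imax]))))
            d_min = abs(x[imin] - float(np.asarray(expected_fi(trace.time[imin]))))
            i_fi, i_et = (imax, imin) if d_max <= d_min else (imin, imax)
        else:
            i_et, i_fi = imin, imax
        et_t.append(trace.time[i_et])
        et_v.append(x[i_et])
        fi_t.append(trace.time[i_fi])
        fi_v.append(x[i_fi])

    if len(et_t) < 2:
        raise ValueError("trace too short: fewer than 2 breaths")

    def ordered(times, values):
        times = np.asarray(times)
        values = np.asarray(values)
        order = np.argsort(times)
        times, values = times[order], values[order]
        keep = np.concatenate([[True], np.diff(times) > 0])
        return times[keep], values[keep]

    et_t, et_v = ordered(et_t, et_v)
    fi_t, fi_v = ordered(fi_t, fi_v)
    return BreathPoints(
        gas=gas,
        et_times=et_t,
        et_values=et_v,
        fi_times=fi_t,
        fi_values=fi_v,
        expected_fi=expected_fi,
    )


def correct_filter_attenuation(points: BreathPoints) -> BreathPoints:
    """Restore ET amplitude lost to sampling-line low-pass filtering.

    Each ET point is shifted by the mean observed-minus-expected FI error of
    the two temporally adjacent FI points (one at a trace boundary).  The
    same-channel FI error has the opposite sign of the ET error under
    symmetric peak-to-peak attenuation, so the addition cancels it.
    """
    if points.expected_fi is None:
        raise ValueError("expected FI schedule required for attenuation correction")
    if points.fi_times.size == 0:
        raise ValueError("no FI points")
    fi_err = points.fi_values - np.asarray(points.expected_fi(points.fi_times), dtype=float)
    idx = np.searchsorted(points.fi_times, points.et_times)
    corrected = points.et_values.copy()
    for k, (i, t) in enumerate(zip(idx, points.et_times)):
        neighbours = []
        if i > 0:
            neighbours.append(fi_err[i - 1])
        if i < points.fi_times.size:
            neighbours.append(fi_err[i])
        corrected[k] += float(np.mean(neighbours))
    return replace(points, et_values=corrected)


def correct_water_vapor(points: BreathPoints, barometric_pressure: float = 760.0) -> BreathPoints:
    """Rescale ET pressures from dry-analyzer fractions to alveolar values.

    The analyzer reports partial pressures of the dried sample; alveolar gas
    is saturated with water vapor (47 mmHg), so
    p_alveolar = p_observed * (PB - 47) / PB.
    """
    if barometric_pressure <= WATER_VAPOR_MMHG:
        raise ValueError("barometric pressure must exceed 47 mmHg")
    factor = (barometric_pressure - WATER_VAPOR_MMHG) / barometric_pressure
    return replace(points, et_values=points.et_values * factor)


@dataclass(frozen=True)
class EndTidalFit:
    """One-channel end-tidal model fit."""

    baseline: float  # mmHg
    hc_effects: np.ndarray  # per-block effect sizes, mmHg
    ho_effects: np.ndarray

    @property
    def d_hc(self) -> float:
        return float(np.mean(self.hc_effects))

    @property
    def d_ho(self) -> float:
        return float(np.mean(self.ho_effects))


def fit_end_tidal_model(points: BreathPoints, paradigm: GasParadigm) -> EndTidalFit:
    """Baseline and per-block ET changes by least squares at breath times.

    The design holds an offset, third-degree polynomial drift terms
    (orthogonalized to zero mean so the offset is the drift-free baseline)
    and one HRF-convolved regressor per gas block; the gas change of a
    challenge is the mean of its two block effect sizes.
    """
    t = points.et_times
    y = points.et_values
    if t.size < 20:
        raise ValueError("need at least 20 breath points")
    cols = [np.ones_like(t)]
    tn = 2.0 * (t - t.min()) / (t.max() - t.min()) - 1.0
    for deg in (1, 2, 3):
        c = tn**deg
        cols.append(c - c.mean())
    n_hc = len(paradigm.hc_blocks)
    for block in paradigm.hc_blocks + paradigm.ho_blocks:
        cols.append(block_response(t, (block,)))
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient end-tidal design")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return EndTidalFit(
        baseline=float(beta[0]),
        hc_effects=beta[4 : 4 + n_hc].copy(),
        ho_effects=beta[4 + n_hc :].copy(),
    )


def summarize_end_tidal(
    points_o2: BreathPoints, points_co2: BreathPoints, paradigm: GasParadigm
) -> EndTidalSummary:
    """Fit both channels and assemble the end-tidal summary."""
    fit_o2 = fit_end_tidal_model(points_o2, paradigm)
    fit_co2 = fit_end_tidal_model(points_co2, paradigm)
    return EndTidalSummary(
        eto2_0=fit_o2.baseline,
        etco2_0=fit_co2.baseline,
        d_eto2_hc=fit_o2.d_hc,
        d_eto2_ho=fit_o2.d_ho,
        d_etco2_hc=fit_co2.d_hc,
        d_etco2_ho=fit_co2.d_ho,
    )


def read_trace_tsv(path, sampling_rate: Optional[float] = None) -> RespiratoryTrace:
    """Read a (time, po2, pco2) TSV/CSV export into a RespiratoryTrace."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower(): c for c in df.columns}
    time = df[cols["time"]].to_numpy(dtype=float)
    if sampling_rate is None:
        sampling_rate = 1.0 / float(np.median(np.diff(time)))
    return RespiratoryTrace(
        time=time,
        po2=df[cols["po2"]].to_numpy(dtype=float),
        pco2=df[cols["pco2"]].to_numpy(dtype=float),
        sampling_rate=sampling_rate,
    )
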