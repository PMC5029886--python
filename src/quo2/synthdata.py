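"""Synthetic calibrated-MRI data with the statistical structure the
analysis assumes.

Generates ground-truth parameter maps, breath-by-breath respiratory traces
and interleaved dual-echo pCASL series for the 18-minute alternating
hypercapnia/hyperoxia paradigm, so that every downstream stage — end-tidal
extraction, the dual-echo GLM, ASL quantification and the calibration
solver — can be validated by parameter recovery without any external data.

The imaging forward model is the exact inverse of the analysis chain.  Each
channel (echo x label-state) has one signal level per condition,
S(TE) = S0 * exp(-TE * R2*), with the label S0 depressed by the
magnetization difference the pCASL quantification model assigns to that
condition's CBF (using the hyperoxia-shortened blood T1 for the HO state);
the channel's time course moves between its condition levels along the
HRF-convolved block responses, plus shared polynomial drift and white
noise.  Transitions therefore lie exactly in the span of the analysis GLM,
so the noiseless series is fitted with machine-precision residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import calibration, perfusion, physiology
from .hrf import block_response
from .paradigm import GasParadigm, make_default_paradigm
from .respiratory import WATER_VAPOR_MMHG, RespiratoryTrace
from .signal import AcquisitionGeometry, drift_columns, frame_annotations

__all__ = [
    "GasParadigm",
    "make_default_paradigm",
    "GroundTruth",
    "RespiratoryProgram",
    "make_ground_truth",
    "simulate_respiratory_trace",
    "simulate_dual_echo_series",
    "expected_fi_schedule",
    "DEFAULT_TRUTH_RANGES",
]

# Ground-truth sampling ranges emulating healthy gray matter at 3 T, with a
# small fraction of low-T2* (susceptibility-degraded) and low-GM-probability
# voxels to exercise the exclusion rules.
DEFAULT_TRUTH_RANGES: Dict[str, Tuple[float, float]] = {
    "cbf0": (40.0, 60.0),  # mL/100 g/min
    "t2s0_ms": (45.0, 65.0),
    "m": (0.04, 0.07),  # fraction at TE 30 ms
    "oef": (0.30, 0.45),
    "gm_prob": (0.55, 0.95),
    "f_hc": (1.3, 1.7),
    "f_ho": (1.0, 1.0),  # no hyperoxic flow change, the group-mean condition
    "s0": (95.0, 105.0),  # signal units (normalized scale)
    "low_t2s0_ms": (20.0, 28.0),
}


@dataclass
class GroundTruth:
    """Simulation truth maps and noise model."""

    shape: Tuple[int, int, int]
    cbf0: np.ndarray
    t2s0_ms: np.ndarray
    m: np.ndarray
    oef: np.ndarray
    gm_prob: np.ndarray
    f_hc: np.ndarray
    f_ho: np.ndarray
    s0: np.ndarray
    noise_sd: float
    drift_coefs: Tuple[float, float, float]
    seed: int

    def __post_init__(self) -> None:
        checks = [
            (np.all((self.oef > 0) & (self.oef < 1)), "OEF must lie in (0,1)"),
            (np.all(self.m > 0), "M must be positive"),
            (np.all(self.f_hc >= 1), "f_HC must be >= 1"),
            (np.all((self.f_ho >= 0.9) & (self.f_ho <= 1.05)), "f_HO outside [0.9, 1.05]"),
            (np.all(self.cbf0 > 0), "CBF0 must be positive"),
            (np.all(self.t2s0_ms > 0), "T2*0 must be positive"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)


@dataclass(frozen=True)
class RespiratoryProgram:
    """Programmed (alveolar) end-tidal levels and dry inspired fractions.

    End-tidal defaults follow the group means of the study conditions:
    ETO2 111 mmHg at baseline rising to 370 during hyperoxia and 118 during
    hypercapnia (minute-ventilation increase), ETCO2 40 rising to ~49.5
    during hypercapnia and dipping ~1 mmHg during hyperoxia.  Inspired O2 is
    60% during hyperoxia (456 mmHg dry at PB 760).  Per-gas changes accept
    a scalar or one amplitude per block.
    """

    eto2_0: float = 111.0
    d_eto2_hc: Tuple[float, ...] | float = 7.0
    d_eto2_ho: Tuple[float, ...] | float = 259.0
    etco2_0: float = 40.0
    d_etco2_hc: Tuple[float, ...] | float = 9.5
    d_etco2_ho: Tuple[float, ...] | float = -1.0
    fio2_0: float = 159.2  # dry air, mmHg
    fio2_hc: float = 152.0  # slight dilution by the CO2 mixture
    fio2_ho: float = 456.0  # 60% O2
    fico2_0: float = 0.0
    fico2_hc: float = 30.0
    barometric_pressure: float = 760.0

    @property
    def pao2_0(self) -> float:
        return self.eto2_0

    @property
    def pao2_hc(self) -> float:
        return self.eto2_0 + float(np.mean(self.d_eto2_hc))

    @property
    def pao2_ho(self) -> float:
        return self.eto2_0 + float(np.mean(self.d_eto2_ho))


def make_ground_truth(
    shape: Tuple[int, int, int] = (12, 12, 4),
    seed: int = 0,
    ranges: Optional[Dict[str, Tuple[float, float]]] = None,
    low_t2s_fraction: float = 0.04,
    low_gm_fraction: float = 0.15,
    noise_sd: float = 0.25,
    drift_coefs: Tuple[float, float, float] = (2.0, -1.0, 0.5),
) -> GroundTruth:
    """Draw ground-truth maps uniformly within physiological ranges.

    Reproducible for a fixed seed.  ``low_t2s_fraction`` of voxels receive a
    baseline T2* below the 30 ms parenchymal cutoff and ``low_gm_fraction``
    a GM probability below 0.5, to exercise masking downstream.
    """
    if any(s <= 0 for s in shape):
        raise ValueError("shape must be positive")
    rng = np.random.default_rng(seed)
    rr = dict(DEFAULT_TRUTH_RANGES)
    if ranges:
        rr.update(ranges)
    for key, (lo, hi) in rr.items():
        if hi < lo:
            raise ValueError(f"invalid range for {key}: ({lo}, {hi})")

    def draw(key: str) -> np.ndarray:
        lo, hi = rr[key]
        return rng.uniform(lo, hi, size=shape)

    t2s0 = draw("t2s0_ms")
    n_low = int(round(low_t2s_fraction * t2s0.size))
    if n_low:
        flat = rng.choice(t2s0.size, size=n_low, replace=False)
        lo, hi = rr["low_t2s0_ms"]
        t2s0.ravel()[flat] = rng.uniform(lo, hi, size=n_low)
    gm = draw("gm_prob")
    n_lowgm = int(round(low_gm_fraction * gm.size))
    if n_lowgm:
        flat = rng.choice(gm.size, size=n_lowgm, replace=False)
        gm.ravel()[flat] = rng.uniform(0.0, 0.45, size=n_lowgm)
    return GroundTruth(
        shape=tuple(shape),
        cbf0=draw("cbf0"),
        t2s0_ms=t2s0,
        m=draw("m"),
        oef=draw("oef"),
        gm_prob=gm,
        f_hc=draw("f_hc"),
        f_ho=draw("f_ho"),
        s0=draw("s0"),
        noise_sd=float(noise_sd),
        drift_coefs=tuple(float(c) for c in drift_coefs),
        seed=int(seed),
    )


def _et_curves(
    program: RespiratoryProgram, paradigm: GasParadigm, times: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Programmed alveolar ET time courses (O2, CO2) at ``times``."""

    def course(base: float, d_hc, d_ho) -> np.ndarray:
        out = np.full_like(times, base, dtype=float)
        for amps, blocks in ((d_hc, paradigm.hc_blocks), (d_ho, paradigm.ho_blocks)):
            amps = np.broadcast_to(np.asarray(amps, dtype=float), (len(blocks),))
            for amp, block in zip(amps, blocks):
                out += amp * block_response(times, (block,))
        return out

    eto2 = course(program.eto2_0, program.d_eto2_hc, program.d_eto2_ho)
    etco2 = course(program.etco2_0, program.d_etco2_hc, program.d_etco2_ho)
    return eto2, etco2


def expected_fi_schedule(
    program: RespiratoryProgram, paradigm: GasParadigm, gas: str
) -> Callable[[np.ndarray], np.ndarray]:
    """Piecewise-constant delivered FI schedule (dry analyzer mmHg)."""
    if gas == "o2":
        base, in_hc, in_ho = program.fio2_0, program.fio2_hc, program.fio2_ho
    elif gas == "co2":
        base, in_hc, in_ho = program.fico2_0, program.fico2_hc, program.fico2_0
    else:
        raise ValueError("gas must be 'o2' or 'co2'")

    def schedule(t):
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, base, dtype=float)
        for onset, dur in paradigm.hc_blocks:
            out[(t >= onset) & (t < onset + dur)] = in_hc
        for onset, dur in paradigm.ho_blocks:
            out[(t >= onset) & (t < onset + dur)] = in_ho
        return out

    return schedule


def simulate_respiratory_trace(
    paradigm: GasParadigm,
    program: RespiratoryProgram = RespiratoryProgram(),
    breath_period: float = 4.0,
    sampling_rate: float = 10.0,
    attenuation: float = 0.1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> RespiratoryTrace:
    """Breath-by-breath O2/CO2 analyzer trace under the gas paradigm.

    Within each breath the waveform swings between the fixed-inspired level
    and the (dry-converted) end-tidal level, phase-locked across channels
    (end-expiration at half-period points).  End-tidal plateaus follow the
    HRF-convolved block responses; inspired levels step with the delivered
    schedule.  The sampling-line low-pass is modelled by shrinking the
    peak-to-peak amplitude by ``attenuation`` symmetrically about the breath
    mean, which raises observed FI and lowers observed ET by equal amounts.
    """
    if not 0 <= attenuation < 1:
        raise ValueError("attenuation must lie in [0, 1)")
    if breath_period <= 0:
        raise ValueError("breath period must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, paradigm.total_duration, 1.0 / sampling_rate)
    eto2_alv, etco2_alv = _et_curves(program, paradigm, t)
    pb = program.barometric_pressure
    dry = pb / (pb - WATER_VAPOR_MMHG)
    phase = np.cos(2.0 * np.pi * t / breath_period)

    def channel(et_alv: np.ndarray, fi: np.ndarray) -> np.ndarray:
        et_dry = et_alv * dry
        mid = 0.5 * (et_dry + fi)
        amp = 0.5 * (et_dry - fi)
        x = mid - (1.0 - attenuation) * amp * phase
        if noise_sd > 0:
            x = x + rng.normal(0.0, noise_sd, size=x.shape)
        return np.clip(x, 0.0, None)

    fi_o2 = expected_fi_schedule(program, paradigm, "o2")(t)
    fi_co2 = expected_fi_schedule(program, paradigm, "co2")(t)
    return RespiratoryTrace(
        time=t,
        po2=channel(eto2_alv, fi_o2),
        pco2=channel(etco2_alv, fi_co2),
        sampling_rate=sampling_rate,
    )


def condition_cao2(
    program: RespiratoryProgram, blood: physiology.BloodParams
) -> Tuple[float, float, float]:
    """Arterial O2 content at baseline, hypercapnia and hyperoxia."""
    return (
        physiology.arterial_o2_content(program.pao2_0, blood).cao2,
        physiology.arterial_o2_content(program.pao2_hc, blood).cao2,
        physiology.arterial_o2_content(program.pao2_ho, blood).cao2,
    )


def simulate_dual_echo_series(
    truth: GroundTruth,
    paradigm: GasParadigm,
    geometry: AcquisitionGeometry,
    params: calibration.ModelParams = calibration.ModelParams(),
    constants: perfusion.PerfusionConstants = perfusion.PerfusionConstants(),
    program: RespiratoryProgram = RespiratoryProgram(),
    seed: Optional[int] = None,
    ar1_rho: float = 0.0,
) -> Tuple[np.ndarray, pd.DataFrame]:
    """Interleaved dual-echo pCASL series implied by the ground truth.

    Per TR two echo frames are emitted, label and control alternating.
    Condition states: R2* changes to the gases are forward-generated from
    the truth (M, OEF) through the calibration model; the label state's S0
    deficit follows the pCASL quantification model at that condition's CBF
    (with slice-dependent PLD, and the shortened blood T1 for the hyperoxic
    state).  Each channel's time course interpolates between its condition
    levels along the HRF-convolved block responses, so the analysis GLM is
    the exact generative model and the full chain inverts the simulation in
    the noiseless limit.  Returns (4D array x,y,z,frames; annotations).
    """
    nx, ny, nz = truth.shape
    if geometry.n_slices != nz:
        raise ValueError("geometry.n_slices must equal the grid's slice count")
    if seed is None:
        seed = truth.seed
    rng = np.random.default_rng(seed)
    n_trs = int(np.floor(paradigm.total_duration / geometry.tr))
    ann = frame_annotations(n_trs, geometry)
    tr_times = np.arange(n_trs) * geometry.tr

    h_hc = block_response(tr_times, paradigm.hc_blocks) if paradigm.hc_blocks else np.zeros(n_trs)
    h_ho = block_response(tr_times, paradigm.ho_blocks) if paradigm.ho_blocks else np.zeros(n_trs)

    cao2_0, cao2_hc, cao2_ho = condition_cao2(program, params.blood)
    d_r2s_hc = np.asarray(
        calibration.forward_delta_r2star(
            truth.m, truth.oef, truth.f_hc, params.r_hc, cao2_hc, cao2_0, params
        )
    )
    d_r2s_ho = np.asarray(
        calibration.forward_delta_r2star(
            truth.m, truth.oef, truth.f_ho, params.r_ho, cao2_ho, cao2_0, params
        )
    )

    r2s0 = 1000.0 / truth.t2s0_ms  # s^-1
    r2s = {"base": r2s0, "hc": r2s0 + d_r2s_hc, "ho": r2s0 + d_r2s_ho}
    cbf = {"base": truth.cbf0, "hc": truth.cbf0 * truth.f_hc, "ho": truth.cbf0 * truth.f_ho}
    t1b = {
        "base": None,
        "hc": None,  # the ~7 mmHg hypercapnic PaO2 rise has a negligible T1 effect
        "ho": physiology.blood_t1_hyperoxia(program.pao2_ho, program.pao2_0, params.blood),
    }
    plds = perfusion.slice_plds(geometry)

    # per-channel condition levels: S(TE) = S0_state * exp(-TE * R2*_cond)
    levels: Dict[Tuple[int, str, str], np.ndarray] = {}
    for cond in ("base", "hc", "ho"):
        kern = perfusion.cbf_kernel(plds, constants, geometry, t1b=t1b[cond])
        dm = cbf[cond] * truth.s0 / kern[np.newaxis, np.newaxis, :]
        for state, s0_state in (("control", truth.s0), ("label", truth.s0 - dm)):
            for echo, te in ((1, geometry.te1), (2, geometry.te2)):
                levels[(echo, state, cond)] = s0_state * np.exp(-te * r2s[cond])

    drift = drift_columns(ann["time"].to_numpy()) @ np.asarray(truth.drift_coefs)
    data = np.empty((nx, ny, nz, 2 * n_trs))
    for i in range(n_trs):
        state = "label" if i % 2 == 0 else "control"
        for echo in (1, 2):
            frame = 2 * i + (echo - 1)
            base = levels[(echo, state, "base")]
            sig = (
                base
                + (levels[(echo, state, "hc")] - base) * h_hc[i]
                + (levels[(echo, state, "ho")] - base) * h_ho[i]
            )
            data[..., frame] = sig + drift[frame]

    if truth.noise_sd > 0:
        noise = rng.normal(0.0, truth.noise_sd, size=data.shape)
        if ar1_rho:
            # serially correlated (physiological-like) noise along frames
            for j in range(1, data.shape[-1]):
                noise[..., j] += ar1_rho * noise[..., j - 1]
            noise *= np.sqrt(1.0 - ar1_rho**2)
        data += noise
    return data, ann
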