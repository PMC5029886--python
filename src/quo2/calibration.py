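"""The generalized calibration model (GCM) solved for M and resting OEF.

Each gas challenge constrains the BOLD calibration parameter M as a function
of the unknown resting oxygen extraction fraction E:

    M(E) = b / (1 - f^alpha * d(E)^beta)

where b = exp(-TE_ref * dR2*) - 1 is the fractional BOLD signal change of
the challenge, f the CBF ratio, alpha the flow-volume coupling exponent,
beta the deoxyhemoglobin nonlinearity, and d(E) the venous deoxyhemoglobin
ratio from the oxygen-transport model.  The hypercapnic and hyperoxic
curves intersect at the voxel's (M, OEF); absolute CMRO2 follows as
OEF x CBF_0 x CaO2_0.  Voxels whose curves do not intersect carry no
solution and are excluded from all downstream averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.optimize import brentq

from .physiology import BloodParams, dhb_ratio


@dataclass(frozen=True)
class ModelParams:
    """Assumed parameters of the calibration model."""

    alpha: float = 0.18  # flow-volume coupling exponent
    beta: float = 1.5  # R2* vs deoxyhemoglobin nonlinearity
    r_hc: float = 1.0  # CMRO2 ratio during hypercapnia (1 = isometabolism)
    r_ho: float = 1.0  # CMRO2 ratio during hyperoxia
    te_ref: float = 0.030  # s, echo time at which M is expressed
    blood: BloodParams = field(default_factory=BloodParams)
    umol_per_ml_o2: float = 44.6
    oef_bounds: Tuple[float, float] = (0.01, 0.99)
    grid_step: float = 1e-3  # OEF grid for the sign-change scan
    root_tol: float = 1e-7  # bisection tolerance on OEF

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.r_hc <= 0 or self.r_ho <= 0:
            raise ValueError("CMRO2 ratios must be positive")
        if self.te_ref <= 0:
            raise ValueError("TE_ref must be positive")


@dataclass
class ConditionResponses:
    """Measured inputs to the calibration model.

    Voxelwise arrays (or scalars): resting CBF, CBF ratios and R2* changes
    for each gas; subject-level scalars: arterial O2 content per condition.
    """

    cbf0: np.ndarray  # mL/100 g/min
    f_hc: np.ndarray  # unitless
    f_ho: np.ndarray  # unitless (typically the GM-mean substituted value)
    d_r2s_hc: np.ndarray  # s^-1
    d_r2s_ho: np.ndarray  # s^-1
    cao2_0: float  # mL O2/dL
    cao2_hc: float
    cao2_ho: float


@dataclass
class CalibrationSolution:
    """Headline outputs of one voxel."""

    solved: bool
    m: float = np.nan  # fraction at TE_ref
    oef: float = np.nan  # fraction
    o2_delivery: float = np.nan  # umol/100 g/min
    cmro2: float = np.nan  # umol/100 g/min
    root_count: int = 0


def bold_fraction(d_r2s, te_ref: float = 0.030):
    """Fractional BOLD signal change from an R2* change at TE_ref.

    b = exp(-TE_ref * dR2*) - 1; positive exactly when R2* decreases.
    """
    if te_ref <= 0:
        raise ValueError("TE_ref must be positive")
    b = np.exp(-te_ref * np.asarray(d_r2s, dtype=float)) - 1.0
    return b if b.ndim else float(b)


def gas_curve(
    e_grid: np.ndarray,
    b: float,
    f: float,
    r: float,
    cao2_gas: float,
    cao2_0: float,
    params: ModelParams,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One gas's M(E) curve on an OEF grid.

    Returns (M values, validity mask, curve denominator).  Grid points where
    the deoxyhemoglobin ratio is non-positive, or where the denominator
    1 - f^alpha d^beta vanishes (the curve's pole), are invalid.
    """
    e = np.asarray(e_grid, dtype=float)
    d = np.asarray(dhb_ratio(e, f, r, cao2_gas, cao2_0, params.blood))
    pos = np.isfinite(d) & (d > 0)
    denom = np.full_like(e, np.nan)
    denom[pos] = 1.0 - f**params.alpha * d[pos] ** params.beta
    valid = pos & (np.abs(denom) > 1e-9)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(valid, b / denom, np.nan)
    return m, valid, denom


def forward_delta_r2star(
    m, oef, f, r: float, cao2_gas: float, cao2_0: float, params: ModelParams
):
    """R2* change produced by a gas challenge in a voxel with known (M, OEF).

    Exact inverse of the curve definition:
    dR2* = -ln(1 + M (1 - f^alpha d^beta)) / TE_ref.  Used by the simulator;
    solving the two forward-generated gases recovers (M, OEF).
    """
    m = np.asarray(m, dtype=float)
    oef = np.asarray(oef, dtype=float)
    f = np.asarray(f, dtype=float)
    d = np.asarray(dhb_ratio(oef, f, r, cao2_gas, cao2_0, params.blood))
    if np.any(~np.isfinite(d)) or np.any(d <= 0):
        raise ValueError("non-physical deoxyhemoglobin ratio")
    arg = 1.0 + m * (1.0 - f**params.alpha * d**params.beta)
    if np.any(arg <= 0):
        raise ValueError("log argument non-positive; inputs outside model range")
    out = -np.log(arg) / params.te_ref
    return out if out.ndim else float(out)


def o2_delivery(cbf0, cao2_0, umol_per_ml_o2: float = 44.6):
    """Resting O2 delivery, umol/100 g/min.

    CBF (mL/100 g/min) times CaO2 (mL O2/dL = mL O2 per 100 mL blood,
    hence /100 per mL blood) times the mL-to-umol O2 conversion.
    """
    out = np.asarray(cbf0, dtype=float) * (np.asarray(cao2_0, dtype=float) / 100.0) * umol_per_ml_o2
    return out if out.ndim else float(out)


def cmro2(oef, delivery):
    """Cerebral metabolic rate of O2: OEF times O2 delivery."""
    out = np.asarray(oef, dtype=float) * np.asarray(delivery, dtype=float)
    return out if out.ndim else float(out)


def solve_voxel(
    cbf0: float,
    f_hc: float,
    f_ho: float,
    d_r2s_hc: float,
    d_r2s_ho: float,
    cao2_0: float,
    cao2_hc: float,
    cao2_ho: float,
    params: ModelParams = ModelParams(),
) -> CalibrationSolution:
    """Intersect the HC and HO curves for one voxel.

    Roots of M_HC(E) - M_HO(E) are located by a sign-change scan on a
    uniform OEF grid and refined by bisection.  Grid intervals that straddle
    a pole of either curve (where its denominator changes sign) are not
    brackets and are skipped.  A root must deliver M > 0 and OEF strictly
    inside the search bounds; if several qualify the smallest OEF is taken
    and the count recorded.
    """
    lo, hi = params.oef_bounds
    e = np.arange(lo, hi + params.grid_step / 2, params.grid_step)
    b_hc = bold_fraction(d_r2s_hc, params.te_ref)
    b_ho = bold_fraction(d_r2s_ho, params.te_ref)
    m_hc, v_hc, den_hc = gas_curve(e, b_hc, f_hc, params.r_hc, cao2_hc, cao2_0, params)
    m_ho, v_ho, den_ho = gas_curve(e, b_ho, f_ho, params.r_ho, cao2_ho, cao2_0, params)
    g = m_hc - m_ho
    ok = v_hc & v_ho & np.isfinite(g)
    if not ok.any():
        return CalibrationSolution(solved=False)

    def g_of(x: float) -> float:
        mh, _, _ = gas_curve(np.array([x]), b_hc, f_hc, params.r_hc, cao2_hc, cao2_0, params)
        mo, _, _ = gas_curve(np.array([x]), b_ho, f_ho, params.r_ho, cao2_ho, cao2_0, params)
        return float(mh[0] - mo[0])

    pair_ok = (
        ok[:-1]
        & ok[1:]
        & (np.sign(den_hc[:-1]) == np.sign(den_hc[1:]))
        & (np.sign(den_ho[:-1]) == np.sign(den_ho[1:]))
    )
    brackets = np.nonzero(pair_ok & (g[:-1] * g[1:] <= 0) & ~((g[:-1] == 0) & (g[1:] == 0)))[0]
    roots = []
    for i in brackets:
        if g[i] == 0.0:
            root = float(e[i])
        elif g[i + 1] == 0.0:
            if i + 1 == len(e) - 1 or i + 1 in brackets:
                continue  # counted by the next interval or at the boundary
            root = float(e[i + 1])
        else:
            root = float(brentq(g_of, e[i], e[i + 1], xtol=params.root_tol))
        m_root, valid, _ = gas_curve(
            np.array([root]), b_hc, f_hc, params.r_hc, cao2_hc, cao2_0, params
        )
        if valid[0] and m_root[0] > 0 and lo < root < hi:
            roots.append((root, float(m_root[0])))
    if not roots:
        return CalibrationSolution(solved=False)
    roots.sort()
    oef, m = roots[0]
    deliv = o2_delivery(cbf0, cao2_0, params.umol_per_ml_o2)
    return CalibrationSolution(
        solved=True,
        m=m,
        oef=oef,
        o2_delivery=deliv,
        cmro2=cmro2(oef, deliv),
        root_count=len(roots),
    )


@dataclass
class SolutionMaps:
    """Voxelwise calibration outputs plus bookkeeping."""

    m: np.ndarray  # fraction
    oef: np.ndarray
    o2_delivery: np.ndarray
    cmro2: np.ndarray
    solved: np.ndarray  # bool
    root_count: np.ndarray  # int


def solve_map(
    responses: ConditionResponses,
    include: np.ndarray,
    params: ModelParams = ModelParams(),
) -> SolutionMaps:
    """Voxelwise GCM solve over the included voxels."""
    include = np.asarray(include, dtype=bool)
    if not include.any():
        raise ValueError("empty include set")
    shape = include.shape
    m = np.full(shape, np.nan)
    oef = np.full(shape, np.nan)
    deliv = np.full(shape, np.nan)
    cm = np.full(shape, np.nan)
    solved = np.zeros(shape, dtype=bool)
    rc = np.zeros(shape, dtype=int)
    cbf0 = np.broadcast_to(np.asarray(responses.cbf0, dtype=float), shape)
    f_hc = np.broadcast_to(np.asarray(responses.f_hc, dtype=float), shape)
    f_ho = np.broadcast_to(np.asarray(responses.f_ho, dtype=float), shape)
    dhc = np.broadcast_to(np.asarray(responses.d_r2s_hc, dtype=float), shape)
    dho = np.broadcast_to(np.asarray(responses.d_r2s_ho, dtype=float), shape)
    for idx in zip(*np.nonzero(include)):
        vals = (cbf0[idx], f_hc[idx], f_ho[idx], dhc[idx], dho[idx])
        if not all(np.isfinite(v) for v in vals):
            continue
        sol = solve_voxel(
            *vals, responses.cao2_0, responses.cao2_hc, responses.cao2_ho, params
        )
        if sol.solved:
            solved[idx] = True
            m[idx] = sol.m
            oef[idx] = sol.oef
            deliv[idx] = sol.o2_delivery
            cm[idx] = sol.cmro2
        rc[idx] = sol.root_count
    return SolutionMaps(m=m, oef=oef, o2_delivery=deliv, cmro2=cm, solved=solved, root_count=rc)


def detection_rate(solved: np.ndarray, include: np.ndarray, roi: Optional[np.ndarray] = None) -> float:
    """Percent of included (ROI) voxels where a solution was found."""
    sel = np.asarray(include, dtype=bool)
    if roi is not None:
        sel = sel & np.asarray(roi, dtype=bool)
    n = int(sel.sum())
    if n == 0:
        raise ValueError("no included voxels in ROI")
    return 100.0 * float(np.asarray(solved, dtype=bool)[sel].sum()) / n


def roi_weighted_average(
    volume: np.ndarray,
    gm_prob: np.ndarray,
    roi: np.ndarray,
    include: np.ndarray,
    solved: Optional[np.ndarray] = None,
    gm_cutoff: float = 0.5,
) -> float:
    """GM-probability-weighted ROI mean.

    Restricted to ROI voxels with GM probability at or above the cutoff that
    pass the exclusion mask; for model outputs (M, OEF, CMRO2) unsolved
    voxels are additionally dropped via ``solved``.
    """
    gm = np.asarray(gm_prob, dtype=float)
    sel = (
        np.asarray(roi, dtype=bool)
        & np.asarray(include, dtype=bool)
        & (gm >= gm_cutoff)
        & np.isfinite(volume)
    )
    if solved is not None:
        sel &= np.asarray(solved, dtype=bool)
    if not sel.any():
        raise ValueError("empty ROI after exclusions")
    w = gm[sel]
    return float(np.sum(w * np.asarray(volume, dtype=float)[sel]) / np.sum(w))
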