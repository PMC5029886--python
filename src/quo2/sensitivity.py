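"""Sensitivity of the calibration outputs to systematic and random errors.

Systematic sweeps vary one assumed parameter (alpha, beta, [Hb], the
CMRO2 ratios during each gas, or the hyperoxic flow ratio) across its
plausible range while the measured inputs stay fixed, re-solving the model
at each grid value.  Random-error propagation scales one measured input
(the hypercapnic flow response or either R2* change) by 1 + e for e in
[-0.33, +0.33] and expresses the displacement of the re-solved estimate as
a two-point coefficient of variation against the unperturbed solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .calibration import (
    CalibrationSolution,
    ModelParams,
    cmro2,
    forward_delta_r2star,
    o2_delivery,
    solve_voxel,
)
from .physiology import arterial_o2_content

SWEEP_PARAMETERS = ("alpha", "beta", "hb", "r_hc", "r_ho", "f_ho")
DEFAULT_SWEEP_RANGES: Dict[str, Tuple[float, float]] = {
    "alpha": (0.15, 0.45),
    "beta": (1.0, 1.5),
    "hb": (11.0, 17.0),  # g Hb/dL
    "r_hc": (0.90, 1.10),  # +/- 1% CMRO2 per mmHg CO2 at ~10 mmHg change
    "r_ho": (0.93, 1.07),  # +/- 1% CMRO2 per 40 mmHg O2 at ~260 mmHg change
    "f_ho": (0.90, 1.00),
}
ERROR_INPUTS = ("dpct_cbf_hc", "d_r2s_hc", "d_r2s_ho")


@dataclass(frozen=True)
class GmBaseline:
    """GM-like baseline voxel for sensitivity analyses.

    Measured inputs are forward-generated from a typical gray-matter state
    (M 5%, OEF 0.39, CBF0 50 mL/100 g/min, 50% hypercapnic flow increase,
    no hyperoxic flow change) at the group-mean end-tidal O2 tensions
    (111 mmHg baseline, 118 hypercapnia, 370 hyperoxia).
    """

    m: float = 0.05
    oef: float = 0.39
    cbf0: float = 50.0
    f_hc: float = 1.5
    f_ho: float = 1.0
    pao2_0: float = 111.0
    pao2_hc: float = 118.0
    pao2_ho: float = 370.0
    params: ModelParams = field(default_factory=ModelParams)

    def cao2(self, params: ModelParams | None = None) -> Tuple[float, float, float]:
        p = self.params if params is None else params
        return tuple(
            arterial_o2_content(pa, p.blood).cao2
            for pa in (self.pao2_0, self.pao2_hc, self.pao2_ho)
        )

    def responses(self) -> Tuple[float, float]:
        """Forward-generated (dR2*_HC, dR2*_HO) measured inputs."""
        cao2_0, cao2_hc, cao2_ho = self.cao2()
        d_hc = forward_delta_r2star(
            self.m, self.oef, self.f_hc, self.params.r_hc, cao2_hc, cao2_0, self.params
        )
        d_ho = forward_delta_r2star(
            self.m, self.oef, self.f_ho, self.params.r_ho, cao2_ho, cao2_0, self.params
        )
        return float(d_hc), float(d_ho)

    def solve(
        self,
        params: ModelParams | None = None,
        f_hc: float | None = None,
        f_ho: float | None = None,
        d_r2s_hc: float | None = None,
        d_r2s_ho: float | None = None,
    ) -> CalibrationSolution:
        p = self.params if params is None else params
        base_hc, base_ho = self.responses()
        cao2_0, cao2_hc, cao2_ho = self.cao2(p)
        sol = solve_voxel(
            self.cbf0,
            self.f_hc if f_hc is None else f_hc,
            self.f_ho if f_ho is None else f_ho,
            base_hc if d_r2s_hc is None else d_r2s_hc,
            base_ho if d_r2s_ho is None else d_r2s_ho,
            cao2_0,
            cao2_hc,
            cao2_ho,
            p,
        )
        if sol.solved:
            # delivery/CMRO2 recomputed so a swept [Hb] propagates into CaO2
            deliv = o2_delivery(self.cbf0, cao2_0, p.umol_per_ml_o2)
            sol = replace(sol, o2_delivery=deliv, cmro2=cmro2(sol.oef, deliv))
        return sol


def sweep_systematic(
    parameter: str,
    baseline: GmBaseline = GmBaseline(),
    value_range: Tuple[float, float] | None = None,
    n_points: int = 13,
) -> pd.DataFrame:
    """Re-solve the model across one assumed parameter's range.

    Returns a tidy table (value, m, oef, cmro2, o2_delivery, solved); rows
    where the perturbed model has no solution are flagged, not fatal.
    """
    if parameter not in SWEEP_PARAMETERS:
        raise ValueError(f"parameter must be one of {SWEEP_PARAMETERS}")
    if not baseline.solve().solved:
        raise ValueError("baseline voxel is not solvable at the default parameters")
    lo, hi = DEFAULT_SWEEP_RANGES[parameter] if value_range is None else value_range
    rows = []
    for value in np.linspace(lo, hi, n_points):
        params = baseline.params
        f_ho = None
        if parameter == "hb":
            params = replace(params, blood=replace(params.blood, hb=float(value)))
        elif parameter == "f_ho":
            f_ho = float(value)
        else:
            params = replace(params, **{parameter: float(value)})
        sol = baseline.solve(params=params, f_ho=f_ho)
        rows.append(
            {
                "parameter": parameter,
                "value": float(value),
                "m": sol.m,
                "oef": sol.oef,
                "cmro2": sol.cmro2,
                "o2_delivery": sol.o2_delivery,
                "solved": sol.solved,
            }
        )
    return pd.DataFrame(rows)


def cv_between(true_value: float, simulated_value: float) -> float:
    """Two-point CV (percent): SD over mean of {true, simulated}.

    For simulated = true * (1 + e) this equals 100 |e| / (sqrt(2) (1 + e/2)),
    hence asymmetric: about 20% at e = +0.33 and 28% at e = -0.33.
    """
    pair = np.array([true_value, simulated_value], dtype=float)
    mean = pair.mean()
    if mean == 0:
        raise ValueError("zero mean")
    return 100.0 * float(np.std(pair, ddof=1) / mean)


def propagate_random_error(
    input_name: str,
    baseline: GmBaseline = GmBaseline(),
    errors: np.ndarray | None = None,
) -> pd.DataFrame:
    """Propagate a relative measurement error through the calibration model.

    The named input is scaled by (1 + e) for each e on the grid, the voxel
    re-solved, and the displacement of M and OEF expressed as two-point CVs
    against the unperturbed solution.  The hypercapnic flow error acts on
    the percent change (f_HC - 1).  Because neither resting CBF nor CaO2 is
    varied, the OEF and CMRO2 CV curves are identical by construction.
    """
    if input_name not in ERROR_INPUTS:
        raise ValueError(f"input must be one of {ERROR_INPUTS}")
    if errors is None:
        errors = np.linspace(-0.33, 0.33, 23)
    errors = np.asarray(errors, dtype=float)
    if not np.any(errors == 0):
        errors = np.sort(np.append(errors, 0.0))
    ref = baseline.solve()
    if not ref.solved:
        raise ValueError("baseline voxel is not solvable at the default parameters")
    base_hc, base_ho = baseline.responses()
    rows = []
    for e in errors:
        kwargs = {}
        if input_name == "dpct_cbf_hc":
            kwargs["f_hc"] = 1.0 + (baseline.f_hc - 1.0) * (1.0 + e)
        elif input_name == "d_r2s_hc":
            kwargs["d_r2s_hc"] = base_hc * (1.0 + e)
        else:
            kwargs["d_r2s_ho"] = base_ho * (1.0 + e)
        sol = baseline.solve(**kwargs)
        rows.append(
            {
                "input": input_name,
                "error": float(e),
                "m": sol.m,
                "oef": sol.oef,
                "cv_m_pct": cv_between(ref.m, sol.m) if sol.solved else np.nan,
                "cv_oef_pct": cv_between(ref.oef, sol.oef) if sol.solved else np.nan,
                "solved": sol.solved,
            }
        )
    return pd.DataFrame(rows)
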