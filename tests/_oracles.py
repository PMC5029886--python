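"""Independent oracles for the calibration solver.

The brute-force oracle never calls the bisection solver: it evaluates both
gas curves on a dense OEF grid and returns the grid point minimizing the
curve separation, so solver and oracle can disagree only through the grid
resolution.
"""

import numpy as np

from quo2.calibration import ModelParams, bold_fraction, gas_curve


def brute_force_oef(
    f_hc, f_ho, d_r2s_hc, d_r2s_ho, cao2_0, cao2_hc, cao2_ho,
    params: ModelParams = ModelParams(), step: float = 1e-5,
):
    """Exhaustive grid minimization of |M_HC(E) - M_HO(E)|.

    Returns (OEF at the minimum, M there), or (nan, nan) when the curves
    are nowhere jointly valid.
    """
    lo, hi = params.oef_bounds
    grid = np.arange(lo, hi, step)
    b_hc = bold_fraction(d_r2s_hc, params.te_ref)
    b_ho = bold_fraction(d_r2s_ho, params.te_ref)
    m1, v1, _ = gas_curve(grid, b_hc, f_hc, params.r_hc, cao2_hc, cao2_0, params)
    m2, v2, _ = gas_curve(grid, b_ho, f_ho, params.r_ho, cao2_ho, cao2_0, params)
    sep = np.where(v1 & v2 & (m1 > 0), np.abs(m1 - m2), np.inf)
    i = int(np.argmin(sep))
    if not np.isfinite(sep[i]):
        return np.nan, np.nan
    return float(grid[i]), float(m1[i])
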