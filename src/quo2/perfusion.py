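"""ASL perfusion quantification.

Converts control-minus-label difference signals to CBF in mL/100 g/min with
the single-compartment pCASL model and consensus constants, a post-labeling
delay that grows linearly with slice index in the 2D readout, and the
arterial-blood-T1 correction of the hyperoxic flow response, whose
GM-averaged value substitutes for the noisy voxelwise estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .signal import AcquisitionGeometry


@dataclass(frozen=True)
class PerfusionConstants:
    """Constants of the single-compartment pCASL quantification model."""

    lam: float = 0.9  # mL/g, blood-brain partition coefficient
    label_efficiency: float = 0.85
    t1b: float = 1.65  # s, arterial blood T1 at 3 T
    umol_per_ml_o2: float = 44.6  # ideal gas at STPD

    def __post_init__(self) -> None:
        for name in ("lam", "label_efficiency", "t1b", "umol_per_ml_o2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CBFMaps:
    """Perfusion outputs of one subject."""

    cbf0: np.ndarray  # mL/100 g/min
    dpct_cbf_hc: np.ndarray  # percent
    dpct_cbf_ho_raw: np.ndarray  # percent, before blood-T1 correction
    dpct_cbf_ho_corrected: np.ndarray  # percent
    f_hc: np.ndarray  # unitless ratio, 1 + dpct/100
    f_ho_gm: float  # unitless ratio from the GM-mean corrected HO response
    t1b_ho: float  # s


def slice_pld(slice_index: int, geometry: AcquisitionGeometry) -> float:
    """Post-labeling delay of a slice (1-based index), linear in index."""
    n = geometry.n_slices
    if not 1 <= slice_index <= n:
        raise ValueError(f"slice index {slice_index} outside 1..{n}")
    if n == 1:
        return geometry.first_slice_pld
    frac = (slice_index - 1) / (n - 1)
    return geometry.first_slice_pld + frac * (geometry.last_slice_pld - geometry.first_slice_pld)


def slice_plds(geometry: AcquisitionGeometry) -> np.ndarray:
    return np.array([slice_pld(i, geometry) for i in range(1, geometry.n_slices + 1)])


def cbf_kernel(
    pld: np.ndarray | float,
    constants: PerfusionConstants,
    geometry: AcquisitionGeometry,
    t1b: Optional[float] = None,
) -> np.ndarray | float:
    """Quantification kernel K such that CBF = K * (dM / M0).

    K = 6000 * lambda * exp(PLD/T1b) /
        (2 * alpha_label * T1b * (1 - exp(-tau/T1b)))
    """
    t1 = constants.t1b if t1b is None else t1b
    if t1 <= 0:
        raise ValueError("blood T1 must be positive")
    num = 6000.0 * constants.lam * np.exp(np.asarray(pld, dtype=float) / t1)
    den = 2.0 * constants.label_efficiency * t1 * (1.0 - np.exp(-geometry.label_duration / t1))
    return num / den


def quantify_cbf(
    asl: np.ndarray,
    m0: np.ndarray,
    constants: PerfusionConstants,
    geometry: AcquisitionGeometry,
    t1b: Optional[float] = None,
) -> np.ndarray:
    """CBF map (mL/100 g/min) from an ASL difference map and M0 map.

    The third array axis indexes slices; the PLD of each slice enters the
    kernel.  Non-positive M0 marks the voxel invalid (NaN).  Linear in the
    difference signal, hence exactly invertible for simulation.
    """
    asl = np.asarray(asl, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    if asl.shape != m0.shape:
        raise ValueError("ASL and M0 shapes differ")
    if asl.shape[2] != geometry.n_slices:
        raise ValueError("third axis must match geometry.n_slices")
    kern = cbf_kernel(slice_plds(geometry), constants, geometry, t1b)
    with np.errstate(divide="ignore", invalid="ignore"):
        cbf = np.where(m0 > 0, asl / np.where(m0 > 0, m0, np.nan), np.nan)
    return cbf * kern[np.newaxis, np.newaxis, :]


def asl_from_cbf(
    cbf: np.ndarray,
    m0: np.ndarray,
    constants: PerfusionConstants,
    geometry: AcquisitionGeometry,
    t1b: Optional[float] = None,
) -> np.ndarray:
    """Inverse of :func:`quantify_cbf`; forward model for the simulator."""
    kern = cbf_kernel(slice_plds(geometry), constants, geometry, t1b)
    return np.asarray(cbf, dtype=float) * np.asarray(m0, dtype=float) / kern[np.newaxis, np.newaxis, :]


def correct_hyperoxia_cbf(
    dpct_cbf_ho_raw: np.ndarray,
    t1b_ho: float,
    constants: PerfusionConstants,
    geometry: AcquisitionGeometry,
    gm_prob: np.ndarray,
    include: Optional[np.ndarray] = None,
    gm_cutoff: float = 0.5,
) -> Tuple[np.ndarray, float]:
    """Re-quantify the hyperoxic flow response with the shortened blood T1.

    Dissolved paramagnetic O2 shortens arterial T1 during hyperoxia, which
    biases an HO flow response quantified with the baseline T1.  Each
    voxel's HO CBF is rescaled by the ratio of the quantification kernels at
    its slice PLD, K(T1b_HO)/K(T1b).  Returns the corrected percent-change
    map and its GM-probability-weighted mean, which downstream replaces the
    voxelwise HO flow response (a per-subject whole-brain estimate, the HO
    response being too noisy voxelwise).
    """
    if not 0 < t1b_ho <= constants.t1b:
        raise ValueError("T1b_HO must lie in (0, T1b]")
    plds = slice_plds(geometry)
    factor = cbf_kernel(plds, constants, geometry, t1b_ho) / cbf_kernel(plds, constants, geometry)
    f_raw = 1.0 + np.asarray(dpct_cbf_ho_raw, dtype=float) / 100.0
    f_corr = f_raw * factor[np.newaxis, np.newaxis, :]
    corrected = 100.0 * (f_corr - 1.0)
    sel = (np.asarray(gm_prob, dtype=float) >= gm_cutoff) & np.isfinite(corrected)
    if include is not None:
        sel &= np.asarray(include, dtype=bool)
    if not sel.any():
        raise ValueError("no GM voxels available for the whole-brain HO estimate")
    w = np.asarray(gm_prob, dtype=float)[sel]
    gm_mean = float(np.sum(w * corrected[sel]) / np.sum(w))
    return corrected, gm_mean
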