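"""Dual-echo pCASL signal extraction.

The interleaved series holds two gradient-echo images per TR, with label and
control frames alternating between TRs.  A single voxelwise GLM extracts,
for each of the four channels (echo x label-state), a baseline level and
hypercapnia/hyperoxia response amplitudes, sharing polynomial drift terms
across channels.  Per-state S0 and R2* then follow from the two-point
exponential decay, after which BOLD (state-averaged R2*) and ASL
(control-minus-label S0) condition maps are formed, median-filtered, and
screened with the parenchymal exclusion rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .hrf import block_response
from .paradigm import GasParadigm

CHANNELS: Tuple[Tuple[int, str], ...] = (
    (1, "control"),
    (1, "label"),
    (2, "control"),
    (2, "label"),
)
CONDITIONS = ("base", "hc", "ho")


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Dual-echo pCASL acquisition parameters (seconds, mm)."""

    tr: float = 4.12
    te1: float = 0.0084
    te2: float = 0.030
    n_slices: int = 21
    first_slice_pld: float = 0.900
    last_slice_pld: float = 1.986
    label_duration: float = 2.0
    voxel_size: Tuple[float, float, float] = (4.5, 4.5, 4.95)

    def __post_init__(self) -> None:
        if not (self.te2 > self.te1 > 0):
            raise ValueError("require TE2 > TE1 > 0")
        if self.tr <= 0 or self.label_duration <= 0 or self.n_slices < 1:
            raise ValueError("invalid geometry")


def frame_annotations(n_trs: int, geometry: AcquisitionGeometry) -> pd.DataFrame:
    """Frame table for the interleaved series: label first, echoes adjacent."""
    rows = []
    for i in range(n_trs):
        state = "label" if i % 2 == 0 else "control"
        t = i * geometry.tr
        for echo in (1, 2):
            rows.append({"frame": 2 * i + (echo - 1), "tr_index": i, "time": t,
                         "echo": echo, "state": state})
    return pd.DataFrame(rows)


def apply_shared_transforms(
    series: np.ndarray, transforms: Sequence[np.ndarray], annotations: pd.DataFrame
) -> np.ndarray:
    """Resample both echo frames of each TR with one rigid transform.

    ``transforms`` holds one 4x4 voxel-space affine per TR — a single matrix
    shared by the two echoes acquired in that TR, never one per frame.
    Exact identity matrices leave the data untouched (no interpolation).
    """
    n_trs = int(annotations["tr_index"].max()) + 1
    if len(transforms) != n_trs:
        raise ValueError(
            f"need exactly one transform per TR ({n_trs}), got {len(transforms)}"
        )
    out = series.copy()
    for _, row in annotations.iterrows():
        mat = np.asarray(transforms[int(row.tr_index)], dtype=float)
        if mat.shape != (4, 4):
            raise ValueError("transforms must be 4x4 matrices")
        if np.array_equal(mat, np.eye(4)):
            continue
        frame = int(row.frame)
        out[..., frame] = ndimage.affine_transform(
            series[..., frame], mat[:3, :3], offset=mat[:3, 3], order=1, mode="nearest"
        )
    return out


def preprocess(
    series: np.ndarray,
    brain_mask: np.ndarray,
    fwhm_mm: float,
    voxel_size: Tuple[float, float, float] = (4.5, 4.5, 4.95),
    target_mean: float = 100.0,
) -> np.ndarray:
    """Smooth each frame, zero extra-cerebral voxels, normalize brain mean.

    A 3D Gaussian kernel of the stated FWHM is applied per frame (FWHM 0
    disables smoothing); the whole series is then rescaled so the mean over
    brain voxels and frames equals ``target_mean``.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty brain mask")
    out = np.asarray(series, dtype=float).copy()
    if fwhm_mm > 0:
        sigma_vox = [fwhm_mm / (np.sqrt(8.0 * np.log(2.0)) * v) for v in voxel_size]
        for j in range(out.shape[-1]):
            out[..., j] = ndimage.gaussian_filter(out[..., j], sigma=sigma_vox)
    out[~mask, :] = 0.0
    mean = out[mask, :].mean()
    if mean == 0:
        raise ValueError("zero brain mean; cannot normalize")
    return out * (target_mean / mean)


@dataclass
class DesignInfo:
    matrix: pd.DataFrame  # frames x named columns
    hc_regressor: np.ndarray  # convolved HC response at frame times
    ho_regressor: np.ndarray


def build_design(
    paradigm: GasParadigm, annotations: pd.DataFrame, geometry: AcquisitionGeometry
) -> DesignInfo:
    """GLM design: channel baselines, channel x condition responses, drift.

    Four baseline indicator columns (one per echo x state channel), eight
    response columns (channel indicator times the HRF-convolved HC or HO
    block response) and three shared zero-mean polynomial drift columns of
    degrees 1-3.  The channel baselines absorb the offset; a separate
    constant drift column would make the design exactly collinear with
    their sum, so the cubic drift is parameterized without it.
    """
    t = annotations["time"].to_numpy(dtype=float)
    h_hc = block_response(t, paradigm.hc_blocks) if paradigm.hc_blocks else np.zeros_like(t)
    h_ho = block_response(t, paradigm.ho_blocks) if paradigm.ho_blocks else np.zeros_like(t)
    cols: Dict[str, np.ndarray] = {}
    for echo, state in CHANNELS:
        ind = ((annotations["echo"] == echo) & (annotations["state"] == state)).to_numpy(float)
        cols[f"base_e{echo}_{state}"] = ind
    for gas, h in (("hc", h_hc), ("ho", h_ho)):
        for echo, state in CHANNELS:
            ind = cols[f"base_e{echo}_{state}"]
            cols[f"{gas}_e{echo}_{state}"] = ind * h
    tn = 2.0 * (t - t.min()) / (t.max() - t.min()) - 1.0
    for deg in (1, 2, 3):
        c = tn**deg
        cols[f"drift_{deg}"] = c - c.mean()
    X = pd.DataFrame(cols, index=annotations["frame"].to_numpy())
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        norms = np.linalg.norm(X.to_numpy(), axis=0)
        bad = [name for name, nrm in zip(X.columns, norms) if nrm < 1e-12]
        detail = f"; zero columns: {bad}" if bad else ""
        raise ValueError(f"rank-deficient design (rank {rank} < {X.shape[1]}){detail}")
    return DesignInfo(matrix=X, hc_regressor=h_hc, ho_regressor=h_ho)


@dataclass
class GLMResult:
    """Voxelwise OLS coefficients of the dual-echo design."""

    coefficients: Dict[str, np.ndarray]  # column name -> 3D map
    residual_variance: np.ndarray  # 3D map
    shape: Tuple[int, int, int] = field(init=False)

    def __post_init__(self) -> None:
        self.shape = self.residual_variance.shape

    def level(self, echo: int, state: str, condition: str) -> np.ndarray:
        """Fitted signal level of one channel in one condition."""
        base = self.coefficients[f"base_e{echo}_{state}"]
        if condition == "base":
            return base
        return base + self.coefficients[f"{condition}_e{echo}_{state}"]


def fit_glm(series: np.ndarray, design: DesignInfo) -> GLMResult:
    """Ordinary least squares per voxel."""
    X = design.matrix.to_numpy()
    nx, ny, nz, nt = series.shape
    if nt != X.shape[0]:
        raise ValueError("series and design frame counts differ")
    Y = series.reshape(-1, nt).T  # frames x voxels
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError("numerically singular design")
    resid = Y - X @ beta
    dof = max(nt - X.shape[1], 1)
    rvar = (resid**2).sum(axis=0) / dof
    coefs = {
        name: beta[i].reshape(nx, ny, nz) for i, name in enumerate(design.matrix.columns)
    }
    return GLMResult(coefficients=coefs, residual_variance=rvar.reshape(nx, ny, nz))


def estimate_r2star(s_e1, s_e2, geometry: AcquisitionGeometry):
    """R2* (s^-1) and S0 from the two echo signals.

    R2* = ln(S1/S2) / (TE2 - TE1), S0 = S1 * exp(TE1 * R2*): the exact
    inverse of the two-point exponential decay.  Non-positive signals yield
    NaN (voxel invalid).
    """
    s1 = np.asarray(s_e1, dtype=float)
    s2 = np.asarray(s_e2, dtype=float)
    valid = (s1 > 0) & (s2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2s = np.where(valid, np.log(np.where(valid, s1 / s2, 1.0)), np.nan) / (
            geometry.te2 - geometry.te1
        )
        s0 = np.where(valid, s1 * np.exp(geometry.te1 * r2s), np.nan)
    if np.ndim(s_e1) == 0:
        return float(r2s), float(s0)
    return r2s, s0


def median_filter_3d(volume: np.ndarray) -> np.ndarray:
    """Median over the full 3x3x3 neighbourhood, truncated at the edges.

    NaNs are excluded from their neighbours' medians and preserved in place.
    """
    v = np.asarray(volume, dtype=float)
    padded = np.full(tuple(s + 2 for s in v.shape), np.nan)
    padded[1:-1, 1:-1, 1:-1] = v
    stack = np.empty((27,) + v.shape)
    k = 0
    for dx in range(3):
        for dy in range(3):
            for dz in range(3):
                stack[k] = padded[dx : dx + v.shape[0], dy : dy + v.shape[1], dz : dz + v.shape[2]]
                k += 1
    with np.errstate(invalid="ignore"):
        out = np.nanmedian(stack, axis=0)
    out[np.isnan(v)] = np.nan
    return out


@dataclass
class StateMaps:
    """Per-condition S0/R2* state maps and the derived response maps."""

    s0: Dict[Tuple[str, str], np.ndarray]  # (condition, state) -> map
    r2s: Dict[Tuple[str, str], np.ndarray]  # s^-1
    asl: Dict[str, np.ndarray]  # condition -> control-minus-label S0
    r2s_bold: Dict[str, np.ndarray]  # condition -> state-averaged R2*
    t2s0_ms: np.ndarray
    d_r2s_hc: np.ndarray  # s^-1
    d_r2s_ho: np.ndarray


def compute_state_maps(
    glm: GLMResult, geometry: AcquisitionGeometry, median_filter: bool = True
) -> StateMaps:
    """Dual-echo R2*/S0 per state and condition, then BOLD/ASL differences.

    The median filter, when enabled, is applied to the per-state S0 and R2*
    condition maps before any differencing.
    """
    s0: Dict[Tuple[str, str], np.ndarray] = {}
    r2s: Dict[Tuple[str, str], np.ndarray] = {}
    for cond in CONDITIONS:
        for state in ("control", "label"):
            rr, ss = estimate_r2star(
                glm.level(1, state, cond), glm.level(2, state, cond), geometry
            )
            if median_filter:
                rr = median_filter_3d(rr)
                ss = median_filter_3d(ss)
            r2s[(cond, state)] = rr
            s0[(cond, state)] = ss
    asl = {c: s0[(c, "control")] - s0[(c, "label")] for c in CONDITIONS}
    r2s_bold = {c: 0.5 * (r2s[(c, "control")] + r2s[(c, "label")]) for c in CONDITIONS}
    with np.errstate(divide="ignore", invalid="ignore"):
        t2s0_ms = 1000.0 / r2s_bold["base"]
    return StateMaps(
        s0=s0,
        r2s=r2s,
        asl=asl,
        r2s_bold=r2s_bold,
        t2s0_ms=t2s0_ms,
        d_r2s_hc=r2s_bold["hc"] - r2s_bold["base"],
        d_r2s_ho=r2s_bold["ho"] - r2s_bold["base"],
    )


@dataclass
class ExclusionMask:
    """Parenchymal inclusion map with per-voxel reason codes."""

    include: np.ndarray  # bool: voxel enters the analysis
    reasons: Dict[str, np.ndarray]  # reason -> bool map (recordable jointly)
    non_gm: np.ndarray  # bool: GM probability below the ROI cutoff

    def counts(self) -> Dict[str, int]:
        out = {name: int(m.sum()) for name, m in self.reasons.items()}
        out["included"] = int(self.include.sum())
        out["non_gm"] = int(self.non_gm.sum())
        return out


def build_exclusion_mask(
    maps: StateMaps,
    gm_prob: np.ndarray,
    t2s_cutoff_ms: float = 30.0,
    gm_cutoff: float = 0.5,
    solved: Optional[np.ndarray] = None,
) -> ExclusionMask:
    """Exclude voxels violating the calibration-model assumptions.

    Excluded: baseline T2* below 30 ms (susceptibility dropout), positive
    R2* change to hyperoxia (paramagnetic O2 artifact near air cavities),
    positive R2* change to hypercapnia (non-parenchymal), or invalid fits.
    Sub-threshold GM probability is recorded separately; it bars a voxel
    from ROI statistics but is not an artifact exclusion.
    """
    finite = np.isfinite(maps.t2s0_ms) & np.isfinite(maps.d_r2s_hc) & np.isfinite(maps.d_r2s_ho)
    reasons = {
        "low_t2star": finite & (maps.t2s0_ms < t2s_cutoff_ms),
        "positive_dr2s_ho": finite & (maps.d_r2s_ho > 0),
        "positive_dr2s_hc": finite & (maps.d_r2s_hc > 0),
        "invalid": ~finite,
    }
    if solved is not None:
        reasons["no_solution"] = np.asarray(solved == False) & finite  # noqa: E712
    exclude = np.zeros(maps.t2s0_ms.shape, dtype=bool)
    for name in ("low_t2star", "positive_dr2s_ho", "positive_dr2s_hc", "invalid"):
        exclude |= reasons[name]
    return ExclusionMask(
        include=~exclude,
        reasons=reasons,
        non_gm=np.asarray(gm_prob, dtype=float) < gm_cutoff,
    )


def drift_columns(times: np.ndarray, degree: int = 3) -> np.ndarray:
    """Zero-mean polynomial drift columns over ``times`` (degrees 1..degree).

    Shared with the simulator so that simulated drift lies exactly in the
    span of the analysis design.
    """
    t = np.asarray(times, dtype=float)
    tn = 2.0 * (t - t.min()) / (t.max() - t.min()) - 1.0
    cols = []
    for deg in range(1, degree + 1):
        c = tn**deg
        cols.append(c - c.mean())
    return np.column_stack(cols)
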