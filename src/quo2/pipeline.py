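"""Subject-level analysis orchestration.

Chains the stages — end-tidal respiratory analysis, dual-echo GLM, state
maps and exclusion, ASL quantification with hyperoxic blood-T1 correction,
and the voxelwise calibration solve — into one call operating on in-memory
arrays.  The command-line layer adds disk I/O around these functions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import calibration, perfusion, physiology, respiratory, signal as sig
from .config import PipelineConfig
from .synthdata import expected_fi_schedule

log = logging.getLogger("quo2")


@dataclass
class RespiratoryResult:
    summary: respiratory.EndTidalSummary
    cao2_0: float
    cao2_hc: float
    cao2_ho: float
    t1b_ho: float


@dataclass
class AnalysisResult:
    respiratory: RespiratoryResult
    state_maps: sig.StateMaps
    exclusion: sig.ExclusionMask
    cbf: perfusion.CBFMaps
    solutions: calibration.SolutionMaps
    detection_rate_gm: float
    gm_means: Dict[str, float]
    summary: Dict


def analyze_respiratory(
    trace: respiratory.RespiratoryTrace, config: PipelineConfig
) -> RespiratoryResult:
    """End-tidal summary, arterial O2 content per condition, hyperoxic T1."""
    points = {}
    for gas in ("o2", "co2"):
        fi = expected_fi_schedule(config.program, config.paradigm, gas)
        bp = respiratory.extract_breath_points(
            trace, gas, expected_fi=fi, breath_period=config.sim.breath_period
        )
        bp = respiratory.correct_filter_attenuation(bp)
        bp = respiratory.correct_water_vapor(bp, config.program.barometric_pressure)
        points[gas] = bp
    summary = respiratory.summarize_end_tidal(points["o2"], points["co2"], config.paradigm)
    blood = config.model.blood
    pao2_0 = summary.eto2_0
    pao2_hc = summary.eto2_0 + summary.d_eto2_hc
    pao2_ho = summary.eto2_0 + summary.d_eto2_ho
    t1b_ho = physiology.blood_t1_hyperoxia(max(pao2_ho, pao2_0), pao2_0, blood)
    return RespiratoryResult(
        summary=summary,
        cao2_0=physiology.arterial_o2_content(pao2_0, blood).cao2,
        cao2_hc=physiology.arterial_o2_content(pao2_hc, blood).cao2,
        cao2_ho=physiology.arterial_o2_content(pao2_ho, blood).cao2,
        t1b_ho=min(t1b_ho, config.perfusion.t1b),
    )


def analyze_subject(
    series: np.ndarray,
    annotations: pd.DataFrame,
    trace: respiratory.RespiratoryTrace,
    gm_prob: np.ndarray,
    config: PipelineConfig,
    brain_mask: Optional[np.ndarray] = None,
    rois: Optional[Dict[str, np.ndarray]] = None,
) -> AnalysisResult:
    """Run the full analysis chain on one subject's session."""
    opts = config.analysis
    resp = analyze_respiratory(trace, config)
    log.info(
        "respiratory: ETO2_0=%.1f dETO2_HO=%.1f dETCO2_HC=%.1f T1b_HO=%.3f",
        resp.summary.eto2_0, resp.summary.d_eto2_ho, resp.summary.d_etco2_hc, resp.t1b_ho,
    )

    if brain_mask is None:
        brain_mask = np.ones(series.shape[:3], dtype=bool)
    data = sig.preprocess(
        series, brain_mask, opts.fwhm_mm, config.geometry.voxel_size, opts.target_mean
    )
    design = sig.build_design(config.paradigm, annotations, config.geometry)
    glm = sig.fit_glm(data, design)
    maps = sig.compute_state_maps(glm, config.geometry, median_filter=opts.median_filter)
    excl = sig.build_exclusion_mask(maps, gm_prob, opts.t2s_cutoff_ms, opts.gm_cutoff)
    log.info("exclusion counts: %s (of %d frames, %d voxels)",
             excl.counts(), series.shape[-1], int(np.prod(series.shape[:3])))

    m0 = maps.s0[("base", "control")] * opts.m0_scale
    cbf0 = perfusion.quantify_cbf(maps.asl["base"], m0, config.perfusion, config.geometry)
    cbf_hc = perfusion.quantify_cbf(maps.asl["hc"], m0, config.perfusion, config.geometry)
    cbf_ho = perfusion.quantify_cbf(maps.asl["ho"], m0, config.perfusion, config.geometry)
    with np.errstate(divide="ignore", invalid="ignore"):
        dpct_hc = 100.0 * (cbf_hc / cbf0 - 1.0)
        dpct_ho_raw = 100.0 * (cbf_ho / cbf0 - 1.0)
    dpct_ho_corr, gm_mean_ho = perfusion.correct_hyperoxia_cbf(
        dpct_ho_raw, resp.t1b_ho, config.perfusion, config.geometry,
        gm_prob, include=excl.include, gm_cutoff=opts.gm_cutoff,
    )
    cbf_maps = perfusion.CBFMaps(
        cbf0=cbf0,
        dpct_cbf_hc=dpct_hc,
        dpct_cbf_ho_raw=dpct_ho_raw,
        dpct_cbf_ho_corrected=dpct_ho_corr,
        f_hc=1.0 + dpct_hc / 100.0,
        f_ho_gm=1.0 + gm_mean_ho / 100.0,
        t1b_ho=resp.t1b_ho,
    )
    log.info("perfusion: GM-mean corrected d%%CBF_HO=%.2f%% (substituted voxelwise)", gm_mean_ho)

    responses = calibration.ConditionResponses(
        cbf0=cbf0,
        f_hc=cbf_maps.f_hc,
        f_ho=np.full_like(cbf0, cbf_maps.f_ho_gm),
        d_r2s_hc=maps.d_r2s_hc,
        d_r2s_ho=maps.d_r2s_ho,
        cao2_0=resp.cao2_0,
        cao2_hc=resp.cao2_hc,
        cao2_ho=resp.cao2_ho,
    )
    sols = calibration.solve_map(responses, excl.include, config.model)
    gm_roi = np.asarray(gm_prob) >= opts.gm_cutoff
    det = calibration.detection_rate(sols.solved, excl.include, gm_roi)
    log.info("calibration: GM detection rate %.1f%%", det)

    def gm_mean(vol, solved=None):
        return calibration.roi_weighted_average(
            vol, gm_prob, gm_roi, excl.include, solved=solved, gm_cutoff=opts.gm_cutoff
        )

    gm_means = {
        "cbf0": gm_mean(cbf0),
        "t2s0_ms": gm_mean(maps.t2s0_ms),
        "d_r2s_hc": gm_mean(maps.d_r2s_hc),
        "d_r2s_ho": gm_mean(maps.d_r2s_ho),
        "dpct_cbf_hc": gm_mean(dpct_hc),
        "m_pct": 100.0 * gm_mean(sols.m, solved=sols.solved),
        "oef": gm_mean(sols.oef, solved=sols.solved),
        "o2_delivery": gm_mean(sols.o2_delivery, solved=sols.solved),
        "cmro2": gm_mean(sols.cmro2, solved=sols.solved),
    }
    summary = {
        "end_tidal": {
            "eto2_0": resp.summary.eto2_0,
            "etco2_0": resp.summary.etco2_0,
            "d_eto2_hc": resp.summary.d_eto2_hc,
            "d_eto2_ho": resp.summary.d_eto2_ho,
            "d_etco2_hc": resp.summary.d_etco2_hc,
            "d_etco2_ho": resp.summary.d_etco2_ho,
        },
        "cao2": {"baseline": resp.cao2_0, "hc": resp.cao2_hc, "ho": resp.cao2_ho},
        "t1b_ho_s": resp.t1b_ho,
        "gm_mean_dpct_cbf_ho_corrected": gm_mean_ho,
        "exclusion_counts": excl.counts(),
        "detection_rate_gm_pct": det,
        "gm_means": gm_means,
    }
    result = AnalysisResult(
        respiratory=resp,
        state_maps=maps,
        exclusion=excl,
        cbf=cbf_maps,
        solutions=sols,
        detection_rate_gm=det,
        gm_means=gm_means,
        summary=summary,
    )
    if rois:
        roi_rows = []
        for name, roi in rois.items():
            try:
                roi_rows.append(
                    {
                        "roi": name,
                        "detection_rate_pct": calibration.detection_rate(
                            sols.solved, excl.include, roi
                        ),
                        "cbf0": calibration.roi_weighted_average(
                            cbf0, gm_prob, roi, excl.include, gm_cutoff=opts.gm_cutoff
                        ),
                        "m_pct": 100.0 * calibration.roi_weighted_average(
                            sols.m, gm_prob, roi, excl.include, sols.solved, opts.gm_cutoff
                        ),
                        "oef": calibration.roi_weighted_average(
                            sols.oef, gm_prob, roi, excl.include, sols.solved, opts.gm_cutoff
                        ),
                        "cmro2": calibration.roi_weighted_average(
                            sols.cmro2, gm_prob, roi, excl.include, sols.solved, opts.gm_cutoff
                        ),
                    }
                )
            except ValueError:
                roi_rows.append({"roi": name, "detection_rate_pct": np.nan})
        summary["rois"] = roi_rows
    return result
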