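"""Pipeline configuration.

A single structured config carries every acquisition, physiological and
numerical constant of the pipeline — nothing is hard-coded downstream — and
round-trips through YAML for the command-line entry points.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Dict, Optional, Tuple

import yaml

from .calibration import ModelParams
from .paradigm import GasParadigm, make_default_paradigm
from .perfusion import PerfusionConstants
from .physiology import BloodParams
from .signal import AcquisitionGeometry
from .synthdata import RespiratoryProgram


@dataclass(frozen=True)
class SimOptions:
    """Synthetic-data generation options (the study conditions)."""

    shape: Tuple[int, int, int] = (12, 12, 4)
    noise_sd: float = 0.25  # signal units on a brain-mean-100 scale
    drift_coefs: Tuple[float, float, float] = (2.0, -1.0, 0.5)
    low_t2s_fraction: float = 0.04
    low_gm_fraction: float = 0.15
    attenuation: float = 0.1
    resp_noise_sd: float = 0.0
    breath_period: float = 4.0  # s
    resp_sampling_rate: float = 10.0  # Hz
    ar1_rho: float = 0.0
    ranges: Optional[Dict[str, Tuple[float, float]]] = None


@dataclass(frozen=True)
class AnalysisOptions:
    """Preprocessing and masking options."""

    fwhm_mm: float = 8.0
    median_filter: bool = True
    t2s_cutoff_ms: float = 30.0
    gm_cutoff: float = 0.5
    m0_scale: float = 1.0
    target_mean: float = 100.0


@dataclass(frozen=True)
class PipelineConfig:
    geometry: AcquisitionGeometry = field(default_factory=AcquisitionGeometry)
    model: ModelParams = field(default_factory=ModelParams)
    perfusion: PerfusionConstants = field(default_factory=PerfusionConstants)
    paradigm: GasParadigm = field(default_factory=make_default_paradigm)
    program: RespiratoryProgram = field(default_factory=RespiratoryProgram)
    sim: SimOptions = field(default_factory=SimOptions)
    analysis: AnalysisOptions = field(default_factory=AnalysisOptions)
    seed: int = 0


def default_config(**overrides) -> PipelineConfig:
    return replace(PipelineConfig(), **overrides)


def noiseless_config(shape: Tuple[int, int, int] = (12, 12, 4), seed: int = 0) -> PipelineConfig:
    """Config for exact-recovery validation.

    No thermal noise, no sampling-line attenuation, and no spatial mixing
    (smoothing and median filtering disabled): voxelwise comparison against
    the generating truth is then meaningful.
    """
    geometry = AcquisitionGeometry(n_slices=shape[2])
    return PipelineConfig(
        geometry=geometry,
        sim=SimOptions(shape=shape, noise_sd=0.0, attenuation=0.0, resp_noise_sd=0.0),
        analysis=AnalysisOptions(fwhm_mm=0.0, median_filter=False),
        seed=seed,
    )


def to_dict(config: PipelineConfig) -> dict:
    return asdict(config)


def from_dict(d: dict) -> PipelineConfig:
    def tup(x):
        return tuple(x) if isinstance(x, (list, tuple)) else x

    geometry = AcquisitionGeometry(**{**d.get("geometry", {}),
                                      **({"voxel_size": tup(d["geometry"]["voxel_size"])}
                                         if "voxel_size" in d.get("geometry", {}) else {})})
    model_d = dict(d.get("model", {}))
    blood = BloodParams(**model_d.pop("blood", {}))
    if "oef_bounds" in model_d:
        model_d["oef_bounds"] = tup(model_d["oef_bounds"])
    model = ModelParams(blood=blood, **model_d)
    perf = PerfusionConstants(**d.get("perfusion", {}))
    par_d = d.get("paradigm", {})
    paradigm = (
        GasParadigm(
            total_duration=par_d["total_duration"],
            hc_blocks=tuple(tup(b) for b in par_d.get("hc_blocks", ())),
            ho_blocks=tuple(tup(b) for b in par_d.get("ho_blocks", ())),
        )
        if par_d
        else make_default_paradigm()
    )
    prog_d = dict(d.get("program", {}))
    for k in ("d_eto2_hc", "d_eto2_ho", "d_etco2_hc", "d_etco2_ho"):
        if k in prog_d and isinstance(prog_d[k], (list, tuple)):
            prog_d[k] = tuple(prog_d[k])
    program = RespiratoryProgram(**prog_d)
    sim_d = dict(d.get("sim", {}))
    for k in ("shape", "drift_coefs"):
        if k in sim_d:
            sim_d[k] = tup(sim_d[k])
    if sim_d.get("ranges"):
        sim_d["ranges"] = {k: tup(v) for k, v in sim_d["ranges"].items()}
    sim = SimOptions(**sim_d)
    analysis = AnalysisOptions(**d.get("analysis", {}))
    return PipelineConfig(
        geometry=geometry,
        model=model,
        perfusion=perf,
        paradigm=paradigm,
        program=program,
        sim=sim,
        analysis=analysis,
        seed=int(d.get("seed", 0)),
    )


def save_yaml(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(config), fh, sort_keys=False)


def load_yaml(path) -> PipelineConfig:
    with open(path) as fh:
        return from_dict(yaml.safe_load(fh) or {})
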