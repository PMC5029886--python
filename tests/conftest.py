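import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from quo2 import synthdata as sd
from quo2.config import noiseless_config
from quo2.pipeline import analyze_subject
from quo2.sensitivity import GmBaseline

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gm_baseline() -> GmBaseline:
    """Typical gray-matter voxel with forward-generated gas responses."""
    return GmBaseline()


@pytest.fixture(scope="session")
def cao2_triple(gm_baseline):
    """(CaO2_0, CaO2_HC, CaO2_HO) at the group-mean end-tidal O2 tensions."""
    return gm_baseline.cao2()


@pytest.fixture(scope="session")
def noiseless_run():
    """One noiseless synthetic subject pushed through the full analysis.

    Shared across tests: the simulation truth, the raw series and the
    analysis result, with no noise, no sampling-line attenuation and no
    spatial mixing so that voxelwise recovery is well defined.
    """
    cfg = noiseless_config(seed=1)
    truth = sd.make_ground_truth(
        shape=cfg.sim.shape, seed=7, noise_sd=0.0, drift_coefs=cfg.sim.drift_coefs
    )
    series, ann = sd.simulate_dual_echo_series(
        truth, cfg.paradigm, cfg.geometry, cfg.model, cfg.perfusion, cfg.program, seed=3
    )
    trace = sd.simulate_respiratory_trace(
        cfg.paradigm, cfg.program, attenuation=0.0, seed=4
    )
    result = analyze_subject(series, ann, trace, truth.gm_prob, cfg)
    gm_solved = result.exclusion.include & (truth.gm_prob >= 0.5) & result.solutions.solved
    return {
        "config": cfg,
        "truth": truth,
        "series": series,
        "annotations": ann,
        "trace": trace,
        "result": result,
        "gm_solved": gm_solved,
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160920)
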