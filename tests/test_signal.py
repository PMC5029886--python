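"""Dual-echo GLM, R2*/S0 estimation, filtering and exclusion rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from quo2 import synthdata as sd
from quo2.paradigm import make_default_paradigm
from quo2.signal import (
    AcquisitionGeometry,
    apply_shared_transforms,
    build_design,
    build_exclusion_mask,
    compute_state_maps,
    estimate_r2star,
    fit_glm,
    frame_annotations,
    median_filter_3d,
    preprocess,
)

GEOM = AcquisitionGeometry(n_slices=4)


class TestDesign:
    def test_column_structure(self):
        """Default paradigm: 4 channel baselines, 8 responses, cubic drift."""
        ann = frame_annotations(262, GEOM)
        design = build_design(make_default_paradigm(), ann, GEOM)
        cols = list(design.matrix.columns)
        assert sum(c.startswith("base_") for c in cols) == 4
        assert sum(c.startswith(("hc_", "ho_")) for c in cols) == 8
        assert sum(c.startswith("drift_") for c in cols) == 3
        X = design.matrix.to_numpy()
        assert np.linalg.matrix_rank(X) == X.shape[1]

    def test_no_gas_blocks_flagged_rank_deficient(self):
        from quo2.paradigm import GasParadigm

        ann = frame_annotations(262, GEOM)
        empty = GasParadigm(total_duration=1080.0)
        with pytest.raises(ValueError, match="rank-deficient"):
            build_design(empty, ann, GEOM)

    def test_response_regressor_peaks_inside_blocks(self):
        ann = frame_annotations(262, GEOM)
        design = build_design(make_default_paradigm(), ann, GEOM)
        t = ann["time"].to_numpy()
        peak_t = t[np.argmax(design.hc_regressor)]
        assert 0.0 <= peak_t <= 240.0 or 540.0 <= peak_t <= 780.0


class TestGlmRecovery:
    def test_noiseless_series_fits_exactly(self):
        """The noiseless simulated series lies in the design span: residuals
        at machine precision and every channel/condition level recovered."""
        cfg_par = make_default_paradigm()
        truth = sd.make_ground_truth(shape=(6, 6, 4), seed=3, noise_sd=0.0)
        series, ann = sd.simulate_dual_echo_series(truth, cfg_par, GEOM)
        design = build_design(cfg_par, ann, GEOM)
        glm = fit_glm(series, design)
        fitted = design.matrix.to_numpy() @ np.stack(
            [glm.coefficients[c].ravel() for c in design.matrix.columns]
        )
        resid = series.reshape(-1, series.shape[-1]).T - fitted
        assert np.max(np.abs(resid)) < 1e-8 * np.max(series)
        # baseline control level equals the truth S0 at the first echo, up to
        # the exponential decay at TE1
        level = glm.level(1, "control", "base")
        expected = truth.s0 * np.exp(-GEOM.te1 * 1000.0 / truth.t2s0_ms)
        assert np.allclose(level, expected, rtol=1e-10)

    def test_pure_drift_series_has_null_responses(self):
        ann = frame_annotations(262, GEOM)
        design = build_design(make_default_paradigm(), ann, GEOM)
        t = ann["time"].to_numpy()
        tn = 2.0 * (t - t.min()) / (t.max() - t.min()) - 1.0
        drift = 5.0 + 2.0 * (tn - tn.mean()) + 0.7 * (tn**3 - (tn**3).mean())
        series = np.tile(drift, (2, 2, 4, 1))
        glm = fit_glm(series, design)
        for gas in ("hc", "ho"):
            for echo in (1, 2):
                for state in ("control", "label"):
                    eff = glm.coefficients[f"{gas}_e{echo}_{state}"]
                    assert np.max(np.abs(eff)) < 1e-8


class TestR2Star:
    def test_forward_inverse_round_trip(self):
        s1 = 100.0 * np.exp(-GEOM.te1 * 25.0)
        s2 = 100.0 * np.exp(-GEOM.te2 * 25.0)
        r2s, s0 = estimate_r2star(s1, s2, GEOM)
        assert r2s == pytest.approx(25.0, rel=1e-12)
        assert s0 == pytest.approx(100.0, rel=1e-12)

    def test_equal_echoes_give_zero_rate(self):
        r2s, s0 = estimate_r2star(80.0, 80.0, GEOM)
        assert r2s == 0.0 and s0 == 80.0

    @given(
        st.floats(min_value=1.0, max_value=500.0),
        st.floats(min_value=-5.0, max_value=60.0),
    )
    def test_exact_inverse_property(self, s0_true, r2s_true):
        """Estimation inverts the two-point exponential decay exactly."""
        s1 = s0_true * np.exp(-GEOM.te1 * r2s_true)
        s2 = s0_true * np.exp(-GEOM.te2 * r2s_true)
        r2s, s0 = estimate_r2star(s1, s2, GEOM)
        assert s1 == pytest.approx(s0 * np.exp(-GEOM.te1 * r2s), rel=1e-12)
        assert r2s == pytest.approx(r2s_true, rel=1e-9, abs=1e-9)

    def test_nonpositive_signal_marks_invalid(self):
        r2s, s0 = estimate_r2star(-1.0, 50.0, GEOM)
        assert np.isnan(r2s) and np.isnan(s0)


class TestMedianFilter:
    def test_constant_map_unchanged(self):
        vol = np.full((5, 5, 3), 7.0)
        assert np.array_equal(median_filter_3d(vol), vol)

    def test_spike_removed(self):
        vol = np.full((5, 5, 3), 1.0)
        vol[2, 2, 1] = 100.0
        out = median_filter_3d(vol)
        assert out[2, 2, 1] == 1.0

    def test_idempotent_on_step(self):
        vol = np.ones((6, 5, 3))
        vol[3:, :, :] = 2.0
        once = median_filter_3d(vol)
        assert np.array_equal(median_filter_3d(once), once)

    def test_nan_preserved_and_ignored(self):
        vol = np.full((4, 4, 3), 2.0)
        vol[1, 1, 1] = np.nan
        out = median_filter_3d(vol)
        assert np.isnan(out[1, 1, 1])
        assert out[1, 2, 1] == 2.0


class TestPreprocess:
    def test_constant_normalized_to_target(self):
        series = np.full((4, 4, 3, 6), 50.0)
        mask = np.ones((4, 4, 3), bool)
        out = preprocess(series, mask, fwhm_mm=0.0)
        assert np.allclose(out, 100.0)

    def test_zero_fwhm_is_identity_up_to_scaling(self):
        rng = np.random.default_rng(0)
        series = rng.uniform(50, 150, size=(4, 4, 3, 5))
        mask = np.ones((4, 4, 3), bool)
        out = preprocess(series, mask, fwhm_mm=0.0)
        scale = 100.0 / series.mean()
        assert np.allclose(out, series * scale, rtol=1e-12)

    def test_impulse_response_width(self):
        """A delta spike smooths to a Gaussian whose FWHM matches the kernel
        within 2% (fine grid so the width is resolved)."""
        vox = (1.0, 1.0, 1.0)
        series = np.zeros((81, 81, 1, 1))
        series[40, 40, 0, 0] = 1.0
        mask = np.ones((81, 81, 1), bool)
        out = preprocess(series, mask, fwhm_mm=8.0, voxel_size=vox)
        profile = out[:, 40, 0, 0]
        x = np.arange(81) - 40.0
        sigma = np.sqrt(np.sum(profile * x**2) / np.sum(profile))
        assert sigma * np.sqrt(8 * np.log(2)) == pytest.approx(8.0, rel=0.02)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.ones((3, 3, 2, 2)), np.zeros((3, 3, 2), bool), 0.0)


class TestSharedTransforms:
    def test_identity_leaves_data_unchanged(self):
        ann = frame_annotations(4, GEOM)
        data = np.random.default_rng(1).uniform(size=(5, 5, 4, 8))
        out = apply_shared_transforms(data, [np.eye(4)] * 4, ann)
        assert np.array_equal(out, data)

    def test_translation_round_trip(self):
        ann = frame_annotations(2, GEOM)
        rng = np.random.default_rng(2)
        data = rng.uniform(size=(8, 8, 4, 4))
        fwd = np.eye(4)
        fwd[0, 3] = 1.0  # one-voxel shift
        inv = np.eye(4)
        inv[0, 3] = -1.0
        shifted = apply_shared_transforms(data, [fwd] * 2, ann)
        back = apply_shared_transforms(shifted, [inv] * 2, ann)
        assert np.allclose(back[2:-2], data[2:-2], atol=1e-9)

    def test_per_frame_transforms_rejected(self):
        """One matrix per frame (allowing echoes to move independently)
        violates the shared-transform contract."""
        ann = frame_annotations(4, GEOM)
        data = np.zeros((5, 5, 4, 8))
        with pytest.raises(ValueError, match="one transform per TR"):
            apply_shared_transforms(data, [np.eye(4)] * 8, ann)


class TestExclusion:
    def test_reason_codes_and_counts(self):
        """A constructed fixture with known reason composition yields exact
        exclusion counts."""
        from quo2.signal import StateMaps

        shape = (5, 5, 4)
        t2s0 = np.full(shape, 50.0)
        d_hc = np.full(shape, -0.5)
        d_ho = np.full(shape, -0.2)
        t2s0[0, 0, 0] = 25.0  # susceptibility dropout
        d_ho[1, 1, 1] = 0.1  # paramagnetic O2 artifact
        d_hc[2, 2, 2] = 0.05  # non-parenchymal
        d_hc[3, 3, 3] = np.nan  # invalid fit
        maps = StateMaps(s0={}, r2s={}, asl={}, r2s_bold={},
                         t2s0_ms=t2s0, d_r2s_hc=d_hc, d_r2s_ho=d_ho)
        gm = np.full(shape, 0.8)
        gm[4, 4, 0] = 0.49
        excl = build_exclusion_mask(maps, gm)
        counts = excl.counts()
        assert counts["low_t2star"] == 1
        assert counts["positive_dr2s_ho"] == 1
        assert counts["positive_dr2s_hc"] == 1
        assert counts["invalid"] == 1
        assert counts["included"] == 5 * 5 * 4 - 4
        assert counts["non_gm"] == 1
        assert not excl.include[0, 0, 0]
        assert excl.include[4, 4, 0]  # low GM is recorded, not excluded

    def test_healthy_voxel_included(self):
        from quo2.signal import StateMaps

        maps = StateMaps(s0={}, r2s={}, asl={}, r2s_bold={},
                         t2s0_ms=np.array([[[45.0]]]),
                         d_r2s_hc=np.array([[[-0.3]]]),
                         d_r2s_ho=np.array([[[-0.1]]]))
        excl = build_exclusion_mask(maps, np.array([[[0.8]]]))
        assert excl.include[0, 0, 0]
        assert not excl.non_gm[0, 0, 0]
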