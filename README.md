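# quo2 — calibrated dual-echo pCASL MRI analysis

`quo2` implements the quantitative-O2 (QUO2) calibrated-BOLD analysis: from
a dual-echo pseudo-continuous ASL time series acquired during a
hypercapnia/hyperoxia (HC/HO) gas paradigm, it maps the BOLD calibration
parameter *M*, the resting oxygen extraction fraction (OEF), O2 delivery
and absolute CMRO2 in μmol/100 g/min. It is aimed at physiological-MRI
researchers who want a tested, fully synthetic-data-validated reference
implementation of this pipeline, together with the test–retest statistics
(wsCV, coefficient of repeatability, Bland–Altman) and the
systematic/random error-sensitivity machinery used to characterize such
measurements.

## The model

Each gas challenge constrains *M* as a function of the unknown resting
extraction fraction E:

    M(E) = b / (1 − f^α · d(E)^β)

where `b = exp(−TE·ΔR2*) − 1` is the fractional BOLD signal change of the
challenge (TE = 30 ms), `f` the CBF ratio during the challenge, α = 0.18
the flow–volume coupling exponent, β = 1.5 the deoxyhemoglobin
nonlinearity, and

    d(E) = (φ·Hb − CaO2_gas + (r/f)·E·CaO2_0) / (φ·Hb − CaO2_0 + E·CaO2_0)

the venous deoxyhemoglobin ratio, with arterial O2 content
`CaO2 = φ·Hb·SaO2(PaO2) + ε·PaO2` from the Severinghaus dissociation curve
and `r` the CMRO2 ratio during the challenge (1 = isometabolism). The
hypercapnic and hyperoxic curves intersect at the voxel's (M, OEF); voxels
whose curves do not intersect carry no solution and are excluded from all
averages. Finally

    CMRO2 = OEF × CBF_0 × CaO2_0   (O2 delivery = CBF_0 × CaO2_0).

Upstream of the solver the package provides: end-tidal O2/CO2 extraction
from analyzer traces (with sampling-line attenuation and water-vapor
corrections), a single GLM on the interleaved dual-echo series (one
regressor per echo × label/control channel and condition, gamma HRF with
20 s time-to-peak and 40 s width, cubic drift), two-point R2*/S0
estimation, 3×3×3 median filtering, parenchymal exclusion rules
(T2*0 < 30 ms, positive ΔR2* to either gas), single-compartment pCASL CBF
quantification with slice-dependent post-labeling delay (900–1986 ms,
brain average 1443 ms), and the hyperoxic blood-T1 correction with
GM-mean substitution of the HO flow response.

A first-class synthetic-data module simulates the whole experiment —
ground-truth maps, breath-by-breath respiratory traces and the dual-echo
series — so every stage is validated by parameter recovery.

## Worked example

```python
import numpy as np
from quo2 import synthdata as sd
from quo2.config import noiseless_config
from quo2.pipeline import analyze_subject

cfg = noiseless_config(seed=1)
truth = sd.make_ground_truth(shape=cfg.sim.shape, seed=8, noise_sd=0.0,
                             drift_coefs=cfg.sim.drift_coefs)
series, ann = sd.simulate_dual_echo_series(
    truth, cfg.paradigm, cfg.geometry, cfg.model, cfg.perfusion, cfg.program, seed=3)
trace = sd.simulate_respiratory_trace(cfg.paradigm, cfg.program,
                                      attenuation=0.0, seed=4)
res = analyze_subject(series, ann, trace, truth.gm_prob, cfg)

print(f"GM detection rate: {res.detection_rate_gm:.1f}%")
print(f"GM means: M = {res.gm_means['m_pct']:.2f}%  OEF = {res.gm_means['oef']:.3f}  "
      f"CBF0 = {res.gm_means['cbf0']:.1f} mL/100g/min  "
      f"CMRO2 = {res.gm_means['cmro2']:.0f} umol/100g/min")
sel = res.exclusion.include & (truth.gm_prob >= 0.5) & res.solutions.solved
print(f"max |OEF - truth| = {np.nanmax(np.abs(res.solutions.oef[sel] - truth.oef[sel])):.2e}")
```

prints

```
GM detection rate: 100.0%
GM means: M = 5.48%  OEF = 0.376  CBF0 = 50.5 mL/100g/min  CMRO2 = 170 umol/100g/min
max |OEF - truth| = 3.78e-05
```

i.e. on a noiseless synthetic subject every gray-matter voxel is solvable
and the full chain — respiratory fit, GLM, perfusion quantification and the
two-curve intersection — returns the generating OEF to a few parts in 10⁵;
the GM means are the probability-weighted averages over solved voxels of
the randomly drawn truth maps.

A command-line interface wraps the same pipelines:

```bash
quo2 simulate --out data/ --seed 1 --subjects 2 --sessions 2
quo2 analyze  --data data/sub-01_ses-1 --out results/sub-01_ses-1
quo2 stats    --input roi_values.tsv --out-prefix results/repro
quo2 sweep    --parameter beta --out results/sweep_beta.tsv
quo2 propagate --input d_r2s_hc --out results/prop_bold_hc.tsv
```

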