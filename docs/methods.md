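# Methods

This note documents the models, the numerical choices and the validation
design of `quo2`, and states what passing its tests does and does not show
about real data.

## The calibration model

The core is the two-gas generalized calibration of the BOLD signal. For a
gas challenge with CBF ratio `f`, CMRO2 ratio `r` and arterial O2 content
`CaO2_gas`, the venous deoxyhemoglobin ratio is

    d(E) = (φ·Hb − CaO2_gas + (r/f)·E·CaO2_0) / (φ·Hb − CaO2_0 + E·CaO2_0)

with `E` the resting oxygen extraction fraction. This follows from mass
balance (`OEF_gas · f · CaO2_gas = r · E · CaO2_0`) with deoxyhemoglobin
taken as the total-content deficit relative to full saturation; venous
dissolved O2 is neglected. Arterial content uses the Severinghaus
dissociation curve `SaO2 = 1/(23400/(P³+150P)+1)` with end-tidal O2 as a
direct proxy for PaO2 (no alveolar–arterial gradient) — the standard
conventions of hypercapnia/hyperoxia calibration.

Each gas then defines a curve `M(E) = b/(1 − f^α·d(E)^β)` with
`b = exp(−TE_ref·ΔR2*) − 1` at TE_ref = 30 ms. The exact algebraic form of
the two-equation system is reconstructed from its verbal definition (the
original publication of the model is not reprinted here); the
forward/inverse round trip (`forward_delta_r2star` → `solve_voxel`,
maximum error ≤ 1e-4 over M ∈ [0.02, 0.12], OEF ∈ [0.2, 0.6],
f_HC ∈ [1.2, 1.8]) and the reproduction of the published α-sensitivity
anchor (α 0.18 → 0.38 moves the GM solution from M = 5.0%, OEF = 0.39 to
M = 5.66%, OEF = 0.44) confirm the reconstruction. An alternative reading
that solves directly on −TE·ΔR2* instead of the exponential mapping
differs only at second order in the BOLD fraction; the exponential mapping
is the default and the only one used.

### Solver

Roots of `M_HC(E) − M_HO(E)` are located by a sign-change scan on a
uniform OEF grid (step 1e-3 between bounds 0.01 and 0.99) and refined by
Brent bisection to |ΔE| < 1e-7. Each curve has a pole where its
denominator `1 − f^α d^β` crosses zero; grid intervals on which either
denominator changes sign are not brackets and are skipped, which prevents
poles from masquerading as intersections. A root must deliver M > 0 and
OEF strictly inside the bounds; with several qualifying roots the smallest
OEF is taken and the count recorded (the system is empirically
single-rooted throughout the physiological grid — the brute-force check
below never found a second root there). No sign change ⇒ no solution; the
voxel is excluded from every M/OEF/CMRO2 average and counted in the
detection rate. An exhaustive-grid oracle (step 1e-5, no bisection) agrees
with the solver to < 2e-5 in OEF over 1,000 random voxels.

### Assumed parameters

| parameter | default | meaning |
|---|---|---|
| α | 0.18 | flow–volume coupling exponent |
| β | 1.5 | R2*–deoxyhemoglobin nonlinearity |
| Hb | 15 g/dL | hemoglobin concentration |
| φ | 1.34 mL O2/g | O2 capacity of hemoglobin |
| ε | 0.003 mL O2/dL/mmHg | plasma solubility |
| r_HC, r_HO | 1.0 | isometabolism during the challenges |
| TE_ref | 30 ms | echo time at which M is expressed |
| u | 44.6 μmol/mL O2 | ideal-gas conversion at STPD |
| T1b_0 | 1.65 s | baseline arterial blood T1 at 3 T |
| κ | 1.38e-4 s⁻¹/mmHg | blood R1 vs PaO2 slope |

κ and T1b_0 jointly reproduce an arterial T1 of 1.558 s at the hyperoxic
end-tidal O2 reached breathing 60% O2 (ΔPaO2 ≈ 259 mmHg); both are
configurable since the underlying relaxometry coefficients vary between
reports. The μmol conversion is config-exposed: published GM O2-delivery
values are sensitive to the Hb/content convention used, and 44.6 with
φ·Hb = 20.1 mL/dL yields ≈450 μmol/100 g/min at CBF 50, somewhat above
some reported group values (≈377); the conversion constant, not the model,
carries that discrepancy.

## Signal extraction

The interleaved series holds two gradient-echo frames per TR
(TR/TE1/TE2 = 4.12 s/8.4 ms/30 ms), label and control states alternating
between TRs (label first). One OLS GLM fits all frames: four channel
baseline indicators (echo × state), eight response regressors (channel ×
HC/HO block response) and shared polynomial drift. The drift is
parameterized as zero-mean polynomials of degrees 1–3 *without* a separate
offset column: the four channel indicators sum to the all-ones vector, so
a design holding both would be exactly rank-deficient. The offset is
therefore absorbed into the channel baselines and the design has full
column rank (15 columns on the default paradigm). OLS rather than
prewhitened GLS is used; no autocorrelation model is assumed.

The HRF is a single gamma density with mode ("time-to-peak") 20 s and
FWHM ("width") 40 s; shape and scale are solved numerically
(k ≈ 2.46, θ ≈ 13.7 s) and block responses are evaluated analytically via
the gamma CDF, so regressors are exact at arbitrary sample times and
identical in the simulator and every GLM. Convolved responses are
peak-normalized, making fitted effect sizes read as plateau amplitudes.

R2* and S0 per state and condition come from the exact two-point inverse
`R2* = ln(S1/S2)/(TE2−TE1)`, `S0 = S1·exp(TE1·R2*)`; BOLD R2* per
condition is the label/control average and ASL the control-minus-label S0
difference. A 3×3×3 median filter (Chebyshev radius 1, edge-truncated,
NaN-aware) is applied to the per-state condition maps *before*
differencing; it suppresses isolated non-parenchymal voxels and is
config-switchable. Exclusion rules: baseline T2* < 30 ms, ΔR2*_HO > 0
(paramagnetic O2 artifact near air cavities), ΔR2*_HC > 0
(non-parenchymal); GM probability < 0.5 separately bars a voxel from ROI
statistics. Motion estimation is out of scope; `apply_shared_transforms`
enforces the contract that both echoes of a TR are resampled with one
matrix when externally supplied transforms are applied.

## Perfusion

Single-compartment pCASL quantification,
`CBF = 6000·λ·ΔM·exp(PLD/T1b) / (2·α_label·T1b·M0·(1−exp(−τ/T1b)))`,
with λ = 0.9 mL/g, labeling efficiency 0.85, τ = 2 s, T1b = 1.65 s and M0
approximated by the baseline control-state S0 map (scale factor
configurable; no separate M0 scan is modeled). The PLD grows linearly with
slice index from 900 to 1986 ms over 21 slices (brain average 1443 ms);
where an acquisition description elsewhere gives 1960 ms for the last
slice, the internally consistent 900/1986/1443 triple is preferred and
both endpoints are config-exposed. During hyperoxia dissolved O2 shortens
arterial T1; the HO flow response is re-quantified with
`T1b_HO = 1/(1/T1b_0 + κ·ΔPaO2)` (kernel ratio per slice PLD), and the
GM-probability-weighted mean of the corrected Δ%CBF_HO replaces the
voxelwise value for each subject — the HO response is too weak for
voxelwise use at ASL contrast-to-noise. Arterial-transit-time effects,
partial-volume correction and background suppression are not modeled.

## Respiratory analysis

End-tidal (ET) and fixed-inspired (FI) points are extracted per breath:
windows are delimited by upward zero-crossings of the mean-subtracted,
low-passed channel; within each window the breath-phase extrema are
located on the detrended residual and the raw values read there. For CO2
the ET is always the maximum; for O2 the extremum closer to the expected
FI schedule is labelled FI — during the return from hyperoxia the decaying
ET temporarily exceeds the freshly lowered FI, and the naive min/max
convention mislabels those breaths. Breaths within half a smoothing window
of a delivered-gas switch are dropped: they have no well-defined FI/ET
pair and the detrender leaks the step into neighbouring windows.

The sampling-line filter attenuates the waveform's peak-to-peak amplitude
symmetrically about the breath mean; each ET point is corrected by adding
the mean observed-minus-expected FI error of its two adjacent FI points
(same channel), which cancels the attenuation exactly for a symmetric
shrink. ET pressures are then rescaled from dry-analyzer to alveolar
values by (PB − 47)/PB (expired water vapor 47 mmHg; PB default 760,
configurable), and fitted at the irregular breath times against an offset,
zero-mean cubic drift and four per-block HRF regressors. The offset is the
drift-free baseline; per-gas changes average the two block effects.
Programmed steps are recovered within 0.2 mmHg at 10% attenuation (within
1 mmHg up to 30%).

## Synthetic data: what it emulates and what it does not

`make_ground_truth` draws voxelwise maps uniformly within healthy
gray-matter ranges at 3 T (CBF0 40–60 mL/100 g/min, T2*0 45–65 ms,
M 4–7%, OEF 0.30–0.45, f_HC 1.3–1.7), with 4% of voxels given T2*0 below
the 30 ms cutoff and 15% a GM probability below 0.5 to exercise masking.
Truth f_HO defaults to 1.0 and spatially constant — matching the measured
condition that the group-mean post-T1-correction hyperoxic flow change is
indistinguishable from zero — which also makes the GM-mean substitution
exact in recovery tests.

The respiratory simulator programs the group-mean end-tidal levels of the
study conditions (ETO2 111 → 370 mmHg under hyperoxia, → 118 under
hypercapnia; ETCO2 40 → 49.5 under hypercapnia, −1 mmHg under hyperoxia)
on the 18-minute paradigm: HC blocks of 120 s at 0 and 540 s, HO blocks of
180 s at 180 and 720 s — the stated block and rest durations fill the run
exactly, so the first HC block starts at t = 0 and baselines are
identified from the rests. ET plateaus follow the same HRF as the
analysis regressors ("near-exponential" transitions); FI steps with the
delivered schedule; the breath waveform is a cosine between FI and ET,
phase-locked across channels.

The imaging simulator computes one physical signal level per channel and
condition, `S(TE) = S0_state·exp(−TE·R2*_cond)`, with the label S0
depressed by the pCASL magnetization difference at that condition's CBF
(slice-dependent PLD; hyperoxia-shortened blood T1 for the HO state, the
~7 mmHg hypercapnic PaO2 rise neglected as the analysis also neglects it)
and the gas ΔR2* forward-generated from the truth (M, OEF) through the
calibration model. Each channel's time course interpolates between its
condition levels along the HRF-convolved block responses, plus shared
additive polynomial drift (in the span of the analysis drift columns) and
white Gaussian noise (optional AR(1) serial correlation, default off).
The analysis GLM is therefore the exact generative model of the noiseless
series — residuals are at machine precision and the full chain inverts the
simulation to ≤ 4e-5 in OEF. This is a deliberate validation design:
round-trip tests certify the *analysis algebra*, not the adequacy of a
linear GLM to a physically exponential transition (the difference is
second-order in TE·ΔR2*, ~1e-4 of signal). What passing these tests does
*not* show: robustness to motion, slice-timing and distortion effects,
non-Gaussian or structured physiological noise, arterial-transit-time
heterogeneity, or partial-volume mixing — none of which are simulated.

The default noise (SD 0.25 signal units on the brain-mean-100 scale) was
chosen to place the synthetic subject in the reported operating regime of
the method: at that level the GM solution-detection rate is ≈87%,
consistent with published whole-GM detection near 89 ± 5%. Noise the
simulator does not attempt: the scanner's actual noise spectrum is
uncharacterized here; Gaussian white noise is a stand-in.

### Noise bias of the solver

The solved OEF responds convexly to input perturbations (the
error-propagation curves are steeper for subtracted than added errors —
the same asymmetry as the two-point CVs, 28% at −33% vs 20% at +33%).
Symmetric input noise therefore inflates the mean recovered OEF: at the
default noise the GM-mean OEF is biased high by ≈+0.05 even though the
noiseless chain is exact. Stochastic recovery tests accordingly run in a
weak-noise regime (SD 0.05) where linearization holds and the GM mean
lands within sampling error of truth; the bias itself is asserted as a
property at realistic noise. Group averages of OEF from this estimator
are noise-level dependent — a caveat that applies to real data as well.

## Test–retest statistics

For each metric × ROI cell with paired sessions: dSD (SD of differences,
n−1), wsSD = dSD/√2 (two measurements), CR = 1.96·dSD (half-width of the
95% limits of agreement), wsCV = 100·√(mean over subjects of
(wsSD_i/mean_i)²) with wsSD_i = |B_i−A_i|/√2, and bsCV = 100·SD/mean of
the pooled values. A decision tree tests normality of the differences
(Shapiro–Wilk) and independence of |difference| from the mean (Kendall's
τ, two-sided) at α = 0.05; failure of either moves the cell to log10,
where wsCV = 100·(10^wsSD_log − 1) with wsSD_log = dSD(log10)/√2 (the
dSD/√2 form is used on the log scale as on the original); log data still
failing normality fall back to original-scale metrics with a
`log10_failed` flag. Degenerate zero-variance cells report zero
dSD/wsCV/CR with undefined p-values. ROI comparisons use Welch two-sample
t-tests on pooled values with Bonferroni correction over the ROI pairs
(Holm available), binned at 0.05/0.005/0.0005 — the correction method and
test are this package's choices where the original analysis names none.

## Sensitivity analyses

Systematic sweeps re-solve the GM-like baseline voxel (M = 5%, OEF = 0.39,
CBF0 = 50, f_HC = 1.5, f_HO = 1.0 at the group-mean end-tidal tensions;
the measured ΔR2* inputs are forward-generated once and held fixed) across
α ∈ [0.15, 0.45], β ∈ [1.0, 1.5], Hb ∈ [11, 17] g/dL, r_HC ∈ [0.90, 1.10]
(±1% CMRO2 per mmHg CO2 at the ~10 mmHg change), r_HO ∈ [0.93, 1.07]
(±1% per 40 mmHg O2 at the ~259 mmHg change) and f_HO ∈ [0.90, 1.00].
Sweeping Hb recomputes the arterial contents and the delivery. Sensitivity
is quantified as the maximum relative deviation of M from the
default-parameter solution. Measured: Hb 0.9%, r_HO 1.5%, f_HO 2.1%
(insensitive parameters; the HO curve slides along the nearly flat section
of the HC curve), versus β 45.7% and r_HC 27.6% (the principal sources).
Note the f_HO deviation sits marginally above a 2% bound — a genuine
property of the model at this baseline, not a numerical artifact.

Random-error propagation scales one measured input — Δ%CBF_HC (acting on
f_HC − 1), ΔR2*_HC or ΔR2*_HO — by 1 + e for e ∈ [−0.33, +0.33],
re-solves, and reports the displacement of M and OEF as two-point CVs
against the unperturbed solution (`cv_between`, closed form
100|e|/(√2(1+e/2))). Directions: overestimated |ΔR2*_HC| raises both M
and OEF; positive Δ%CBF_HC error lowers both; ±20% ΔR2*_HO perturbation
moves M by < 2% relative. Since resting CBF and CaO2 are not varied, the
OEF and CMRO2 CV curves coincide by construction.

## Problem sizes and numerics

Validation runs use a 12×12×4 voxel grid with 262 TRs (1080 s / 4.12 s,
524 frames), respiratory traces at 10 Hz with 4 s breaths, 1,000-voxel
round-trip grids, and 10,000-replicate estimator calibrations — sizes
chosen so the full suite and the acceptance script each complete in
seconds while every estimator's sampling error is far below its asserted
tolerance. Solver tolerances: OEF grid step 1e-3, bisection 1e-7,
curve-pole guard |denominator| > 1e-9. Noiseless-recovery configurations
disable smoothing and median filtering (spatial mixing would make
voxelwise truth comparison meaningless) and set respiratory attenuation
to zero; the acquisition-faithful defaults (8 mm FWHM, median filter on,
attenuation 0.1) remain the standard configuration.

## Known limitations

- Accuracy at the population level is validated only against the model's
  own forward simulation and one published sensitivity anchor; no gold
  standard (e.g. ¹⁵O PET) is involved.
- The GM-mean substitution of the hyperoxic flow response trades voxelwise
  HO information for stability; spatial heterogeneity in f_HO becomes a
  voxelwise OEF error by construction.
- The multiple-root tie rule (smallest OEF with M > 0) is untested by data
  since the physiological grid is single-rooted; it exists for safety.
- The noise model is white (optionally AR(1)); structured physiological
  noise, motion and susceptibility geometry beyond low-T2* assignment are
  not simulated.
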