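# Methods

## The compartment model

Each acquisition voxel is modeled as four partial volumes — myelin
(MY), cellular tissue (CL), free water (FW), and excess parenchymal
water (EPW) — summing to 100 %.  Each compartment carries its own
relaxation rates and proton density (PD, % of pure water at 37 °C):

| compartment | R1 (s⁻¹) | R2 (s⁻¹) | PD (%) | role |
|---|---|---|---|---|
| MY  | 16.6 (free) | 77 (fixed) | 42 (free) | myelin water + semi-solids |
| CL  | 0.78 (free) | 10.3 (free) | 85 (free) | intra/extracellular tissue |
| FW  | 0.24 (fixed) | 0.87 (fixed) | 100 (fixed) | bulk CSF |
| EPW | = FW | = FW | = FW | edema proxy |

Magnetization exchange: MY↔CL at a combined forward+backward rate
`k_my_cl` (default 6.7 s⁻¹, free); EPW↔CL infinitely fast (the two pools
behave as one merged pool wherever both exist); FW exchanges with
nothing.  The ordering R1/R2(FW) < R1/R2(CL) < R1/R2(MY) is enforced —
it is what makes the exchange-induced shift identifiable.

Assumptions worth stating: two exchange rates summarize all magnetic
interaction; compartment properties are spatially uniform; B0 is
homogeneous; flow and diffusion are ignored; the model is calibrated for
1.5 T — grids must be rebuilt for other field strengths or parameter
sets (grid files carry model/sequence hashes for that reason).

## Bloch engine

The state is one 3-vector per compartment per slice-profile element.
One integration step applies transverse relaxation/exchange, then
longitudinal relaxation/exchange with recovery, then the slice-select
gradient rotation about z, then the RF rotation.  The longitudinal
update is `mz' = A_L mz + (1 − E1)` with exchange couplings scaled by
the partner's share of proton density; MY↔CL couplings are attenuated by
`1 − exp(−dt·k)`, while the EPW↔CL coupling moves the full
weight-fraction every step, which equilibrates the pair within a couple
of microsecond steps — the infinite-exchange limit.  An exchange pair is
active only when both partners carry proton-density weight; absent pools
relax mono-exponentially.

Two sequence configurations exist:

* **Ideal profile** (`hard_pulse_sequence()`): instantaneous on-axis
  rotations, one element.  The steady state is computed exactly: with
  transverse magnetization spoiled at both ends of a repetition, the
  full-TR cycle is an affine map of the 4-pool longitudinal state, which
  is probed with basis vectors and solved in closed form.  This is the
  configuration the quantitative pipeline (manifold, lookup grid,
  phantom acquisition, calibration) uses.
* **Shaped profile** (`default_sequence()`): 150 elements over 15 mm,
  Hann-windowed sinc pulses (time-bandwidth 4; saturation 1.2 ms,
  excitation/refocusing 1.0 ms) with 1-µs integration during RF, and
  exact matrix-power propagation over RF-free intervals
  (`propagation="stepwise"` forces explicit stepping and is the
  brute-force reference; the two agree to machine precision).  The
  slice-select gradient maps each pulse's bandwidth to the 4-mm slice.
  Steady state is iterated with an analytic per-element seed
  (tolerance 1e-4 on ΔMz of weighted pools, cap 10 cycles, flagged).

Three stand-in pulse-design choices matter and were fixed by physics,
not convention: the saturation slice is twice the excitation slice
(equal widths leave the excited profile's edges unsaturated and their
positive signal cancels most of the short-TD magnitude signal); the
refocusing pulses are non-selective by default (slice-selective
refocusing leaves sub-percent stimulated/FID leakage per echo through
the 150-element comb, enough to bias fitted R2 by ~0.5–2 s⁻¹; a
selective mode with 3×-wide slices and variable-area crushers remains
available); the excitation is followed by a half-area rephase lobe.
Echoes are read as the PD-and-volume-weighted complex transverse sum
over elements, magnitude taken, normalized by the element count.

## Quantification fit

The 5 × 4 signal matrix is fitted with the saturation-recovery
spin-echo model (see README for the expression) by a vectorized
Levenberg–Marquardt in (log A·PD, log R1, log R2[, B1]) on magnitude
data (the model's absolute value — short-TD points cross zero).
Deterministic initialization: R2 from a log-linear regression of the
echoes at the longest delay; R1 from a coarse logarithmic scan with
per-candidate linear amplitude; amplitude by extrapolation to TE = 0.
Bounds R1 ∈ [0.05, 30] s⁻¹, R2 ∈ [0.1, 100] s⁻¹; convergence at a bound
is flagged, all-zero input returns a no-fit flag.

B1 handling: the public fit keeps B1 fixed at 1 by default.  Wherever
the data come from the Bloch forward model the pipeline fits B1 jointly
from the four TD points (`fit_b1=True`): the echo train's effect on the
recovering longitudinal magnetization makes the simulated TD curve an
exact member of the model family only once B1 is free — with B1 pinned,
R1 is biased by tens of percent.

PD calibration: the fit determines A·PD jointly; percent PD needs a
reference.  Options: an explicit `a_scale`, a pure-CSF reference region
(mean amplitude ↦ 100 %), or `csf_amplitude_scale()` which simulates a
pure free-water voxel through the same forward model (exact for phantom
studies).

**Known limitation (shaped profile):** fitting the single-(θ, α) model
to profile-mixed recovery curves distorts the amplitude in an
R1-dependent way (≈ +1 % for cellular tissue, ≈ +6 % for free water with
the default pulses), so CSF-referenced PD is biased ~4 % low for
parenchyma.  R1 and R2 are unaffected (within ±0.05 s⁻¹).  The
ideal-profile configuration has no such distortion, which is why the
quantitative pipeline defaults to it; shaped-profile studies should
treat absolute PD with care.

## Calibration

The healthy-cohort data structure is summarized by ridge maxima: three
pairwise 200 × 200 histograms (R1 0–2 s⁻¹, R2 0–15 s⁻¹, PD 50–100 %;
out-of-range voxels excluded from all three so totals agree), and for
every bin along every axis the argmax bin of each paired axis (ties to
the lower index; columns under `min_count = 5` voxels skipped; ≤ 600
triples).  The model side simulates and fits 141 compositions: the
FW–CL series at 1 % steps (101 points) and the MY–CL series from 1 to
40 % myelin (the cap reflects the most myelinated white matter).

Cost: each model point is paired with a *distinct* ridge point by greedy
one-to-one assignment in variance-normalized 3-D distance (σ² per axis =
variance of the ridge values); the cost averages the squared residuals
of the two coordinates the partner's scan axis did not index.  One-to-one
selection is essential — allowing reuse lets a degenerate parameter set
collapse the manifold onto one dense cluster and undercut the true
minimum (observed numerically).  When the ridge has fewer points than
the model set, plain nearest matching is used.

Optimization: cyclic coordinate descent over the six free parameters
(initial step 10 % of each range, halved when a full cycle yields no
improvement, stop below 1e-3 relative), from random initializations
rejection-sampled to satisfy the relaxation ordering; default 100
restarts (tests use 10).  Fully seeded and cached.

Confidence bounds: the named parameter is scanned outward while the
others are re-minimized; the bound is the last value whose cost stays at
or below 9.488.  The threshold is compared against the cost itself, as
the procedure defines it (a `use_delta` flag provides the conventional
cost-increase criterion).  Note 9.488 is the 5 % upper-tail χ² point at
4 degrees of freedom; the df = 5 quantile would be 11.07.
`chi2_threshold(a, df)` itself is the standard quantile.

Identifiability: with an anatomical cohort whose most "cellular-like"
tissue still carries ~2–5 % myelin, the pure-CL knee is fixed only by
extrapolation and the cost minimum sits ~10–15 % away in R1_CL — a
shallow-minimum behavior consistent with the wide calibrated
uncertainties of the myelin compartment.  The recovery tests therefore
use a mixture-series cohort (`make_manifold_phantom`, the digital
analogue of a physical mixture calibration phantom), where every
calibration composition is present and the cellular parameters return
within 1 %.

## Lookup grid and inversion

Compositions on the simplex lattice (myelin ≤ 40 %, free/excess water
free, cellular the remainder) are simulated at 5 % steps together with
the 1 %-stepped FW–CL and MY–CL edge curves, fitted, PD-normalized to
the pure-FW vertex, and linearly interpolated onto the 1 % target
lattice (exact simulated values kept where lattices coincide;
interpolation agrees with direct simulation to < 2 % per coordinate).
Physically degenerate samples — notably the cellular-free plane, where
excess water has no exchange partner and is indistinguishable from free
water — are collapsed onto the tie-break representative (smallest
V_EPW, then smallest V_MY), and nearest-neighbor queries (cKDTree in
σ-normalized coordinates) apply the same tie-break.  The normalized
distance is returned per voxel; beyond 3 a voxel is flagged
off-manifold in the QC report.  Inversion output sums to exactly 100 %
(compositions are lattice members) and is deterministic.

The free-water/excess-water near-degeneracy is real: both are water, and
they separate only through the exchange with cellular tissue.  Under 1 %
noise the median recovery error is ≲ 1 point for V_MY and larger for
V_EPW in low-cellular voxels; peripheral CSF partial-volume voxels can
legitimately read as tissue with excess water.

## Synthetic phantom

`make_phantom` builds a brain-like composition field: an ellipsoidal
intracranial volume (~1.2 L) with a 3-mm subarachnoid CSF layer, a
cortical shell (5 % myelin), a white-matter core (30 %), a
periventricular deep-gray sleeve (2 %, the caudate/thalamus analogue),
pure-free-water ventricles, and optional spherical lesions with elevated
excess water (up to ~55 %) and reduced myelin.  Borders are mixed by
Gaussian smoothing (2 mm default) and compositions quantized to the 1 %
lattice by largest-remainder rounding — matching the inversion lattice
and making composition-cached acquisition simulation cheap.  Acquisition
noise defaults to Gaussian at 1 % of the mean in-mask signal (SNR ~100,
typical for this sequence); Rician is available.  Everything is
deterministic given the seed.

What the phantom does *not* emulate: real gyral geometry and anatomical
variability, B0/B1 field maps, motion, flow, partial-volume effects
below the quantization step, and spatial normalization artifacts.
Passing tests therefore demonstrate correctness of the pipeline under
the model's own assumptions, not robustness to everything in vivo data
brings.

## Problem sizes used in the tests

Unit and acceptance tests run the ideal-profile configuration except
where the slice profile is the point.  The propagator-equivalence check
uses a shortened repetition (TR 300 ms) so brute-force 1-µs stepping
stays cheap; the calibration recovery uses 24 voxels per mixture, one
noisy cohort and 10 restarts; inversion recovery uses 200 random
compositions; the coarse test phantom is the same anatomy on a 6-mm
grid with enlarged ventricles (so pure-CSF interiors survive the border
mixing).  These sizes are stated here as the package's chosen validation
conditions.
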