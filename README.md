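# brainpv

Four-compartment relaxation-and-exchange modeling of quantitative brain
MRI: from a single multi-echo, multi-delay acquisition to voxelwise
myelin, cellular, free-water and edema partial volumes, and the clinical
volumetrics built on them.

## The problem

A fast quantitative MRI scan measures three numbers per voxel: the
longitudinal relaxation rate R1, the transverse relaxation rate R2, and
the proton density PD (percent of pure water at 37 °C).  None of them is
specific: myelin loss and edema both lower R1/R2 and raise PD.  This
package implements a tissue model that makes those changes separable.
Every acquisition voxel is a mixture of four partial volumes,

* **V_MY** — myelin (myelin water + sheet semi-solids), very fast
  relaxation, exchanging magnetization with the cellular pool at a
  combined rate *k*;
* **V_CL** — cellular tissue (intra/extracellular and axonal water,
  non-myelin macromolecules), medium relaxation;
* **V_FW** — free water (bulk CSF), no exchange with anything;
* **V_EPW** — excess parenchymal water (edema proxy), in infinitely fast
  exchange with the cellular pool,

with V_MY + V_CL + V_FW + V_EPW = 100 %.  Myelin water itself relaxes
too fast to observe with a 14-ms echo train; it is detected indirectly,
through the exchange-induced shift of the *dominant* relaxation
component.  The forward model simulates the full acquisition — a 120°(x)
saturation pulse, a delay TD ∈ {100, 400, 1380, 2860} ms, then a CPMG
readout (90°(x), 180°(y) refocusing) with echoes at 14–70 ms, TR
2950 ms — with coupled Bloch equations over the four pools,

    M(n+1) = R_RF · R_GR · R_R1 · R_R2 · M(n),

where the longitudinal/transverse relaxation matrices carry the
exchange couplings weighted by each pool's share of proton density.
Fitting the resulting 5 × 4 signal matrix with the mono-exponential
quantification model

    I(TE, TD) = A·PD·e^(−R2·TE) ·
        (1 − (1 − cos B1θ) e^(−R1·TD) − cos B1θ · e^(−R1·TR)) /
        (1 − cos B1α · cos B1θ · e^(−R1·TR))

maps any composition to an effective (R1, R2, PD) triple.  Enumerating
compositions on a lattice produces a curved manifold in (R1, R2, PD)
space; inverting a measured voxel is a nearest-neighbor lookup on that
manifold.  Model parameters (defaults: R1_MY = 16.6 s⁻¹, PD_MY = 42 %,
k = 6.7 s⁻¹, R1_CL = 0.78 s⁻¹, R2_CL = 10.3 s⁻¹, PD_CL = 85 %, water
fixed at R1 = 0.24 s⁻¹, R2 = 0.87 s⁻¹, PD = 100 %, R2_MY = 77 s⁻¹) are
calibrated by matching the simulated manifold to the ridge maxima of a
control cohort's 2-D map histograms.

Downstream metrics: brain parenchymal volume BPV = ICV − FWV and
fraction BPF = BPV/ICV; myelin, cellular and excess-water fractions
(MYF, CF, EPWF) of BPV; the voxel myelin water fraction
MWF = V_MY·PD_MY / (V_CL·PD_CL + V_EPW·PD_EPW); and the aqueous /
non-aqueous (macromolecular) content.

## Who it is for

Researchers in quantitative neuroimaging who want a transparent,
scriptable implementation of the model — to simulate sequences, study
identifiability, regenerate lookup grids for other parameter sets, or
process R1/R2/PD maps into partial-volume maps and volumetrics — plus a
synthetic brain phantom so the entire pipeline runs and is testable
without any scanner data.

## Worked example

```python
import brainpv as bp

model = bp.default_model_params()
seq = bp.hard_pulse_sequence()          # ideal-profile configuration

comp = bp.VoxelComposition.from_percent(v_my=20, v_cl=80)
signal = bp.simulate_sequence(comp, model, seq)
fit = bp.fit_qmaps(signal, seq, fit_b1=True)
print(fit.r1, fit.r2)                   # 1.309 11.675

grid = bp.build_grid(model, seq, step=1.0, sim_step=5.0)
comp_hat, dist = bp.invert_voxel(1.55, 12.4, 67.0, grid)
print(comp_hat.as_percent())            # (28.0, 72.0, 0.0, 0.0)

print(round(bp.mwf((19, 81, 0, 0), model)))   # 12  (thalamus-like voxel)
```

A 20 % myelin voxel simulates and fits to (R1, R2) = (1.31, 11.7) s⁻¹ —
shifted up from the pure-cellular (0.78, 10.3) by exchange; a
white-matter-like measurement inverts to 28 % myelin; the thalamus-like
composition yields an MWF of 12 %.  The `examples/` directory holds one
narrative script per capability (simulation+fit, lookup inversion,
phantom volumetrics, MWF/aqueous content, calibration), each printing
the numbers it computes and what they mean.  A thin CLI mirrors the
pipeline (`brainpv simulate|fit|build-grid|invert|metrics|phantom|
calibrate|selftest`).

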