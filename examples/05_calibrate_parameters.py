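"""Calibrate the free model parameters from a synthetic cohort.

Simulates a mixture-series calibration phantom (every free-water/cellular
and myelin/cellular mixture of the calibration set), fits the maps,
extracts the histogram ridge, and runs the multi-restart coordinate
descent on the ridge-matching cost.  With a fully identifiable cohort the
cellular-compartment parameters come back within a percent; the myelin
parameters stay loose, mirroring the shallow-minimum behavior of the
in vivo calibration.  A few minutes of runtime.
"""

import brainpv as bp
from brainpv import calibration as cal

model = bp.default_model_params()
seq = bp.hard_pulse_sequence()

phantom = bp.make_manifold_phantom(voxels_per_comp=24, noise_sigma_pct=1.0, seed=5)
series = bp.simulate_acquisition(phantom, model, seq)
a_scale = bp.csf_amplitude_scale(model, seq)
qmaps = bp.fit_volume(series, seq, phantom.icv_mask, fit_b1=True,
                      a_scale=a_scale, voxel_size_mm=(2.0, 2.0, 2.0))
ridge = cal.extract_ridge(cal.build_histograms(qmaps), min_count=5)
print(f"ridge: {len(ridge.r1)} histogram maxima")

result = bp.optimize(ridge, seq, n_restarts=4, seed=11)
print(f"minimum cost {result.min_cost:.4f}\n")
truth = dict(r1_my=16.6, pd_my=42.0, k_my_cl=6.7, r1_cl=0.78, r2_cl=10.3, pd_cl=85.0)
print(f"{'parameter':10s} {'fitted':>8s} {'generating':>11s}")
for name, value in result.theta.items():
    print(f"{name:10s} {value:8.3f} {truth[name]:11.3f}")

print("\nThe cellular parameters (r1_cl, r2_cl, pd_cl) are tightly")
print("determined; the myelin compartment is only loosely constrained --")
print("the cost minimum is shallow along those directions.")
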