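"""Simulate the quantification scan for single voxels and fit R1/R2/PD.

Builds the 5 x 4 (echo time x saturation delay) signal matrix for a pure
cellular voxel and for a 20 % myelin voxel, then fits the
saturation-recovery spin-echo model.  The pure cellular voxel returns
its generating parameters; the myelin voxel shows how magnetization
exchange shifts the apparent (dominant-component) relaxation toward the
myelin rates even though myelin water itself is too short-lived to see.
"""

import numpy as np

import brainpv as bp

model = bp.default_model_params()
seq = bp.hard_pulse_sequence()

for name, comp in [("pure cellular", bp.VoxelComposition.from_percent(v_cl=100)),
                   ("20% myelin", bp.VoxelComposition.from_percent(v_my=20, v_cl=80))]:
    signal = bp.simulate_sequence(comp, model, seq)
    fit = bp.fit_qmaps(signal, seq, fit_b1=True)
    print(f"{name}: echo-1 intensities across delays "
          f"{np.round(signal.intensities[0], 2)}")
    print(f"  fitted R1 = {fit.r1:.3f} 1/s, R2 = {fit.r2:.3f} 1/s, "
          f"amplitude = {fit.pd:.1f}")

print("\nThe 20% myelin voxel fits to higher R1/R2 and lower amplitude than")
print("pure cellular tissue: that shift is the myelin signature the")
print("partial-volume model inverts.")
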