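"""Invert a measured (R1, R2, PD) triple into partial volumes.

Builds the composition-lattice lookup grid (simulated at 5 % steps,
interpolated to 1 %), then inverts a white-matter-like measurement and a
CSF measurement.  The returned normalized distance says how far the
measurement sits from the model manifold (a quality check).
"""

import brainpv as bp

model = bp.default_model_params()
seq = bp.hard_pulse_sequence()

print("building lookup grid (a few seconds)...")
grid = bp.build_grid(model, seq, step=1.0, sim_step=5.0)
print(f"grid holds {len(grid.triples)} lattice samples\n")

for name, (r1, r2, pd) in [("white-matter-like", (1.55, 12.4, 67.0)),
                           ("CSF", (0.24, 0.87, 100.0)),
                           ("edematous tissue", (0.55, 6.5, 92.0))]:
    comp, dist = bp.invert_voxel(r1, r2, pd, grid)
    v_my, v_cl, v_fw, v_epw = comp.as_percent()
    print(f"{name}: R1={r1} R2={r2} PD={pd}")
    print(f"  -> V_MY={v_my:.0f}% V_CL={v_cl:.0f}% V_FW={v_fw:.0f}% "
          f"V_EPW={v_epw:.0f}%  (distance {dist:.2f})")

print("\nMyelin shows up as V_MY, bulk CSF as V_FW, and edema-like excess")
print("water as V_EPW; distances near zero mean the voxel is explained by")
print("the four-compartment model.")
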