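"""Simulate one trajectory per species preset plus a drone, and compare
their basic motion statistics.

Birds fly at species-specific cruise speeds with stochastic banking;
the drone flies a PID approach to its goal and then hovers, which is
exactly the smooth/slow signature the classifier exploits.
"""

import numpy as np

import skytrace as st

for kind, preset in [("bird", "pigeon"), ("bird", "gull"),
                     ("bird", "peregrine"), ("drone", None)]:
    rec = st.simulate_trajectory(kind, preset, T=60.0, dt=0.03, seed=4)
    vel = np.diff(rec.positions, axis=0) / rec.dt
    speed = np.linalg.norm(vel, axis=1)
    kappa = st.curvature_series(rec)
    name = preset or "drone"
    print(f"{name:10s}  mean speed {speed.mean():6.2f} m/s   "
          f"median curvature {np.nanmedian(kappa):.4f} 1/m   "
          f"altitude range [{rec.positions[:, 2].min():6.1f}, "
          f"{rec.positions[:, 2].max():6.1f}] m")

print()
print("Birds cruise at ~10-22 m/s with curvature set by their bank limits;")
print("the drone creeps toward its goal at ~1 m/s on a nearly straight path.")
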