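# skytrace

Trajectory-based discrimination of drones from birds.  At surveillance
ranges a flying target spans only a few pixels, so appearance is
uninformative — but *motion* is not: birds cruise at species-typical
airspeeds with bank-limited turning and rich stochastic variability,
while multirotor drones fly smooth, controller-shaped paths.
`skytrace` is a self-contained testbed for that idea: it simulates
physically plausible 3-D trajectories of three bird species and a
quadrotor under correlated wind gusts, audits their biomechanical
plausibility, and trains a bidirectional LSTM that labels a trajectory
as bird-like or drone-like from its positions alone.

It is aimed at researchers prototyping motion-based aerial
classifiers who need controlled, reproducible, labelled 3-D data
before (or instead of) field recordings.

## The models in brief

**Bird** — a point mass with state `(x, u, s, phi)` stepped at
`dt = 0.03 s`:

    x' = s u + w(x)            (airspeed along heading + wind)
    u' = omega x u             omega = (u x a_L) / s
    s' = k_s (s* + beta_tw (u.w) - s) + sigma_s xi
    phi' = k_phi (phi* - phi) + sigma_phi xi

with the coordinated-turn constraint `|a_L| = g tan(phi)` (so
`tan phi = V^2 / gR`), a desired bank derived from goal attraction,
altitude hold, wind compensation and obstacle avoidance, and
species presets (pigeon / gull / peregrine) within published
parameter ranges.  **Drone** — a point-mass quadrotor with PID
waypoint control, separate horizontal/vertical acceleration
saturation, a rate- and angle-limited thrust vector and a ground
constraint.  **Wind** — constant base + exact-discretisation
Ornstein–Uhlenbeck gusts + a Gaussian thermal updraft.

**Classifier** — two stacked bidirectional LSTM layers (64 units per
direction, dropout 0.2) with a per-frame sigmoid head, trained with
Adam (lr 1e-3, 35 epochs) on a masked binary cross-entropy over
zero-padded length-100 sequences; a trajectory's score is the masked
mean of its per-frame P(drone).  The recurrent network,
backpropagation through time and Adam are implemented in numpy and
verified against finite-difference gradients.  A GRU baseline of
identical dimensions is built in.

See `docs/methods.md` for the full model description and numerical
choices.

## Worked example

```python
import numpy as np
import skytrace as st
from skytrace.classifier import ClassifierConfig, predict_record, train_records
from skytrace.simulate import downsample

st.generate_dataset(30, "data", seed=2)           # 30 birds + 30 drones
records = [downsample(r) for r in st.load_dataset("data")]
tm = train_records(records, ClassifierConfig(epochs=12, seed=2))
print(max(tm.auc_history), tm.best_epoch)

fresh = downsample(st.simulate_trajectory("drone", T=100.0, dt=0.03, seed=999))
probs, seq_prob = predict_record(tm, fresh)
print(np.median(probs), seq_prob)
```

printed (exact values are seed-reproducible):

```
1.0 12
0.6974154775206565 0.6946220131769119
```

i.e. the model reaches validation AUC 1.0 on the held-out split, and a
freshly simulated drone trajectory it has never seen receives a median
per-frame P(drone) of 0.70 — above the 0.5 decision threshold, so the
track is flagged drone-like.  At the full study scale (200
trajectories per class, 35 epochs) held-out drone tracks typically
score above 0.9.

The `examples/` directory holds one short script per capability:
simulation (`01`), dataset generation + plausibility audit (`02`),
training + prediction (`03`), camera projection and sky rendering
(`04`).  A thin CLI wraps the same functions:

```sh
skytrace generate --n-per-class 200 --out data --seed 1
skytrace train --data data --out model --seed 1
skytrace predict --model model --traj data/drone_0000.json --per-frame
skytrace validate --data data --report audit.csv
skytrace render --traj data/bird_0000_pigeon.json --out frames
```

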