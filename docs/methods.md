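# Methods

`skytrace` is a self-contained testbed for trajectory-based
discrimination of drones from birds: a stochastic flight simulator
produces labelled 3-D tracks, and a bidirectional recurrent classifier
learns to separate biological from mechanical motion using positions
alone.  This note documents the models, the parameters that matter,
the numerical choices, and what the synthetic data does and does not
establish.

## Wind field

All agents share one wind field

    w(x, t) = w_base + g(t) + (0, 0, A exp(-d^2 / 2 r^2)),

with `w_base` a constant background wind, `g(t)` a spatially uniform
gust vector following a per-axis Ornstein–Uhlenbeck process, and a
"thermal" updraft of peak `A` and Gaussian length scale `r` centred at
a fixed horizontal point at distance `d`.  The gust uses the exact OU
discretisation

    g' = a g + sigma_gust sqrt(1 - a^2) eta,    a = exp(-dt / tau),

so its stationary per-axis variance is `sigma_gust^2` for any step
size — a property the tests verify by Monte Carlo.  Defaults:
`w_base = (1.5, 0.5, 0)` m/s, `tau = 2` s, `sigma_gust = 0.6` m/s,
`A = 1` m/s, `r = 40` m.  These perturb, but do not dominate, cruise
speeds of 10–22 m/s.  The gust has no spatial structure; real
turbulence is spatially correlated, which this model does not attempt.

## Bird model

A bird is a point mass with state `(x, u, s, phi)` — position, unit
heading, airspeed, bank angle — advanced by Euler–Maruyama at
`dt = 0.03 s`:

    x' = s u + w(x)
    u' = omega x u,      omega = (u x a_L) / s
    s' = k_s (s* + beta_tw (u.w) - s) + sigma_s xi_s
    phi' = k_phi (phi* - phi) + sigma_phi xi_phi

The bank angle sets the sustainable lateral acceleration through the
coordinated-turn relation `|a_L| = g tan(phi)`, equivalently
`tan(phi) = V^2 / (g R)` and heading rate `g tan(phi) / V`.  The
desired bank `phi*` is `atan(|a_lat|/g)` of the commanded behavioural
acceleration, saturated at the species ceiling `phi_max`; the
commanded acceleration sums

* goal attraction: `k_g * s` times the unit-to-goal vector projected
  perpendicular to the heading;
* altitude hold: `k_h (h_pref - z) - 2 sqrt(k_h) s u_z` vertically;
* cross-wind compensation: `-k_w` times the horizontal wind projected
  perpendicular to the heading;
* obstacle avoidance: inverse-square repulsion `k_a / d^2` away from
  each obstacle within a 25 m cutoff;
* a Gaussian lateral perturbation of amplitude `sigma_a` projected
  perpendicular to the heading.

The realised perpendicular acceleration is the banked lateral part
plus the vertical command, with total magnitude capped at
`g tan(phi_max)`; heading noise of amplitude `sigma_u sqrt(dt)` is
injected orthogonally after the rotation and the heading renormalised,
so `|u| = 1` holds to 1e-9 indefinitely.  Speed is clamped to
`[0.5 s*, 1.6 s*]`.

The damping term in the altitude command is a deliberate addition: the
proportional law alone is an undamped oscillator (natural frequency
`sqrt(k_h)` ≈ 0.14 rad/s) and under stochastic forcing produced ±70 m
altitude excursions, down to well below ground — incompatible with the
plausibility constraints the simulator is supposed to satisfy.
Near-critical damping (`2 sqrt(k_h)`) closes the loop; in level flight
(`u_z = 0`) the command reduces to the plain proportional law.

Species presets (pigeon, gull, peregrine) differ in cruise speed
(12 / 10 / 22 m/s), bank ceiling (40° / 35° / 70°), roll response,
wind sensitivity and noise amplitudes, giving a direct goal-oriented
flyer, a slow wind-drifting flyer, and a fast agile one.  All values
sit inside published typical ranges for the model's parameters; the
test suite asserts this.  Note a structural consequence of pure goal
attraction: a bird that reaches its goal orbits it near the bank
ceiling (radius `V^2 / (g tan(phi_max))`), because nothing in the
model tells it to stop.

## Drone model

The quadrotor is a point mass with a PID position controller: desired
acceleration `kp e - kd v + ki ∫e dt` toward the goal (goal altitude
replaced by the target altitude `h_star = 30` m), feed-forward wind
compensation, the same obstacle-avoidance law as the bird, and
additive control noise (`sigma_ctrl = 0.15 m/s^2`).  The command is
saturated separately in the horizontal (4 m/s²) and vertical (3 m/s²)
components and realised through a thrust vector that rotates toward
the commanded direction at most 2 rad/s, never tilts more than 35°
from vertical, and carries thrust clipped to `[0, 2.5 m g]`; a ground
constraint keeps `z >= 0`.  Gains `kp = 1.2, kd = 1.8, ki = 0.05`
(damping ratio ≈ 0.8) give a smooth approach with at most one small
overshoot.  Yaw tracks the velocity (or goal) heading at a bounded
rate with small noise; it does not affect the translational track.

Rotor-level rigid-body dynamics, fixed-wing aircraft as a simulated
class, and wingbeat oscillations are out of scope; the closed-form
coordinated-turn relations are retained as utilities and test oracles.

## Scene randomisation and datasets

Each trajectory draws its own scene from its seed: goal uniform in a
200 m box at 25–55 m altitude, preferred altitude 25–50 m, 0–3 point
obstacles.  Birds start in a 100 m box at 20–60 m altitude with a
uniform horizontal heading, at cruise speed, wings level; the drone
starts at rest on the ground within 30 m horizontally of the goal.
Simulations run `floor(T/dt)` steps (horizon `T = 100` s, so 3334
positions).  `generate_dataset` cycles bird files uniformly over the
three species and derives per-file seeds from the global seed, so a
dataset is reproducible bit-for-bit.  Records are exchanged as JSON
(`is_drone`, `movement_history`, optional `species`/`dt`/`seed`);
serialisation keeps full decimal precision, making the round trip
lossless.

## Classifier

Architecture: two stacked bidirectional LSTM layers, 64 hidden units
per direction, dropout 0.2 between layers, and an affine head mapping
the 128 concatenated top-layer states to one logit per frame, through
a logistic function.  A GRU variant of identical dimensions serves as
the architecture baseline.  The network, backpropagation through time
and the Adam optimiser are implemented directly in numpy; the
gradients are validated against central finite differences in the test
suite, and all randomness (initialisation, shuffling, dropout) flows
from one seeded generator, so training is bit-reproducible.

Pipeline: tracks are thinned to at most 100 uniformly spaced samples
(first and last retained, `dt` rescaled) — the classifier operates on
the whole-trajectory shape at about 1 s resolution rather than on raw
0.03 s steps.  The 80/20 split is stratified by class; per-feature
mean and standard deviation are computed on training frames only
(population std, floored at 1e-8) and applied to both subsets.
Sequences are zero-padded to length 100 with a validity mask; the
sequence label is broadcast to every valid frame and the loss is the
masked per-frame binary cross-entropy (probabilities clipped at 1e-7),
so padded frames provably contribute nothing.  Training uses Adam at
lr 1e-3, batch size 16, 35 epochs; the reported per-epoch loss is the
valid-frame-weighted mean of batch losses.  A trajectory's overall
score is the masked mean of its per-frame probabilities (threshold 0.5
for the binary label), and validation AUC of that score is evaluated
every epoch.  The checkpoint with the highest validation AUC is the
selected model; ties resolve to the most recent epoch, because on
separable data the AUC saturates at 1.0 within a few epochs and the
first such epoch is far less calibrated per frame than later ones.

## Plausibility auditing

The audit checks each bird record, from positions alone, against

1. lateral acceleration `<= g tan(phi_max) * 1.05`,
2. ground speed within the species airspeed range widened by a wind
   bound `w_max = |w_base| + 3 sigma_gust + A`,
3. per-step displacement `<= (s_max + w_max) dt * 1.05`.

The acceleration estimate deliberately smooths positions with a 101
sample (~3 s) boxcar before central differencing.  The model's white
forcing terms (heading noise, gust increments) are amplified by `1/dt`
in a raw second difference — at `dt = 0.03` s they alone contribute
several m/s² — so an unsmoothed per-sample check would flag every
noisy trajectory regardless of parameters.  The 3 s window suppresses
that step-scale forcing while retaining maneuver-scale acceleration;
it attenuates a sustained max-bank turn by its boxcar sinc factor, so
the audit bounds *sustained* maneuvers, while the per-step cap on the
realised `a_L` inside the integrator enforces the instantaneous limit
by construction.  Curvature, velocity autocorrelation and
altitude-change statistics use plain central differences
(`numpy.gradient`), with near-zero-speed frames flagged rather than
propagated.

## What the synthetic data shows — and what it does not

The generated classes are separable by construction: birds cruise at
10–22 m/s with bank-limited turning, drones approach a waypoint at
~1 m/s and hover.  Consequently the classifier reaches held-out AUC
1.0 and a training-loss plateau near 1e-3, and both LSTM and GRU solve
the task — the dataset does not discriminate between recurrent cell
types.  Passing tests therefore establish the correctness and
reproducibility of the pipeline, not classifier performance on real
surveillance tracks, where sensor noise, wind regimes, aggressive
drone flight modes and unmodelled species would all narrow the
margin.  The image-plane encoding (pinhole projection plus apparent
size) is provided as an alternative input channel, but the classifier
consumes 3-D world coordinates by default.

## Problem sizes

Default study scale, used by the acceptance script and the end-to-end
tests: 200 trajectories per class at `T = 100` s, thinned to 100
steps, 35 training epochs for each cell type.  Unit and property
tests use shorter horizons and smaller networks chosen to exercise the
same code paths.
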