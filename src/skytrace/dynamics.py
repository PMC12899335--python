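"""Flight dynamics: stochastic bird kinematics and a point-mass PID quadrotor.

Bird model
----------
A bird is a point mass with state ``(x, u, s, phi)``: position, unit
heading, airspeed and bank angle.  Ground velocity is ``s*u + w(x)``
(self-propulsion plus wind).  Turning follows coordinated-turn
kinematics: the bank angle limits the sustainable lateral acceleration
to ``g*tan(phi)``, the heading rotates with angular velocity
``omega = (u x a_L)/s``, and the bank itself relaxes toward a desired
value computed from goal attraction, altitude hold, cross-wind
compensation, obstacle avoidance and random lateral perturbations.
Speed relaxes toward a species-specific cruise speed modulated by the
tailwind component.  All stochastic terms are Euler-Maruyama increments
(scaled by sqrt(dt)) and every update is clamped so biomechanical
bounds -- |phi| <= phi_max, ``s`` within the species range, lateral
acceleration below ``g*tan(phi_max)`` -- hold at every step.

Drone model
-----------
The quadrotor is a point mass driven by a PID position controller whose
commanded acceleration is saturated separately in the horizontal and
vertical components, realised through a thrust vector that can only
tilt at a finite rate up to a maximum tilt angle, with thrust magnitude
clipped to ``[0, thrust_max]``, plus a ground constraint at z = 0.

Closed-form coordinated-turn utilities (:func:`turn_radius`,
:func:`yaw_rate`) are provided both for analysis and as the oracle the
bird stepper is tested against: noise-free flight at constant bank must
trace a circle of radius ``V^2/(g*tan(phi))``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .environment import EnvironmentState, wind_at

__all__ = [
    "G",
    "SpeciesParams",
    "BirdState",
    "DroneParams",
    "DroneState",
    "SPECIES_PRESETS",
    "turn_radius",
    "yaw_rate",
    "rodrigues_rotate",
    "bird_behavioral_accel",
    "desired_bank",
    "bird_step",
    "drone_step",
]

#: Gravitational acceleration, m/s^2.
G = 9.81

#: Obstacle repulsion is ignored beyond this range, m.
OBSTACLE_CUTOFF = 25.0


# ---------------------------------------------------------------------------
# parameter and state containers
# ---------------------------------------------------------------------------


@dataclass
class SpeciesParams:
    """One bird species' flight signature.

    Rates are 1/s, speeds m/s, angles rad.  Noise amplitudes are
    Euler-Maruyama diffusion coefficients: ``sigma_s`` in m/(s*sqrt(s)),
    ``sigma_phi`` in rad/sqrt(s), ``sigma_a`` an m/s^2 lateral
    acceleration perturbation and ``sigma_u`` a 1/sqrt(s) heading
    perturbation.  ``s_min``/``s_max`` default to 0.5 and 1.6 times the
    cruise speed.
    """

    name: str
    k_s: float
    s_star: float
    beta_tw: float
    sigma_s: float
    k_phi: float
    k_g: float
    k_h: float
    k_w: float
    k_a: float
    phi_max: float
    sigma_phi: float
    sigma_a: float
    sigma_u: float
    s_min: float | None = None
    s_max: float | None = None

    def __post_init__(self) -> None:
        if self.s_min is None:
            self.s_min = 0.5 * self.s_star
        if self.s_max is None:
            self.s_max = 1.6 * self.s_star
        if not (0.0 < self.phi_max < math.pi / 2):
            raise ValueError("phi_max must lie in (0, pi/2)")
        if not (self.s_min < self.s_star < self.s_max):
            raise ValueError("need s_min < s_star < s_max")
        for attr in ("k_s", "k_phi", "k_g", "k_h", "k_w", "k_a",
                     "sigma_s", "sigma_phi", "sigma_a", "sigma_u"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")


@dataclass
class BirdState:
    """Instantaneous bird state: position, unit heading, airspeed, bank."""

    x: np.ndarray
    u: np.ndarray
    s: float
    phi: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        n = np.linalg.norm(self.u)
        if abs(n - 1.0) > 1e-6:
            raise ValueError("heading u must be a unit vector")
        self.u = self.u / n


@dataclass
class DroneParams:
    """Point-mass quadrotor parameters (PID gains, saturations, noise)."""

    mass: float = 1.2
    kp: float = 1.2
    kd: float = 1.8
    ki: float = 0.05
    a_h_max: float = 4.0
    a_v_max: float = 3.0
    tilt_max: float = math.radians(35.0)
    tilt_rate_max: float = 2.0
    thrust_max: float = 2.5 * 1.2 * G
    k_a_drone: float = 3.0
    sigma_ctrl: float = 0.15
    yaw_rate_max: float = 2.0
    sigma_yaw: float = 0.05
    h_star: float = 30.0

    def __post_init__(self) -> None:
        if self.tilt_max >= math.pi / 2:
            raise ValueError("tilt_max must be below pi/2")
        for attr in ("mass", "kp", "kd", "a_h_max", "a_v_max",
                     "tilt_rate_max", "thrust_max", "yaw_rate_max"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")


@dataclass
class DroneState:
    """Instantaneous drone state."""

    x: np.ndarray
    v: np.ndarray = field(default_factory=lambda: np.zeros(3))
    t_hat: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    psi: float = 0.0
    e_int: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.t_hat = np.asarray(self.t_hat, dtype=float)
        self.e_int = np.asarray(self.e_int, dtype=float)
        n = np.linalg.norm(self.t_hat)
        if abs(n - 1.0) > 1e-6:
            raise ValueError("t_hat must be a unit vector")
        self.t_hat = self.t_hat / n


# Species presets.  Cruise speeds, bank limits and noise levels contrast a
# direct, goal-oriented pigeon; a slower, wind-sensitive, drifting gull;
# and a fast, agile peregrine with aggressive roll response.
SPECIES_PRESETS: dict[str, SpeciesParams] = {
    "pigeon": SpeciesParams(
        name="pigeon", k_s=1.0, s_star=12.0, beta_tw=0.25, sigma_s=0.5,
        k_phi=4.0, k_g=1.5, k_h=0.02, k_w=1.0, k_a=3.0,
        phi_max=math.radians(40.0), sigma_phi=0.08, sigma_a=0.7, sigma_u=0.08,
    ),
    "gull": SpeciesParams(
        name="gull", k_s=0.8, s_star=10.0, beta_tw=0.35, sigma_s=0.4,
        k_phi=3.0, k_g=1.0, k_h=0.018, k_w=1.8, k_a=3.0,
        phi_max=math.radians(35.0), sigma_phi=0.06, sigma_a=0.5, sigma_u=0.1,
    ),
    "peregrine": SpeciesParams(
        name="peregrine", k_s=1.5, s_star=22.0, beta_tw=0.15, sigma_s=0.8,
        k_phi=6.0, k_g=2.5, k_h=0.03, k_w=0.6, k_a=3.5,
        phi_max=math.radians(70.0), sigma_phi=0.12, sigma_a=1.0, sigma_u=0.06,
    ),
}


# ---------------------------------------------------------------------------
# closed-form coordinated-turn utilities
# ---------------------------------------------------------------------------


def turn_radius(phi: float, V: float) -> float:
    """Coordinated-turn radius ``R = V^2 / (g tan(phi))``."""
    if not (0.0 < phi < math.pi / 2):
        raise ValueError("phi must lie in (0, pi/2)")
    if V <= 0:
        raise ValueError("V must be positive")
    return V * V / (G * math.tan(phi))


def yaw_rate(phi: float, V: float) -> float:
    """Coordinated-turn heading rate ``psi' = g tan(phi) / V``."""
    if not (0.0 < phi < math.pi / 2):
        raise ValueError("phi must lie in (0, pi/2)")
    if V <= 0:
        raise ValueError("V must be positive")
    return G * math.tan(phi) / V


def rodrigues_rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotate ``v`` by ``angle`` about the unit vector ``axis``.

    Rodrigues' formula; preserves the norm of ``v`` exactly up to
    floating point.
    """
    v = np.asarray(v, dtype=float)
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        raise ValueError("rotation axis must be non-zero")
    if abs(n - 1.0) > 1e-9:
        raise ValueError("rotation axis must be a unit vector")
    c, s = math.cos(angle), math.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * float(np.dot(axis, v)) * (1.0 - c)


# ---------------------------------------------------------------------------
# hot-path scalar helpers (avoid numpy overhead in per-step loops)
# ---------------------------------------------------------------------------


def _cross(a, b):
    return (a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0])


def _dot(a, b):
    return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]


def _norm(a):
    return math.sqrt(a[0] * a[0] + a[1] * a[1] + a[2] * a[2])


def _perp(a, u):
    """Component of ``a`` perpendicular to the unit vector ``u``."""
    d = _dot(a, u)
    return (a[0] - d * u[0], a[1] - d * u[1], a[2] - d * u[2])


def _rotate(v, axis, angle):
    c, s = math.cos(angle), math.sin(angle)
    k = axis
    cx = _cross(k, v)
    d = _dot(k, v) * (1.0 - c)
    return (v[0] * c + cx[0] * s + k[0] * d,
            v[1] * c + cx[1] * s + k[1] * d,
            v[2] * c + cx[2] * s + k[2] * d)


def _obstacle_accel(x, obstacles, gain):
    """Inverse-square repulsion away from each obstacle within cutoff."""
    ax = ay = az = 0.0
    for obs in obstacles:
        rx, ry, rz = x[0] - obs[0], x[1] - obs[1], x[2] - obs[2]
        d = math.sqrt(rx * rx + ry * ry + rz * rz)
        if d < 1e-9 or d > OBSTACLE_CUTOFF:
            continue  # singularity guard / cutoff
        w = gain / (d * d * d)
        ax += w * rx
        ay += w * ry
        az += w * rz
    return (ax, ay, az)


# ---------------------------------------------------------------------------
# bird guidance and stepping
# ---------------------------------------------------------------------------


def bird_behavioral_accel(
    bird: BirdState,
    sp: SpeciesParams,
    env: EnvironmentState,
    rng: np.random.Generator | None = None,
    wind: np.ndarray | None = None,
) -> np.ndarray:
    """Commanded behavioural acceleration for a bird, m/s^2.

    Sum of goal attraction (projected perpendicular to the heading and
    scaled by the airspeed), altitude hold toward ``h_pref``, cross-wind
    compensation against the horizontal wind, inverse-square obstacle
    repulsion and, when ``rng`` is given, a Gaussian lateral
    perturbation of amplitude ``sigma_a`` projected perpendicular to
    the heading.
    """
    x, u, s = bird.x, bird.u, bird.s
    if wind is None:
        wind = wind_at(env, x)

    # goal attraction, perpendicular to heading
    gvec = (env.goal[0] - x[0], env.goal[1] - x[1], env.goal[2] - x[2])
    gn = _norm(gvec)
    if gn > 1e-9:
        ghat = (gvec[0] / gn, gvec[1] / gn, gvec[2] / gn)
        gp = _perp(ghat, u)
        k = sp.k_g * s
        a = [k * gp[0], k * gp[1], k * gp[2]]
    else:
        a = [0.0, 0.0, 0.0]

    # altitude hold, damped on the vertical self-motion (near-critical:
    # c_z = 2 sqrt(k_h) closes the otherwise undamped oscillator)
    a[2] += sp.k_h * (env.h_pref - x[2]) - 2.0 * math.sqrt(sp.k_h) * s * u[2]

    # cross-wind compensation (horizontal wind, perpendicular to heading)
    wh = (wind[0], wind[1], 0.0)
    wp = _perp(wh, u)
    a[0] -= sp.k_w * wp[0]
    a[1] -= sp.k_w * wp[1]
    a[2] -= sp.k_w * wp[2]

    # obstacle avoidance
    oa = _obstacle_accel(x, env.obstacles, sp.k_a)
    a[0] += oa[0]
    a[1] += oa[1]
    a[2] += oa[2]

    # random lateral perturbation
    if rng is not None and sp.sigma_a > 0:
        eta = rng.standard_normal(3)
        ep = _perp(eta, u)
        a[0] += sp.sigma_a * ep[0]
        a[1] += sp.sigma_a * ep[1]
        a[2] += sp.sigma_a * ep[2]

    return np.array(a)


def _lateral_axis(u):
    """Horizontal unit vector to the left of heading ``u`` (z cross u)."""
    lx, ly = -u[1], u[0]
    n = math.hypot(lx, ly)
    if n < 1e-9:
        return (1.0, 0.0, 0.0)  # heading vertical: any horizontal axis
    return (lx / n, ly / n, 0.0)


def desired_bank(a_cmd: np.ndarray, u: np.ndarray, sp: SpeciesParams) -> float:
    """Desired bank from a commanded acceleration.

    The horizontal part of ``a_cmd`` perpendicular to the heading sets
    the magnitude through ``atan(|a_lat| / g)``, saturated at
    ``phi_max``; the sign is positive for a left turn.
    """
    n_lat = _lateral_axis(u)
    a_h = (a_cmd[0], a_cmd[1], 0.0)
    a_lat = _dot(a_h, n_lat)
    mag = min(math.atan(abs(a_lat) / G), sp.phi_max)
    return math.copysign(mag, a_lat) if a_lat != 0.0 else 0.0


def bird_step(
    bird: BirdState,
    sp: SpeciesParams,
    env: EnvironmentState,
    dt: float,
    rng: np.random.Generator | None = None,
) -> BirdState:
    """Advance a bird by one Euler-Maruyama step of length ``dt``.

    Order of sub-updates: bank relaxation toward the desired bank (with
    roll noise, clamped to +/- phi_max); realised perpendicular
    acceleration ``g tan(phi)`` laterally plus the vertical command,
    capped at ``g tan(phi_max)``; heading rotation by
    ``omega = (u x a_L)/s`` via Rodrigues' formula; orthogonal heading
    noise followed by renormalisation; speed relaxation toward the
    tailwind-modulated cruise speed, clamped to the species range;
    finally position advance with ground velocity ``s u + w``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    sqdt = math.sqrt(dt)
    wind = wind_at(env, bird.x)
    u = (bird.u[0], bird.u[1], bird.u[2])
    s = bird.s

    # (1) bank dynamics
    a_cmd = bird_behavioral_accel(bird, sp, env, rng=rng, wind=wind)
    phi_star = desired_bank(a_cmd, bird.u, sp)
    phi = bird.phi + sp.k_phi * (phi_star - bird.phi) * dt
    if rng is not None and sp.sigma_phi > 0:
        phi += sp.sigma_phi * sqdt * rng.standard_normal()
    phi = max(-sp.phi_max, min(sp.phi_max, phi))

    # (2) realised perpendicular acceleration: banked lateral + vertical command
    n_lat = _lateral_axis(u)
    lat = G * math.tan(phi)
    a_L = [lat * n_lat[0], lat * n_lat[1], lat * n_lat[2] + a_cmd[2]]
    cap = G * math.tan(sp.phi_max)
    a_L_norm = _norm(a_L)
    if a_L_norm > cap:
        f = cap / a_L_norm
        a_L = [a_L[0] * f, a_L[1] * f, a_L[2] * f]

    # (3) heading rotation, omega = (u x a_L) / s
    om = _cross(u, a_L)
    om_n = _norm(om) / s
    if om_n > 1e-12:
        axis = (om[0] / (om_n * s), om[1] / (om_n * s), om[2] / (om_n * s))
        u = _rotate(u, axis, om_n * dt)

    # (4) orthogonal heading noise, then renormalise
    if rng is not None and sp.sigma_u > 0:
        eta = rng.standard_normal(3)
        ep = _perp(eta, u)
        k = sp.sigma_u * sqdt
        u = (u[0] + k * ep[0], u[1] + k * ep[1], u[2] + k * ep[2])
    n = _norm(u)
    u = (u[0] / n, u[1] / n, u[2] / n)

    # (5) speed relaxation with tailwind modulation
    s_target = sp.s_star + sp.beta_tw * _dot(u, wind)
    s = s + sp.k_s * (s_target - s) * dt
    if rng is not None and sp.sigma_s > 0:
        s += sp.sigma_s * sqdt * rng.standard_normal()
    s = max(sp.s_min, min(sp.s_max, s))

    # (6) position advance
    x = np.array([
        bird.x[0] + (s * u[0] + wind[0]) * dt,
        bird.x[1] + (s * u[1] + wind[1]) * dt,
        bird.x[2] + (s * u[2] + wind[2]) * dt,
    ])
    out = BirdState.__new__(BirdState)
    out.x = x
    out.u = np.array(u)
    out.s = s
    out.phi = phi
    return out


# ---------------------------------------------------------------------------
# drone stepping
# ---------------------------------------------------------------------------


def drone_step(
    drone: DroneState,
    dp: DroneParams,
    env: EnvironmentState,
    dt: float,
    rng: np.random.Generator | None = None,
) -> DroneState:
    """Advance the point-mass PID quadrotor by one step of length ``dt``.

    PID position control toward the goal (goal altitude replaced by
    ``h_star``) with feed-forward wind compensation and obstacle
    avoidance, saturated horizontally/vertically; thrust direction
    rotated toward the commanded direction at a bounded tilt rate and
    clamped to ``tilt_max`` from vertical; thrust magnitude clipped to
    ``[0, thrust_max]``; yaw steered toward the velocity (or goal)
    heading at a bounded rate; ground constraint at z = 0.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    wind = wind_at(env, drone.x)
    x, v = drone.x, drone.v

    # PID error, with the goal altitude replaced by the target altitude
    e = (env.goal[0] - x[0], env.goal[1] - x[1], dp.h_star - x[2])
    e_int = drone.e_int + np.array(e) * dt
    a_des = [
        dp.kp * e[0] - dp.kd * v[0] + dp.ki * e_int[0] - dp.kd * wind[0],
        dp.kp * e[1] - dp.kd * v[1] + dp.ki * e_int[1] - dp.kd * wind[1],
        dp.kp * e[2] - dp.kd * v[2] + dp.ki * e_int[2] - dp.kd * wind[2],
    ]
    oa = _obstacle_accel(x, env.obstacles, dp.k_a_drone)
    a_des[0] += oa[0]
    a_des[1] += oa[1]
    a_des[2] += oa[2]
    if rng is not None and dp.sigma_ctrl > 0:
        eta = rng.standard_normal(3)
        a_des[0] += dp.sigma_ctrl * eta[0]
        a_des[1] += dp.sigma_ctrl * eta[1]
        a_des[2] += dp.sigma_ctrl * eta[2]

    # separate horizontal / vertical saturation
    ah = math.hypot(a_des[0], a_des[1])
    if ah > dp.a_h_max:
        f = dp.a_h_max / ah
        a_des[0] *= f
        a_des[1] *= f
    a_des[2] = max(-dp.a_v_max, min(dp.a_v_max, a_des[2]))

    # desired thrust direction = normalize(a_des + g e_z)
    f_des = (a_des[0], a_des[1], a_des[2] + G)
    fn = _norm(f_des)
    t_hat = (drone.t_hat[0], drone.t_hat[1], drone.t_hat[2])
    if fn > 1e-9:
        t_des = (f_des[0] / fn, f_des[1] / fn, f_des[2] / fn)
        # rotate t_hat toward t_des at a bounded tilt rate
        cr = _cross(t_hat, t_des)
        crn = _norm(cr)
        ang = math.atan2(crn, _dot(t_hat, t_des))
        if crn > 1e-12 and ang > 1e-12:
            step_ang = min(ang, dp.tilt_rate_max * dt)
            axis = (cr[0] / crn, cr[1] / crn, cr[2] / crn)
            t_hat = _rotate(t_hat, axis, step_ang)
    # clamp tilt from vertical
    tilt = math.acos(max(-1.0, min(1.0, t_hat[2])))
    if tilt > dp.tilt_max:
        cr = _cross(t_hat, (0.0, 0.0, 1.0))
        crn = _norm(cr)
        if crn > 1e-12:
            axis = (cr[0] / crn, cr[1] / crn, cr[2] / crn)
            t_hat = _rotate(t_hat, axis, tilt - dp.tilt_max)
    n = _norm(t_hat)
    t_hat = (t_hat[0] / n, t_hat[1] / n, t_hat[2] / n)

    # thrust magnitude: desired force projected on the actual thrust axis
    T = dp.mass * _dot(f_des, t_hat)
    T = max(0.0, min(dp.thrust_max, T))

    # translational update + ground constraint
    acc = (T / dp.mass * t_hat[0],
           T / dp.mass * t_hat[1],
           T / dp.mass * t_hat[2] - G)
    v_new = [v[0] + acc[0] * dt, v[1] + acc[1] * dt, v[2] + acc[2] * dt]
    x_new = [x[0] + v_new[0] * dt, x[1] + v_new[1] * dt, x[2] + v_new[2] * dt]
    if x_new[2] < 0.0:
        x_new[2] = 0.0
        v_new[2] = max(v_new[2], 0.0)

    # yaw steering toward the velocity (or goal) heading
    vh = math.hypot(v_new[0], v_new[1])
    if vh > 0.5:
        psi_target = math.atan2(v_new[1], v_new[0])
    else:
        psi_target = math.atan2(env.goal[1] - x[1], env.goal[0] - x[0])
    dpsi = (psi_target - drone.psi + math.pi) % (2.0 * math.pi) - math.pi
    dpsi = max(-dp.yaw_rate_max * dt, min(dp.yaw_rate_max * dt, dpsi))
    psi = drone.psi + dpsi
    if rng is not None and dp.sigma_yaw > 0:
        psi += dp.sigma_yaw * math.sqrt(dt) * rng.standard_normal()

    out = DroneState.__new__(DroneState)
    out.x = np.array(x_new)
    out.v = np.array(v_new)
    out.t_hat = np.array(t_hat)
    out.psi = psi
    out.e_int = e_int
    return out
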