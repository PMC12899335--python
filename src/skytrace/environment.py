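"""Shared 3-D environment: wind field and static scene elements.

The wind felt by every agent is the sum of three parts:

* a constant background wind ``w_base``,
* a temporally correlated gust vector evolving as an Ornstein-Uhlenbeck
  (OU) process, spatially uniform,
* a "thermal" updraft -- a Gaussian bump of vertical wind centred on a
  fixed horizontal location.

The OU gust is advanced with the exact conditional-Gaussian update, so
its stationary per-axis variance is ``sigma_gust**2`` independently of
the integration step.  The scene additionally carries a goal waypoint, a
preferred flight altitude and a list of point obstacles; those are read
by the agent dynamics in :mod:`skytrace.dynamics`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["WindConfig", "EnvironmentState", "step_gust", "wind_at"]


@dataclass
class WindConfig:
    """Parameters of the wind field.

    Parameters
    ----------
    w_base
        Constant background wind, m/s.
    tau_gust
        Gust correlation time, s (must be positive).
    sigma_gust
        Stationary per-axis gust standard deviation, m/s.
    thermal_center
        Horizontal (x, y) centre of the thermal, m.
    thermal_strength
        Peak vertical wind at the thermal centre, m/s.
    thermal_radius
        Gaussian length scale of the thermal, m.
    """

    w_base: np.ndarray = field(default_factory=lambda: np.array([1.5, 0.5, 0.0]))
    tau_gust: float = 2.0
    sigma_gust: float = 0.6
    thermal_center: np.ndarray = field(default_factory=lambda: np.zeros(2))
    thermal_strength: float = 1.0
    thermal_radius: float = 40.0

    def __post_init__(self) -> None:
        self.w_base = np.asarray(self.w_base, dtype=float)
        self.thermal_center = np.asarray(self.thermal_center, dtype=float)
        if self.tau_gust <= 0:
            raise ValueError("tau_gust must be positive")
        if self.sigma_gust < 0:
            raise ValueError("sigma_gust must be non-negative")
        if self.thermal_radius <= 0:
            raise ValueError("thermal_radius must be positive")

    def max_wind_speed(self) -> float:
        """Conservative bound on the wind magnitude (3-sigma gusts)."""
        return (
            float(np.linalg.norm(self.w_base))
            + 3.0 * self.sigma_gust
            + abs(self.thermal_strength)
        )


@dataclass
class EnvironmentState:
    """Wind state plus static scene elements shared by all agents."""

    wind: WindConfig = field(default_factory=WindConfig)
    goal: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 40.0]))
    h_pref: float = 40.0
    obstacles: list = field(default_factory=list)
    gust: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        self.goal = np.asarray(self.goal, dtype=float)
        self.gust = np.asarray(self.gust, dtype=float)
        self.obstacles = [np.asarray(o, dtype=float) for o in self.obstacles]
        if self.h_pref < 0:
            raise ValueError("h_pref must be non-negative")
        if not np.all(np.isfinite(self.gust)):
            raise ValueError("gust must be finite")


def step_gust(env: EnvironmentState, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Advance the OU gust by one step of length ``dt`` and return it.

    Uses the exact discretisation of the OU process: with
    ``a = exp(-dt/tau)`` the update is

        gust' = a * gust + sigma * sqrt(1 - a**2) * eta,

    where ``eta`` is standard normal per axis.  The environment's stored
    gust is replaced in place.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    w = env.wind
    a = math.exp(-dt / w.tau_gust)
    noise_scale = w.sigma_gust * math.sqrt(1.0 - a * a)
    env.gust = a * env.gust + noise_scale * rng.standard_normal(3)
    return env.gust


def wind_at(env: EnvironmentState, x: np.ndarray) -> np.ndarray:
    """Total wind at position ``x``: base + gust + thermal updraft.

    The thermal contributes only vertically, with magnitude
    ``thermal_strength * exp(-d^2 / (2 r^2))`` where ``d`` is the
    horizontal distance from the thermal centre.  Deterministic given
    the current environment state; randomness enters only through
    :func:`step_gust`.
    """
    x = np.asarray(x, dtype=float)
    w = env.wind
    dx = x[0] - w.thermal_center[0]
    dy = x[1] - w.thermal_center[1]
    d2 = dx * dx + dy * dy
    thermal = w.thermal_strength * math.exp(-d2 / (2.0 * w.thermal_radius**2))
    out = w.w_base + env.gust
    return np.array([out[0], out[1], out[2] + thermal])
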