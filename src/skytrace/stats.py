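"""Descriptive statistics and biomechanical plausibility audits of tracks.

These routines double as validation reports for generated datasets and
as oracles in the test suite: finite-difference kinematics, turning
curvature, velocity autocorrelation, altitude-change histograms, a
per-record plausibility report against coordinated-turn limits, and a
seed-diversity report.

Numerical choices.  Velocities and accelerations use central
differences (one-sided at the ends).  The plausibility report estimates
acceleration from boxcar-smoothed positions (default window 101
samples, about 3 s at the native 0.03 s step): the model's stochastic
forcing terms (heading noise, gust increments) are white at the step
scale and would otherwise be amplified by 1/dt in a raw second
difference, swamping the maneuver-scale acceleration that the
coordinated-turn bound ``g tan(phi_max)`` actually constrains.  The
window is a compromise -- long enough to suppress the white forcing,
short against the slowest max-bank turn period (about 5-9 s), whose
sustained centripetal acceleration it attenuates by at most the boxcar
sinc factor.  Speeds measured from positions
are ground speeds, so the species airspeed range is widened by a bound
on the wind magnitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter1d

from .dynamics import G, SpeciesParams
from .environment import WindConfig
from .simulate import TrajectoryRecord

__all__ = [
    "PlausibilityReport",
    "TrajectorySummary",
    "kinematics",
    "curvature_series",
    "velocity_autocorrelation",
    "altitude_change_hist",
    "plausibility_report",
    "diversity_report",
    "summarize",
]

#: Frames slower than this (m/s) are flagged as degenerate for curvature.
SPEED_FLOOR = 1e-3

#: Pairs of trajectories closer than this RMS distance (m) are near-duplicates.
DUPLICATE_RMS = 1.0


@dataclass
class PlausibilityReport:
    """Outcome of the biomechanical audit of one bird record."""

    max_lateral_accel: float
    lateral_accel_bound: float
    speed_range_ok: bool
    max_step_jump: float
    continuity_ok: bool
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


@dataclass
class TrajectorySummary:
    """Distribution summaries used for dataset-level reporting."""

    speed: np.ndarray
    curvature: np.ndarray
    altitude_changes: np.ndarray
    velocity_autocorr: np.ndarray
    position_variance: np.ndarray


def kinematics(record: TrajectoryRecord) -> tuple[np.ndarray, np.ndarray]:
    """Velocity and acceleration series by central differences.

    Interior frames use central differences; the first and last frame
    fall back to one-sided differences (``numpy.gradient`` semantics).
    """
    if len(record.positions) < 3:
        raise ValueError("kinematics needs at least 3 positions")
    if record.dt <= 0:
        raise ValueError("dt must be positive")
    vel = np.gradient(record.positions, record.dt, axis=0)
    acc = np.gradient(vel, record.dt, axis=0)
    return vel, acc


def curvature_series(record: TrajectoryRecord) -> np.ndarray:
    """Turning curvature ``kappa = |v x a| / |v|^3`` per frame, 1/m.

    Frames with near-zero speed are returned as NaN (curvature is
    undefined there).
    """
    vel, acc = kinematics(record)
    speed = np.linalg.norm(vel, axis=1)
    cross = np.cross(vel, acc)
    kappa = np.full(len(speed), np.nan)
    ok = speed > SPEED_FLOOR
    kappa[ok] = np.linalg.norm(cross[ok], axis=1) / speed[ok] ** 3
    return kappa


def velocity_autocorrelation(record: TrajectoryRecord, max_lag: int) -> np.ndarray:
    """Mean-removed dot-product autocorrelation of the velocity series.

    ``rho(lag) = <(v_t - vbar) . (v_{t+lag} - vbar)> / <|v_t - vbar|^2>``
    with the denominator the lag-0 value, so ``rho(0) = 1``.  A
    zero-variance (constant-velocity) record returns 1 at lag 0 and NaN
    elsewhere.
    """
    vel, _ = kinematics(record)
    if len(vel) < max_lag + 2:
        raise ValueError("record too short for the requested max_lag")
    dv = vel - vel.mean(axis=0)
    var = float((dv * dv).sum(axis=1).mean())
    rho = np.empty(max_lag + 1)
    rho[0] = 1.0
    if var < 1e-12:
        rho[1:] = np.nan
        return rho
    for lag in range(1, max_lag + 1):
        rho[lag] = float((dv[:-lag] * dv[lag:]).sum(axis=1).mean()) / var
    return rho


def altitude_change_hist(record: TrajectoryRecord, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of the per-step altitude increments, m."""
    if n_bins < 1:
        raise ValueError("n_bins must be at least 1")
    if len(record.positions) < 2:
        raise ValueError("need at least 2 positions")
    dz = np.diff(record.positions[:, 2])
    counts, edges = np.histogram(dz, bins=n_bins)
    return counts, edges


def plausibility_report(
    record: TrajectoryRecord,
    sp: SpeciesParams,
    *,
    wind: WindConfig | None = None,
    smooth_window: int = 101,
    tol: float = 0.05,
) -> PlausibilityReport:
    """Audit one bird record against coordinated-turn and speed limits.

    Checks, each appending ``(frame, rule)`` entries on failure:

    1. perpendicular acceleration of the smoothed path stays below
       ``g tan(phi_max) (1 + tol)``;
    2. ground speed stays within ``[s_min - w_max, s_max + w_max]``
       (positions encode ground speed, so the airspeed range is widened
       by the wind bound ``w_max``);
    3. per-step displacement stays below ``(s_max + w_max) dt (1 + tol)``.
    """
    if record.is_drone:
        raise ValueError("plausibility_report audits bird records only")
    if wind is None:
        wind = WindConfig()
    w_max = wind.max_wind_speed()
    violations: list[tuple[int, str]] = []

    # (1) lateral (perpendicular-to-velocity) acceleration of the smoothed path
    smooth = uniform_filter1d(record.positions, size=smooth_window, axis=0,
                              mode="nearest")
    vel = np.gradient(smooth, record.dt, axis=0)
    acc = np.gradient(vel, record.dt, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    vhat = vel / np.maximum(speed, SPEED_FLOOR)[:, None]
    a_par = (acc * vhat).sum(axis=1)
    a_perp = np.linalg.norm(acc - a_par[:, None] * vhat, axis=1)
    bound = G * math.tan(sp.phi_max) * (1.0 + tol)
    for i in np.nonzero(a_perp > bound)[0]:
        violations.append((int(i), "lateral_accel"))

    # (2) ground-speed range
    lo, hi = sp.s_min - w_max, sp.s_max + w_max
    speed_bad = np.nonzero((speed < max(lo, 0.0)) | (speed > hi))[0]
    for i in speed_bad:
        violations.append((int(i), "speed_range"))

    # (3) step-displacement continuity
    steps = np.linalg.norm(np.diff(record.positions, axis=0), axis=1)
    step_bound = (sp.s_max + w_max) * record.dt * (1.0 + tol)
    jump_bad = np.nonzero(steps > step_bound)[0]
    for i in jump_bad:
        violations.append((int(i) + 1, "continuity"))

    return PlausibilityReport(
        max_lateral_accel=float(a_perp.max()),
        lateral_accel_bound=bound,
        speed_range_ok=len(speed_bad) == 0,
        max_step_jump=float(steps.max()),
        continuity_ok=len(jump_bad) == 0,
        violations=violations,
    )


def diversity_report(records: list[TrajectoryRecord]) -> dict:
    """Pairwise RMS distances between aligned position sequences.

    Returns the mean pairwise RMS distance and flags any near-duplicate
    pair (RMS below 1 m), which would indicate broken seeding.
    """
    if len(records) < 2:
        raise ValueError("diversity_report needs at least 2 records")
    n = min(len(r.positions) for r in records)
    rms = []
    flagged = []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            d = records[i].positions[:n] - records[j].positions[:n]
            r = math.sqrt(float((d * d).sum(axis=1).mean()))
            rms.append(r)
            if r < DUPLICATE_RMS:
                flagged.append((i, j, r))
    return {
        "mean_rms": float(np.mean(rms)),
        "min_rms": float(np.min(rms)),
        "flagged_pairs": flagged,
    }


def summarize(record: TrajectoryRecord, max_lag: int = 50) -> TrajectorySummary:
    """Bundle the descriptive statistics of one record."""
    vel, _ = kinematics(record)
    return TrajectorySummary(
        speed=np.linalg.norm(vel, axis=1),
        curvature=curvature_series(record),
        altitude_changes=np.diff(record.positions[:, 2]),
        velocity_autocorr=velocity_autocorrelation(record, max_lag),
        position_variance=record.positions.var(axis=0),
    )
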