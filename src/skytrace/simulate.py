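"""Trajectory generation, the JSON interchange format and dataset building.

A :class:`TrajectoryRecord` is the unit of interchange: a class flag
(``is_drone``), an optional species label, the time step and an ordered
sequence of 3-D positions.  On disk it is one JSON file with keys
``is_drone`` and ``movement_history`` (a list of ``[x, y, z]``) plus
optional ``species``, ``dt`` and ``seed`` metadata; unknown extra keys
are ignored on read.  Serialisation keeps full decimal precision so the
write/read round trip is bit-exact.

:func:`generate_dataset` builds a balanced, seeded corpus of bird and
drone trajectories -- bird files cycle uniformly over the three species
presets -- and :func:`downsample` thins full-resolution tracks to the
classifier's maximum sequence length.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .dynamics import (
    SPECIES_PRESETS,
    BirdState,
    DroneParams,
    DroneState,
    bird_step,
    drone_step,
)
from .environment import EnvironmentState, WindConfig, step_gust

__all__ = [
    "TrajectoryRecord",
    "DatasetManifest",
    "simulate_trajectory",
    "write_trajectory_json",
    "read_trajectory_json",
    "generate_dataset",
    "load_dataset",
    "downsample",
    "DEFAULT_DT",
    "DEFAULT_HORIZON",
]

DEFAULT_DT = 0.03
DEFAULT_HORIZON = 100.0


@dataclass
class TrajectoryRecord:
    """A labelled, ordered sequence of 3-D positions with time step."""

    is_drone: bool | None
    positions: np.ndarray
    dt: float = DEFAULT_DT
    species: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        if len(self.positions) == 0:
            raise ValueError("positions must be non-empty")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class DatasetManifest:
    """Summary of one generated dataset directory."""

    directory: str
    n_bird: int
    n_drone: int
    seed: int
    species_counts: dict[str, int]
    files: list[dict]
    config: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# single-trajectory simulation
# ---------------------------------------------------------------------------


def _random_environment(rng: np.random.Generator, wind: WindConfig) -> EnvironmentState:
    """Scene randomisation: goal in a 200 m box, 0-3 obstacles."""
    goal = np.array([
        rng.uniform(-100.0, 100.0),
        rng.uniform(-100.0, 100.0),
        rng.uniform(25.0, 55.0),
    ])
    h_pref = float(rng.uniform(25.0, 50.0))
    n_obs = int(rng.integers(0, 4))
    obstacles = [
        np.array([
            rng.uniform(-100.0, 100.0),
            rng.uniform(-100.0, 100.0),
            rng.uniform(10.0, 60.0),
        ])
        for _ in range(n_obs)
    ]
    return EnvironmentState(wind=wind, goal=goal, h_pref=h_pref, obstacles=obstacles)


def simulate_trajectory(
    kind: str,
    preset: str | None = None,
    *,
    T: float = DEFAULT_HORIZON,
    dt: float = DEFAULT_DT,
    seed: int = 0,
    env: EnvironmentState | None = None,
    wind: WindConfig | None = None,
    drone_params: DroneParams | None = None,
) -> TrajectoryRecord:
    """Simulate one labelled trajectory of ``floor(T/dt) + 1`` positions.

    ``kind`` is ``"bird"`` or ``"drone"``; for birds ``preset`` names a
    species in :data:`skytrace.dynamics.SPECIES_PRESETS`.  When ``env``
    is not supplied, the scene (goal, preferred altitude, obstacles) and
    the agent's initial condition are drawn from the seeded generator,
    so the record is fully deterministic given its arguments.
    """
    if T <= 0 or dt <= 0:
        raise ValueError("T and dt must be positive")
    if kind not in ("bird", "drone"):
        raise ValueError(f"unknown kind {kind!r}")
    rng = np.random.default_rng(seed)
    if wind is None:
        wind = WindConfig()
    if env is None:
        env = _random_environment(rng, wind)

    n_steps = math.floor(T / dt)
    positions = np.empty((n_steps + 1, 3))

    if kind == "bird":
        if preset is None:
            preset = "pigeon"
        if preset not in SPECIES_PRESETS:
            raise ValueError(f"unknown species preset {preset!r}")
        sp = SPECIES_PRESETS[preset]
        theta = rng.uniform(0.0, 2.0 * math.pi)
        state = BirdState(
            x=np.array([
                rng.uniform(-50.0, 50.0),
                rng.uniform(-50.0, 50.0),
                rng.uniform(20.0, 60.0),
            ]),
            u=np.array([math.cos(theta), math.sin(theta), 0.0]),
            s=sp.s_star,
            phi=0.0,
        )
        positions[0] = state.x
        for i in range(1, n_steps + 1):
            step_gust(env, dt, rng)
            state = bird_step(state, sp, env, dt, rng)
            positions[i] = state.x
        return TrajectoryRecord(is_drone=False, positions=positions, dt=dt,
                                species=preset, seed=seed)

    dp = drone_params if drone_params is not None else DroneParams()
    state = DroneState(
        x=np.array([
            env.goal[0] + rng.uniform(-30.0, 30.0),
            env.goal[1] + rng.uniform(-30.0, 30.0),
            0.0,
        ]),
    )
    positions[0] = state.x
    for i in range(1, n_steps + 1):
        step_gust(env, dt, rng)
        state = drone_step(state, dp, env, dt, rng)
        positions[i] = state.x
    return TrajectoryRecord(is_drone=True, positions=positions, dt=dt, seed=seed)


# ---------------------------------------------------------------------------
# JSON interchange
# ---------------------------------------------------------------------------


def write_trajectory_json(record: TrajectoryRecord, path: str | Path) -> None:
    """Write one record to a JSON file (full float precision)."""
    payload: dict = {
        "is_drone": bool(record.is_drone),
        "movement_history": record.positions.tolist(),
        "dt": record.dt,
    }
    if record.species is not None:
        payload["species"] = record.species
    if record.seed is not None:
        payload["seed"] = int(record.seed)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def read_trajectory_json(path: str | Path, *, require_label: bool = True) -> TrajectoryRecord:
    """Read one record back, ignoring unknown auxiliary keys.

    A missing or malformed ``movement_history`` raises ``ValueError``
    naming the key.  A missing ``is_drone`` flag is an error for
    training data (``require_label=True``) but allowed for prediction
    inputs, where the label is left as ``None``.
    """
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if "movement_history" not in payload:
        raise ValueError(f"{path}: missing required key 'movement_history'")
    try:
        positions = np.asarray(payload["movement_history"], dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: malformed 'movement_history'") from exc
    if positions.ndim != 2 or positions.shape[1] != 3:
        raise ValueError(f"{path}: 'movement_history' must be a list of [x, y, z]")
    is_drone = payload.get("is_drone")
    if is_drone is None and require_label:
        raise ValueError(f"{path}: missing required key 'is_drone'")
    return TrajectoryRecord(
        is_drone=None if is_drone is None else bool(is_drone),
        positions=positions,
        dt=float(payload.get("dt", DEFAULT_DT)),
        species=payload.get("species"),
        seed=payload.get("seed"),
    )


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

_SPECIES_CYCLE = ("pigeon", "gull", "peregrine")


def _file_seed(global_seed: int, index: int) -> int:
    """Deterministic per-file seed below 2**31."""
    return int(np.random.SeedSequence([global_seed, index]).generate_state(1)[0] % (2**31))


def generate_dataset(
    n_per_class: int,
    out_dir: str | Path,
    seed: int,
    *,
    T: float = DEFAULT_HORIZON,
    dt: float = DEFAULT_DT,
    wind: WindConfig | None = None,
    log=None,
) -> DatasetManifest:
    """Generate a balanced dataset of ``2 * n_per_class`` JSON files.

    Bird files cycle uniformly over the three species presets; per-file
    seeds derive deterministically from the global seed.  A manifest
    (``manifest.json``) snapshotting the configuration is written next
    to the trajectory files.  ``log`` may be a callable receiving one
    line per generated file.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be at least 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if wind is None:
        wind = WindConfig()

    files: list[dict] = []
    species_counts: dict[str, int] = {s: 0 for s in _SPECIES_CYCLE}
    for i in range(n_per_class):
        species = _SPECIES_CYCLE[i % len(_SPECIES_CYCLE)]
        fseed = _file_seed(seed, 2 * i)
        rec = simulate_trajectory("bird", species, T=T, dt=dt, seed=fseed, wind=wind)
        name = f"bird_{i:04d}_{species}.json"
        write_trajectory_json(rec, out_dir / name)
        species_counts[species] += 1
        files.append({"file": name, "kind": "bird", "species": species, "seed": fseed})
        if log is not None:
            log(f"bird {name} species={species} seed={fseed}")

        fseed = _file_seed(seed, 2 * i + 1)
        rec = simulate_trajectory("drone", T=T, dt=dt, seed=fseed, wind=wind)
        name = f"drone_{i:04d}.json"
        write_trajectory_json(rec, out_dir / name)
        files.append({"file": name, "kind": "drone", "species": None, "seed": fseed})
        if log is not None:
            log(f"drone {name} seed={fseed}")

    manifest = DatasetManifest(
        directory=str(out_dir),
        n_bird=n_per_class,
        n_drone=n_per_class,
        seed=seed,
        species_counts=species_counts,
        files=files,
        config={
            "T": T,
            "dt": dt,
            "wind": {
                "w_base": wind.w_base.tolist(),
                "tau_gust": wind.tau_gust,
                "sigma_gust": wind.sigma_gust,
                "thermal_center": wind.thermal_center.tolist(),
                "thermal_strength": wind.thermal_strength,
                "thermal_radius": wind.thermal_radius,
            },
        },
    )
    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest.__dict__, fh, indent=1)
    return manifest


def load_dataset(directory: str | Path, *, require_label: bool = True) -> list[TrajectoryRecord]:
    """Load every trajectory JSON in a directory (manifest excluded)."""
    directory = Path(directory)
    records = []
    for name in sorted(os.listdir(directory)):
        if not name.endswith(".json") or name == "manifest.json":
            continue
        records.append(read_trajectory_json(directory / name, require_label=require_label))
    return records


def downsample(record: TrajectoryRecord, target_len: int = 100) -> TrajectoryRecord:
    """Thin a record to at most ``target_len`` uniformly spaced samples.

    The first and last positions are always retained and the time step
    is rescaled by the stride; records already short enough come back
    unchanged (no upsampling).
    """
    if target_len < 2:
        raise ValueError("target_len must be at least 2")
    n = len(record.positions)
    if n <= target_len:
        return TrajectoryRecord(
            is_drone=record.is_drone, positions=record.positions.copy(),
            dt=record.dt, species=record.species, seed=record.seed,
        )
    idx = np.round(np.linspace(0, n - 1, target_len)).astype(int)
    stride = (n - 1) / (target_len - 1)
    return TrajectoryRecord(
        is_drone=record.is_drone,
        positions=record.positions[idx],
        dt=record.dt * stride,
        species=record.species,
        seed=record.seed,
    )
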