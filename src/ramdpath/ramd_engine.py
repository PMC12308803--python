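"""Overdamped Langevin dynamics with the random-acceleration (RAMD) protocol.

The ligand is a single bead obeying Brownian (overdamped) dynamics

    x' = x + mobility * (F_landscape(x) + F_random) * dt
           + sqrt(2 * mobility * kB * T * dt) * xi

with ``xi`` a standard-normal 3-vector.  The RAMD protocol adds a force of
constant magnitude along a random unit direction; after every evaluation
window the straight-line ligand displacement over that window is compared with
a threshold, and a new random direction is drawn whenever the ligand failed to
advance.  A dissociation event is recorded at the first saved frame whose
distance from the reference marker exceeds the dissociation distance.

Protocol structure mirrors the tauRAMD convention: a handful of independently
equilibrated replicas, each the common start of a batch of RAMD runs
(default 5 x 20 = 100 unbinding events per system).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .toy_system import ToySystem, force, force_scalar, pack_system

__all__ = [
    "RAMDParams",
    "LangevinParams",
    "Trajectory",
    "ProtocolResult",
    "WindowEvent",
    "unit_convert_force",
    "step_langevin",
    "run_ramd_trajectory",
    "equilibrate",
    "run_protocol",
]

logger = logging.getLogger(__name__)

KB = 0.008314463  # kJ/mol/K


def unit_convert_force(value: float) -> float:
    """kcal/mol/Angstrom -> kJ/mol/nm (x 4.184 x 10)."""
    if value < 0:
        raise ValueError("force magnitude must be >= 0")
    return value * 4.184 * 10.0


@dataclass
class RAMDParams:
    """Random-force protocol constants.

    ``force_magnitude`` is the 9 kcal/mol/Å of the source protocol converted
    to kJ/mol/nm; dissociation distance, evaluation window and time step are
    likewise the protocol's values.  ``threshold_distance`` is calibrated to
    the toy's Brownian dynamics: it sits at about half the free drift
    displacement per window, so a stalled ligand (thermal jitter only) falls
    below it and a freely driven one stays above it, which is the role the
    threshold plays in the source protocol.
    """

    force_magnitude: float = unit_convert_force(9.0)  # 376.56 kJ/mol/nm
    threshold_distance: float = 0.08   # nm per evaluation window
    evaluation_window: float = 0.05    # ps (50 fs)
    dissociation_distance: float = 6.0  # nm
    max_time: float = 1e5              # ps (100 ns)
    time_step: float = 0.002           # ps
    save_stride: int = 25              # steps between saved frames

    def __post_init__(self) -> None:
        for name in ("force_magnitude", "threshold_distance", "evaluation_window",
                     "dissociation_distance", "max_time", "time_step"):
            if getattr(self, name) < 0 or (name != "force_magnitude" and getattr(self, name) == 0):
                raise ValueError(f"{name} must be positive")
        if self.save_stride < 1:
            raise ValueError("save_stride must be >= 1")
        n = self.evaluation_window / self.time_step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("evaluation_window must be an integer multiple of time_step")

    @property
    def steps_per_window(self) -> int:
        return int(round(self.evaluation_window / self.time_step))


@dataclass
class LangevinParams:
    temperature: float = 313.0  # K
    mobility: float = 0.01      # nm^2 / (kJ/mol) / ps
    kB: float = KB

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.mobility <= 0:
            raise ValueError("mobility must be > 0")


@dataclass
class WindowEvent:
    """Audit record for one evaluation window."""

    time: float           # ps, window end
    displacement: float   # nm, straight-line over the window
    redrawn: bool
    direction: np.ndarray  # unit vector in effect during the window


@dataclass
class Trajectory:
    positions: np.ndarray          # (n_frames, 3), nm
    times: np.ndarray              # (n_frames,), ps
    replica_id: int
    run_id: int
    dissociated: bool
    dissociation_time: Optional[float]   # ps; None when censored
    ground_truth_channel: str            # "external" | "internal" | "none"
    rng_seed: int
    events: Optional[List[WindowEvent]] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.positions):
            raise ValueError("times and positions must have equal length")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
                raise ValueError("times must increase with constant spacing")

    @property
    def n_frames(self) -> int:
        return len(self.times)


@dataclass
class ProtocolResult:
    trajectories: List[Trajectory]
    n_replicas: int
    n_runs_per_replica: int
    label: str
    system: Optional[ToySystem] = None

    def __post_init__(self) -> None:
        ids = [(t.replica_id, t.run_id) for t in self.trajectories]
        if len(set(ids)) != len(ids):
            raise ValueError("(replica_id, run_id) pairs must be unique")


# --------------------------------------------------------------------------

def step_langevin(position, system: ToySystem, extra_force, params: LangevinParams,
                  dt: float, rng: np.random.Generator):
    """One Euler-Maruyama step; vectorized over leading axes of ``position``."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    x = np.asarray(position, dtype=float)
    f = force(system, x) + np.asarray(extra_force, dtype=float)
    noise_scale = math.sqrt(2.0 * params.mobility * params.kB * params.temperature * dt)
    x_new = x + params.mobility * f * dt + noise_scale * rng.standard_normal(x.shape)
    if not np.all(np.isfinite(x_new)):
        raise FloatingPointError(
            "non-finite position after Langevin step (time step too large for the landscape?)")
    return x_new


def _seed_for(base_seed: int, *tags: int) -> int:
    """Counter-based derived seed: order-insensitive in (replica, run)."""
    ss = np.random.SeedSequence((int(base_seed),) + tuple(int(t) for t in tags))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.standard_normal(3)
        n = np.linalg.norm(v)
        if n > 1e-12:
            return v / n


def equilibrate(system: ToySystem, lang: LangevinParams, seed: int,
                n_steps: int = 10_000, dt: float = 0.002) -> np.ndarray:
    """Unperturbed Langevin relaxation from the well center (replica prep)."""
    rng = np.random.Generator(np.random.PCG64(seed))
    packed = pack_system(system)
    mob = lang.mobility
    noise = math.sqrt(2.0 * mob * lang.kB * lang.temperature * dt)
    x, y, z = (float(v) for v in system.well_center)
    xi = rng.standard_normal((n_steps, 3))
    for i in range(n_steps):
        fx, fy, fz = force_scalar(x, y, z, packed)
        x += mob * fx * dt + noise * xi[i, 0]
        y += mob * fy * dt + noise * xi[i, 1]
        z += mob * fz * dt + noise * xi[i, 2]
    if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)):
        raise FloatingPointError("equilibration diverged")
    return np.array([x, y, z])


def run_ramd_trajectory(system: ToySystem, ramd: RAMDParams, lang: LangevinParams,
                        seed: int, start_position=None, replica_id: int = 0,
                        run_id: int = 0, log_events: bool = False) -> Trajectory:
    """One RAMD unbinding run.

    The random-force direction is re-drawn at an evaluation-window boundary
    iff the ligand's straight-line displacement over the window fell below
    ``ramd.threshold_distance``.  The run ends at the first saved frame more
    than ``dissociation_distance`` from the reference marker, or at
    ``max_time`` (censored).
    """
    rng = np.random.Generator(np.random.PCG64(int(seed)))
    packed = pack_system(system)
    ref = system.markers["reference_atom"]
    if start_position is None:
        start_position = system.well_center
    x, y, z = (float(v) for v in np.asarray(start_position, dtype=float))

    dt = ramd.time_step
    mob = lang.mobility
    noise = math.sqrt(2.0 * mob * lang.kB * lang.temperature * dt)
    fmag = ramd.force_magnitude
    spw = ramd.steps_per_window
    stride = ramd.save_stride
    max_steps = int(round(ramd.max_time / dt))
    d2_diss = ramd.dissociation_distance ** 2

    # exit-region bookkeeping for the ground-truth channel
    exits = [(ch.role, ch.axis_direction, ch.exit_distance ** 2) for ch in system.channels]
    gt_channel = "none"

    direction = _random_unit(rng)
    positions = [np.array([x, y, z])]
    times = [0.0]
    events: List[WindowEvent] = []

    dissociated = False
    dissociation_time: Optional[float] = None
    step = 0
    wx, wy, wz = x, y, z  # window start
    while step < max_steps and not dissociated:
        xi = rng.standard_normal((spw, 3))
        ex = fmag * direction[0]
        ey = fmag * direction[1]
        ez = fmag * direction[2]
        for i in range(spw):
            fx, fy, fz = force_scalar(x, y, z, packed)
            x += mob * (fx + ex) * dt + noise * xi[i, 0]
            y += mob * (fy + ey) * dt + noise * xi[i, 1]
            z += mob * (fz + ez) * dt + noise * xi[i, 2]
            step += 1
            if step % stride == 0:
                if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)):
                    raise FloatingPointError(
                        f"trajectory diverged at t={step * dt:.3f} ps "
                        "(time step too large for the landscape?)")
                positions.append(np.array([x, y, z]))
                t_now = step * dt
                times.append(t_now)
                dx, dy, dz = x - ref[0], y - ref[1], z - ref[2]
                r2 = dx * dx + dy * dy + dz * dz
                if gt_channel == "none":
                    best = None
                    for role, axis, ed2 in exits:
                        if r2 > ed2:
                            cosang = (dx * axis[0] + dy * axis[1] + dz * axis[2]) / math.sqrt(r2)
                            if best is None or cosang > best[1]:
                                best = (role, cosang)
                    if best is not None:
                        gt_channel = best[0]
                if r2 > d2_diss:
                    dissociated = True
                    dissociation_time = t_now
                    break
        if dissociated:
            break
        disp = math.sqrt((x - wx) ** 2 + (y - wy) ** 2 + (z - wz) ** 2)
        redraw = disp < ramd.threshold_distance
        if log_events:
            events.append(WindowEvent(time=step * dt, displacement=disp,
                                      redrawn=redraw, direction=direction.copy()))
        if redraw:
            direction = _random_unit(rng)
        wx, wy, wz = x, y, z

    if dissociation_time is not None and dissociation_time == 0.0:
        logger.warning("dissociation at t=0 for seed %d: suspicious start position", seed)

    return Trajectory(
        positions=np.asarray(positions), times=np.asarray(times),
        replica_id=replica_id, run_id=run_id, dissociated=dissociated,
        dissociation_time=dissociation_time, ground_truth_channel=gt_channel,
        rng_seed=int(seed), events=events if log_events else None,
    )


def run_protocol(system: ToySystem, ramd: RAMDParams, lang: LangevinParams,
                 n_replicas: int = 5, n_runs: int = 20, base_seed: int = 0,
                 equil_steps: int = 10_000) -> ProtocolResult:
    """Replica-structured protocol: equilibrate each replica, then batch runs.

    Seeds derive from ``base_seed`` and the (replica, run) pair through a
    counter-based scheme, so each run is reproducible in isolation and the
    result is independent of execution order.
    """
    if n_replicas < 1 or n_runs < 1:
        raise ValueError("n_replicas and n_runs must be >= 1")
    trajectories: List[Trajectory] = []
    for rep in range(n_replicas):
        start = equilibrate(system, lang, _seed_for(base_seed, 0xE9, rep),
                            n_steps=equil_steps, dt=ramd.time_step)
        for run in range(n_runs):
            seed = _seed_for(base_seed, 1, rep, run)
            traj = run_ramd_trajectory(system, ramd, lang, seed,
                                       start_position=start,
                                       replica_id=rep, run_id=run)
            logger.info(
                "replica=%d run=%d seed=%d dissociation_time=%s channel=%s",
                rep, run, seed,
                "CENSORED" if not traj.dissociated else f"{traj.dissociation_time:.3f} ps",
                traj.ground_truth_channel)
            trajectories.append(traj)
    return ProtocolResult(trajectories=trajectories, n_replicas=n_replicas,
                          n_runs_per_replica=n_runs, label=system.label, system=system)
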