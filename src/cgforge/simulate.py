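"""Langevin dynamics and parallel tempering over a CG potential.

The integrator is BAOAB underdamped Langevin: half kicks (B), half drifts
(A) around an exact Ornstein-Uhlenbeck velocity update (O).  BAOAB gives
accurate configurational averages at moderate time steps, which is what
matters here — CG dynamics are not physical dynamics, only the sampled
thermodynamics is meaningful, so masses and friction are sampling knobs.

Parallel tempering runs one replica per ladder temperature and attempts
Metropolis configuration swaps between neighbours on alternating even/odd
pair sweeps; reduced energies of every saved frame are evaluated at every
ladder temperature so MBAR can reweight the whole ensemble afterwards.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import kbt

__all__ = ["SimulationConfig", "Trajectory", "ReplicaEnsemble",
           "langevin_run", "parallel_tempering", "geometric_ladder",
           "SimulationDiverged"]


@dataclass
class SimulationConfig:
    temperature: float = 300.0     # K
    friction: float = 1.0         # 1/ps
    timestep: float = 0.002       # ps
    n_steps: int = 1000
    save_interval: int = 10
    seed: int = 0
    masses: np.ndarray | float = 1.0

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be > 0")
        if self.friction <= 0:
            raise ValueError("friction must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass
class Trajectory:
    coords: np.ndarray             # (S, n, 3) or (S, B, n, 3)
    potential_energies: np.ndarray
    velocities: np.ndarray         # final velocities
    config: SimulationConfig


@dataclass
class ReplicaEnsemble:
    """Multi-temperature trajectories with per-frame reduced energies."""

    temperatures: np.ndarray                 # (K,)
    trajectories: np.ndarray                 # (S, K, n, 3)
    potential_energies: np.ndarray           # (S, K)
    exchange_attempts: np.ndarray            # (K-1,)
    exchange_accepts: np.ndarray             # (K-1,)
    reduced_energy_matrix: np.ndarray        # (S*K, K): u[n, k] = beta_k U_n

    def __post_init__(self):
        if np.any(self.exchange_accepts > self.exchange_attempts):
            raise ValueError("acceptance counts cannot exceed attempts")

    @property
    def frame_counts(self) -> np.ndarray:
        """Frames contributed per ladder state (for MBAR)."""
        S, K = self.potential_energies.shape
        return np.full(K, S)


class SimulationDiverged(RuntimeError):
    """Raised when energies/forces go non-finite mid-run."""

    def __init__(self, step, last_coords):
        super().__init__(f"non-finite energy or force at step {step}")
        self.step = step
        self.last_coords = last_coords


def _masses_array(config, n):
    m = np.asarray(config.masses, float)
    if m.ndim == 0:
        m = np.full(n, float(m))
    return m[:, None]


def langevin_run(potential, R0, config: SimulationConfig,
                 temperatures: np.ndarray | None = None) -> Trajectory:
    """BAOAB Langevin at ``config.temperature``; batched if R0 is (B, n, 3).

    ``temperatures`` optionally assigns one temperature per batch walker
    (used by parallel tempering).  Frames are saved every
    ``config.save_interval`` steps; the initial configuration is frame 0.
    Bitwise reproducible for a given seed.
    """
    R = np.array(R0, float)
    single = R.ndim == 2
    if single:
        R = R[None]
    B, n, _ = R.shape
    rng = np.random.default_rng(config.seed)
    m = _masses_array(config, n)                      # (n, 1)
    if temperatures is None:
        kT = np.full(B, kbt(config.temperature))
    else:
        kT = kbt(np.asarray(temperatures, float))
    dt = config.timestep
    c1 = np.exp(-config.friction * dt)
    c2 = np.sqrt(1.0 - c1 * c1)
    sigma_v = np.sqrt(kT[:, None, None] / m[None])    # (B, n, 1)

    v = rng.normal(0.0, 1.0, R.shape) * sigma_v
    U, F = potential.energy_forces(R)
    if not (np.all(np.isfinite(U)) and np.all(np.isfinite(F))):
        raise SimulationDiverged(0, R[0] if single else R)

    saved_R = [R.copy()]
    saved_U = [np.array(U, float, ndmin=1).copy()]
    for step in range(1, config.n_steps + 1):
        v = v + 0.5 * dt * F / m
        R = R + 0.5 * dt * v
        v = c1 * v + c2 * sigma_v * rng.normal(0.0, 1.0, R.shape)
        R = R + 0.5 * dt * v
        U, F = potential.energy_forces(R)
        if not (np.all(np.isfinite(U)) and np.all(np.isfinite(F))):
            last = saved_R[-1]
            raise SimulationDiverged(step, last[0] if single else last)
        v = v + 0.5 * dt * F / m
        if step % config.save_interval == 0:
            saved_R.append(R.copy())
            saved_U.append(np.array(U, float, ndmin=1).copy())

    coords = np.stack(saved_R)
    energies = np.stack(saved_U)
    if single:
        coords = coords[:, 0]
        energies = energies[:, 0]
        v = v[0]
    return Trajectory(coords, energies, v, config)


def geometric_ladder(t_min: float, t_max: float, n: int) -> np.ndarray:
    """Geometrically spaced temperature ladder from t_min to t_max."""
    return t_min * (t_max / t_min) ** (np.arange(n) / (n - 1))


def parallel_tempering(potential, R0, ladder, exchange_interval: int,
                       config: SimulationConfig) -> ReplicaEnsemble:
    """Replica exchange over a strictly increasing temperature ladder.

    Configurations (not temperatures) are swapped with the Metropolis rule
    min{1, exp[(beta_i - beta_j)(U_i - U_j)]} on alternating even/odd
    neighbour sweeps; velocities are rescaled by sqrt(T_new/T_old) on
    exchange.  Reduced energies of every saved frame are recorded at every
    ladder temperature.
    """
    ladder = np.asarray(ladder, float)
    if ladder.ndim != 1 or ladder.size < 2:
        raise ValueError("ladder needs >= 2 replicas")
    if np.any(np.diff(ladder) < 0):
        raise ValueError("ladder must be non-decreasing")
    K = ladder.size
    R = np.repeat(np.asarray(R0, float)[None], K, axis=0)
    n = R.shape[1]
    rng = np.random.default_rng(config.seed + 104729)
    betas = 1.0 / kbt(ladder)

    attempts = np.zeros(K - 1, int)
    accepts = np.zeros(K - 1, int)
    frames, energies = [], []

    n_rounds = max(config.n_steps // exchange_interval, 0)
    leftover = config.n_steps - n_rounds * exchange_interval
    v = None
    sweep = 0
    for rnd in range(n_rounds + 1):
        steps = exchange_interval if rnd < n_rounds else leftover
        if steps > 0 or rnd == 0:
            sub = SimulationConfig(
                temperature=config.temperature, friction=config.friction,
                timestep=config.timestep, n_steps=steps,
                save_interval=config.save_interval,
                seed=config.seed + 31 * rnd, masses=config.masses)
            traj = langevin_run(potential, R, sub, temperatures=ladder)
            # drop the duplicated initial frame on later rounds
            start = 0 if rnd == 0 else 1
            for s in range(start, traj.coords.shape[0]):
                frames.append(traj.coords[s])
                energies.append(traj.potential_energies[s])
            R = traj.coords[-1].copy()
            v = traj.velocities
        if rnd == n_rounds:
            break
        U = np.asarray(potential.energy_forces(R)[0], float)
        first = sweep % 2
        for i in range(first, K - 1, 2):
            attempts[i] += 1
            log_p = (betas[i] - betas[i + 1]) * (U[i] - U[i + 1])
            if np.log(rng.uniform()) < min(0.0, log_p):
                accepts[i] += 1
                R[[i, i + 1]] = R[[i + 1, i]]
                U[[i, i + 1]] = U[[i + 1, i]]
                if v is not None:
                    scale_up = np.sqrt(ladder[i + 1] / ladder[i])
                    vi = v[i].copy()
                    v[i] = v[i + 1] / scale_up
                    v[i + 1] = vi * scale_up
        sweep += 1

    trajectories = np.stack(frames)              # (S, K, n, 3)
    pot_e = np.stack(energies)                   # (S, K)
    # reduced energies: frame (s, k) evaluated at every ladder temperature
    S = pot_e.shape[0]
    u = (pot_e.reshape(S * K)[:, None]) * betas[None, :]
    return ReplicaEnsemble(ladder, trajectories, pot_e, attempts, accepts, u)


def extended_configuration(top, bond_length: float = 0.38) -> np.ndarray:
    """Fully extended starting structure: beads zig-zag along x.

    For protein topologies the backbone runs along x with CB/O offsets
    perpendicular to it; for free-form chains this is a near-straight line
    with small alternating lateral displacement.
    """
    n = top.n_beads
    R = np.zeros((n, 3))
    x = 0.0
    for i in range(n):
        name = top.bead_names[i]
        off = {"N": (0.0, 0.05), "CA": (0.0, -0.05), "C": (0.0, 0.05),
               "O": (0.12, 0.17), "CB": (0.0, -0.2)}.get(name, (0.0, 0.0))
        if name in ("N", "CA", "C") or name == top.bead_names[0]:
            R[i] = [x, off[1], 0.02 * (-1) ** i]
            x += bond_length * 0.85
        else:
            base = R[i - 1] if i else np.zeros(3)
            R[i] = base + [off[0], off[1], 0.0]
    if len(set(top.bead_names)) == 1:   # free-form chain
        R = np.zeros((n, 3))
        R[:, 0] = np.arange(n) * bond_length
        R[:, 1] = 0.02 * (-1) ** np.arange(n)
    return R
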