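"""Synthetic systems with known ground truth.

These generators emulate the statistical structure of all-atom training
data — equilibrium frames with stored instantaneous forces — while keeping
the generating potential known and differentiable, so that force-matching
recovery, prior fitting and free-energy machinery can all be checked
against exact references.

Each CG-resolution bead may carry fast "satellite" atoms, harmonically
tethered like constrained hydrogens: they make the force-aggregation
operator nontrivial (the aggregated bead force is not the bead-atom force)
without changing the CG marginal, because their tether forces average to
zero over the fast degrees of freedom.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .framesets import AtomisticFrameSet
from .topology import AtomisticTopology, CGTopology
from .units import kbt

__all__ = ["ToySystemSpec", "GroundTruthPotential", "toy_topologies",
           "generate_toy_frameset", "generate_two_state_foldamer",
           "double_well_pair_spec", "generate_dimer_umbrella_set",
           "chain_spec"]


@dataclass
class ToySystemSpec:
    """Definition of a toy system: beads, ground-truth terms, satellites.

    Ground-truth terms, all in nm / kJ-per-mol units:
    ``bonds``        [(i, j, r0, k)] harmonic
    ``angles``       [(i, j, k, theta0, kappa)] harmonic in the angle
    ``pair_wells``   [(i, j, eps, r0, width)] attractive Gaussian wells,
                     U = -eps exp(-(r - r0)^2 / (2 width^2))
    ``repulsions``   [(i, j, sigma, eps, p)] the same C1 truncated power
                     repulsion the prior uses
    ``double_wells`` [(i, j, a, d0, c)] quartic double well on a pair
                     distance, U = a ((d - d0)^2 - c^2)^2
    """

    n_beads: int
    bead_types: np.ndarray = None
    bonds: list = field(default_factory=list)
    angles: list = field(default_factory=list)
    pair_wells: list = field(default_factory=list)
    repulsions: list = field(default_factory=list)
    double_wells: list = field(default_factory=list)
    n_satellites: int = 1
    satellite_k: float = 40000.0        # kJ/mol/nm^2, stiff = fast
    temperature: float = 300.0
    seed: int = 0

    def __post_init__(self):
        if self.bead_types is None:
            self.bead_types = np.zeros(self.n_beads, int)
        self.bead_types = np.asarray(self.bead_types, int)
        bond_k = [b[3] for b in self.bonds]
        if bond_k and self.n_satellites and self.satellite_k <= 4 * max(bond_k):
            raise ValueError("satellite stiffness must greatly exceed the "
                             "backbone stiffness (timescale separation)")


class GroundTruthPotential:
    """Analytic energy/forces of a ToySystemSpec on the bead coordinates."""

    def __init__(self, spec: ToySystemSpec):
        self.spec = spec

    def energy_forces(self, R: np.ndarray):
        R = np.asarray(R, float)
        single = R.ndim == 2
        if single:
            R = R[None]
        U = np.zeros(R.shape[0])
        G = np.zeros_like(R)

        def pair(i, j):
            d = R[:, i] - R[:, j]
            r = np.linalg.norm(d, axis=-1)
            return d, np.maximum(r, 1e-10)

        def acc(i, j, dU_dr, d, r):
            g = (dU_dr / r)[:, None] * d
            G[:, i] += g
            G[:, j] -= g

        for (i, j, r0, k) in self.spec.bonds:
            d, r = pair(i, j)
            U += 0.5 * k * (r - r0) ** 2
            acc(i, j, k * (r - r0), d, r)
        for (i, j, l, t0, kap) in self.spec.angles:
            u = R[:, i] - R[:, j]
            v = R[:, l] - R[:, j]
            nu = np.linalg.norm(u, axis=-1)
            nv = np.linalg.norm(v, axis=-1)
            cost = np.clip(np.sum(u * v, -1) / np.maximum(nu * nv, 1e-12), -1, 1)
            th = np.arccos(cost)
            sint = np.maximum(np.sqrt(1 - cost ** 2), 1e-8)
            uh = u / nu[:, None]
            vh = v / nv[:, None]
            dti = (cost[:, None] * uh - vh) / (nu * sint)[:, None]
            dtl = (cost[:, None] * vh - uh) / (nv * sint)[:, None]
            U += 0.5 * kap * (th - t0) ** 2
            g = (kap * (th - t0))[:, None]
            G[:, i] += g * dti
            G[:, l] += g * dtl
            G[:, j] -= g * (dti + dtl)
        for (i, j, eps, r0, w) in self.spec.pair_wells:
            d, r = pair(i, j)
            e = np.exp(-((r - r0) ** 2) / (2 * w ** 2))
            U += -eps * e
            acc(i, j, eps * e * (r - r0) / w ** 2, d, r)
        for (i, j, sigma, eps, p) in self.spec.repulsions:
            d, r = pair(i, j)
            inside = r < sigma
            sr = np.where(inside, sigma / r, 1.0)
            U += np.where(inside, eps * (sr ** p - 1 + p * (r / sigma - 1)), 0.0)
            acc(i, j, np.where(inside, eps * p * (1 / sigma - sr ** p / r), 0.0), d, r)
        for (i, j, a, d0, c) in self.spec.double_wells:
            d, r = pair(i, j)
            x = (r - d0) ** 2 - c ** 2
            U += a * x ** 2
            acc(i, j, 4 * a * x * (r - d0), d, r)
        return (U[0], -G[0]) if single else (U, -G)


def toy_topologies(spec: ToySystemSpec):
    """Matching (AtomisticTopology, CGTopology) for a toy system.

    Each bead becomes one preserved heavy atom ("CA") plus
    ``spec.n_satellites`` constrained hydrogens; one toy residue per bead.
    Bonded term lists on the CG side follow the spec's bond list, with
    angles/dihedrals over consecutive chain triples/quadruples.
    """
    n, s = spec.n_beads, spec.n_satellites
    atom_names, res_index, elements, con_h, h_parent = [], [], [], [], []
    for b in range(n):
        atom_names.append("CA")
        res_index.append(b)
        elements.append("C")
        con_h.append(False)
        h_parent.append(-1)
        heavy = len(atom_names) - 1
        for hh in range(s):
            atom_names.append(f"H{hh + 1}")
            res_index.append(b)
            elements.append("H")
            con_h.append(True)
            h_parent.append(heavy)
    atop = AtomisticTopology(
        atom_names=tuple(atom_names),
        residue_index=np.array(res_index, int),
        residue_names=tuple("GLY" for _ in range(n)),
        chain_id=tuple("A" for _ in range(n)),
        elements=tuple(elements),
        constrained_h=np.array(con_h, bool),
        h_parent=np.array(h_parent, int),
    )
    bond_list = np.array([[b[0], b[1]] for b in spec.bonds], int).reshape(-1, 2)
    adj = [[] for _ in range(n)]
    for a, b in bond_list:
        adj[a].append(b)
        adj[b].append(a)
    angles = []
    for j in range(n):
        nb = sorted(adj[j])
        for x in range(len(nb)):
            for y in range(x + 1, len(nb)):
                angles.append((nb[x], j, nb[y]))
    dihedrals = [(i, i + 1, i + 2, i + 3) for i in range(n - 3)
                 if all((i + k, i + k + 1) in {tuple(b) for b in bond_list.tolist()}
                        or (i + k + 1, i + k) in {tuple(b) for b in bond_list.tolist()}
                        for k in range(3))]
    agg = []
    stride = 1 + s
    for b in range(n):
        agg.append(tuple(range(b * stride, (b + 1) * stride)))
    ctop = CGTopology(
        n_beads=n,
        bead_names=tuple("CA" for _ in range(n)),
        bead_types=spec.bead_types,
        residue_index=np.arange(n),
        residue_names=tuple("G" for _ in range(n)),
        chain_id=tuple("A" for _ in range(n)),
        aggregation_map=tuple(agg),
        bond_list=bond_list,
        angle_list=np.array(angles, int).reshape(-1, 3),
        dihedral_list=np.array(dihedrals, int).reshape(-1, 4),
    )
    return atop, ctop


def _baoab_sample(pot, R0, temperature, n_frames, stride, seed,
                  dt=0.002, friction=2.0, burn_in=4000, n_walkers=8):
    """Long-stride Langevin equilibrium sampling, parallel over walkers."""
    from .simulate import SimulationConfig, langevin_run
    rng = np.random.default_rng(seed)
    n_walkers = min(n_walkers, max(n_frames // 25, 1))
    per = -(-n_frames // n_walkers)        # ceil
    starts = R0[None] + rng.normal(0, 0.01, size=(n_walkers,) + R0.shape)
    cfg = SimulationConfig(temperature=temperature, friction=friction,
                           timestep=dt, n_steps=burn_in + per * stride,
                           save_interval=stride, seed=seed)
    traj = langevin_run(pot, starts, cfg)
    frames = traj.coords[-per:]            # (per, n_walkers, n, 3)
    return frames.reshape(per * n_walkers, *R0.shape)[:n_frames]


def generate_toy_frameset(spec: ToySystemSpec, n_frames: int,
                          stride: int = 20) -> AtomisticFrameSet:
    """Equilibrium "atomistic" frames with exact stored forces.

    Bead positions are sampled from the ground-truth potential by
    long-stride Langevin; satellites are drawn from their exact harmonic
    Boltzmann distribution around each bead.  Stored forces are the exact
    negative gradient of (ground truth + tether terms), so CG aggregation
    recovers ground-truth bead forces plus the fluctuating tether reaction.
    """
    pot = GroundTruthPotential(spec)
    R0 = _default_start(spec)
    beads = _baoab_sample(pot, R0, spec.temperature, n_frames, stride, spec.seed)
    if not np.all(np.isfinite(beads)):
        raise RuntimeError("non-finite sample during toy generation")
    _, f_beads = pot.energy_forces(beads)
    return _assemble_frameset(spec, beads, f_beads, spec.seed + 7)


def _default_start(spec: ToySystemSpec) -> np.ndarray:
    """Slightly zig-zagged chain start, bonds near their rest lengths."""
    n = spec.n_beads
    r0 = spec.bonds[0][2] if spec.bonds else 0.38
    R = np.zeros((n, 3))
    for i in range(1, n):
        R[i] = R[i - 1] + [r0 * np.cos(0.3 * (-1) ** i), r0 * np.sin(0.3 * (-1) ** i), 0.0]
    return R


def chain_spec(n_beads: int = 8, seed: int = 0, n_satellites: int = 1,
               temperature: float = 300.0) -> ToySystemSpec:
    """A flexible chain with one attractive non-bonded well: the standard
    toy training system for force-matching recovery tests."""
    # bonds stiff relative to the nonbonded terms (as in real proteins), so
    # thermal bond fluctuations stay well below the decoy noise scale
    bonds = [(i, i + 1, 0.38, 4000.0) for i in range(n_beads - 1)]
    angles = [(i, i + 1, i + 2, 2.2, 40.0) for i in range(n_beads - 2)]
    wells = [(0, n_beads - 1, 12.0, 0.5, 0.12)]
    reps = [(i, j, 0.35, 8.0, 6.0) for i in range(n_beads)
            for j in range(i + 2, n_beads)]
    # distinct bead types, as in proteins where CB types carry identity;
    # a type-blind pair feature could not represent an end-specific well
    return ToySystemSpec(n_beads=n_beads, bead_types=np.arange(n_beads),
                         bonds=bonds, angles=angles,
                         pair_wells=wells, repulsions=reps,
                         n_satellites=n_satellites, temperature=temperature,
                         seed=seed)


def double_well_pair_spec(seed: int = 0, temperature: float = 300.0,
                          a: float = 600.0, d0: float = 0.55,
                          c: float = 0.15) -> ToySystemSpec:
    """An isolated bead pair with a quartic double well on its distance.

    The radial free energy F(d) = U(d) - 2 k_B T ln d is exactly known, so
    basin populations follow from 1D quadrature — the reference for
    sampler and MBAR checks.
    """
    return ToySystemSpec(n_beads=2, bonds=[], n_satellites=0,
                         double_wells=[(0, 1, a, d0, c)],
                         temperature=temperature, seed=seed)


def double_well_quadrature(spec: ToySystemSpec, edges: np.ndarray,
                           temperature: float | None = None) -> np.ndarray:
    """Exact bin free energies (in k_B T, min 0) of the pair double well."""
    (i, j, a, d0, c) = spec.double_wells[0]
    T = temperature or spec.temperature
    beta = 1.0 / kbt(T)
    d = np.linspace(max(edges[0], 1e-4), edges[-1], 20001)
    dens = d ** 2 * np.exp(-beta * a * ((d - d0) ** 2 - c ** 2) ** 2)
    mass = np.array([np.trapezoid(dens[(d >= lo) & (d < hi)], d[(d >= lo) & (d < hi)])
                     for lo, hi in zip(edges[:-1], edges[1:])])
    with np.errstate(divide="ignore"):
        fe = -np.log(mass / mass.max())
    return fe


def generate_two_state_foldamer(seed: int = 0, n_beads: int = 12,
                                temperature: float = 300.0):
    """A 12-bead chain with a compact "folded" and extended "unfolded" basin.

    Gaussian wells between beads (i, i+3)/(i, i+4) at helix-like contact
    distances stabilize a compact native; the local angle terms prefer
    extended geometry, so the fold is carried entirely by the nonlocal
    wells (a prior fitted on local statistics cannot hold it), and chain
    entropy favours the extended basin.  Returns (native coordinates,
    ToySystemSpec).  The reference free-energy balance is obtained by
    direct long sampling of the ground-truth potential, against which
    PT + MBAR results are checked for consistency.
    """
    bonds = [(i, i + 1, 0.38, 1500.0) for i in range(n_beads - 1)]
    angles = [(i, i + 1, i + 2, 2.6, 5.0) for i in range(n_beads - 2)]
    # helix-like native: contacts between i and i+3
    native = _helix_native(n_beads)
    wells = []
    for i in range(n_beads):
        for j in range(i + 3, n_beads):
            r_nat = np.linalg.norm(native[i] - native[j])
            if r_nat < 0.75:
                wells.append((i, j, 3.0, float(r_nat), 0.08))
    reps = [(i, j, 0.33, 8.0, 6.0) for i in range(n_beads)
            for j in range(i + 2, n_beads)]
    spec = ToySystemSpec(n_beads=n_beads, bonds=bonds, angles=angles,
                         pair_wells=wells, repulsions=reps, n_satellites=1,
                         temperature=temperature, seed=seed)
    return native, spec


def _helix_native(n: int, radius: float = 0.23, rise: float = 0.15,
                  turn: float = 1.75) -> np.ndarray:
    t = np.arange(n) * turn
    return np.stack([radius * np.cos(t), radius * np.sin(t), rise * np.arange(n)],
                    axis=1)


def generate_dimer_umbrella_set(spec: ToySystemSpec, window_centers,
                                stiffness: float, n_frames: int = 2000,
                                seed: int = 0, stride: int = 10):
    """Umbrella-sampled dimer windows along the cluster COM distance.

    ``spec`` must describe two bonded clusters (beads split half/half).
    Each window adds a harmonic bias 0.5 k (d_com - c)^2 during sampling;
    stored forces are those of the *unbiased* ground-truth potential, and
    every returned frameset carries (center, stiffness) metadata for
    reweighting.  Returns a list of (AtomisticFrameSet, center, stiffness).
    """
    n = spec.n_beads
    half = n // 2
    ga, gb = np.arange(half), np.arange(half, n)
    base = GroundTruthPotential(spec)

    class Biased:
        def __init__(self, c):
            self.c = c

        def energy_forces(self, R):
            R = np.asarray(R, float)
            single = R.ndim == 2
            if single:
                R = R[None]
            U, F = base.energy_forces(R)
            ca = R[:, ga].mean(axis=1)
            cb = R[:, gb].mean(axis=1)
            dv = ca - cb
            d = np.maximum(np.linalg.norm(dv, axis=-1), 1e-10)
            U = U + 0.5 * stiffness * (d - self.c) ** 2
            g = (stiffness * (d - self.c) / d)[:, None] * dv
            F = F.copy()
            F[:, ga] -= g[:, None, :] / half
            F[:, gb] += g[:, None, :] / (n - half)
            return (U[0], F[0]) if single else (U, F)

    out = []
    for w, c in enumerate(window_centers):
        wspec = ToySystemSpec(**{**spec.__dict__, "seed": seed + 1000 * w})
        R0 = _default_start(spec)
        # separate the clusters along x with a lateral offset so no two
        # beads start on top of each other even at tight window centres
        target = np.array([max(c, 0.2), 0.12, 0.0])
        R0[gb] += target - (R0[gb].mean(0) - R0[ga].mean(0))
        beads = _baoab_sample(Biased(c) if stiffness > 0 else base, R0,
                              spec.temperature, n_frames, stride,
                              seed + 1000 * w, dt=0.001)
        _, f = base.energy_forces(beads)      # unbiased ground-truth forces
        fs = _assemble_frameset(wspec, beads, f, seed + 1000 * w)
        out.append((fs, float(c), float(stiffness)))
    return out


def _assemble_frameset(spec, beads, f_beads, seed) -> AtomisticFrameSet:
    rng = np.random.default_rng(seed)
    n, s = spec.n_beads, spec.n_satellites
    stride_a = 1 + s
    n_frames = beads.shape[0]
    coords = np.zeros((n_frames, n * stride_a, 3))
    forces = np.zeros((n_frames, n * stride_a, 3))
    heavy = np.arange(n) * stride_a
    coords[:, heavy] = beads
    forces[:, heavy] = f_beads
    if s:
        sd = np.sqrt(kbt(spec.temperature) / spec.satellite_k)
        disp = rng.normal(0.0, sd, size=(n_frames, n, s, 3))
        for hh in range(s):
            cols = heavy + 1 + hh
            coords[:, cols] = beads + disp[:, :, hh]
            forces[:, cols] = -spec.satellite_k * disp[:, :, hh]
            forces[:, heavy] += spec.satellite_k * disp[:, :, hh]
    atop, _ = toy_topologies(spec)
    return AtomisticFrameSet(coords, forces, atop, spec.temperature)
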