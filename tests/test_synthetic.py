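"""Synthetic generators: exact forces, Boltzmann marginals, foldamer, umbrella."""
import numpy as np
import pytest

from cgforge.analysis import fraction_native_contacts
from cgforge.framesets import map_frameset
from cgforge.synthetic import (GroundTruthPotential, ToySystemSpec,
                               chain_spec, double_well_pair_spec,
                               double_well_quadrature,
                               generate_dimer_umbrella_set,
                               generate_two_state_foldamer,
                               generate_toy_frameset, toy_topologies)
from cgforge.units import kbt


def test_timescale_separation_enforced():
    with pytest.raises(ValueError, match="stiffness"):
        ToySystemSpec(n_beads=3, bonds=[(0, 1, 0.38, 5000.0)],
                      n_satellites=1, satellite_k=6000.0)


def test_ground_truth_forces_match_finite_differences():
    spec = chain_spec(n_beads=5, seed=0)
    pot = GroundTruthPotential(spec)
    rng = np.random.default_rng(1)
    R = np.cumsum(rng.normal(0.3, 0.03, (5, 3)), axis=0)
    U, F = pot.energy_forces(R)
    eps = 1e-6
    num = np.zeros_like(R)
    for i in range(5):
        for d in range(3):
            Rp, Rm = R.copy(), R.copy()
            Rp[i, d] += eps
            Rm[i, d] -= eps
            num[i, d] = -(pot.energy_forces(Rp)[0]
                          - pot.energy_forces(Rm)[0]) / (2 * eps)
    assert np.abs(F - num).max() / np.abs(num).max() < 1e-6


def test_stored_frameset_forces_match_total_potential(toy_spec, toy_frameset,
                                                      toy_tops):
    """Frameset forces = -grad of (ground truth + satellite tethers)."""
    atop, ctop = toy_tops
    gt = GroundTruthPotential(toy_spec)
    k = toy_spec.satellite_k
    frame = toy_frameset.coords[0]
    stored = toy_frameset.forces[0]
    heavy = np.array([m[0] for m in ctop.aggregation_map])
    beads = frame[heavy]
    _, f_gt = gt.energy_forces(beads)
    recon = np.zeros_like(stored)
    recon[heavy] = f_gt
    for b, members in enumerate(ctop.aggregation_map):
        for a in members[1:]:
            disp = frame[a] - frame[members[0]]
            recon[a] = -k * disp
            recon[members[0]] += k * disp
    np.testing.assert_allclose(stored, recon, rtol=1e-10, atol=1e-10)


def test_aggregated_forces_equal_ground_truth_bead_forces(toy_spec, toy_cg,
                                                          toy_tops):
    """M_F cancels the satellite tether reactions exactly."""
    gt = GroundTruthPotential(toy_spec)
    _, f_beads = gt.energy_forces(toy_cg.coords)
    np.testing.assert_allclose(toy_cg.mapped_forces, f_beads,
                               rtol=1e-9, atol=1e-9)


def test_same_seed_bit_identical():
    spec = chain_spec(n_beads=4, seed=5)
    a = generate_toy_frameset(spec, 50)
    b = generate_toy_frameset(spec, 50)
    np.testing.assert_array_equal(a.coords, b.coords)
    np.testing.assert_array_equal(a.forces, b.forces)


def test_cg_bond_marginal_matches_boltzmann():
    """Sampled bond-length variance within 3% of the Boltzmann value.

    The exact reference is the radial marginal with its r^2 Jacobian,
    computed by quadrature; it sits ~3% below the naive k_B T / k.
    """
    from scipy.integrate import quad
    k, r0, T = 1000.0, 0.38, 300.0
    spec = ToySystemSpec(n_beads=2, bonds=[(0, 1, r0, k)],
                         n_satellites=1, temperature=T, seed=2)
    fs = generate_toy_frameset(spec, 48_000, stride=30)
    _, ctop = toy_topologies(spec)
    cg = map_frameset(fs, ctop)
    d = np.linalg.norm(cg.coords[:, 0] - cg.coords[:, 1], axis=1)
    s2 = kbt(T) / k
    dens = lambda r: r ** 2 * np.exp(-(r - r0) ** 2 / (2 * s2))
    Z = quad(dens, 0, 2.0)[0]
    mean = quad(lambda r: r * dens(r), 0, 2.0)[0] / Z
    expected = quad(lambda r: (r - mean) ** 2 * dens(r), 0, 2.0)[0] / Z
    assert abs(d.var() - expected) / expected < 0.03


def test_double_well_quadrature_vs_direct_sampling():
    """Basin free-energy balance by quadrature vs long Langevin, 0.2 kT."""
    from cgforge.simulate import SimulationConfig, langevin_run
    spec = double_well_pair_spec(seed=3)
    pot = GroundTruthPotential(spec)
    edges = np.linspace(0.25, 0.85, 13)
    fe_exact = double_well_quadrature(spec, edges)
    rng = np.random.default_rng(4)
    starts = np.zeros((32, 2, 3))
    starts[:, 1, 0] = rng.choice([0.4, 0.7], size=32)
    cfg = SimulationConfig(temperature=300.0, friction=10.0, timestep=0.002,
                           n_steps=60_000, save_interval=20, seed=5)
    traj = langevin_run(pot, starts, cfg)
    frames = traj.coords[150:].reshape(-1, 2, 3)
    d = np.linalg.norm(frames[:, 0] - frames[:, 1], axis=1)
    mass, _ = np.histogram(d, bins=edges)
    with np.errstate(divide="ignore"):
        fe_sim = -np.log(mass / mass.max())
    ok = (mass >= 200) & np.isfinite(fe_exact)
    dev = (fe_sim - fe_exact)[ok]
    assert np.abs(dev - dev.mean()).max() < 0.2


def test_foldamer_q_separates_native_and_extended():
    native, spec = generate_two_state_foldamer(seed=1)
    assert fraction_native_contacts(native, native) >= 0.9
    extended = np.zeros_like(native)
    extended[:, 0] = np.arange(len(native)) * 0.38
    assert fraction_native_contacts(extended, native) <= 0.15


def test_prior_only_simulation_never_stays_folded():
    """A generic prior alone cannot stabilize the foldamer's native state.

    The prior is fitted on local-statistics data without native wells (as a
    prior fitted across a diverse corpus would be); simulated from the
    native structure it must lose the fold and essentially never revisit it.
    """
    from dataclasses import replace as dc_replace
    from cgforge.priors import PriorPotential, fit_priors
    from cgforge.simulate import SimulationConfig, langevin_run
    native, spec = generate_two_state_foldamer(seed=2)
    generic = dc_replace(spec, pair_wells=[], seed=4)
    fs = generate_toy_frameset(generic, 1200)
    _, ctop = toy_topologies(spec)
    cg = map_frameset(fs, ctop)
    prior = fit_priors(cg, ctop)
    pot = PriorPotential(ctop, prior)
    cfg = SimulationConfig(temperature=300.0, friction=2.0, timestep=0.002,
                           n_steps=30_000, save_interval=50, seed=3)
    traj = langevin_run(pot, np.repeat(native[None], 6, axis=0), cfg)
    frames = traj.coords[20:].reshape(-1, *native.shape)
    q = fraction_native_contacts(frames, native)
    assert (q > 0.8).mean() < 0.01


def test_umbrella_windows_cover_close_approach():
    spec = ToySystemSpec(
        n_beads=4,
        bonds=[(0, 1, 0.3, 2000.0), (2, 3, 0.3, 2000.0)],
        repulsions=[(i, j, 0.35, 8.0, 6.0) for i in (0, 1) for j in (2, 3)],
        n_satellites=1, temperature=300.0, seed=6)
    centers = [0.3, 0.6, 1.0]
    windows = generate_dimer_umbrella_set(spec, centers, stiffness=800.0,
                                          n_frames=300, seed=7)
    assert len(windows) == 3
    mins, means = [], []
    for (fs, c, k), center in zip(windows, centers):
        assert c == center and k == 800.0
        _, ctop = toy_topologies(spec)
        cg = map_frameset(fs, ctop)
        ca = cg.coords[:, :2].mean(axis=1)
        cb = cg.coords[:, 2:].mean(axis=1)
        d = np.linalg.norm(ca - cb, axis=1)
        mins.append(d.min())
        means.append(d.mean())
    # windows at smaller centres reach smaller separations, and per-window
    # mean distances track their centres
    assert mins[0] < mins[1] < mins[2]
    assert means[0] < means[1] < means[2]
    assert mins[0] < 0.35          # close-approach (repulsive) data present


def test_zero_stiffness_window_is_unbiased():
    spec = ToySystemSpec(n_beads=4,
                         bonds=[(0, 1, 0.3, 2000.0), (2, 3, 0.3, 2000.0)],
                         n_satellites=0, temperature=300.0, seed=8)
    (fs, c, k), = generate_dimer_umbrella_set(spec, [0.0], stiffness=0.0,
                                              n_frames=200, seed=9)
    assert k == 0.0
    # unbiased sampling of two free clusters: stored forces must equal the
    # ground-truth forces (no bias force leaked into the labels)
    gt = GroundTruthPotential(spec)
    _, ctop = toy_topologies(spec)
    beads = fs.coords[:, [m[0] for m in ctop.aggregation_map]]
    _, f_gt = gt.energy_forces(beads)
    np.testing.assert_allclose(fs.forces, f_gt, atol=1e-9)


def test_pt_mbar_basin_ratio_matches_quadrature():
    """MBAR-reweighted PT populations of the double-well basins agree with
    the exact quadrature reference at the target temperature."""
    from cgforge.analysis import mbar_weights
    from cgforge.simulate import SimulationConfig, parallel_tempering
    from cgforge.units import kbt

    spec = double_well_pair_spec(seed=10)
    pot = GroundTruthPotential(spec)
    (i, j, a, d0, c) = spec.double_wells[0]
    ladder = np.array([300.0, 400.0, 550.0])
    R0 = np.array([[0.0, 0.0, 0.0], [0.42, 0.0, 0.0]])
    cfg = SimulationConfig(temperature=300.0, friction=10.0, timestep=0.002,
                           n_steps=60_000, save_interval=20, seed=11)
    ens = parallel_tempering(pot, R0, ladder, 200, cfg)
    assert ens.exchange_accepts.sum() > 0
    S, K = ens.potential_energies.shape
    d = np.linalg.norm(ens.trajectories[:, :, 0] - ens.trajectories[:, :, 1],
                       axis=2)                       # (S, K)
    burn = S // 5
    u = ens.reduced_energy_matrix.reshape(S, K, K)[burn:].reshape(-1, K)
    d = d[burn:].reshape(-1)
    w = mbar_weights(u, np.full(K, S - burn),
                     u[:, 0])                        # reweight to 300 K
    p_compact = w[d < d0].sum()

    # exact reference: radial Boltzmann quadrature at 300 K
    x = np.linspace(1e-4, 1.5, 40001)
    dens = x ** 2 * np.exp(-(a * ((x - d0) ** 2 - c ** 2) ** 2) / kbt(300.0))
    p_exact = np.trapezoid(dens[x < d0], x[x < d0]) / np.trapezoid(dens, x)
    assert abs(p_compact - p_exact) < 0.05
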