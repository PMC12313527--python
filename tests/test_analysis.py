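"""Observables: RMSD/RMSF/Rg/Q, TICA, MBAR and free-energy surfaces."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cgforge.analysis import (fraction_native_contacts, free_energy_profile,
                              free_energy_surface, mbar, mbar_weights,
                              radius_of_gyration, rmsd, rmsf, tica)
from cgforge.units import kbt


# -- rmsd -------------------------------------------------------------------

def test_rmsd_zero_on_identical_and_rigidly_moved(rng):
    ref = rng.normal(size=(12, 3))
    assert rmsd(ref, ref) == pytest.approx(0.0, abs=1e-12)
    moved = ref @ Rotation.random(random_state=1).as_matrix().T + [2.0, 0, -1]
    assert rmsd(moved, ref) == pytest.approx(0.0, abs=1e-8)


def test_rmsd_matches_rotation_grid_bruteforce(rng):
    """3-point toy: compare against exhaustive search over rotations."""
    ref = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1.0, 0]])
    frame = ref.copy()
    frame[2] += [0.3, -0.2, 0.4]
    best = np.inf
    refc = ref - ref.mean(0)
    framec = frame - frame.mean(0)
    rot = Rotation.random(20000, random_state=2)
    for M in rot.as_matrix():
        r = np.sqrt(np.mean(np.sum((framec @ M.T - refc) ** 2, axis=1)))
        best = min(best, r)
    value = rmsd(frame, ref)
    # closed-form optimum can only undercut the finite rotation grid
    assert value <= best + 1e-12
    assert value == pytest.approx(best, rel=0.05)


def test_rmsd_invariant_under_rigid_transform_fuzzing(rng):
    ref = rng.normal(size=(8, 3))
    traj = ref[None] + 0.1 * rng.normal(size=(5, 8, 3))
    base = rmsd(traj, ref)
    for rs in range(3):
        M = Rotation.random(random_state=rs).as_matrix()
        t = rng.normal(size=3)
        np.testing.assert_allclose(rmsd(traj @ M.T + t, ref), base, atol=1e-8)


def test_rmsd_shape_errors(rng):
    with pytest.raises(ValueError, match="mismatch"):
        rmsd(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))
    with pytest.raises(ValueError, match="empty"):
        rmsd(rng.normal(size=(4, 3)), rng.normal(size=(4, 3)), selection=[])


# -- rmsf -------------------------------------------------------------------

def test_rmsf_static_trajectory_is_zero(rng):
    frame = rng.normal(size=(6, 3))
    traj = np.repeat(frame[None], 10, axis=0)
    assert np.abs(rmsf(traj)).max() < 1e-12


def test_rmsf_iid_jitter_closed_form(rng):
    """i.i.d. jitter of sd sigma per coordinate gives RMSF sigma sqrt(3).

    Uses enough sites that the 6 rigid-body degrees of freedom absorbed by
    the superposition are negligible against 3n fluctuation dofs.
    """
    sigma = 0.03
    n = 100
    base = rng.normal(size=(n, 3)) * 2.0
    traj = base[None] + rng.normal(0, sigma, size=(10_000, n, 3))
    vals = rmsf(traj)
    np.testing.assert_allclose(vals, sigma * np.sqrt(3), rtol=0.03)


def test_rmsf_unchanged_by_appending_rotated_copy(rng):
    base = rng.normal(size=(8, 3))
    traj = base[None] + 0.05 * rng.normal(size=(500, 8, 3))
    M = Rotation.random(random_state=3).as_matrix()
    doubled = np.concatenate([traj, traj @ M.T + 1.0])
    np.testing.assert_allclose(rmsf(doubled), rmsf(traj), rtol=1e-6, atol=1e-9)


# -- radius of gyration -----------------------------------------------------

def test_radius_of_gyration_closed_forms():
    assert radius_of_gyration(np.zeros((1, 3))) == 0.0
    two = np.array([[0.0, 0, 0], [1.0, 0, 0]])
    assert radius_of_gyration(two) == pytest.approx(0.5)
    assert radius_of_gyration(two + [5.0, -2.0, 1.0]) == pytest.approx(0.5)


# -- fraction of native contacts -------------------------------------------

def _compact_native(n=10):
    """Beads on a tight helix so i,i+3+ contacts exist within 0.8 nm."""
    t = np.arange(n) * 1.7
    return np.stack([0.25 * np.cos(t), 0.25 * np.sin(t), 0.12 * np.arange(n)],
                    axis=1)


def test_q_native_vs_itself_near_one():
    native = _compact_native()
    assert 0.9 <= fraction_native_contacts(native, native) <= 1.0


def test_q_extended_vs_native_low():
    native = _compact_native()
    extended = np.zeros_like(native)
    extended[:, 0] = np.arange(len(native)) * 0.38
    q = fraction_native_contacts(extended, native)
    # brute-force check: no extended pair with sep >= 3 is near its native
    # distance, so the soft switch must read essentially zero
    assert q < 0.15


def test_q_no_native_pairs_errors():
    short = np.array([[0.0, 0, 0], [0.38, 0, 0]])
    with pytest.raises(ValueError, match="native contacts"):
        fraction_native_contacts(short, short)


# -- TICA -------------------------------------------------------------------

def test_tica_iid_noise_has_no_slow_mode(rng):
    X = rng.normal(size=(100_000, 3))
    model, _ = tica(X, lag=5)
    assert np.abs(model.eigenvalues[0]) < 0.05


def test_tica_two_state_markov_closed_form(rng):
    """lambda_1 = exp(-lag/tau) for a symmetric 2-state chain."""
    p = 0.02                       # switch probability per step
    tau = -1.0 / np.log(1 - 2 * p)
    n = 100_000
    s = np.empty(n, int)
    s[0] = 0
    flips = rng.uniform(size=n) < p
    for t in range(1, n):
        s[t] = s[t - 1] ^ int(flips[t])
    X = np.stack([s + 0.2 * rng.normal(size=n),
                  -s + 0.2 * rng.normal(size=n)], axis=1)
    lag = 10
    model, proj = tica(X, lag=lag)
    expected = np.exp(-lag / tau)
    assert abs(model.eigenvalues[0] - expected) / expected < 0.1


def test_tica_invariant_under_invertible_linear_map(rng):
    X = np.cumsum(rng.normal(size=(5000, 3)), axis=0) * 0.01 \
        + rng.normal(size=(5000, 3))
    A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
    m1, _ = tica(X, lag=3)
    m2, _ = tica(X @ A.T, lag=3)
    np.testing.assert_allclose(m1.eigenvalues, m2.eigenvalues, atol=1e-8)


# -- MBAR -------------------------------------------------------------------

def test_mbar_single_state_uniform_weights(rng):
    u = rng.normal(size=(50, 1))
    w = mbar_weights(u, np.array([50]), u[:, 0])
    np.testing.assert_allclose(w, np.full(50, 1 / 50), atol=1e-12)


def test_mbar_two_harmonic_states_closed_form(rng):
    """Free-energy difference of two 1D harmonic states: 1/2 ln(k2/k1)."""
    T = 300.0
    beta = 1.0 / kbt(T)
    k1, k2 = 100.0, 400.0
    n = 100_000
    x1 = rng.normal(0, np.sqrt(1 / (beta * k1)), n // 2)
    x2 = rng.normal(0, np.sqrt(1 / (beta * k2)), n // 2)
    x = np.concatenate([x1, x2])
    u = np.stack([0.5 * beta * k1 * x ** 2, 0.5 * beta * k2 * x ** 2], axis=1)
    f = mbar(u, np.array([n // 2, n // 2]))
    # Z_k ~ 1/sqrt(k): the stiffer state is higher in free energy
    expected = 0.5 * np.log(k2 / k1)    # per dof, in kT
    assert abs((f[1] - f[0]) - expected) / expected < 0.01


def test_mbar_equal_temperature_ladder_is_plain_averaging(rng):
    """Target state = sampled state everywhere -> exactly uniform weights."""
    U = rng.normal(10.0, 2.0, size=120)
    u = np.repeat(U[:, None], 3, axis=1)
    w = mbar_weights(u, np.array([40, 40, 40]), U)
    np.testing.assert_allclose(w, np.full(120, 1 / 120), rtol=1e-10)


def test_mbar_weights_permute_with_frames(rng):
    n = 60
    u = rng.normal(size=(n, 2))
    n_k = np.array([30, 30])
    w = mbar_weights(u, n_k, u[:, 0])
    perm = rng.permutation(n)
    w_p = mbar_weights(u[perm], n_k, u[perm, 0])
    np.testing.assert_allclose(w_p, w[perm], rtol=1e-10)


def test_mbar_input_validation(rng):
    with pytest.raises(ValueError, match="finite"):
        mbar(np.array([[np.inf]]), np.array([1]))
    with pytest.raises(ValueError, match="at least one frame"):
        mbar(np.zeros((2, 2)), np.array([2, 0]))


# -- free-energy surfaces ---------------------------------------------------

def test_fes_all_mass_one_bin():
    fes = free_energy_profile(np.zeros(100), bins=4, range=(-1, 1))
    populated = np.isfinite(fes.free_energy)
    assert populated.sum() == 1
    assert fes.free_energy[populated][0] == 0.0


def test_fes_mass_ratio_e_gives_one_kt(rng):
    x = np.concatenate([np.zeros(1000), np.ones(1000)])
    w = np.concatenate([np.full(1000, np.e), np.ones(1000)])
    fes = free_energy_profile(x, weights=w, bins=2, range=(-0.5, 1.5))
    assert fes.free_energy[0] == pytest.approx(0.0, abs=1e-12)
    assert fes.free_energy[1] == pytest.approx(1.0, rel=1e-12)


def test_fes_invariant_to_frame_duplication(rng):
    x = rng.normal(size=2000)
    y = rng.normal(size=2000)
    f1 = free_energy_surface(x, y, bins=8)
    f2 = free_energy_surface(np.tile(x, 2), np.tile(y, 2), bins=8)
    np.testing.assert_allclose(f1.free_energy, f2.free_energy, atol=1e-12)


def test_fes_csv_roundtrip_columns(tmp_path, rng):
    fes = free_energy_surface(rng.normal(size=500), rng.normal(size=500),
                              bins=4, x_name="q", y_name="rmsd")
    path = tmp_path / "fes.csv"
    fes.to_csv(path)
    header = path.read_text().splitlines()[0]
    assert header == "q,rmsd,free_energy_kT,mass"
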