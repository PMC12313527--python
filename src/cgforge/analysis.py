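"""Observables and landscape analysis for CG trajectories.

RMSD/RMSF use optimal rigid-body superposition (Kabsch); the fraction of
native contacts Q uses a soft switching function over native pairs; TICA
solves the symmetrized time-lagged generalized eigenproblem; MBAR combines
multi-temperature samples into consistent weights at a target temperature;
free-energy surfaces are weighted negative-log histograms in k_B T.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.special import logsumexp

from .units import kbt

__all__ = ["rmsd", "rmsf", "radius_of_gyration", "fraction_native_contacts",
           "native_contact_pairs", "tica", "TICAModel", "mbar",
           "mbar_weights", "free_energy_surface", "free_energy_profile",
           "FreeEnergySurface"]


# ---------------------------------------------------------------------------
# superposition-based observables
# ---------------------------------------------------------------------------

def _kabsch(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Rotation matrix aligning centred P onto centred Q (right-multiply)."""
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    return U @ D @ Vt


def rmsd(traj: np.ndarray, reference: np.ndarray, selection=None) -> np.ndarray:
    """Minimum RMSD (nm) to ``reference`` per frame, over rigid transforms.

    ``traj`` is (S, n, 3) or (n, 3); ``selection`` restricts both sides to
    the given site indices before superposition.
    """
    traj = np.asarray(traj, float)
    single = traj.ndim == 2
    if single:
        traj = traj[None]
    ref = np.asarray(reference, float)
    if selection is not None:
        selection = np.asarray(selection, int)
        if selection.size == 0:
            raise ValueError("selection is empty")
        traj = traj[:, selection]
        ref = ref[selection]
    if traj.shape[1] != ref.shape[0]:
        raise ValueError(
            f"atom-count mismatch: frames have {traj.shape[1]}, reference "
            f"has {ref.shape[0]}")
    ref0 = ref - ref.mean(axis=0)
    out = np.empty(traj.shape[0])
    for s in range(traj.shape[0]):
        P = traj[s] - traj[s].mean(axis=0)
        R = _kabsch(P, ref0)
        out[s] = np.sqrt(np.mean(np.sum((P @ R - ref0) ** 2, axis=1)))
    return out[0] if single else out


def rmsf(traj: np.ndarray, max_iter: int = 20, tol: float = 1e-8) -> np.ndarray:
    """Per-site RMSF (nm) about the mean structure, reference-free.

    Every frame is aligned to the running mean structure, iterated until
    the mean converges; RMSF is the root-mean-square displacement of each
    site from that converged mean.
    """
    traj = np.asarray(traj, float)
    aligned = traj - traj.mean(axis=1, keepdims=True)
    mean = aligned[0].copy()
    for _ in range(max_iter):
        mean0 = mean - mean.mean(axis=0)
        for s in range(aligned.shape[0]):
            R = _kabsch(aligned[s], mean0)
            aligned[s] = aligned[s] @ R
        new_mean = aligned.mean(axis=0)
        if np.max(np.abs(new_mean - mean)) < tol:
            mean = new_mean
            break
        mean = new_mean
    return np.sqrt(np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0))


def radius_of_gyration(traj: np.ndarray, masses=None) -> np.ndarray:
    """Mass-weighted radius of gyration (nm) per frame."""
    traj = np.asarray(traj, float)
    single = traj.ndim == 2
    if single:
        traj = traj[None]
    if masses is None:
        masses = np.ones(traj.shape[1])
    m = np.asarray(masses, float)
    w = m / m.sum()
    com = np.sum(w[None, :, None] * traj, axis=1, keepdims=True)
    rg = np.sqrt(np.sum(w[None, :] * np.sum((traj - com) ** 2, axis=2), axis=1))
    return rg[0] if single else rg


# ---------------------------------------------------------------------------
# fraction of native contacts
# ---------------------------------------------------------------------------

def _residue_representatives(top):
    """One bead per residue: CB where present, else CA."""
    reps: dict[int, int] = {}
    for i in range(top.n_beads):
        r = int(top.residue_index[i])
        name = top.bead_names[i]
        if name == "CB" or (name == "CA" and r not in reps):
            reps[r] = i
    return np.array([reps[r] for r in sorted(reps)], int)


def native_contact_pairs(native: np.ndarray, top=None, cutoff: float = 0.8,
                         min_seq_sep: int = 3):
    """Native pairs: representative beads within ``cutoff`` (nm) in the
    native structure, sequence separation >= ``min_seq_sep`` residues."""
    native = np.asarray(native, float)
    if top is not None:
        sel = _residue_representatives(top)
    else:
        sel = np.arange(native.shape[0])
    pairs = []
    for a in range(len(sel)):
        for b in range(a + min_seq_sep, len(sel)):
            r = np.linalg.norm(native[sel[a]] - native[sel[b]])
            if r < cutoff:
                pairs.append((sel[a], sel[b], r))
    if not pairs:
        raise ValueError("no native contacts: chain too short or no pairs "
                         f"within {cutoff} nm at separation >= {min_seq_sep}")
    idx = np.array([(a, b) for a, b, _ in pairs], int)
    r0 = np.array([r for _, _, r in pairs])
    return idx, r0


def fraction_native_contacts(traj: np.ndarray, native: np.ndarray, top=None,
                             beta: float = 50.0, lam: float = 1.5,
                             cutoff: float = 0.8,
                             min_seq_sep: int = 3) -> np.ndarray:
    """Soft fraction of native contacts Q in [0, 1] per frame.

    Q = mean over native pairs of 1 / (1 + exp[beta (r - lam r0)]), the
    community-standard soft switch (beta in 1/nm, default 50/nm = 5/A).
    The tolerance factor defaults to lam = 1.5: native CG bead contacts sit
    at 0.5-0.8 nm, so the atomistic convention of 1.8 would count most coil
    configurations as contacts and stop Q from discriminating folds.
    Native pairs come from :func:`native_contact_pairs`.
    """
    traj = np.asarray(traj, float)
    single = traj.ndim == 2
    if single:
        traj = traj[None]
    idx, r0 = native_contact_pairs(native, top, cutoff, min_seq_sep)
    d = np.linalg.norm(traj[:, idx[:, 0]] - traj[:, idx[:, 1]], axis=2)
    q = 1.0 / (1.0 + np.exp(beta * (d - lam * r0[None, :])))
    q = q.mean(axis=1)
    return q[0] if single else q


# ---------------------------------------------------------------------------
# TICA
# ---------------------------------------------------------------------------

@dataclass
class TICAModel:
    components: np.ndarray    # (n_features, n_components), columns
    eigenvalues: np.ndarray
    mean: np.ndarray
    lag: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.mean) @ self.components


def tica(X: np.ndarray, lag: int, n_components: int | None = None,
         ridge: float = 1e-10):
    """Symmetrized TICA on a feature time series (T, n_features).

    Solves C_tau v = lambda C_0 v with symmetrized covariance estimators,
    which keeps |lambda| <= 1.  A singular instantaneous covariance is
    regularized with a small ridge (with a warning).  Returns
    (TICAModel, projected series), eigenvalues sorted descending.
    """
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[:, None]
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if X.shape[0] <= lag:
        raise ValueError("series must be longer than the lag")
    mean = X.mean(axis=0)
    X0 = X[:-lag] - mean
    Xt = X[lag:] - mean
    T = X0.shape[0]
    C0 = 0.5 * (X0.T @ X0 + Xt.T @ Xt) / T
    Ct = 0.5 * (X0.T @ Xt + Xt.T @ X0) / T
    cond = np.linalg.cond(C0)
    if not np.isfinite(cond) or cond > 1e12:
        import warnings
        warnings.warn(f"singular instantaneous covariance (cond={cond:.2e}); "
                      f"applying ridge {ridge:g}")
    C0r = C0 + ridge * np.trace(C0) / C0.shape[0] * np.eye(C0.shape[0])
    evals, evecs = scipy.linalg.eigh(Ct, C0r)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if n_components is not None:
        evals = evals[:n_components]
        evecs = evecs[:, :n_components]
    model = TICAModel(evecs, evals, mean, lag)
    return model, model.transform(X)


# ---------------------------------------------------------------------------
# MBAR
# ---------------------------------------------------------------------------

def mbar(u_nk: np.ndarray, n_k: np.ndarray, tol: float = 1e-8,
         max_iter: int = 10000):
    """Self-consistent MBAR state free energies.

    ``u_nk[n, k]`` is the reduced energy of frame n evaluated in state k;
    ``n_k`` the frames sampled from each state.  Returns f_k (f_0 = 0),
    solved to ``tol`` in the free energies.
    """
    u_nk = np.asarray(u_nk, float)
    n_k = np.asarray(n_k, float)
    if not np.all(np.isfinite(u_nk)):
        raise ValueError("non-finite reduced energies")
    if np.any(n_k < 1):
        raise ValueError("every state needs at least one frame")
    N, K = u_nk.shape
    if int(n_k.sum()) != N:
        raise ValueError(f"frame counts sum to {int(n_k.sum())}, matrix has {N}")
    f = np.zeros(K)
    log_nk = np.log(n_k)
    for it in range(max_iter):
        # log denominator per frame: logsumexp_k [log N_k + f_k - u_nk]
        log_den = logsumexp(log_nk[None, :] + f[None, :] - u_nk, axis=1)
        new_f = -logsumexp(-u_nk - log_den[:, None], axis=0)
        new_f -= new_f[0]
        delta = np.max(np.abs(new_f - f))
        f = new_f
        if delta < tol:
            return f
    raise RuntimeError(f"MBAR did not converge in {max_iter} iterations "
                       f"(residual {delta:.3e})")


def mbar_weights(u_nk: np.ndarray, n_k: np.ndarray, u_target: np.ndarray,
                 tol: float = 1e-8) -> np.ndarray:
    """Normalized per-frame weights at a target state.

    ``u_target[n]`` is the reduced energy of frame n in the target state
    (for temperature reweighting: beta_target * U_n).  With a single
    source state the weights degenerate to uniform 1/N.
    """
    u_nk = np.asarray(u_nk, float)
    u_target = np.asarray(u_target, float)
    n_k = np.asarray(n_k, float)
    f = mbar(u_nk, n_k, tol=tol)
    log_den = logsumexp(np.log(n_k)[None, :] + f[None, :] - u_nk, axis=1)
    log_w = -u_target - log_den
    log_w -= logsumexp(log_w)
    return np.exp(log_w)


# ---------------------------------------------------------------------------
# free-energy surfaces
# ---------------------------------------------------------------------------

@dataclass
class FreeEnergySurface:
    """Binned free energies in k_B T, minimum shifted to zero.

    Empty bins carry +inf (unbounded, never zero); ``masses`` holds the
    weighted sample mass per bin.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray | None
    free_energy: np.ndarray
    masses: np.ndarray
    x_name: str = "x"
    y_name: str | None = None

    def __post_init__(self):
        pop = self.free_energy[np.isfinite(self.free_energy)]
        if pop.size and (pop.min() < -1e-9 or pop.min() > 1e-9):
            raise ValueError("populated free energies must have minimum 0")

    def to_csv(self, path):
        with open(path, "w") as fh:
            if self.y_edges is None:
                fh.write(f"{self.x_name},free_energy_kT,mass\n")
                centers = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
                for c, fe, m in zip(centers, self.free_energy, self.masses):
                    fh.write(f"{c:.6g},{fe:.6g},{m:.6g}\n")
            else:
                fh.write(f"{self.x_name},{self.y_name},free_energy_kT,mass\n")
                xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
                yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
                for i, cx in enumerate(xc):
                    for j, cy in enumerate(yc):
                        fh.write(f"{cx:.6g},{cy:.6g},"
                                 f"{self.free_energy[i, j]:.6g},"
                                 f"{self.masses[i, j]:.6g}\n")


def free_energy_surface(x, y, weights=None, bins=32, x_name="x",
                        y_name="y") -> FreeEnergySurface:
    """2D weighted free-energy surface F = -log(mass/max mass) in k_B T."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if weights is None:
        weights = np.ones_like(x)
    mass, xe, ye = np.histogram2d(x, y, bins=bins, weights=weights)
    with np.errstate(divide="ignore"):
        fe = -np.log(mass / mass.max())
    return FreeEnergySurface(xe, ye, fe, mass, x_name, y_name)


def free_energy_profile(x, weights=None, bins=32, range=None,
                        x_name="x") -> FreeEnergySurface:
    """1D weighted free-energy profile in k_B T."""
    x = np.asarray(x, float)
    if weights is None:
        weights = np.ones_like(x)
    mass, xe = np.histogram(x, bins=bins, range=range, weights=weights)
    with np.errstate(divide="ignore"):
        fe = -np.log(mass / mass.max())
    return FreeEnergySurface(xe, None, fe, mass, x_name)
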