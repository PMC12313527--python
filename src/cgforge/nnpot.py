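"""Trainable many-body CG energy: a continuous-filter graph network.

The model follows the SchNet/CGSchNet family: typed beads carry learned
embeddings; pairwise distances are expanded in Gaussian radial basis
functions and fed through a filter-generating network; continuous-filter
convolutions update bead features over a fixed number of interaction
blocks; per-bead energy heads are summed into a scalar energy.  A cosine
switching envelope makes the energy smooth as pairs cross the distance
cutoff, so conservative forces exist everywhere: F = -grad_R U, obtained
by reverse-mode differentiation of the same graph that computes U.

No attention and no explicit long-range terms — interactions are strictly
local within the cutoff.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .topology import N_BEAD_TYPES

__all__ = ["EnergyModel", "init_model", "energy", "forces", "energy_batch",
           "forces_batch", "save_model", "load_model",
           "neighbor_pairs_brute", "neighbor_pairs_cell"]

BRUTE_FORCE_LIMIT = 200   # beads; above this the cell list takes over


@dataclass
class EnergyModel:
    """Trainable parameters plus featurization hyperparameters."""

    params: dict                    # name -> ndarray
    embedding_dim: int = 64
    n_interactions: int = 2
    cutoff: float = 1.2             # nm
    n_rbf: int = 32
    n_types: int = N_BEAD_TYPES

    def copy(self) -> "EnergyModel":
        return EnergyModel({k: v.copy() for k, v in self.params.items()},
                           self.embedding_dim, self.n_interactions,
                           self.cutoff, self.n_rbf, self.n_types)


def init_model(seed: int = 0, embedding_dim: int = 64, n_interactions: int = 2,
               cutoff: float = 1.2, n_rbf: int = 32,
               n_types: int = N_BEAD_TYPES) -> EnergyModel:
    """Initialize with unit-variance-scaled weights and a near-zero head.

    The output head starts small so the untrained model is a gentle
    perturbation on top of the prior.
    """
    rng = np.random.default_rng(seed)
    F, K = embedding_dim, n_rbf
    p = {}
    p["embedding"] = 0.1 * rng.standard_normal((n_types, F))

    def dense(name, nin, nout, scale=None):
        s = scale if scale is not None else 1.0 / np.sqrt(nin)
        p[f"{name}_W"] = s * rng.standard_normal((nin, nout))
        p[f"{name}_b"] = np.zeros(nout)

    for k in range(n_interactions):
        dense(f"int{k}_filt1", K, F)
        dense(f"int{k}_filt2", F, F)
        dense(f"int{k}_in", F, F)
        dense(f"int{k}_out1", F, F)
        dense(f"int{k}_out2", F, F)
    half = max(F // 2, 1)
    dense("head1", F, half)
    dense("head2", half, 1, scale=0.01 / np.sqrt(half))
    return EnergyModel(p, embedding_dim, n_interactions, cutoff, n_rbf, n_types)


# ---------------------------------------------------------------------------
# neighbour lists (ordered pairs i != j within cutoff)
# ---------------------------------------------------------------------------

def neighbor_pairs_brute(R: np.ndarray, cutoff: float):
    n = R.shape[0]
    d = np.linalg.norm(R[:, None] - R[None], axis=-1)
    src, dst = np.where((d < cutoff) & ~np.eye(n, dtype=bool))
    return src, dst


def neighbor_pairs_cell(R: np.ndarray, cutoff: float):
    """Cell-list pair search; same contract as the brute-force variant."""
    n = R.shape[0]
    lo = R.min(axis=0)
    cell = np.floor((R - lo) / cutoff).astype(int)
    buckets: dict[tuple, list[int]] = {}
    for i, c in enumerate(map(tuple, cell)):
        buckets.setdefault(c, []).append(i)
    src, dst = [], []
    offsets = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
               for dz in (-1, 0, 1)]
    for c, members in buckets.items():
        neigh = []
        for off in offsets:
            neigh.extend(buckets.get((c[0] + off[0], c[1] + off[1], c[2] + off[2]), ()))
        m = np.array(members)
        nb = np.array(neigh)
        d = np.linalg.norm(R[m][:, None] - R[nb][None], axis=-1)
        ii, jj = np.where(d < cutoff)
        keep = m[ii] != nb[jj]
        src.extend(m[ii][keep])
        dst.extend(nb[jj][keep])
    src = np.array(src, int)
    dst = np.array(dst, int)
    order = np.lexsort((dst, src))
    return src[order], dst[order]


def neighbor_pairs(R: np.ndarray, cutoff: float):
    if R.shape[0] <= BRUTE_FORCE_LIMIT:
        s, d = neighbor_pairs_brute(R, cutoff)
        order = np.lexsort((d, s))
        return s[order], d[order]
    return neighbor_pairs_cell(R, cutoff)


# ---------------------------------------------------------------------------
# forward graph
# ---------------------------------------------------------------------------

def _forward(pv: dict, R: ad.Var, z: np.ndarray, src, dst, n_total: int,
             n_frames: int, model: EnergyModel) -> ad.Var:
    """Per-frame energies (n_frames,) from flattened coordinates (n_total, 3).

    ``src``/``dst`` index into the flattened bead axis; ``z`` is the
    flattened type vector.
    """
    rc = model.cutoff
    diff = ad.take(R, dst) - ad.take(R, src)
    d = ad.sqrt(ad.vsum(diff * diff, axis=1))                 # (P,)

    # Gaussian radial basis on [0, rc]
    mu = np.linspace(0.0, rc, model.n_rbf)
    gamma = 0.5 / (rc / (model.n_rbf - 1)) ** 2
    dk = ad.reshape(d, (-1, 1)) - ad.Var(mu[None, :])
    rbf = ad.exp(ad.Var(-gamma) * dk * dk)                    # (P, K)

    # cosine switching envelope, exactly zero beyond the cutoff
    mask = (d.data < rc).astype(float)
    env = ad.Var(0.5) * (ad.cos(d * (np.pi / rc)) + 1.0) * ad.Var(mask)

    x = ad.take(pv["embedding"], z)                           # (n_total, F)
    for k in range(model.n_interactions):
        w = ad.softplus(rbf @ pv[f"int{k}_filt1_W"] + pv[f"int{k}_filt1_b"])
        w = w @ pv[f"int{k}_filt2_W"] + pv[f"int{k}_filt2_b"]
        w = w * ad.reshape(env, (-1, 1))                      # (P, F)
        xin = x @ pv[f"int{k}_in_W"] + pv[f"int{k}_in_b"]
        msg = ad.take(xin, dst) * w
        agg = ad.scatter_add(msg, src, n_total)
        v = ad.softplus(agg @ pv[f"int{k}_out1_W"] + pv[f"int{k}_out1_b"])
        v = v @ pv[f"int{k}_out2_W"] + pv[f"int{k}_out2_b"]
        x = x + v

    h = ad.softplus(x @ pv["head1_W"] + pv["head1_b"])
    e_bead = h @ pv["head2_W"] + pv["head2_b"]                # (n_total, 1)
    e = ad.reshape(e_bead, (n_frames, n_total // n_frames))
    return ad.vsum(e, axis=1)                                 # (n_frames,)


def _flatten_batch(R: np.ndarray, z: np.ndarray, cutoff: float):
    """Union neighbour list across frames on the flattened bead axis."""
    B, n, _ = R.shape
    if n <= BRUTE_FORCE_LIMIT:
        d2 = np.sum((R[:, :, None, :] - R[:, None, :, :]) ** 2, axis=-1)
        mask = (d2 < cutoff * cutoff)
        mask &= ~np.eye(n, dtype=bool)[None]
        b, i, j = np.nonzero(mask)          # already sorted by (b, i, j)
        src = b * n + i
        dst = b * n + j
    else:
        src_all, dst_all = [], []
        for b in range(B):
            s, d = neighbor_pairs(R[b], cutoff)
            src_all.append(s + b * n)
            dst_all.append(d + b * n)
        src = np.concatenate(src_all) if src_all else np.empty(0, int)
        dst = np.concatenate(dst_all) if dst_all else np.empty(0, int)
    z_flat = np.tile(np.asarray(z, int), B)
    return R.reshape(B * n, 3), z_flat, src, dst


def _check_inputs(R, z):
    R = np.asarray(R, float)
    z = np.asarray(z, int)
    if R.shape[-2] != z.shape[0]:
        raise ValueError(f"{R.shape[-2]} coordinates but {z.shape[0]} types")
    if z.shape[0] < 2:
        raise ValueError("need at least 2 beads")
    return R, z


def energy_batch(R: np.ndarray, z: np.ndarray, model: EnergyModel) -> np.ndarray:
    """Energies (kJ/mol) for a batch of frames (B, n, 3)."""
    R, z = _check_inputs(R, z)
    B, n, _ = R.shape
    flat, z_flat, src, dst = _flatten_batch(R, z, model.cutoff)
    pv = {k: ad.var(v) for k, v in model.params.items()}
    e = _forward(pv, ad.var(flat), z_flat, src, dst, B * n, B, model)
    return e.data


def forces_batch(R: np.ndarray, z: np.ndarray, model: EnergyModel):
    """(energies, forces) for a batch of frames; forces are -grad U."""
    R, z = _check_inputs(R, z)
    B, n, _ = R.shape
    flat, z_flat, src, dst = _flatten_batch(R, z, model.cutoff)
    pv = {k: ad.var(v) for k, v in model.params.items()}
    Rv = ad.var(flat)
    e = _forward(pv, Rv, z_flat, src, dst, B * n, B, model)
    (g,) = ad.grad(ad.vsum(e), [Rv])
    return e.data, -g.data.reshape(B, n, 3)


def energy(R: np.ndarray, z: np.ndarray, model: EnergyModel) -> float:
    """Scalar energy of a single configuration (n, 3)."""
    return float(energy_batch(np.asarray(R, float)[None], z, model)[0])


def forces(R: np.ndarray, z: np.ndarray, model: EnergyModel) -> np.ndarray:
    """Forces (n, 3) of a single configuration; exact -grad of energy()."""
    _, f = forces_batch(np.asarray(R, float)[None], z, model)
    return f[0]


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def energy_forces_fast(R: np.ndarray, z: np.ndarray, model: EnergyModel):
    """Energies and forces by a hand-written forward/backward pass.

    Mathematically identical to the autodiff route (tested for agreement);
    used in the simulation hot loop where only dE/dR is needed and graph
    construction overhead would dominate.
    """
    R, z = _check_inputs(R, z)
    single = R.ndim == 2
    if single:
        R = R[None]
    B, n, _ = R.shape
    p = model.params
    rc = model.cutoff
    flat, z_flat, src, dst = _flatten_batch(R, z, rc)
    P = src.shape[0]
    F_dim = model.embedding_dim

    # ---- forward -----------------------------------------------------
    diff = flat[dst] - flat[src]                       # (P, 3)
    d = np.sqrt(np.sum(diff * diff, axis=1))           # (P,)
    mu = np.linspace(0.0, rc, model.n_rbf)
    gamma = 0.5 / (rc / (model.n_rbf - 1)) ** 2
    dk = d[:, None] - mu[None, :]
    rbf = np.exp(-gamma * dk * dk)                     # (P, K)
    mask = (d < rc).astype(float)
    env = 0.5 * (np.cos(d * (np.pi / rc)) + 1.0) * mask

    x = p["embedding"][z_flat]                         # (N, F)
    cache = []
    for k in range(model.n_interactions):
        a1 = rbf @ p[f"int{k}_filt1_W"] + p[f"int{k}_filt1_b"]
        s1 = _sigmoid(a1)
        h1 = np.logaddexp(0.0, a1)
        w0 = h1 @ p[f"int{k}_filt2_W"] + p[f"int{k}_filt2_b"]
        w = w0 * env[:, None]                          # (P, F)
        xin = x @ p[f"int{k}_in_W"] + p[f"int{k}_in_b"]
        msg = xin[dst] * w
        agg = ad.segment_sum(msg, src, B * n)
        a2 = agg @ p[f"int{k}_out1_W"] + p[f"int{k}_out1_b"]
        s2 = _sigmoid(a2)
        h2 = np.logaddexp(0.0, a2)
        v = h2 @ p[f"int{k}_out2_W"] + p[f"int{k}_out2_b"]
        cache.append((x, s1, h1, w0, w, xin, s2, h2))
        x = x + v

    a3 = x @ p["head1_W"] + p["head1_b"]
    s3 = _sigmoid(a3)
    h3 = np.logaddexp(0.0, a3)
    e_bead = h3 @ p["head2_W"] + p["head2_b"]          # (N, 1)
    energies = e_bead.reshape(B, n).sum(axis=1)

    # ---- backward: dE/d(flat) ----------------------------------------
    gx = (np.ones((B * n, 1)) @ p["head2_W"].T) * s3   # dE/da3
    gx = gx @ p["head1_W"].T                           # dE/dx (final)
    g_d = np.zeros(P)                                  # dE/dd accumulated
    for k in reversed(range(model.n_interactions)):
        x_in, s1, h1, w0, w, xin, s2, h2 = cache[k]
        gv = gx                                        # dE/dv (+ passthrough)
        ga2 = (gv @ p[f"int{k}_out2_W"].T) * s2
        gagg = ga2 @ p[f"int{k}_out1_W"].T             # (N, F)
        gmsg = gagg[src]                               # (P, F)
        # msg = xin[dst] * w0 * env
        gw0 = gmsg * xin[dst] * env[:, None]
        genv_k = np.sum(gmsg * xin[dst] * w0, axis=1)  # (P,)
        gxin = ad.segment_sum(gmsg * w, dst, B * n)
        gx_from_xin = gxin @ p[f"int{k}_in_W"].T
        gh1 = gw0 @ p[f"int{k}_filt2_W"].T
        ga1 = gh1 * s1
        grbf_k = ga1 @ p[f"int{k}_filt1_W"].T          # (P, K)
        g_d += genv_k * (-0.5 * np.pi / rc) * np.sin(d * (np.pi / rc)) * mask
        g_d += np.sum(grbf_k * rbf * (-2.0 * gamma * dk), axis=1)
        gx = gx + gx_from_xin                          # residual connection

    gdiff = (g_d / np.maximum(d, 1e-12))[:, None] * diff
    gflat = ad.segment_sum(gdiff, dst, B * n) - ad.segment_sum(gdiff, src, B * n)
    forces = -gflat.reshape(B, n, 3)
    return (energies[0], forces[0]) if single else (energies, forces)


class NetworkPotential:
    """Adapter giving the network the same batched interface as the prior."""

    def __init__(self, model: EnergyModel, z: np.ndarray):
        self.model = model
        self.z = np.asarray(z, int)

    def energy_forces(self, R: np.ndarray):
        return energy_forces_fast(R, self.z, self.model)


class CompositePotential:
    """Sum of potentials (e.g. prior + network) as one sampler target."""

    def __init__(self, *parts):
        self.parts = parts

    def energy_forces(self, R: np.ndarray):
        U, F = None, None
        for p in self.parts:
            u, f = p.energy_forces(R)
            U = u if U is None else U + u
            F = f if F is None else F + f
        return U, F


# ---------------------------------------------------------------------------
# checkpoints (text JSON; Python float repr round-trips exactly)
# ---------------------------------------------------------------------------

def save_model(model: EnergyModel, path) -> None:
    doc = {
        "format": "cgforge-energy-model-1",
        "units": {"length": "nm", "energy": "kJ/mol"},
        "hyper": {
            "embedding_dim": model.embedding_dim,
            "n_interactions": model.n_interactions,
            "cutoff": model.cutoff,
            "n_rbf": model.n_rbf,
            "n_types": model.n_types,
        },
        "params": {k: v.tolist() for k, v in model.params.items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> EnergyModel:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("format") != "cgforge-energy-model-1":
        raise ValueError("not a cgforge energy-model checkpoint")
    h = doc["hyper"]
    params = {k: np.array(v, float) for k, v in doc["params"].items()}
    return EnergyModel(params, h["embedding_dim"], h["n_interactions"],
                       h["cutoff"], h["n_rbf"], h["n_types"])
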