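"""Prior energy: bonds, angles, dihedrals and purely repulsive pairs.

The prior is a fixed, pre-fit term added to the trainable network energy.
Its job is only to keep simulations out of unphysical configurations
(stretched bonds, overlapping beads); it is deliberately incapable of
stabilizing secondary or tertiary structure on its own, having no
attractive nonbonded interactions.

Functional forms
----------------
bonds/angles   harmonic, ``U = k/2 (x - x0)^2``
dihedrals      cosine series, ``U = sum_n c_n cos(n*phi - delta_n)``, n = 1..3
repulsion      ``U = eps[(sigma/r)^p - 1 + p(r/sigma - 1)]`` for r < sigma,
               0 beyond — strictly decreasing on (0, sigma) and C^1 at the
               cutoff, so forces are continuous everywhere.

Fitting is moment matching against CG marginals sampled at temperature T:
harmonic stiffness = k_B T / variance, equilibrium = mean; dihedral
coefficients from a least-squares fit of -k_B T log(histogram) on the
periodic basis; the repulsion radius from the low-distance edge of the
nonbonded pair-distance marginal.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .topology import CGTopology
from .units import kbt

__all__ = ["PriorModel", "PriorPotential", "fit_priors", "prior_energy_forces",
           "save_prior", "load_prior", "nonbonded_pairs"]

log = logging.getLogger(__name__)

DIST_FLOOR = 1e-3        # nm; repulsion distances clamped here on pathological input
N_DIHEDRAL_HARMONICS = 3
HIST_BINS = 64
HIST_PSEUDOCOUNT = 1.0
MIN_SAMPLES = 20         # below this a term key falls back to the pooled fit


def _pair_key(t1, t2):
    return tuple(sorted((int(t1), int(t2))))


def _triple_key(t1, t2, t3):
    a, b, c = int(t1), int(t2), int(t3)
    return (a, b, c) if (a, c) <= (c, a) and a <= c else (c, b, a)


def _quad_key(ts):
    ts = tuple(int(t) for t in ts)
    return min(ts, ts[::-1])


@dataclass
class PriorModel:
    """Parameters of the prior energy, keyed by bead-type tuples.

    ``bond_terms[(t1,t2)] = (r0 nm, k kJ/mol/nm^2)``;
    ``angle_terms[(t1,t2,t3)] = (theta0 rad, k kJ/mol/rad^2)``;
    ``dihedral_terms[quad] = [(c_n kJ/mol, n, delta_n rad), ...]``;
    ``repulsion_terms[(t1,t2)] = (sigma nm, eps kJ/mol, p)``.
    A ``None`` key in each class is the pooled type-generic fallback.
    """

    bond_terms: dict = field(default_factory=dict)
    angle_terms: dict = field(default_factory=dict)
    dihedral_terms: dict = field(default_factory=dict)
    repulsion_terms: dict = field(default_factory=dict)
    exclusion_policy: int = 2       # bonded separation <= this is excluded
    clamp_count: int = 0            # repulsion distance-floor warnings

    def __post_init__(self):
        for (r0, k) in self.bond_terms.values():
            if k < 0:
                raise ValueError("bond stiffness must be >= 0")
        for (t0, k) in self.angle_terms.values():
            if k < 0:
                raise ValueError("angle stiffness must be >= 0")
        for terms in self.dihedral_terms.values():
            for (c, n, d) in terms:
                if c < 0:
                    raise ValueError("dihedral amplitudes must be >= 0")
        for (s, e, p) in self.repulsion_terms.values():
            if e < 0 or s < 0:
                raise ValueError("repulsion parameters must be >= 0")

    def _lookup(self, table, key):
        v = table.get(key)
        if v is None:
            v = table.get(None)
        if v is None:
            raise KeyError(f"no prior parameters for key {key} and no fallback")
        return v


# ---------------------------------------------------------------------------
# geometry kernels (batched over frames; R is (B, n, 3))
# ---------------------------------------------------------------------------

def _acc(G, col, vals):
    """Accumulate per-term gradient rows into G (B, n, 3) at bead indices."""
    np.add.at(G.transpose(1, 0, 2), col, vals.transpose(1, 0, 2))


def _bond_terms_ef(R, idx, params, U, G):
    if idx.shape[0] == 0:
        return
    i, j = idx[:, 0], idx[:, 1]
    d = R[:, i] - R[:, j]                       # (B, nb, 3)
    r = np.linalg.norm(d, axis=-1)
    r0 = params[:, 0]
    k = params[:, 1]
    dr = r - r0
    U += 0.5 * np.sum(k * dr ** 2, axis=-1)
    # dU/dr_i = k (r - r0) * d/r ; opposite sign on j
    g = (k * dr / np.maximum(r, 1e-12))[..., None] * d
    _acc(G, i, g)
    _acc(G, j, -g)


def _angle_geometry(R, idx):
    i, j, k = idx[:, 0], idx[:, 1], idx[:, 2]
    u = R[:, i] - R[:, j]
    v = R[:, k] - R[:, j]
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    cost = np.sum(u * v, axis=-1) / np.maximum(nu * nv, 1e-12)
    cost = np.clip(cost, -1.0, 1.0)
    theta = np.arccos(cost)
    sint = np.maximum(np.sqrt(1.0 - cost ** 2), 1e-8)
    uh = u / np.maximum(nu, 1e-12)[..., None]
    vh = v / np.maximum(nv, 1e-12)[..., None]
    # d theta / d r_i and d r_k; central bead balances both
    dti = (cost[..., None] * uh - vh) / (nu * sint)[..., None]
    dtk = (cost[..., None] * vh - uh) / (nv * sint)[..., None]
    return theta, dti, dtk


def _angle_terms_ef(R, idx, params, U, G):
    if idx.shape[0] == 0:
        return
    theta, dti, dtk = _angle_geometry(R, idx)
    t0 = params[:, 0]
    k = params[:, 1]
    dt = theta - t0
    U += 0.5 * np.sum(k * dt ** 2, axis=-1)
    g = (k * dt)[..., None]
    _acc(G, idx[:, 0], g * dti)
    _acc(G, idx[:, 2], g * dtk)
    _acc(G, idx[:, 1], -g * (dti + dtk))


def _dihedral_geometry(R, idx):
    """Dihedral angle and its gradient w.r.t. the four bead positions."""
    i, j, k, l = idx[:, 0], idx[:, 1], idx[:, 2], idx[:, 3]
    b1 = R[:, j] - R[:, i]
    b2 = R[:, k] - R[:, j]
    b3 = R[:, l] - R[:, k]
    m = np.cross(b1, b2)
    n = np.cross(b2, b3)
    b2n = np.maximum(np.linalg.norm(b2, axis=-1), 1e-12)
    x = np.sum(m * n, axis=-1)
    y = np.sum(np.cross(m, n) * b2, axis=-1) / b2n
    phi = np.arctan2(y, x)
    m2 = np.maximum(np.sum(m * m, axis=-1), 1e-12)
    n2 = np.maximum(np.sum(n * n, axis=-1), 1e-12)
    dpi = -(b2n / m2)[..., None] * m
    dpl = (b2n / n2)[..., None] * n
    s12 = (np.sum(b1 * b2, axis=-1) / b2n ** 2)[..., None]
    s32 = (np.sum(b3 * b2, axis=-1) / b2n ** 2)[..., None]
    dpj = -dpi - s12 * dpi + s32 * dpl
    dpk = -dpl + s12 * dpi - s32 * dpl
    return phi, (dpi, dpj, dpk, dpl)


def _dihedral_terms_ef(R, idx, coeffs, U, G):
    """coeffs: list (per dihedral) of [(c, n, delta), ...]."""
    if idx.shape[0] == 0:
        return
    phi, grads = _dihedral_geometry(R, idx)
    dU_dphi = np.zeros_like(phi)
    for t, terms in enumerate(coeffs):
        for (c, n, delta) in terms:
            U += c * np.cos(n * phi[:, t] - delta)
            dU_dphi[:, t] += -c * n * np.sin(n * phi[:, t] - delta)
    for col, dp in zip(idx.T, grads):
        _acc(G, col, dU_dphi[..., None] * dp)


def _repulsion_ef(R, idx, params, U, G, model: PriorModel | None = None):
    if idx.shape[0] == 0:
        return
    i, j = idx[:, 0], idx[:, 1]
    d = R[:, i] - R[:, j]
    r = np.linalg.norm(d, axis=-1)
    n_clamped = int(np.sum(r < DIST_FLOOR))
    if n_clamped:
        if model is not None:
            model.clamp_count += n_clamped
        log.warning("repulsion: clamped %d pair distances below %.0e nm",
                    n_clamped, DIST_FLOOR)
    r = np.maximum(r, DIST_FLOOR)
    sigma = params[:, 0]
    eps = params[:, 1]
    p = params[:, 2]
    inside = r < sigma
    with np.errstate(divide="ignore", invalid="ignore"):
        sr = np.where(inside, sigma / r, 1.0)
        U += np.sum(np.where(inside,
                             eps * (sr ** p - 1.0 + p * (r / sigma - 1.0)), 0.0),
                    axis=-1)
        dU_dr = np.where(inside, eps * p * (1.0 / sigma - sr ** p / r), 0.0)
    g = (dU_dr / r)[..., None] * d
    _acc(G, i, g)
    _acc(G, j, -g)


def nonbonded_pairs(top: CGTopology, exclusion: int = 2) -> np.ndarray:
    """Bead pairs separated by more than ``exclusion`` bonds (undirected)."""
    n = top.n_beads
    adj = [[] for _ in range(n)]
    for a, b in top.bond_list:
        adj[a].append(b)
        adj[b].append(a)
    pairs = []
    for s in range(n):
        # BFS bond distance up to exclusion
        dist = {s: 0}
        frontier = [s]
        for depth in range(exclusion):
            nxt = []
            for u in frontier:
                for v in adj[u]:
                    if v not in dist:
                        dist[v] = depth + 1
                        nxt.append(v)
            frontier = nxt
        for t in range(s + 1, n):
            if t not in dist:
                pairs.append((s, t))
    return np.array(pairs, int).reshape(-1, 2)


class PriorPotential:
    """Prior energy/forces bound to one topology; batched evaluation."""

    def __init__(self, top: CGTopology, model: PriorModel):
        self.top = top
        self.model = model
        t = top.bead_types
        self._bond_idx = top.bond_list
        self._bond_par = np.array(
            [model._lookup(model.bond_terms, _pair_key(t[a], t[b]))
             for a, b in top.bond_list]).reshape(-1, 2)
        self._angle_idx = top.angle_list
        self._angle_par = np.array(
            [model._lookup(model.angle_terms, _triple_key(t[a], t[b], t[c]))
             for a, b, c in top.angle_list]).reshape(-1, 2)
        self._dih_idx = top.dihedral_list
        self._dih_coeffs = [
            model._lookup(model.dihedral_terms, _quad_key(t[list(q)]))
            for q in top.dihedral_list
        ] if len(top.dihedral_list) else []
        self._rep_idx = nonbonded_pairs(top, model.exclusion_policy)
        self._rep_par = np.array(
            [model._lookup(model.repulsion_terms, _pair_key(t[a], t[b]))
             for a, b in self._rep_idx]).reshape(-1, 3)

    def energy_forces(self, R: np.ndarray):
        R = np.asarray(R, float)
        single = R.ndim == 2
        if single:
            R = R[None]
        if not np.all(np.isfinite(R)):
            raise ValueError("non-finite coordinates")
        U = np.zeros(R.shape[0])
        G = np.zeros_like(R)      # accumulates the gradient dU/dR
        _bond_terms_ef(R, self._bond_idx, self._bond_par, U, G)
        _angle_terms_ef(R, self._angle_idx, self._angle_par, U, G)
        _dihedral_terms_ef(R, self._dih_idx, self._dih_coeffs, U, G)
        _repulsion_ef(R, self._rep_idx, self._rep_par, U, G, self.model)
        return (U[0], -G[0]) if single else (U, -G)


def prior_energy_forces(R: np.ndarray, top: CGTopology, model: PriorModel):
    """Energy (kJ/mol) and analytic forces (kJ/mol/nm) of the prior.

    ``R`` is (n, 3) or (frames, n, 3).  Forces are the exact negative
    gradient; energy is invariant under rigid motions.
    """
    return PriorPotential(top, model).energy_forces(R)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _harmonic_fit(samples_by_key, temperature):
    """Mean/variance inversion per key plus pooled fallback."""
    out = {}
    pooled = []
    kT = kbt(temperature)
    for key, vals in samples_by_key.items():
        pooled.extend(vals)
    if pooled:
        arr = np.asarray(pooled)
        out[None] = (float(arr.mean()), float(kT / max(arr.var(), 1e-12)))
    for key, vals in samples_by_key.items():
        if len(vals) < MIN_SAMPLES:
            log.warning("prior fit: %d samples for key %s < %d, using pooled "
                        "fallback", len(vals), key, MIN_SAMPLES)
            continue
        arr = np.asarray(vals)
        out[key] = (float(arr.mean()), float(kT / max(arr.var(), 1e-12)))
    return out


def _dihedral_fit(samples_by_key, temperature):
    """LSQ fit of -kT log(histogram) on a cos/sin basis, per key + pooled."""
    kT = kbt(temperature)

    def fit(vals):
        vals = np.asarray(vals)
        hist, edges = np.histogram(vals, bins=HIST_BINS, range=(-np.pi, np.pi))
        centers = 0.5 * (edges[:-1] + edges[1:])
        fe = -kT * np.log(hist + HIST_PSEUDOCOUNT)
        fe -= fe.mean()
        cols = [np.ones_like(centers)]
        for n in range(1, N_DIHEDRAL_HARMONICS + 1):
            cols += [np.cos(n * centers), np.sin(n * centers)]
        A = np.stack(cols, axis=1)
        coef, *_ = np.linalg.lstsq(A, fe, rcond=None)
        terms = []
        for n in range(1, N_DIHEDRAL_HARMONICS + 1):
            a, b = coef[2 * n - 1], coef[2 * n]
            c = float(np.hypot(a, b))
            delta = float(np.arctan2(-b, a))   # c cos(n phi - delta) = a cos + b sin
            terms.append((c, n, delta))
        return terms

    out = {}
    pooled = [v for vals in samples_by_key.values() for v in vals]
    if pooled:
        out[None] = fit(pooled)
    for key, vals in samples_by_key.items():
        if len(vals) < MIN_SAMPLES:
            log.warning("prior fit: %d samples for dihedral key %s < %d, "
                        "using pooled fallback", len(vals), key, MIN_SAMPLES)
            continue
        out[key] = fit(vals)
    return out


def _repulsion_fit(samples_by_key, temperature, p=6.0, quantile=0.02):
    kT = kbt(temperature)

    def fit(vals):
        arr = np.asarray(vals)
        sigma = float(np.quantile(arr, quantile))
        return (sigma, float(kT), float(p))

    out = {}
    pooled = [v for vals in samples_by_key.values() for v in vals]
    if pooled:
        out[None] = fit(pooled)
    for key, vals in samples_by_key.items():
        if len(vals) < MIN_SAMPLES:
            log.warning("prior fit: %d samples for repulsion key %s < %d, "
                        "using pooled fallback", len(vals), key, MIN_SAMPLES)
            continue
        out[key] = fit(vals)
    return out


ALL_TERM_CLASSES = ("bonds", "angles", "dihedrals", "repulsion")


def fit_priors(cg_frames, top: CGTopology, exclusion: int = 2,
               term_classes=ALL_TERM_CLASSES) -> PriorModel:
    """Fit the prior from CG marginal distributions.

    ``cg_frames`` is one CGFrameSet or a list of them (sharing the topology's
    type vocabulary, not necessarily the topology).  Harmonic terms by moment
    matching, dihedrals by histogram inversion, repulsion radii from the
    low-distance edge of nonbonded marginals.

    ``term_classes`` selects which classes to fit; a class left out gets an
    identically-zero fallback.  Each marginal is inverted as if independent,
    so a class fitted on strongly correlated data (e.g. torsions shaped by
    nonbonded structure) absorbs that correlation as a systematic bias —
    choose the classes to match what the prior should represent.
    """
    if not isinstance(cg_frames, (list, tuple)):
        cg_frames = [cg_frames]
    temperature = cg_frames[0].temperature

    bond_s: dict = {}
    angle_s: dict = {}
    dih_s: dict = {}
    rep_s: dict = {}
    for fs in cg_frames:
        ftop = fs.topology
        t = ftop.bead_types
        R = fs.coords
        for a, b in ftop.bond_list:
            r = np.linalg.norm(R[:, a] - R[:, b], axis=-1)
            bond_s.setdefault(_pair_key(t[a], t[b]), []).extend(r)
        if len(ftop.angle_list):
            theta, _, _ = _angle_geometry(R, ftop.angle_list)
            for col, (a, b, c) in enumerate(ftop.angle_list):
                angle_s.setdefault(_triple_key(t[a], t[b], t[c]), []).extend(theta[:, col])
        if len(ftop.dihedral_list):
            phi, _ = _dihedral_geometry(R, ftop.dihedral_list)
            for col, q in enumerate(ftop.dihedral_list):
                dih_s.setdefault(_quad_key(t[list(q)]), []).extend(phi[:, col])
        for a, b in nonbonded_pairs(ftop, exclusion):
            r = np.linalg.norm(R[:, a] - R[:, b], axis=-1)
            rep_s.setdefault(_pair_key(t[a], t[b]), []).extend(r)

    return PriorModel(
        bond_terms=_harmonic_fit(bond_s, temperature)
        if "bonds" in term_classes else {None: (0.0, 0.0)},
        angle_terms=_harmonic_fit(angle_s, temperature)
        if "angles" in term_classes else {None: (0.0, 0.0)},
        dihedral_terms=_dihedral_fit(dih_s, temperature)
        if "dihedrals" in term_classes else {None: []},
        repulsion_terms=_repulsion_fit(rep_s, temperature)
        if "repulsion" in term_classes else {None: (0.0, 0.0, 6.0)},
        exclusion_policy=exclusion,
    )


# ---------------------------------------------------------------------------
# serialization: human-readable keyed text
# ---------------------------------------------------------------------------

def save_prior(model: PriorModel, path) -> None:
    lines = [
        "# cgforge prior model",
        "# units: length nm, energy kJ/mol, angles rad",
        f"exclusion_policy {model.exclusion_policy}",
    ]

    def keystr(key):
        return "pooled" if key is None else ",".join(map(str, key))

    for key, (r0, k) in sorted(model.bond_terms.items(),
                               key=lambda kv: (kv[0] is not None, kv[0] or ())):
        lines.append(f"bond {keystr(key)} {r0!r} {k!r}")
    for key, (t0, k) in sorted(model.angle_terms.items(),
                               key=lambda kv: (kv[0] is not None, kv[0] or ())):
        lines.append(f"angle {keystr(key)} {t0!r} {k!r}")
    for key, terms in sorted(model.dihedral_terms.items(),
                             key=lambda kv: (kv[0] is not None, kv[0] or ())):
        flat = " ".join(f"{c!r} {n} {d!r}" for c, n, d in terms)
        lines.append(f"dihedral {keystr(key)} {flat}")
    for key, (s, e, p) in sorted(model.repulsion_terms.items(),
                                 key=lambda kv: (kv[0] is not None, kv[0] or ())):
        lines.append(f"repulsion {keystr(key)} {s!r} {e!r} {p!r}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_prior(path) -> PriorModel:
    model = PriorModel()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            kind = parts[0]
            if kind == "exclusion_policy":
                model.exclusion_policy = int(parts[1])
                continue
            key = None if parts[1] == "pooled" else tuple(int(x) for x in parts[1].split(","))
            vals = [float(x) for x in parts[2:]]
            if kind == "bond":
                model.bond_terms[key] = (vals[0], vals[1])
            elif kind == "angle":
                model.angle_terms[key] = (vals[0], vals[1])
            elif kind == "dihedral":
                terms = [(vals[i], int(vals[i + 1]), vals[i + 2])
                         for i in range(0, len(vals), 3)]
                model.dihedral_terms[key] = terms
            elif kind == "repulsion":
                model.repulsion_terms[key] = (vals[0], vals[1], vals[2])
            else:
                raise ValueError(f"unknown prior record {kind!r}")
    return model
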