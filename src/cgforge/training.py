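"""Variational force matching on delta-force labels.

The trainable network learns only the correction on top of the fixed prior:
labels are mapped atomistic forces minus prior forces, and the model's
delta-force prediction is simply its own conservative force field.  The
loss is the mean over frames of (1/3N) sum_j ||label_j - F_net_j||^2.

Decoy frames — noise-distorted copies of training frames with zero
delta-force labels — teach the network to predict no correction in
distorted regions where the prior should dominate.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .framesets import CGFrameSet
from .nnpot import EnergyModel, _forward, _flatten_batch
from .priors import PriorModel, PriorPotential

__all__ = ["make_delta_labels", "make_decoys", "force_matching_loss",
           "train", "TrainConfig", "TrainResult"]

log = logging.getLogger(__name__)

DECOY_STRIDE = 50          # take every 50th frame
DECOY_SIGMA_NM = 0.05      # Gaussian displacement sd, 0.5 Angstrom


def make_delta_labels(cg: CGFrameSet, prior: PriorModel, top=None) -> CGFrameSet:
    """Fill delta labels: mapped forces minus prior forces, frame-wise.

    Rejects framesets that are already labelled (re-subtracting the prior
    would corrupt the labels) and decoys (their labels are zero by fiat).
    """
    if cg.delta_labels is not None:
        raise ValueError("frameset already carries delta labels")
    if cg.source_tag == "decoy":
        raise ValueError("decoy framesets carry zero labels by construction")
    if cg.mapped_forces is None:
        raise ValueError("frameset has no mapped forces")
    top = top if top is not None else cg.topology
    pot = PriorPotential(top, prior)
    _, f_prior = pot.energy_forces(cg.coords)
    return CGFrameSet(cg.coords, cg.topology, cg.temperature,
                      cg.mapped_forces, cg.mapped_forces - f_prior,
                      cg.weights, cg.source_tag)


def make_decoys(cg: CGFrameSet, stride: int = DECOY_STRIDE,
                sigma: float = DECOY_SIGMA_NM, seed: int = 0) -> CGFrameSet:
    """Noise-distorted decoy frames with zero delta-force labels.

    Takes every ``stride``-th frame and adds i.i.d. Gaussian displacement of
    sd ``sigma`` (nm) to every coordinate; reproducible under ``seed``.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = np.random.default_rng(seed)
    base = cg.coords[::stride]
    coords = base + rng.normal(0.0, sigma, size=base.shape)
    return CGFrameSet(coords, cg.topology, cg.temperature,
                      mapped_forces=None,
                      delta_labels=np.zeros_like(coords),
                      weights=np.ones(coords.shape[0]),
                      source_tag="decoy")


def force_matching_loss(pred: np.ndarray, labels: np.ndarray,
                        weights=None) -> float:
    """Mean over frames of (1/3N) sum_j ||label_j - pred_j||^2.

    ``pred``/``labels`` are (B, N, 3).  With ``weights`` the frame average
    is weighted.  N is taken per frame from the array shape, which is the
    frame-wise generalization needed when batches mix system sizes.
    """
    pred = np.asarray(pred, float)
    labels = np.asarray(labels, float)
    if pred.shape != labels.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {labels.shape}")
    if pred.ndim != 3 or pred.shape[1] == 0:
        raise ValueError("expected (frames, N >= 1, 3) arrays")
    per_frame = np.sum((labels - pred) ** 2, axis=(1, 2)) / (3.0 * pred.shape[1])
    if weights is None:
        return float(per_frame.mean())
    weights = np.asarray(weights, float)
    return float(np.sum(weights * per_frame) / np.sum(weights))


@dataclass
class TrainConfig:
    n_epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 3e-3
    lr_min_factor: float = 0.05          # cosine decay floor
    grad_clip: float = 10.0
    validation_fraction: float = 0.2
    patience: int = 10                   # early-stopping epochs
    exclude_tags: tuple = ()             # dataset ablation hook


@dataclass
class TrainResult:
    model: EnergyModel
    history: list = field(default_factory=list)   # (epoch, train, val, lr)
    best_val: float = np.inf


def _loss_graph(model: EnergyModel, z: np.ndarray, coords: np.ndarray,
                labels: np.ndarray, weights: np.ndarray):
    """Build the differentiable loss; returns (loss Var, param Vars)."""
    B, n, _ = coords.shape
    flat, z_flat, src, dst = _flatten_batch(coords, z, model.cutoff)
    pv = {k: ad.var(v) for k, v in model.params.items()}
    Rv = ad.var(flat)
    e = _forward(pv, Rv, z_flat, src, dst, B * n, B, model)
    (g,) = ad.grad(ad.vsum(e), [Rv])
    pred = ad.reshape(ad.Var(0.0) - g, (B, n, 3))
    resid = ad.var(labels) - pred
    per_frame = ad.vsum(resid * resid, axis=(1, 2)) * ad.Var(1.0 / (3.0 * n))
    w = weights / weights.sum()
    loss = ad.vsum(per_frame * ad.Var(w))
    return loss, pv


def evaluate_loss(model: EnergyModel, z, coords, labels, weights=None) -> float:
    if weights is None:
        weights = np.ones(coords.shape[0])
    loss, _ = _loss_graph(model, z, coords, labels, np.asarray(weights, float))
    return float(loss.data)


class _Adam:
    """Adaptive-moment gradient descent with per-parameter state."""

    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params, grads, lr):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in params:
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= lr * mhat / (np.sqrt(vhat) + self.eps)


def _split_blocks(n_frames: int, val_fraction: float):
    """Contiguous-block split to limit autocorrelation leakage."""
    n_val = max(int(round(n_frames * val_fraction)), 1) if val_fraction > 0 else 0
    train_idx = np.arange(0, n_frames - n_val)
    val_idx = np.arange(n_frames - n_val, n_frames)
    return train_idx, val_idx


def train(datasets, model: EnergyModel, config: TrainConfig | None = None,
          seed: int = 0) -> TrainResult:
    """Minimize the force-matching loss over labelled CG framesets.

    ``datasets`` is a list of CGFrameSet sharing one topology (per-system
    batching).  Frames are split into contiguous train/validation blocks
    per dataset; the checkpoint with the lowest validation loss is
    returned.  Reproducible given ``seed``.
    """
    config = config or TrainConfig()
    if isinstance(datasets, CGFrameSet):
        datasets = [datasets]
    datasets = [d for d in datasets if d.source_tag not in config.exclude_tags]
    if not datasets:
        raise ValueError("no datasets left after tag exclusion")
    z = datasets[0].topology.bead_types
    for d in datasets:
        if d.delta_labels is None:
            raise ValueError(f"dataset with tag {d.source_tag!r} has no labels")
        if d.topology.n_beads != len(z):
            raise ValueError("per-system batching: topologies must share size")

    tr_c, tr_l, tr_w, va_c, va_l, va_w = [], [], [], [], [], []
    for d in datasets:
        ti, vi = _split_blocks(d.n_frames, config.validation_fraction)
        tr_c.append(d.coords[ti]); tr_l.append(d.delta_labels[ti]); tr_w.append(d.weights[ti])
        va_c.append(d.coords[vi]); va_l.append(d.delta_labels[vi]); va_w.append(d.weights[vi])
    tr_c = np.concatenate(tr_c); tr_l = np.concatenate(tr_l); tr_w = np.concatenate(tr_w)
    va_c = np.concatenate(va_c); va_l = np.concatenate(va_l); va_w = np.concatenate(va_w)

    rng = np.random.default_rng(seed)
    model = model.copy()
    opt = _Adam(model.params)
    best = model.copy()
    best_val = np.inf
    history = []
    n_train = tr_c.shape[0]
    steps_per_epoch = max(n_train // config.batch_size, 1)
    total_steps = config.n_epochs * steps_per_epoch
    step = 0
    stale = 0

    for epoch in range(config.n_epochs):
        order = rng.permutation(n_train)
        ep_losses = []
        for b in range(steps_per_epoch):
            idx = order[b * config.batch_size:(b + 1) * config.batch_size]
            if idx.size == 0:
                continue
            lr = config.learning_rate * (
                config.lr_min_factor + (1 - config.lr_min_factor)
                * 0.5 * (1 + np.cos(np.pi * step / max(total_steps - 1, 1))))
            loss, pv = _loss_graph(model, z, tr_c[idx], tr_l[idx], tr_w[idx])
            if not np.isfinite(loss.data):
                log.error("non-finite loss at step %d; aborting with last "
                          "finite checkpoint", step)
                return TrainResult(best, history, best_val)
            names = list(pv)
            gs = ad.grad(loss, [pv[k] for k in names])
            grads = {k: g.data for k, g in zip(names, gs)}
            gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
            if gnorm > config.grad_clip:
                scale = config.grad_clip / gnorm
                grads = {k: g * scale for k, g in grads.items()}
            if config.learning_rate > 0:
                opt.step(model.params, grads, lr)
            ep_losses.append(float(loss.data))
            step += 1
        val = evaluate_loss(model, z, va_c, va_l, va_w)
        history.append((epoch, float(np.mean(ep_losses)), val, lr))
        log.info("epoch %d train %.6g val %.6g lr %.3g", epoch,
                 history[-1][1], val, lr)
        if val < best_val:
            best_val = val
            best = model.copy()
            stale = 0
        else:
            stale += 1
            if stale > config.patience:
                break
    return TrainResult(best, history, best_val)
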