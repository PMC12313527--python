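"""Delta labels, decoys and the force-matching loss/trainer."""
import numpy as np
import pytest

from cgforge.framesets import CGFrameSet
from cgforge.nnpot import init_model
from cgforge.priors import PriorPotential
from cgforge.training import (TrainConfig, force_matching_loss, make_decoys,
                              make_delta_labels, train, evaluate_loss)


def test_delta_labels_are_mapped_minus_prior(toy_cg, toy_tops, simple_prior):
    _, ctop = toy_tops
    lab = make_delta_labels(toy_cg, simple_prior)
    _, f_prior = PriorPotential(ctop, simple_prior).energy_forces(toy_cg.coords)
    np.testing.assert_allclose(lab.delta_labels,
                               toy_cg.mapped_forces - f_prior, atol=1e-12)


def test_delta_labels_zero_when_forces_equal_prior(toy_cg, toy_tops, simple_prior):
    _, ctop = toy_tops
    _, f_prior = PriorPotential(ctop, simple_prior).energy_forces(toy_cg.coords)
    fs = CGFrameSet(toy_cg.coords, ctop, toy_cg.temperature,
                    mapped_forces=f_prior)
    lab = make_delta_labels(fs, simple_prior)
    assert np.abs(lab.delta_labels).max() < 1e-12


def test_hand_computed_three_bead_delta(simple_prior, toy_tops):
    _, ctop = toy_tops
    rng = np.random.default_rng(0)
    R = rng.normal(0, 0.3, (1, ctop.n_beads, 3))
    mf = rng.normal(size=(1, ctop.n_beads, 3))
    fs = CGFrameSet(R, ctop, 300.0, mapped_forces=mf)
    lab = make_delta_labels(fs, simple_prior)
    _, fp = PriorPotential(ctop, simple_prior).energy_forces(R)
    # brute-force elementwise subtraction oracle
    for b in range(ctop.n_beads):
        for d in range(3):
            assert lab.delta_labels[0, b, d] == mf[0, b, d] - fp[0, b, d]


def test_relabelling_rejected(toy_cg, simple_prior):
    lab = make_delta_labels(toy_cg, simple_prior)
    with pytest.raises(ValueError, match="already"):
        make_delta_labels(lab, simple_prior)


def test_decoy_stride_count_and_determinism(toy_cg):
    d1 = make_decoys(toy_cg, stride=50, seed=9)
    d2 = make_decoys(toy_cg, stride=50, seed=9)
    assert d1.n_frames == int(np.ceil(toy_cg.n_frames / 50))
    np.testing.assert_array_equal(d1.coords, d2.coords)
    assert np.abs(d1.delta_labels).max() == 0.0
    assert d1.source_tag == "decoy"


def test_decoy_displacement_statistics(toy_cg):
    """Default sigma 0.05 nm (0.5 A); sample sd within 2% at ~1e5 draws."""
    wide = CGFrameSet(np.repeat(toy_cg.coords, 20, axis=0), toy_cg.topology,
                      toy_cg.temperature)
    dec = make_decoys(wide, stride=1, seed=3)
    disp = (dec.coords - wide.coords).ravel()
    assert disp.size >= 1e5
    assert abs(disp.std() - 0.05) / 0.05 < 0.02
    assert abs(disp.mean()) < 0.001


def test_loss_hand_example():
    """One frame, one bead, unit residual -> chi^2 = 1/3."""
    pred = np.zeros((1, 1, 3))
    label = np.array([[[1.0, 0.0, 0.0]]])
    assert force_matching_loss(pred, label) == pytest.approx(1.0 / 3.0)


def test_loss_zero_iff_exact_and_quadratic(rng):
    pred = rng.normal(size=(4, 5, 3))
    assert force_matching_loss(pred, pred) == 0.0
    label = pred + rng.normal(size=pred.shape)
    l1 = force_matching_loss(pred, label)
    l2 = force_matching_loss(pred, pred + 2 * (label - pred))
    assert l1 > 0
    assert l2 == pytest.approx(4 * l1, rel=1e-12)


def test_loss_batched_matches_naive_loop(rng):
    """Batched implementation vs per-frame loop oracle, 1e-10 relative."""
    for B, N in [(1, 1), (7, 4), (16, 11)]:
        pred = rng.normal(size=(B, N, 3))
        label = rng.normal(size=(B, N, 3))
        naive = 0.0
        for f in range(B):
            s = 0.0
            for j in range(N):
                s += np.sum((label[f, j] - pred[f, j]) ** 2)
            naive += s / (3 * N)
        naive /= B
        assert abs(force_matching_loss(pred, label) - naive) <= 1e-10 * naive


def test_empty_system_rejected():
    with pytest.raises(ValueError):
        force_matching_loss(np.zeros((1, 0, 3)), np.zeros((1, 0, 3)))


@pytest.fixture(scope="module")
def labelled_toy():
    from cgforge.framesets import map_frameset
    from cgforge.priors import fit_priors
    from cgforge.synthetic import chain_spec, generate_toy_frameset, toy_topologies
    spec = chain_spec(n_beads=5, seed=21)
    fs = generate_toy_frameset(spec, 800)
    _, ctop = toy_topologies(spec)
    cg = map_frameset(fs, ctop)
    prior = fit_priors(cg, ctop)
    return make_delta_labels(cg, prior), ctop


def test_zero_learning_rate_leaves_parameters_unchanged(labelled_toy):
    lab, ctop = labelled_toy
    model = init_model(seed=5, embedding_dim=8, n_interactions=1, cutoff=1.0,
                       n_rbf=6, n_types=5)
    before = {k: v.copy() for k, v in model.params.items()}
    res = train(lab, model, TrainConfig(n_epochs=2, batch_size=64,
                                        learning_rate=0.0), seed=0)
    for k in before:
        np.testing.assert_array_equal(res.model.params[k], before[k])
    losses = [h[1] for h in res.history]
    assert max(losses) - min(losses) < 1e-10 * max(losses)


def test_training_reduces_validation_loss(labelled_toy):
    lab, ctop = labelled_toy
    model = init_model(seed=5, embedding_dim=16, n_interactions=1, cutoff=1.0,
                       n_rbf=8, n_types=5)
    z = ctop.bead_types
    ti = np.arange(0, 640)
    vi = np.arange(640, 800)
    before = evaluate_loss(model, z, lab.coords[vi], lab.delta_labels[vi])
    res = train(lab, model, TrainConfig(n_epochs=10, batch_size=64,
                                        learning_rate=8e-3), seed=0)
    assert res.best_val < 0.8 * before


def test_tag_exclusion_hook(labelled_toy):
    lab, _ = labelled_toy
    model = init_model(seed=5, embedding_dim=8, n_interactions=1, cutoff=1.0,
                       n_rbf=6, n_types=5)
    with pytest.raises(ValueError, match="no datasets"):
        train([lab], model,
              TrainConfig(n_epochs=1, exclude_tags=("domain-trajectory",)),
              seed=0)


def test_training_is_reproducible(labelled_toy):
    lab, _ = labelled_toy
    cfg = TrainConfig(n_epochs=2, batch_size=64, learning_rate=3e-3)
    model = init_model(seed=5, embedding_dim=8, n_interactions=1, cutoff=1.0,
                       n_rbf=6, n_types=5)
    r1 = train(lab, model, cfg, seed=7)
    r2 = train(lab, model, cfg, seed=7)
    for k in r1.model.params:
        np.testing.assert_array_equal(r1.model.params[k], r2.model.params[k])
    assert r1.history == r2.history


def test_decoys_suppress_forces_on_distorted_frames(labelled_toy):
    """A decoy-trained model predicts weaker corrections on noise-distorted
    configurations than the same model trained without decoys."""
    from cgforge.framesets import CGFrameSet
    from cgforge.nnpot import energy_forces_fast
    lab, ctop = labelled_toy
    base = CGFrameSet(lab.coords, ctop, lab.temperature,
                      mapped_forces=lab.mapped_forces)
    decoys = make_decoys(base, stride=5, seed=1)
    cfg = TrainConfig(n_epochs=4, batch_size=64, learning_rate=5e-3)
    m0 = init_model(seed=9, embedding_dim=16, n_interactions=1, cutoff=1.0,
                    n_rbf=8, n_types=5)
    with_dec = train([lab, decoys], m0, cfg, seed=2).model
    without = train([lab], m0, cfg, seed=2).model
    rng = np.random.default_rng(3)
    distorted = lab.coords[::7] + rng.normal(0, 0.05, lab.coords[::7].shape)
    z = ctop.bead_types
    _, f_with = energy_forces_fast(distorted, z, with_dec)
    _, f_without = energy_forces_fast(distorted, z, without)
    mag = lambda f: np.linalg.norm(f, axis=-1).mean()
    assert mag(f_with) < mag(f_without)
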