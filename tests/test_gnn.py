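"""Backbone components: closed-form values, invariances, and a
loop-based single-structure oracle for the batched forward pass."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import special_ortho_group

from molrank.gnn import (RBFConfig, atom_wise, batch_structures, cutoff_decay,
                         embed_atoms, forward_score, forward_scores_batch,
                         init_parameters, interaction_step, load_parameters,
                         prediction_layer, rbf_expand, save_parameters,
                         shifted_softplus)
from molrank.moldata import Structure

from conftest import random_structure


def loop_forward(structure, params, cfg):
    """From-scratch single-structure re-implementation: explicit loops
    over atoms and pairs, no batching or masking. Oracle for the batched
    forward pass."""
    def ssp(x):
        return np.logaddexp(0.0, x) - np.log(2.0)

    z = structure.atomic_numbers
    pos = structure.positions
    n = len(z)
    r_cut = float(np.logaddexp(0.0, params.cutoff_raw.data))
    x = np.stack([params.embedding.data[int(zi)] for zi in z])
    E = x.copy()
    taps = []
    for t in range(params.n_interactions):
        W, b = params.atom_wise[t]
        x = x @ W.data + b.data
        taps.append(x.copy())
        fw1, fb1, fw2, fb2 = (a.data for a in params.filter_mlp[t])
        uw1, ub1, uw2, ub2 = (a.data for a in params.update_mlp[t])
        new = np.zeros_like(x)
        for i in range(n):
            m = np.zeros(x.shape[1])
            for j in range(n):
                if j == i:
                    continue
                d = float(np.linalg.norm(pos[i] - pos[j]))
                rbf = np.array([np.exp(-cfg.width_coefficient * (d - mu) ** 2)
                                for mu in cfg.centers])
                filt = ssp(rbf @ fw1 + fb1) @ fw2 + fb2
                u = d / r_cut
                phi = (1 - 6 * u ** 5 + 15 * u ** 4 - 10 * u ** 3) if u <= 1 else 0.0
                m = m + phi * x[j] * filt
            new[i] = x[i] + ssp(m @ uw1 + ub1) @ uw2 + ub2
        x = new
    W, b = params.atom_wise[params.n_interactions]
    x = x @ W.data + b.data
    taps.append(x.copy())
    p = (params.pred_u.data * E + params.pred_w1.data * taps[-2]
         + params.pred_w2.data * taps[-1])
    return float(p.sum(axis=0) @ params.readout_w.data + params.readout_b.data)


# -- shifted softplus --------------------------------------------------------

def test_shifted_softplus_values():
    assert shifted_softplus(0.0) == pytest.approx(0.0, abs=1e-12)
    assert shifted_softplus(20.0) == pytest.approx(20.0 + np.log(0.5), abs=1e-6)
    assert shifted_softplus(-20.0) == pytest.approx(np.log(0.5), abs=1e-6)
    # overflow safety
    assert np.isfinite(shifted_softplus(1000.0))
    assert np.isfinite(shifted_softplus(-1000.0))
    x = np.linspace(-5, 5, 11)
    assert np.allclose(shifted_softplus(x), np.log(0.5 * np.exp(x) + 0.5))


# -- RBF expansion -----------------------------------------------------------

def test_rbf_default_grid():
    cfg = RBFConfig()
    assert cfg.n_centers == 300
    assert cfg.centers[0] == 0.0
    assert cfg.centers[-1] == pytest.approx(29.9)
    assert np.allclose(np.diff(cfg.centers), 0.1)
    assert rbf_expand(3.7, cfg).shape == (300,)


def test_rbf_values(small_rbf):
    out = rbf_expand(small_rbf.centers[3], small_rbf)
    assert out[3] == pytest.approx(1.0)
    cfg = RBFConfig.uniform(0.0, 8.0, 4.0)   # centers 0, 4
    assert rbf_expand(5.0, cfg)[1] == pytest.approx(np.exp(-1.0))
    with pytest.raises(ValueError):
        rbf_expand(-0.1, small_rbf)


def test_rbf_matches_scalar_oracle(rng, small_rbf):
    """Vectorised expansion equals independent per-component evaluation."""
    d = rng.uniform(0, 10, size=50)
    out = rbf_expand(d, small_rbf)
    for k, mu in enumerate(small_rbf.centers):
        expect = np.exp(-small_rbf.width_coefficient * (d - mu) ** 2)
        assert np.allclose(out[:, k], expect, atol=1e-12)
    assert np.all(out > 0) and np.all(out <= 1)


# -- cutoff ------------------------------------------------------------------

def test_cutoff_decay_anchor_values():
    for r_cut in (1.0, 5.0, 10.0):
        assert cutoff_decay(0.0, r_cut) == pytest.approx(1.0)
        assert cutoff_decay(r_cut / 2, r_cut) == pytest.approx(0.5)
        assert cutoff_decay(r_cut, r_cut) == pytest.approx(0.0, abs=1e-12)
        assert cutoff_decay(r_cut * 1.5, r_cut) == 0.0   # clamped


def test_cutoff_decay_smooth_and_monotone():
    r_cut = 7.3
    d = np.linspace(0, r_cut, 1000)
    phi = cutoff_decay(d, r_cut)
    assert np.all(np.diff(phi) <= 1e-12)      # non-increasing
    h = 1e-4
    d0 = (cutoff_decay(h, r_cut) - cutoff_decay(0.0, r_cut)) / h
    d1 = (cutoff_decay(r_cut, r_cut) - cutoff_decay(r_cut - h, r_cut)) / h
    assert abs(d0) <= 1e-6 and abs(d1) <= 1e-6
    with pytest.raises(ValueError):
        cutoff_decay(1.0, 0.0)


# -- embedding / atom-wise / prediction --------------------------------------

def test_embed_atoms(small_params):
    feats = embed_atoms([6, 1, 6], small_params)
    assert feats.shape == (3, small_params.n_features)
    assert np.array_equal(feats.data[0], feats.data[2])
    perm = embed_atoms([1, 6, 6], small_params)
    assert np.array_equal(perm.data[[1, 0, 2]], feats.data)
    with pytest.raises(KeyError, match="99"):
        embed_atoms([99], small_params)


def test_atom_wise_layer(small_params):
    F = small_params.n_features
    feats = embed_atoms([1, 1, 8], small_params)
    w, b = small_params.atom_wise[0]
    w.data[:] = np.eye(F)
    b.data[:] = 0.0
    out = atom_wise(feats, 0, small_params)
    assert np.allclose(out.data, feats.data)
    # shared weights: equal inputs give equal outputs
    w.data[:] = np.random.default_rng(0).standard_normal((F, F))
    out = atom_wise(feats, 0, small_params)
    assert np.allclose(out.data[0], out.data[1])
    # zero weights, constant bias
    w.data[:] = 0.0
    b.data[:] = 2.5
    out = atom_wise(feats, 0, small_params)
    assert np.allclose(out.data, 2.5)
    import molrank.autodiff as ad
    with pytest.raises(ValueError):
        atom_wise(ad.constant(np.zeros((2, F + 1))), 0, small_params)


def test_interaction_step_identities(small_params, small_rbf):
    F = small_params.n_features
    import molrank.autodiff as ad
    # single atom, all MLP biases zero -> features unchanged
    p = small_params
    for grp in (p.filter_mlp[0], p.update_mlp[0]):
        grp[1].data[:] = 0.0
        grp[3].data[:] = 0.0
    feats = ad.constant(np.random.default_rng(1).standard_normal((1, F)))
    out = interaction_step(feats, np.zeros((1, 1)), p, small_rbf, layer=0)
    assert np.allclose(out.data, feats.data)
    # zero update MLP -> residual identity for any system
    for t in (p.update_mlp[1],):
        for a in t:
            a.data[:] = 0.0
    d = np.array([[0.0, 2.0], [2.0, 0.0]])
    feats2 = ad.constant(np.random.default_rng(2).standard_normal((2, F)))
    out2 = interaction_step(feats2, d, p, small_rbf, layer=1)
    assert np.allclose(out2.data, feats2.data)


def test_interaction_step_symmetry(small_params, small_rbf):
    """Two identical atoms at any distance get identical updated rows."""
    import molrank.autodiff as ad
    F = small_params.n_features
    row = np.random.default_rng(3).standard_normal(F)
    feats = ad.constant(np.stack([row, row]))
    d = np.array([[0.0, 1.7], [1.7, 0.0]])
    out = interaction_step(feats, d, small_params, small_rbf, layer=0)
    assert np.allclose(out.data[0], out.data[1])


def test_interaction_step_validates_distances(small_params, small_rbf):
    import molrank.autodiff as ad
    feats = ad.constant(np.zeros((2, small_params.n_features)))
    with pytest.raises(ValueError):
        interaction_step(feats, np.array([[0.0, 1.0], [2.0, 0.0]]),
                         small_params, small_rbf)
    with pytest.raises(ValueError):
        interaction_step(feats, np.array([[1.0, 2.0], [2.0, 0.0]]),
                         small_params, small_rbf)


def test_prediction_layer(small_params):
    import molrank.autodiff as ad
    F = small_params.n_features
    rng = np.random.default_rng(4)
    E, a1, a2 = (ad.constant(rng.standard_normal((3, F))) for _ in range(3))
    p = small_params
    p.pred_u.data[:] = 1.0
    p.pred_w1.data[:] = 0.0
    p.pred_w2.data[:] = 0.0
    assert np.allclose(prediction_layer(E, a1, a2, p).data, E.data)
    p.pred_u.data[:] = 0.0
    assert np.allclose(prediction_layer(E, a1, a2, p).data, 0.0)
    # linearity
    rng = np.random.default_rng(5)
    p.pred_u.data[:] = rng.standard_normal(F)
    p.pred_w1.data[:] = rng.standard_normal(F)
    p.pred_w2.data[:] = rng.standard_normal(F)
    one = prediction_layer(E, a1, a2, p).data
    two = prediction_layer(E * 2.0, a1 * 2.0, a2 * 2.0, p).data
    assert np.allclose(two, 2 * one)
    with pytest.raises(ValueError):
        prediction_layer(E, a1, ad.constant(np.zeros((2, F))), p)


# -- full forward ------------------------------------------------------------

def test_forward_invariances(small_params, small_rbf, rng):
    for _ in range(20):
        s = random_structure(rng)
        score = forward_score(s, small_params, small_rbf)
        R = special_ortho_group.rvs(3, random_state=rng)
        t = rng.uniform(-5, 5, size=3)
        rot = Structure(s.structure_id, s.group_id, s.atomic_numbers,
                        s.positions @ R.T + t)
        assert forward_score(rot, small_params, small_rbf) == pytest.approx(
            score, rel=1e-5, abs=1e-5 * (1 + abs(score)))
        perm = rng.permutation(s.n_atoms)
        permuted = Structure(s.structure_id, s.group_id,
                             s.atomic_numbers[perm], s.positions[perm])
        assert forward_score(permuted, small_params, small_rbf) == pytest.approx(
            score, rel=1e-5, abs=1e-5 * (1 + abs(score)))


def test_forward_constant_readout(small_params, small_rbf, rng):
    small_params.readout_w.data[:] = 0.0
    small_params.readout_b.data = np.asarray(3.25)
    for _ in range(3):
        s = random_structure(rng)
        assert forward_score(s, small_params, small_rbf) == pytest.approx(3.25)


def test_batched_forward_matches_loop_oracle(small_params, small_rbf, rng):
    """Padding/masking in the batched path is exactly neutral: scores of a
    mixed-size batch equal the loop-based per-structure evaluation."""
    structures = [random_structure(rng, n_atoms=int(n))
                  for n in rng.integers(2, 7, size=10)]
    Z, D, mask = batch_structures(structures)
    batched = forward_scores_batch(Z, D, mask, small_params, small_rbf).data
    for k, s in enumerate(structures):
        assert batched[k] == pytest.approx(
            loop_forward(s, small_params, small_rbf), rel=1e-6, abs=1e-6)


def test_checkpoint_roundtrip(tmp_path, small_params, small_rbf, rng):
    s = random_structure(rng)
    before = forward_score(s, small_params, small_rbf)
    path = tmp_path / "ckpt.npz"
    save_parameters(small_params, small_rbf, path)
    params2, rbf2 = load_parameters(path)
    assert rbf2 == small_rbf
    assert forward_score(s, params2, rbf2) == before
    assert params2.r_cut == pytest.approx(small_params.r_cut)
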