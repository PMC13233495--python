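import numpy as np
import pytest

from eegfatigue import (deflate_mu, extract_mu_atom, npls_fit, npls_predict,
                        npls_project, parafac_als)
from eegfatigue.montage import CENTRAL_10, make_montage
from eegfatigue.multiway import (Atom, average_atoms, enumerate_subsets,
                                 select_component_subset, tucker_congruence)
from eegfatigue.spectral import FeatureTensor


def _unit(v):
    return v / np.linalg.norm(v)


def _rank_tensor(rank, shape, seed, snr=None):
    """Random rank-R tensor with unit-norm B, C columns; optional noise."""
    rng = np.random.default_rng(seed)
    I, J, K = shape
    A = rng.standard_normal((I, rank)) * (2.0 + np.arange(rank))[::-1]
    B = np.linalg.qr(rng.standard_normal((J, rank)))[0]
    C = np.linalg.qr(rng.standard_normal((K, rank)))[0]
    X = np.einsum("ir,jr,kr->ijk", A, B, C)
    if snr is not None:
        noise = rng.standard_normal(shape)
        X = X + noise * np.linalg.norm(X) / (snr * np.linalg.norm(noise))
    return X, A, B, C


def test_parafac_recovers_a_rank_one_tensor_exactly():
    rng = np.random.default_rng(0)
    a, b, c = rng.standard_normal(12), _unit(rng.standard_normal(8)), _unit(rng.standard_normal(6))
    X = np.einsum("i,j,k->ijk", a, b, c)
    res = parafac_als(X, rank=1, seed=0, n_restarts=2)
    assert res.fit > 1.0 - 1e-8
    atom = res.atoms[0]
    sgn = np.sign(atom.freq_weights @ b)
    assert np.allclose(sgn * atom.freq_weights, b, atol=1e-6)
    sgn_c = np.sign(atom.spatial_weights @ c)
    assert np.allclose(sgn_c * atom.spatial_weights, c, atol=1e-6)
    assert np.allclose(sgn * sgn_c * atom.scores, a, atol=1e-6 * np.abs(a).max())


def test_parafac_recovers_noiseless_rank3_factors():
    X, A, B, C = _rank_tensor(3, (20, 15, 10), seed=1)
    res = parafac_als(X, rank=3, seed=0)
    assert res.fit > 1.0 - 1e-6
    for b_true, c_true in zip(B.T, C.T):
        best = max(abs(tucker_congruence(at.freq_weights, b_true))
                   * abs(tucker_congruence(at.spatial_weights, c_true))
                   for at in res.atoms)
        assert best > 1.0 - 1e-5


def test_parafac_is_deterministic_and_orders_by_score_norm():
    X, *_ = _rank_tensor(2, (15, 10, 8), seed=2, snr=10.0)
    r1 = parafac_als(X, rank=2, seed=7)
    r2 = parafac_als(X, rank=2, seed=7)
    for a1, a2 in zip(r1.atoms, r2.atoms):
        assert np.array_equal(a1.freq_weights, a2.freq_weights)
    norms = [np.linalg.norm(a.scores) for a in r1.atoms]
    assert norms == sorted(norms, reverse=True)


def test_parafac_input_validation():
    with pytest.raises(ValueError):
        parafac_als(np.zeros((3, 3)), rank=1)
    with pytest.raises(ValueError):
        parafac_als(np.ones((3, 3, 3)), rank=0)
    with pytest.raises(ValueError):
        parafac_als(np.zeros((3, 3, 3)), rank=1)


def test_atom_requires_unit_norm_weights():
    with pytest.raises(ValueError):
        Atom(freq_weights=np.ones(4), spatial_weights=_unit(np.ones(3)))


def _feature_tensor(vals, freqs=None, labels=None):
    I, J, K = vals.shape
    freqs = np.linspace(5.0, 20.0, J) if freqs is None else freqs
    labels = tuple(make_montage(32).labels[:K]) if labels is None else labels
    return FeatureTensor(vals, freqs, labels, np.array(["pre-EC"] * I))


def test_npls_first_factor_matches_svd_oracle():
    for seed in (0, 1, 2):
        rng = np.random.default_rng(seed)
        vals = rng.standard_normal((30, 12, 6))
        y = rng.integers(0, 2, 30).astype(float)
        X = _feature_tensor(vals)
        model = npls_fit(X, y, 2)
        Xc = vals - vals.mean(axis=0)
        yc = y - y.mean()
        Z = np.einsum("i,ijk->jk", yc, Xc)
        U, s, Vt = np.linalg.svd(Z)
        wf, wc = U[:, 0], Vt[0]
        sgn = np.sign(wc[np.argmax(np.abs(wc))])
        assert np.allclose(model.freq_weights[0], sgn * wf, atol=1e-10)
        assert np.allclose(model.spatial_weights[0], sgn * wc, atol=1e-10)
        # the first factor maximizes |cov(t, y)| over 1000 random weight pairs
        t0 = np.einsum("ijk,j,k->i", Xc, wf, wc)
        cov0 = abs(t0 @ yc)
        rnd = np.random.default_rng(seed + 100)
        for _ in range(1000):
            a, b = _unit(rnd.standard_normal(12)), _unit(rnd.standard_normal(6))
            assert abs(np.einsum("ijk,j,k->i", Xc, a, b) @ yc) <= cov0 + 1e-9


def test_npls_project_reproduces_training_scores():
    rng = np.random.default_rng(3)
    X = _feature_tensor(rng.standard_normal((24, 10, 5)))
    y = rng.integers(0, 2, 24).astype(float)
    model = npls_fit(X, y, 3)
    assert np.allclose(npls_project(model, X), model.T, atol=1e-10)
    # mismatched axes raise
    bad = _feature_tensor(rng.standard_normal((4, 10, 5)),
                          freqs=np.linspace(1.0, 4.0, 10))
    with pytest.raises(ValueError):
        npls_project(model, bad)


def test_npls_predicts_an_exactly_trilinear_response():
    # rank-1 tensor with y a linear function of the scores: one factor is exact
    rng = np.random.default_rng(4)
    wf, wc = _unit(rng.standard_normal(8)), _unit(rng.standard_normal(4))
    t = rng.standard_normal(40)
    vals = np.einsum("i,j,k->ijk", t, wf, wc)
    y = 2.0 * t + 0.5
    X = _feature_tensor(vals)
    model = npls_fit(X, y, 1)
    assert np.allclose(npls_predict(model, X), y, atol=1e-8)
    # held-out data with the same structure is predicted exactly too
    t_new = rng.standard_normal(10)
    X_new = _feature_tensor(np.einsum("i,j,k->ijk", t_new, wf, wc))
    assert np.allclose(npls_predict(model, X_new), 2.0 * t_new + 0.5, atol=1e-8)
    # factor subset (0,) equals the full single-factor model
    assert np.allclose(npls_predict(model, X, factors=[0]),
                       npls_predict(model, X), atol=1e-10)


def test_npls_validation_and_truncation():
    rng = np.random.default_rng(5)
    X = _feature_tensor(rng.standard_normal((10, 6, 4)))
    with pytest.raises(ValueError):
        npls_fit(X, np.ones(10), 1)
    with pytest.raises(ValueError):
        npls_fit(X, np.zeros(9), 1)
    # a rank-1 planted response truncates well before 5 factors
    wf, wc = _unit(np.ones(6)), _unit(np.ones(4))
    vals = np.einsum("i,j,k->ijk", np.arange(10.0), wf, wc)
    Xr1 = _feature_tensor(vals)
    y = np.arange(10.0)
    with pytest.warns(UserWarning, match="truncating"):
        model = npls_fit(Xr1, y, 5)
    assert model.n_factors < 5


def test_deflation_removes_a_planted_atom_exactly():
    rng = np.random.default_rng(6)
    montage = make_montage(32)
    freqs = np.linspace(5.0, 20.0, 16)
    wf = _unit(np.exp(-((freqs - 10.75) / 1.0) ** 2))
    wc_sub = _unit(rng.random(10) + 0.5)
    atom = Atom(freq_weights=wf, spatial_weights=wc_sub,
                channel_support=CENTRAL_10, freq_axis=freqs.copy())
    wc_full = np.zeros(32)
    for w, lb in zip(wc_sub, CENTRAL_10):
        wc_full[montage.labels.index(lb)] = w
    scores = rng.random(12) * 5.0
    planted = np.einsum("i,j,k->ijk", scores, wf, wc_full)
    background = rng.standard_normal((12, 16, 32))
    # orthogonalize the background against the atom so removal is exact
    P = np.outer(wf, wc_full)
    proj = np.einsum("ijk,jk->i", background, P) / np.sum(P * P)
    background -= proj[:, None, None] * P[None, :, :]
    X = _feature_tensor(planted + background, freqs=freqs,
                        labels=tuple(montage.labels))
    out = deflate_mu(X, atom)
    assert np.max(np.abs(out.values - background)) < 1e-10
    # idempotent and norm-reducing
    out2 = deflate_mu(out, atom)
    assert np.allclose(out2.values, out.values, atol=1e-8)
    assert np.linalg.norm(out.values) <= np.linalg.norm(X.values) + 1e-12
    # non-central channels are untouched
    untouched = [i for i, lb in enumerate(montage.labels) if lb not in CENTRAL_10]
    assert np.array_equal(out.values[:, :, untouched], X.values[:, :, untouched])


def test_deflation_rejects_misaligned_atoms():
    rng = np.random.default_rng(7)
    X = _feature_tensor(rng.standard_normal((4, 8, 5)))
    atom = Atom(freq_weights=_unit(np.ones(8)), spatial_weights=_unit(np.ones(2)),
                channel_support=("Qz", "Rz"), freq_axis=X.freqs.copy())
    with pytest.raises(ValueError):
        deflate_mu(X, atom)
    atom2 = Atom(freq_weights=_unit(np.ones(6)), spatial_weights=_unit(np.ones(5)))
    with pytest.raises(ValueError):
        deflate_mu(X, atom2)


def test_extract_mu_atom_finds_a_planted_central_mu_peak():
    rng = np.random.default_rng(8)
    montage = make_montage(32)
    freqs = np.linspace(5.0, 20.0, 31)
    wf = _unit(np.exp(-((freqs - 10.75) / 0.8) ** 2))
    wc = np.zeros(32)
    for lb in CENTRAL_10:
        wc[montage.labels.index(lb)] = 1.0
    wc = _unit(wc)
    vals = np.einsum("i,j,k->ijk", 3.0 + rng.random(20), wf, wc)
    vals += 0.05 * rng.standard_normal(vals.shape)
    X = _feature_tensor(vals, freqs=freqs, labels=tuple(montage.labels))
    atom = extract_mu_atom(X, rank=2, n_restarts=2)
    assert atom.peak_frequency == pytest.approx(10.75, abs=0.5)
    assert atom.channel_support == tuple(CENTRAL_10)


def test_average_atoms_aligns_signs_and_matches_permutations():
    rng = np.random.default_rng(9)
    wf1, wf2 = _unit(rng.standard_normal(8)), _unit(rng.standard_normal(8))
    wc1, wc2 = _unit(rng.standard_normal(5)), _unit(rng.standard_normal(5))

    def model(pairs):
        from eegfatigue.multiway import NPLSModel
        Wf = np.array([p[0] for p in pairs])
        Wc = np.array([p[1] for p in pairs])
        F = len(pairs)
        return NPLSModel(n_factors=F, freq_weights=Wf, spatial_weights=Wc,
                         T=np.zeros((3, F)), U=np.zeros((3, F)), q=np.ones(F),
                         B=np.zeros(F), x_mean=np.zeros((8, 5)), y_mean=0.0)

    ref = model([(wf1, wc1), (wf2, wc2)])
    flipped = model([(-wf2, wc2), (wf1, -wc1)])  # permuted and sign-flipped
    atoms = average_atoms([ref, flipped])
    assert len(atoms) == 2
    assert abs(tucker_congruence(atoms[0].freq_weights, wf1)) > 1.0 - 1e-9
    assert abs(tucker_congruence(atoms[1].spatial_weights, wc2)) > 1.0 - 1e-9
    with pytest.raises(ValueError):
        average_atoms([ref])


def test_subset_enumeration_and_selection():
    subs = enumerate_subsets(4)
    assert len(subs) == 15
    assert subs[0] == (0,) and (0, 1, 2, 3) in subs
    scores = {(0,): 0.7, (1,): 0.9, (0, 1): 0.9, (0, 1, 2): 0.85}
    # tie between (1,) and (0, 1) breaks toward the smaller subset
    assert select_component_subset(scores) == (1,)
    with pytest.raises(ValueError):
        select_component_subset({})
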