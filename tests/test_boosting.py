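import numpy as np
import pytest
from hypothesis import given, strategies as st

import covdet as cd
from covdet.boosting import BPNetwork, BPNetworkConfig
from covdet.exceptions import (DegenerateLabelError, InvalidArgumentError,
                               InvalidStateError)


def blobs(n=100, d=2, sep=4.0, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.standard_normal((n // 2, d))
    X1 = rng.standard_normal((n - n // 2, d)) + sep
    X = np.vstack([X0, X1])
    y = np.r_[np.zeros(n // 2), np.ones(n - n // 2)]
    X = (X - X.mean(0)) / X.std(0)
    return X, y


# ---------------------------------------------------------------------------
# Boosting arithmetic
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("x, expected", [(0.3, 1), (0.2, 0), (0.0, 0), (1.0, 1)])
def test_indicator_boundary(x, expected):
    assert cd.indicator(x) == expected


def test_update_distribution_all_correct():
    D = np.array([0.1, 0.2, 0.3, 0.4])
    y = np.array([0, 1, 0, 1])
    np.testing.assert_allclose(cd.update_distribution(D, y, y, delta=1.0), D)


def test_update_distribution_one_misclassified():
    D = np.full(4, 0.25)
    y = np.array([0, 1, 0, 1])
    y_hat = np.array([0, 1, 0, 0])  # last one wrong
    out = cd.update_distribution(D, y, y_hat, delta=1.0)
    np.testing.assert_allclose(out, [0.2, 0.2, 0.2, 0.4])


def test_update_distribution_delta_zero_noop():
    D = np.array([0.5, 0.25, 0.25])
    out = cd.update_distribution(D, [1, 1, 0], [0, 0, 1], delta=0.0)
    np.testing.assert_allclose(out, D)


def test_update_distribution_symmetric_in_error_direction():
    """Both 0→1 and 1→0 errors upweight (absolute difference indicator)."""
    D = np.full(2, 0.5)
    out = cd.update_distribution(D, [0, 1], [1, 0], delta=1.0)
    np.testing.assert_allclose(out, [0.5, 0.5])
    out2 = cd.update_distribution(np.full(2, 0.5), [0, 1], [1, 1], delta=1.0)
    assert out2[0] > out2[1]


def test_ensemble_error_cases():
    y = np.array([0, 1, 0, 1])
    assert cd.ensemble_error(np.full(4, 0.25), y, y) == 0.0
    half_wrong = np.array([1, 0, 0, 1])
    assert cd.ensemble_error(np.full(4, 0.25), y, half_wrong) == pytest.approx(0.5)
    one_hot = np.array([1.0, 0, 0, 0])
    assert cd.ensemble_error(one_hot, y, np.array([1, 1, 0, 1])) == 1.0


def test_learner_weight():
    assert cd.learner_weight(0.5) == pytest.approx(2.0)
    assert cd.learner_weight(0.1) == pytest.approx(10.0)
    capped = cd.learner_weight(0.0)
    assert capped == pytest.approx(1e6)
    assert capped > cd.learner_weight(1e-6) - 1e-9  # monotone through the cap
    with pytest.raises(InvalidArgumentError):
        cd.learner_weight(-0.1)


def test_ensemble_score():
    assert cd.ensemble_score([0.7], [3.0]) == pytest.approx(0.7)
    assert cd.ensemble_score([1.0, 0.0], [3.0, 1.0]) == pytest.approx(0.75)
    assert cd.ensemble_score([0.4, 0.4, 0.4], [1, 5, 2]) == pytest.approx(0.4)
    with pytest.raises(InvalidStateError):
        cd.ensemble_score([0.5, 0.5], [0.0, 0.0])


@given(st.data())
def test_ensemble_score_properties(data):
    """Q stays in [0,1] and is non-decreasing in any single prediction."""
    L = data.draw(st.integers(1, 6))
    p = np.array(data.draw(st.lists(st.floats(0, 1), min_size=L, max_size=L)))
    w = np.array(data.draw(st.lists(st.floats(0.01, 10), min_size=L, max_size=L)))
    q = cd.ensemble_score(p, w)
    assert -1e-12 <= q <= 1 + 1e-12
    i = data.draw(st.integers(0, L - 1))
    p2 = p.copy()
    p2[i] = min(1.0, p2[i] + 0.25)
    assert cd.ensemble_score(p2, w) >= q - 1e-12


@given(st.integers(0, 500))
def test_distribution_conservation(seed):
    rng = np.random.default_rng(seed)
    n = rng.integers(2, 40)
    D = rng.random(n)
    D /= D.sum()
    y = rng.integers(0, 2, n)
    y_hat = rng.integers(0, 2, n)
    out = cd.update_distribution(D, y, y_hat, delta=rng.random() * 2)
    assert out.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(out >= 0)


# ---------------------------------------------------------------------------
# The weak learner
# ---------------------------------------------------------------------------

def test_bp_network_fits_separable_blobs():
    X, y = blobs(seed=1)
    net = BPNetwork(BPNetworkConfig(seed=0)).fit(X, y)
    assert (net.predict(X) == y).mean() >= 0.95
    assert np.all((net.predict_proba(X) >= 0) & (net.predict_proba(X) <= 1))


def test_bp_network_weight_concentration():
    """Concentrating nearly all mass on one example forces its label."""
    rng = np.random.default_rng(5)
    X = rng.standard_normal((20, 3))
    y = np.r_[np.zeros(10), np.ones(10)]
    w = np.full(20, 1e-4)
    w[0] = 1.0
    y_flip = y.copy()
    y_flip[0] = 1.0  # example 0 labelled against its blob
    net = BPNetwork(BPNetworkConfig(seed=2, val_fraction=0.0)).fit(X, y_flip, sample_weight=w)
    assert net.predict(X[:1])[0] == 1


def test_bp_network_single_class_rejected():
    X = np.zeros((10, 2))
    with pytest.raises(DegenerateLabelError):
        BPNetwork().fit(X, np.zeros(10))


def test_bp_network_deterministic_under_seed():
    X, y = blobs(seed=3)
    a = BPNetwork(BPNetworkConfig(seed=9)).fit(X, y).predict_raw(X)
    b = BPNetwork(BPNetworkConfig(seed=9)).fit(X, y).predict_raw(X)
    np.testing.assert_array_equal(a, b)


def test_bp_network_serialization_roundtrip():
    X, y = blobs(n=40, seed=4)
    net = BPNetwork(BPNetworkConfig(seed=1)).fit(X, y)
    clone = BPNetwork.from_dict(net.to_dict())
    np.testing.assert_array_equal(net.predict_raw(X), clone.predict_raw(X))


# ---------------------------------------------------------------------------
# The ensemble
# ---------------------------------------------------------------------------

def test_adaboost_beats_or_matches_single_learner():
    X, y = blobs(n=120, sep=2.0, seed=6)
    rng = np.random.default_rng(6)
    test_idx = rng.permutation(120)[:40]
    train_mask = np.ones(120, bool)
    train_mask[test_idx] = False
    ens = cd.fit_adaboost(X[train_mask], y[train_mask], L=8, seed=0)
    single = cd.fit_adaboost(X[train_mask], y[train_mask], L=1, seed=0)
    acc_e = (ens.predict(X[test_idx]) == y[test_idx]).mean()
    acc_s = (single.predict(X[test_idx]) == y[test_idx]).mean()
    assert acc_e >= acc_s


def test_adaboost_single_learner_equals_bp_network():
    X, y = blobs(n=60, seed=7)
    ens = cd.fit_adaboost(X, y, L=1, seed=3)
    assert len(ens.learners) == 1
    np.testing.assert_allclose(ens.predict_score(X),
                               ens.learners[0].predict_proba(X))


def test_adaboost_weight_ordering():
    X, y = blobs(n=150, sep=1.0, seed=8)  # overlapping → nonzero errors
    ens = cd.fit_adaboost(X, y, L=6, seed=1)
    E = np.asarray(ens.errors)
    w = ens.normalized_weights
    order = np.argsort(E)
    # lower error → strictly larger normalized weight (ties only at equal E)
    for a, b in zip(order, order[1:]):
        if E[a] < E[b]:
            assert w[a] > w[b]


def test_adaboost_reproducible():
    X, y = blobs(n=80, seed=9)
    s1 = cd.fit_adaboost(X, y, L=4, seed=5).predict_score(X)
    s2 = cd.fit_adaboost(X, y, L=4, seed=5).predict_score(X)
    np.testing.assert_array_equal(s1, s2)


def test_ensemble_serialization_roundtrip(tmp_path):
    X, y = blobs(n=50, seed=10)
    ens = cd.fit_adaboost(X, y, L=3, seed=2)
    path = tmp_path / "model.json"
    ens.save(path)
    clone = cd.BoostedEnsemble.load(path)
    np.testing.assert_array_equal(ens.predict_score(X), clone.predict_score(X))
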