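"""Perceptron forward pass, bags, losses and LLP / pseudo-label training."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import myorecovery as mr
from myorecovery.classifier import KL_EPS, init_params


def _zero_params(D=4, H1=4, H2=3, K=4):
    z = init_params(D, H1, H2, K, seed=0)
    for a in (z.W1, z.b1, z.W2, z.b2, z.W3, z.b3):
        a[...] = 0.0
    return z


def _random_simplex(rng, K=4):
    v = rng.dirichlet(np.ones(K))
    return v / v.sum()


class TestForward:
    def test_zero_params_uniform(self):
        out = mr.forward(_zero_params(), np.ones(4))
        np.testing.assert_allclose(out, 0.25)

    def test_output_on_simplex(self, rng):
        params = init_params(6, 6, 5, 4, seed=3)
        X = rng.normal(size=(50, 6))
        probs = mr.forward(params, X)
        assert (probs > 0).all()
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_closed_form_softmax(self):
        # force logits (ln 3, 0) through the last layer of a 2-class net
        params = _zero_params(D=2, H1=2, H2=2, K=2)
        params.b3[...] = [np.log(3.0), 0.0]
        np.testing.assert_allclose(mr.forward(params, np.zeros(2)), [0.75, 0.25])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            mr.forward(_zero_params(D=4), np.ones(5))


class TestPredictClass:
    def test_clear_max(self):
        params = _zero_params()
        params.b3[...] = [2.0, 0.0, 0.0, 0.0]
        assert mr.predict_class(params, np.zeros(4)) == 0

    def test_tie_goes_to_lowest_index(self):
        params = _zero_params()
        params.b3[...] = [1.0, 1.0, 0.0, 0.0]
        assert mr.predict_class(params, np.zeros(4)) == 0

    def test_matches_linear_scan_oracle(self, rng):
        params = init_params(5, 5, 4, 4, seed=9)
        for _ in range(20):
            x = rng.normal(size=5)
            conf = mr.forward(params, x)
            assert mr.predict_class(params, x) == max(range(4), key=lambda k: conf[k])


class TestMakeBags:
    def test_remainder_dropped(self):
        bags = mr.make_bags([0] * 10, N=3, seed=0)
        assert len(bags) == 3
        assert all(b.N == 3 for b in bags)
        used = np.concatenate([b.instance_indices for b in bags])
        assert len(np.unique(used)) == 9

    def test_bag_size_one(self):
        bags = mr.make_bags([0, 0, 1], N=1, seed=0)
        assert len(bags) == 3

    def test_no_day_mixing(self):
        days = [0] * 7 + [3] * 9
        for bag in mr.make_bags(days, N=4, seed=5):
            assert len({days[i] for i in bag.instance_indices}) == 1

    def test_bag_count_formula(self):
        days = [0] * 13 + [3] * 21 + [5] * 3
        assert len(mr.make_bags(days, N=4, seed=1)) == 13 // 4 + 21 // 4 + 3 // 4


class TestPredictedProportion:
    def test_identical_members(self, rng):
        params = _zero_params()
        X = np.tile(rng.normal(size=4), (6, 1))
        bag = mr.Bag(0, np.arange(6))
        np.testing.assert_allclose(mr.predicted_proportion(params, bag, X), 0.25)

    def test_equals_column_mean_oracle(self, rng):
        params = init_params(5, 5, 4, 4, seed=2)
        X = rng.normal(size=(12, 5))
        bag = mr.Bag(0, np.arange(12))
        oracle = np.vstack([mr.forward(params, x) for x in X]).mean(axis=0)
        np.testing.assert_allclose(mr.predicted_proportion(params, bag, X), oracle)

    def test_union_of_equal_bags_is_mean(self, rng):
        params = init_params(5, 5, 4, 4, seed=2)
        X = rng.normal(size=(10, 5))
        a, b = mr.Bag(0, np.arange(5)), mr.Bag(0, np.arange(5, 10))
        u = mr.Bag(0, np.arange(10))
        np.testing.assert_allclose(
            mr.predicted_proportion(params, u, X),
            0.5 * (mr.predicted_proportion(params, a, X)
                   + mr.predicted_proportion(params, b, X)),
        )

    def test_empty_bag_errors(self):
        with pytest.raises(ValueError):
            mr.predicted_proportion(_zero_params(), mr.Bag(0, np.array([], dtype=int)),
                                    np.zeros((0, 4)))


class TestProportionLoss:
    def test_identity_is_zero(self):
        p = np.array([0.3, 0.2, 0.4, 0.1])
        assert mr.proportion_loss(p, p) == pytest.approx(0.0, abs=1e-7)

    def test_hand_evaluated_ln2(self):
        loss = mr.proportion_loss([1, 0, 0, 0], [0.5, 0.5, 0, 0], eps=1e-12)
        assert loss == pytest.approx(np.log(2), abs=1e-9)

    def test_asymmetry(self):
        a, b = [0.9, 0.1, 0, 0], [0.5, 0.5, 0, 0]
        assert mr.proportion_loss(a, b) != pytest.approx(mr.proportion_loss(b, a))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_nonnegative_zero_iff_equal(self, seed):
        rng = np.random.default_rng(seed)
        p, q = _random_simplex(rng), _random_simplex(rng)
        assert mr.proportion_loss(p, q) >= 0.0
        assert mr.proportion_loss(p, p) == pytest.approx(0.0, abs=1e-6)
        if np.abs(p - q).max() > 1e-3:
            assert mr.proportion_loss(p, q) > 0.0


class TestPseudoLabelSample:
    def test_degenerate_distribution(self):
        y = mr.pseudo_label_sample([1, 0, 0, 0], n=50, seed=0)
        assert (y[:, 0] == 1).all()

    def test_binomial_concentration(self):
        n = 10000
        y = mr.pseudo_label_sample([0.25] * 4, n=n, seed=1)
        freq = y.mean(axis=0)
        tol = 4 * np.sqrt(0.25 * 0.75 / n)
        assert (np.abs(freq - 0.25) < tol).all()

    def test_empty(self):
        assert mr.pseudo_label_sample([0.5, 0.5], n=0, seed=0).shape == (0, 2)


class TestCrossEntropy:
    def test_perfect_prediction_limit(self):
        assert mr.cross_entropy_loss([1 - 1e-12, 1e-12], [1, 0]) == pytest.approx(0, abs=1e-9)

    def test_uniform_is_ln_k(self):
        assert mr.cross_entropy_loss([0.25] * 4, [0, 1, 0, 0]) == pytest.approx(np.log(4))

    def test_decreases_with_confidence(self):
        lo = mr.cross_entropy_loss([0.25, 0.75], [1, 0])
        hi = mr.cross_entropy_loss([0.75, 0.25], [1, 0])
        assert hi < lo


@pytest.fixture(scope="module")
def sim():
    cfg = mr.FeatureSimConfig(D=16, K=4, separation=6.0, n_per_day=200, seed=5)
    X, days, cls = mr.generate_feature_dataset(cfg)
    return cfg, X, days, cls


class TestTraining:
    def test_zero_epochs_returns_initialization(self, sim):
        cfg, X, days, _ = sim
        model = mr.RecoveryPhaseClassifier(X, days, cfg.schedule)
        r0 = model.fit(epochs=0, seed=4)
        r1 = model.fit(epochs=0, seed=4)
        np.testing.assert_array_equal(r0.params.W1, r1.params.W1)
        assert len(r0.loss_trace) == 0

    def test_fixed_seed_identical_trace(self, sim):
        cfg, X, days, _ = sim
        model = mr.RecoveryPhaseClassifier(X, days, cfg.schedule)
        t1 = model.fit(loss_mode="llp", epochs=5, bag_size=16, seed=7).loss_trace
        t2 = model.fit(loss_mode="llp", epochs=5, bag_size=16, seed=7).loss_trace
        np.testing.assert_array_equal(t1, t2)

    def test_separable_llp_converges(self, sim):
        cfg, X, days, cls = sim
        model = mr.RecoveryPhaseClassifier(X, days, cfg.schedule)
        res = model.fit(loss_mode="llp", epochs=120, bag_size=16, seed=0)
        assert res.loss_trace[-1] < 0.05

    def test_pseudo_mode_decreases_loss(self, sim):
        cfg, X, days, _ = sim
        model = mr.RecoveryPhaseClassifier(X, days, cfg.schedule)
        res = model.fit(loss_mode="pseudo", epochs=30, seed=0)
        assert res.loss_trace[-1] < res.loss_trace[0]
        assert (res.loss_trace > 0).all()

    def test_unknown_loss_mode(self, sim):
        cfg, X, days, _ = sim
        model = mr.RecoveryPhaseClassifier(X, days, cfg.schedule)
        with pytest.raises(ValueError):
            model.fit(loss_mode="contrastive")

    def test_missing_day_proportion_rejected(self, sim):
        cfg, X, days, _ = sim
        props = {d: p for d, p in cfg.schedule.items() if d != 3}
        with pytest.raises(ValueError):
            mr.RecoveryPhaseClassifier(X, days, props)

    def test_save_load_round_trip(self, sim, tmp_path):
        cfg, X, days, _ = sim
        model = mr.RecoveryPhaseClassifier(X, days, cfg.schedule)
        res = model.fit(loss_mode="llp", epochs=3, bag_size=16, seed=0)
        res.save(tmp_path / "model.json")
        loaded = mr.RecoveryPhaseResults.load(tmp_path / "model.json")
        np.testing.assert_allclose(loaded.predict_proba(X[:5]), res.predict_proba(X[:5]))
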