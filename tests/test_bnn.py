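"""Variational network: reparameterized sampling, closed-form KL, the
hand-written backprop, and the deterministic (sigma = 0) limit against an
independently coded plain forward pass."""

import numpy as np
import pytest

from p300gomoku.bnn import (
    BayesianCNN, GaussianParam, TrainConfig, elbo_loss, kl_to_prior,
    predict_p300, recognize, sample_weight, softplus, softplus_inv, train,
)


def separable_toy(n=120, noise=1.0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(150)
    bump = 5 * np.exp(-0.5 * ((t - 87) / 12) ** 2)
    tmpl = bump[:, None] * np.linspace(0.1, 1.0, 30)[None, :]
    X = rng.normal(0, noise, (n, 150, 30))
    y = np.zeros(n, dtype=int)
    y[: n // 2] = 1
    X[: n // 2] += tmpl
    return X, y


class TestSampleWeight:
    def test_eps_zero_returns_mu(self):
        p = GaussianParam(mu=np.array([1.0, -2.0]), rho=np.array([0.5, 0.5]))
        np.testing.assert_array_equal(sample_weight(p, np.zeros(2)), p.mu)

    def test_eps_one_returns_mu_plus_sigma(self):
        p = GaussianParam(mu=np.array([1.0, -2.0]), rho=np.array([0.3, -1.0]))
        np.testing.assert_allclose(sample_weight(p, np.ones(2)),
                                   p.mu + softplus(p.rho))

    def test_shape_mismatch_rejected(self):
        p = GaussianParam(mu=np.zeros(3), rho=np.zeros(3))
        with pytest.raises(ValueError):
            sample_weight(p, np.zeros(4))

    def test_monte_carlo_moments(self, rng):
        mu, sigma = 0.7, 0.25
        p = GaussianParam(mu=np.array([mu]),
                          rho=np.array([softplus_inv(sigma)]))
        draws = np.array([
            sample_weight(p, rng.standard_normal(1))[0]
            for _ in range(100_000)
        ])
        assert draws.mean() == pytest.approx(mu, abs=3 * sigma / np.sqrt(1e5))
        assert draws.std() == pytest.approx(sigma, rel=0.05)


class TestKlToPrior:
    def test_zero_when_posterior_equals_prior(self):
        p = GaussianParam(mu=np.zeros(5),
                          rho=np.full(5, softplus_inv(0.3)))
        assert kl_to_prior(p, prior_sd=0.3) == pytest.approx(0.0, abs=1e-12)

    def test_unit_example(self):
        # mu=1, sigma=1, prior_sd=1: 0 + (1+1)/2 - 1/2 = 0.5
        p = GaussianParam(mu=np.array([1.0]),
                          rho=np.array([softplus_inv(1.0)]))
        assert kl_to_prior(p, 1.0) == pytest.approx(0.5)

    def test_nonnegative_on_random_params(self, rng):
        for _ in range(20):
            p = GaussianParam(mu=rng.normal(size=4),
                              rho=rng.normal(size=4))
            assert kl_to_prior(p, prior_sd=float(rng.uniform(0.1, 2))) >= 0

    def test_nonpositive_prior_sd_rejected(self):
        p = GaussianParam(mu=np.zeros(1), rho=np.zeros(1))
        with pytest.raises(ValueError):
            kl_to_prior(p, 0.0)

    def test_matches_monte_carlo_estimate(self, rng):
        """Closed form vs sample-based KL (1e5 draws) within 2%."""
        p = GaussianParam(mu=rng.normal(0, 0.5, 6),
                          rho=rng.normal(-1.5, 0.3, 6))
        prior_sd = 0.4
        closed = kl_to_prior(p, prior_sd)
        eps = rng.standard_normal((100_000, 6))
        w = p.mu + eps * softplus(p.rho)
        sigma = softplus(p.rho)
        log_q = -0.5 * ((w - p.mu) / sigma) ** 2 - np.log(sigma)
        log_p = -0.5 * (w / prior_sd) ** 2 - np.log(prior_sd)
        mc = float((log_q - log_p).sum(axis=1).mean())
        assert mc == pytest.approx(closed, rel=0.02)


def independent_point_forward(model, X):
    """Straightforward loop-based re-implementation of the point-weight
    forward pass (evaluation-mode batch norm), independent of the vectorized
    code under test."""
    def bn(x, g, b, rm, rv):
        return g * (x - rm) / np.sqrt(rv + 1e-5) + b

    def softmax(z):
        e = np.exp(z - z.max())
        return e / e.sum()

    mus = {k: p.mu for k, p in model.params.items()}
    out = []
    for x in X:
        b0 = model.bn0
        i0 = bn(x, b0.gamma[0], b0.beta[0], b0.running_mean[0],
                b0.running_var[0])
        c1 = np.zeros((150, 10))
        for f in range(10):
            for t in range(150):
                c1[t, f] = np.dot(i0[t], mus["w_spat"][f]) + mus["b_spat"][f]
            c1[:, f] = bn(c1[:, f], model.bn1.gamma[f], model.bn1.beta[f],
                          model.bn1.running_mean[f], model.bn1.running_var[f])
        c1 = np.maximum(c1, 0.0)
        m1 = np.zeros((75, 10))
        for f in range(10):
            for t in range(75):
                m1[t, f] = max(c1[2 * t, f], c1[2 * t + 1, f])
        c2 = np.zeros((10, 10))
        for g in range(10):
            for pos in range(10):
                s = mus["b_temp"][g]
                for dt in range(20):
                    for f in range(10):
                        s += m1[pos * 6 + dt, f] * mus["w_temp"][g, dt, f]
                c2[pos, g] = s
        for g in range(10):
            c2[:, g] = bn(c2[:, g], model.bn3.gamma[g], model.bn3.beta[g],
                          model.bn3.running_mean[g], model.bn3.running_var[g])
        c2 = np.maximum(c2, 0.0)
        h = c2.reshape(100)
        z4 = mus["w_fc1"] @ h + mus["b_fc1"]
        a4 = softmax(z4)
        z5 = mus["w_out"] @ a4 + mus["b_out"]
        out.append(softmax(z5))
    return np.array(out)


class TestForward:
    def test_probabilities_normalized(self, rng):
        model = BayesianCNN(seed=0)
        probs = model.forward(rng.normal(size=(5, 150, 30)),
                              rng=np.random.default_rng(1))
        assert probs.shape == (5, 2)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_wrong_shape_rejected(self, rng):
        model = BayesianCNN(seed=0)
        with pytest.raises(ValueError):
            model.forward(rng.normal(size=(5, 100, 30)))

    def test_internal_shapes(self, rng):
        """Pooling halves time to 75; the flattened temporal features number
        exactly 100 (10 positions x 10 filters)."""
        model = BayesianCNN(seed=0)
        _, cache = model.forward(rng.normal(size=(3, 150, 30)),
                                 rng=np.random.default_rng(0),
                                 return_cache=True)
        assert cache["m1"].shape == (3, 75, 10)
        assert cache["h"].shape == (3, 100)

    def test_sigma_zero_equals_independent_plain_cnn(self, rng):
        """Deterministic limit: the full vectorized pass agrees with a
        separately coded loop implementation on 20 random epochs."""
        model = BayesianCNN(seed=3, stochastic=False)
        # perturb BN parameters so the check is not trivial
        model.bn1.gamma = rng.uniform(0.5, 1.5, 10)
        model.bn1.beta = rng.normal(0, 0.2, 10)
        model.bn1.running_mean = rng.normal(0, 0.3, 10)
        model.bn1.running_var = rng.uniform(0.5, 2.0, 10)
        model.bn3.running_mean = rng.normal(0, 0.3, 10)
        model.bn3.running_var = rng.uniform(0.5, 2.0, 10)
        X = rng.normal(size=(20, 150, 30))
        fast = model.forward(X, training=False)
        slow = independent_point_forward(model, X)
        np.testing.assert_allclose(fast, slow, atol=1e-5)


class TestBackprop:
    def test_gradients_match_finite_differences(self, rng):
        model = BayesianCNN(seed=1)
        X = rng.normal(size=(6, 150, 30))
        y = rng.integers(0, 2, size=6)
        eps = model.draw_eps(np.random.default_rng(5))
        kl_w = 1.0 / 3

        _, cache = model.forward(X, eps=eps, training=True, return_cache=True)
        grads = model._backward(cache, y, kl_weight=kl_w)

        def loss_fn():
            probs = model.forward(X, eps=eps, training=True)
            ce = -np.sum(np.log(probs[np.arange(len(y)), y] + 1e-12))
            return ce + kl_w * model.kl()

        h = 1e-6
        entries = [(p.mu, f"mu:{n}") for n, p in model.params.items()]
        entries += [(p.rho, f"rho:{n}") for n, p in model.params.items()]
        for bnk, bn in (("bn0", model.bn0), ("bn1", model.bn1),
                        ("bn3", model.bn3)):
            entries += [(bn.gamma, f"{bnk}:gamma"), (bn.beta, f"{bnk}:beta")]
        for arr, key in entries:
            for _ in range(2):
                idx = tuple(int(rng.integers(0, s)) for s in arr.shape)
                orig = arr[idx]
                arr[idx] = orig + h
                lp = loss_fn()
                arr[idx] = orig - h
                lm = loss_fn()
                arr[idx] = orig
                numeric = (lp - lm) / (2 * h)
                analytic = grads[key][idx]
                assert numeric == pytest.approx(analytic, abs=2e-5, rel=1e-3), key


class TestElboAndTraining:
    def test_loss_equals_cross_entropy_when_posterior_is_prior(self, rng):
        model = BayesianCNN(seed=0, prior_sd=0.5)
        for p in model.params.values():
            p.mu[:] = 0.0
            p.rho[:] = softplus_inv(0.5)
        X = rng.normal(size=(4, 150, 30))
        y = np.array([0, 1, 0, 1])
        eps = {n: np.zeros(p.mu.shape) for n, p in model.params.items()}
        loss = elbo_loss(model, X, y, n_batches=2, eps=eps)
        probs = model.forward(X, eps=eps)
        ce = -np.sum(np.log(probs[np.arange(4), y] + 1e-12))
        assert loss == pytest.approx(ce, abs=1e-8)

    def test_loss_at_least_cross_entropy(self, rng):
        model = BayesianCNN(seed=2)
        X = rng.normal(size=(4, 150, 30))
        y = np.array([0, 1, 1, 0])
        eps = model.draw_eps(np.random.default_rng(0))
        loss = elbo_loss(model, X, y, n_batches=3, eps=eps)
        probs = model.forward(X, eps=eps)
        ce = -np.sum(np.log(probs[np.arange(4), y] + 1e-12))
        assert loss >= ce - 1e-12

    def test_empty_batch_rejected(self):
        model = BayesianCNN(seed=0)
        with pytest.raises(ValueError):
            elbo_loss(model, np.zeros((0, 150, 30)), np.zeros(0, dtype=int))

    def test_training_loss_decreases_on_separable_data(self):
        X, y = separable_toy()
        model = BayesianCNN(seed=0)
        trace = train(model, X, y, TrainConfig(n_epochs=10, seed=0))
        assert trace[-1] < trace[0]

    def test_training_reaches_full_accuracy_on_noiseless_data(self):
        """Template vs zeros with no noise: 100% within 20 epochs."""
        X, y = separable_toy(noise=0.0)
        X[y == 0] += 0.0
        model = BayesianCNN(seed=0)
        train(model, X, y, TrainConfig(n_epochs=20, seed=0))
        p = predict_p300(model, X, T=8, rng=1)
        assert np.mean((p > 0.5) == y) == 1.0

    def test_seed_determinism_of_training(self):
        X, y = separable_toy(n=60)
        cfg = TrainConfig(n_epochs=3, seed=7)
        t1 = train(BayesianCNN(seed=1), X, y, cfg)
        t2 = train(BayesianCNN(seed=1), X, y, cfg)
        t3 = train(BayesianCNN(seed=1), X, y,
                   TrainConfig(n_epochs=3, seed=8))
        assert t1 == t2
        assert t1 != t3

    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        X, y = separable_toy(n=60)
        model = BayesianCNN(seed=4)
        before = {k: v.copy() for k, v in model.state_dict().items()}
        train(model, X, y, TrainConfig(n_epochs=2, learning_rate=0.0, seed=0))
        after = model.state_dict()
        for k in before:
            if "running" in k:
                continue  # BN statistics update regardless of the optimizer
            np.testing.assert_array_equal(before[k], after[k])

    def test_small_dataset_falls_back_to_single_batch(self):
        X, y = separable_toy(n=20)
        model = BayesianCNN(seed=0)
        with pytest.warns(UserWarning, match="single batch"):
            train(model, X, y, TrainConfig(n_epochs=1, batch_size=85, seed=0))


class TestPrediction:
    def test_deterministic_model_invariant_to_T(self, rng):
        model = BayesianCNN(seed=0, stochastic=False)
        x = rng.normal(size=(1, 150, 30))
        p1 = predict_p300(model, x, T=1, rng=0)
        p5 = predict_p300(model, x, T=5, rng=1)
        assert p1[0] == pytest.approx(p5[0], abs=1e-12)

    def test_probability_in_unit_interval(self, rng):
        model = BayesianCNN(seed=0)
        p = predict_p300(model, rng.normal(size=(8, 150, 30)), T=3, rng=2)
        assert np.all((p >= 0) & (p <= 1))

    def test_invalid_T_rejected(self, rng):
        model = BayesianCNN(seed=0)
        with pytest.raises(ValueError):
            predict_p300(model, rng.normal(size=(1, 150, 30)), T=0)

    def test_monte_carlo_error_shrinks_like_inverse_sqrt_T(self, rng):
        """sd of the MC probability estimate at T=16 is ~half that at T=4."""
        model = BayesianCNN(seed=6)
        x = rng.normal(size=(1, 150, 30))
        sds = []
        for T in (4, 16):
            reps = [predict_p300(model, x, T=T, rng=1000 + r)[0]
                    for r in range(60)]
            sds.append(np.std(reps))
        ratio = sds[0] / sds[1]
        assert 2.0 * 0.7 < ratio < 2.0 * 1.3

    def test_recognize_single_candidate(self, rng):
        model = BayesianCNN(seed=0)
        assert recognize(model, rng.normal(size=(1, 150, 30)), T=2, rng=0) == 0

    def test_recognize_ties_break_to_lowest_index(self, rng):
        model = BayesianCNN(seed=0)
        x = rng.normal(size=(150, 30))
        cands = np.stack([x, x, x])
        assert recognize(model, cands, T=2, rng=3) == 0

    def test_recognize_is_argmax_of_probabilities(self, rng):
        """Invariant to any strictly increasing transform of the candidate
        probabilities: the choice is exactly their argmax."""
        model = BayesianCNN(seed=0)
        cands = rng.normal(size=(6, 150, 30))
        choice, probs = recognize(model, cands, T=4, rng=5, return_probs=True)
        assert choice == int(np.argmax(probs))
        assert choice == int(np.argmax(np.exp(3 * probs)))  # monotone map

    def test_empty_candidates_rejected(self):
        model = BayesianCNN(seed=0)
        with pytest.raises(ValueError):
            recognize(model, np.zeros((0, 150, 30)))


def test_checkpoint_round_trip(tmp_path, rng):
    model = BayesianCNN(seed=9)
    X = rng.normal(size=(3, 150, 30))
    ref = model.forward(X, eps={n: np.zeros(p.mu.shape)
                                for n, p in model.params.items()})
    prefix = str(tmp_path / "ckpt")
    model.save(prefix)
    loaded = BayesianCNN.load(prefix)
    out = loaded.forward(X, eps={n: np.zeros(p.mu.shape)
                                 for n, p in loaded.params.items()})
    np.testing.assert_allclose(out, ref, atol=1e-12)
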