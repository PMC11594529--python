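"""Flow machinery and amortized-posterior training/sampling contracts."""

import numpy as np
import pytest

from dmipost.flows import ConditionalMAF
from dmipost.npe_core import (
    AmortizedPosterior,
    EmbeddingConfig,
    FlowConfig,
    TrainConfig,
    log_density,
    posterior_predictive_check,
    sample_posterior,
    train,
)
from dmipost.simulation_engine import TrainingSet


def _toy_set(n=20_000, seed=0):
    """Conjugate-Gaussian toy: θ ~ N(0,1), x = θ + N(0, 0.5²); the
    posterior at observation x is N(0.8·x, 0.2)."""
    rng = np.random.default_rng(seed)
    theta = rng.standard_normal((n, 1))
    x = theta + 0.5 * rng.standard_normal((n, 1))
    return TrainingSet(theta=theta, x=x, model_name="toy", scheme=None,
                       snr=None, seed=seed)


@pytest.fixture(scope="module")
def toy_ap():
    return train(
        _toy_set(),
        EmbeddingConfig(n_features=1, hidden=(16, 16, 8)),
        FlowConfig(n_transforms=3, hidden=20),
        TrainConfig(max_epochs=30, patience=10, seed=1),
    )


@pytest.fixture(scope="module")
def bs_ap_micro():
    """Tiny Ball&Stick estimator for interface contracts (not accuracy)."""
    from dmipost.protocol_io import make_default_scheme
    from dmipost.simulation_engine import generate_training_set

    scheme = make_default_scheme()
    tset = generate_training_set("ball_stick", scheme, 15_000, None, seed=21)
    ap = train(
        tset, EmbeddingConfig(n_features=6), FlowConfig(),
        TrainConfig(max_epochs=12, patience=12, seed=3),
    )
    return ap, scheme


class TestFlowMachinery:
    def test_analytic_gradients_match_finite_differences(self):
        rng = np.random.default_rng(3)
        net = ConditionalMAF(dim=3, x_dim=7, n_features=4,
                             embed_hidden=(8, 6, 5), n_transforms=3,
                             flow_hidden=12, rng=rng)
        z = rng.standard_normal((9, 3))
        x = rng.standard_normal((9, 7))
        net.loss_and_grads(z, x)
        grads = {k: v.copy() for k, v in net._gstore.views.items()}
        for key in ("emb0_W", "f0_in_W", "f1_m_W", "f2_Ca", "f1_a_b"):
            P = net.params[key]
            idx = tuple(rng.integers(0, s) for s in P.shape)
            eps = 1e-2
            old = float(P[idx])
            P[idx] = old + eps
            lp = -net.log_prob(z, x).mean()
            P[idx] = old - eps
            lm = -net.log_prob(z, x).mean()
            P[idx] = old
            fd = (lp - lm) / (2 * eps)
            assert grads[key][idx] == pytest.approx(fd, rel=5e-2, abs=1e-4)

    def test_inverse_is_exact_inverse(self):
        rng = np.random.default_rng(5)
        net = ConditionalMAF(dim=4, x_dim=6, n_features=3,
                             embed_hidden=(8, 8, 8), n_transforms=5,
                             flow_hidden=16, rng=rng)
        c = net.embed(rng.standard_normal((7, 6)))
        u = rng.standard_normal((7, 4)).astype(np.float32)
        z = net._inverse(u, c)
        cur = z
        for k in range(net.K):
            cur, _, _ = net._block_forward(k, cur, c, want_cache=False)
        np.testing.assert_allclose(cur, u, atol=1e-4)

    def test_flow_concentrates_mass_relative_to_prior(self, toy_ap):
        """Flow samples score higher mean log-density than broad draws."""
        rng = np.random.default_rng(0)
        x = np.array([0.7])
        s_flow = sample_posterior(toy_ap, x, 1000, rng)
        s_broad = rng.uniform(-3, 3, (1000, 1))
        lp_flow = log_density(toy_ap, s_flow, x)
        lp_broad = log_density(toy_ap, s_broad, x)
        assert np.isfinite(lp_flow).all()
        assert lp_flow.mean() > lp_broad.mean()


class TestTraining:
    def test_deterministic_under_fixed_seed(self):
        tset = _toy_set(4000, seed=2)
        cfgs = (
            EmbeddingConfig(n_features=1, hidden=(8, 8, 8)),
            FlowConfig(n_transforms=2, hidden=10),
            TrainConfig(max_epochs=4, patience=4, seed=9),
        )
        a = train(tset, *cfgs)
        b = train(tset, *cfgs)
        assert a.history["val_loss"] == b.history["val_loss"]

    def test_training_improves_validation_loss(self):
        tset = _toy_set(6000, seed=3)
        ap = train(
            tset,
            EmbeddingConfig(n_features=1, hidden=(8, 8, 8)),
            FlowConfig(n_transforms=2, hidden=10),
            TrainConfig(max_epochs=6, patience=6, seed=4),
        )
        assert ap.history["best_val_loss"] < ap.history["val_loss"][0]

    def test_embedding_layer_count_enforced(self):
        with pytest.raises(ValueError, match="three"):
            EmbeddingConfig(hidden=(10, 10))

    def test_flow_without_embedding_conditions_on_features(self):
        """hidden=() drops the MLP: the flow conditions directly on the
        (standardized) feature vector, as used for precomputed summary
        statistics."""
        tset = _toy_set(8000, seed=6)
        ap = train(
            tset,
            EmbeddingConfig(hidden=()),
            FlowConfig(n_transforms=2, hidden=10),
            TrainConfig(max_epochs=10, patience=10, seed=2),
        )
        s = sample_posterior(ap, np.array([1.0]), 20_000,
                             np.random.default_rng(4))
        assert abs(s.mean() - 0.8) < 0.15

    def test_checkpoint_roundtrip(self, toy_ap, tmp_path):
        path = tmp_path / "ckpt.pkl"
        toy_ap.save(path)
        back = AmortizedPosterior.load(path)
        x = np.array([0.4])
        theta = np.array([[0.2]])
        assert log_density(back, theta, x) == pytest.approx(
            log_density(toy_ap, theta, x)
        )


class TestPosteriorContracts:
    def test_toy_posterior_matches_conjugate_closed_form(self, toy_ap):
        rng = np.random.default_rng(8)
        s = sample_posterior(toy_ap, np.array([1.0]), 50_000, rng)
        se = s.std() / np.sqrt(len(s))
        assert abs(s.mean() - 0.8) < max(3 * se, 0.08)
        assert s.var() == pytest.approx(0.2, rel=0.10)

    def test_density_normalizes_on_toy(self, toy_ap):
        grid = np.linspace(-5, 5, 2001)[:, None]
        ld = log_density(toy_ap, grid, np.array([0.5]))
        integral = np.trapezoid(np.exp(ld), grid[:, 0])
        assert integral == pytest.approx(1.0, abs=0.05)

    def test_samples_respect_prior_box(self, bs_ap_micro, rng):
        ap, scheme = bs_ap_micro
        from dmipost.simulation_engine import generate_training_set

        obs = generate_training_set("ball_stick", scheme, 1, None, seed=44).x[0]
        s = sample_posterior(ap, obs, 5000, rng)
        assert s.shape == (5000, 3)
        assert ap.prior.contains(s).all()
        assert ap.last_acceptance > 0.99

    def test_log_density_outside_bounds_is_minus_inf(self, bs_ap_micro):
        ap, scheme = bs_ap_micro
        x = np.ones(scheme.n_dw)
        assert log_density(ap, np.array([[1.5, 1.0, 1.0]]), x) == -np.inf
        assert log_density(ap, np.array([[0.5, 0.05, 1.0]]), x) == -np.inf

    def test_sampling_deterministic_given_rng_seed(self, toy_ap):
        a = sample_posterior(toy_ap, np.array([0.3]), 100,
                             np.random.default_rng(5))
        b = sample_posterior(toy_ap, np.array([0.3]), 100,
                             np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)


class TestPosteriorPredictiveCheck:
    def test_well_specified_observation_covered(self, bs_ap_micro):
        ap, scheme = bs_ap_micro
        from dmipost.forward_models import get_model
        from dmipost.simulation_engine import generate_training_set

        obs = generate_training_set("ball_stick", scheme, 1, None, seed=50).x[0]
        rep = posterior_predictive_check(
            ap, obs, get_model("ball_stick"), scheme, 400,
            np.random.default_rng(1), snr=50.0,
        )
        assert rep.inside.size == scheme.n_dw
        assert rep.coverage >= 0.9

    def test_gross_misfit_detected(self, bs_ap_micro):
        ap, scheme = bs_ap_micro
        from dmipost.forward_models import get_model

        rep = posterior_predictive_check(
            ap, np.zeros(scheme.n_dw), get_model("ball_stick"), scheme, 200,
            np.random.default_rng(2),
        )
        assert rep.coverage < 0.5
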