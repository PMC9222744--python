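import numpy as np
import pytest
from scipy.stats import norm

from nedsem.hgmm import (
    HGMMConfig,
    component_density,
    compute_g,
    data_log_likelihood,
    e_step,
    fit,
    init_state,
    log_likelihood,
    m_step,
)

from oracles import textbook_em


def bimodal(rng, n=400):
    x = np.concatenate([rng.normal(-2, 0.3, n // 2), rng.normal(2, 0.3, n // 2)])
    rng.shuffle(x)
    return x.reshape(20, -1)


def test_init_deterministic_and_brackets_modes(rng):
    x = bimodal(rng)
    cfg = HGMMConfig(k=2, seed=7)
    a = init_state(x, cfg)
    b = init_state(x, cfg)
    np.testing.assert_array_equal(a.mu, b.mu)
    np.testing.assert_array_equal(a.sigma, b.sigma)
    assert a.mu[0, 0] < -1 and a.mu[1, 0] > 1  # one initial mean per mode
    assert np.allclose(a.pi.sum(axis=1), 1.0)


def test_init_rejects_more_components_than_pixels():
    with pytest.raises(ValueError):
        init_state(np.zeros((2, 2)), HGMMConfig(k=5))


def test_config_validation():
    with pytest.raises(ValueError):
        HGMMConfig(k=0)
    with pytest.raises(ValueError):
        HGMMConfig(beta=-1)
    with pytest.raises(ValueError):
        HGMMConfig(conv_tol=0.0)


def test_component_density_reduces_to_gaussian(rng):
    state = init_state(bimodal(rng), HGMMConfig(k=2, r=1))
    for j in range(2):
        got = component_density(0.3, j, state)
        want = norm.pdf(0.3, loc=state.mu[j, 0], scale=np.sqrt(state.sigma[j, 0]))
        assert got == pytest.approx(want, rel=1e-12)


def test_component_density_degenerate_equal_subgaussians(rng):
    state = init_state(bimodal(rng), HGMMConfig(k=2, r=2))
    state.mu[:, 1] = state.mu[:, 0]
    state.sigma[:, 1] = state.sigma[:, 0]
    state.eta[:] = 0.5
    want = norm.pdf(0.1, loc=state.mu[0, 0], scale=np.sqrt(state.sigma[0, 0]))
    assert component_density(0.1, 0, state) == pytest.approx(want, rel=1e-12)


def test_component_density_matches_direct_summation(rng):
    state = init_state(rng.random((5, 5)), HGMMConfig(k=2, r=3, seed=0))
    state.eta = np.array([[0.2, 0.5, 0.3], [0.6, 0.1, 0.3]])
    want = sum(
        state.eta[1, r]
        * norm.pdf(0.4, loc=state.mu[1, r], scale=np.sqrt(state.sigma[1, r]))
        for r in range(3)
    )
    assert component_density(0.4, 1, state) == pytest.approx(want, rel=1e-10)


def test_e_step_symmetry_and_prior_override(rng):
    x = np.array([[0.0, 0.0]])
    state = init_state(x, HGMMConfig(k=2))
    state.mu = np.array([[-1.0], [1.0]])
    state.sigma = np.array([[0.5], [0.5]])
    z = e_step(x.ravel(), state)
    np.testing.assert_allclose(z, 0.5)
    state.pi = np.tile([1.0, 0.0], (2, 1))
    z = e_step(x.ravel(), state)
    np.testing.assert_allclose(z, np.tile([1.0, 0.0], (2, 1)), atol=1e-250)


def test_e_step_matches_bayes_rule_oracle(rng):
    x = rng.random(12)
    state = init_state(x.reshape(3, 4), HGMMConfig(k=3, seed=2))
    state.pi = rng.dirichlet(np.ones(3), size=12)
    z = e_step(x, state)
    dens = np.array([[component_density(xi, j, state) for j in range(3)] for xi in x])
    want = state.pi * dens
    want /= want.sum(axis=1, keepdims=True)
    np.testing.assert_allclose(z, want, atol=1e-12)
    np.testing.assert_allclose(z.sum(axis=1), 1.0)


def test_neighborhood_weights_beta_zero(rng):
    state = init_state(rng.random((4, 4)), HGMMConfig(k=2))
    g = compute_g(state, HGMMConfig(k=2, beta=0.0))
    np.testing.assert_array_equal(g, 1.0)


def test_neighborhood_weights_uniform_closed_form(rng):
    k, beta = 3, 1.5
    cfg = HGMMConfig(k=k, beta=beta)
    state = init_state(rng.random((5, 5)), cfg)
    state.z = np.full((25, k), 1.0 / k)
    state.pi = np.full((25, k), 1.0 / k)
    g = compute_g(state, cfg).reshape(5, 5, k)
    # interior pixel: all 8 neighbors contribute (1/k + 1/k)
    assert g[2, 2, 0] == pytest.approx(np.exp(beta / k), rel=1e-12)
    # corner pixel: 3 neighbors, but the average over |N_i| is unchanged
    assert g[0, 0, 0] == pytest.approx(np.exp(beta / k), rel=1e-12)


def test_neighborhood_truncation_at_border(rng):
    cfg = HGMMConfig(k=2, beta=2.0)
    state = init_state(rng.random((3, 3)), cfg)
    state.z = np.zeros((9, 2))
    state.z[:, 0] = 1.0
    state.pi = np.zeros((9, 2))
    state.pi[:, 0] = 1.0
    g = compute_g(state, cfg).reshape(3, 3, 2)
    # every neighbor contributes z+pi = 2; the normalized sum is the same
    # for the corner (3 neighbors) and the center (8 neighbors)
    assert g[0, 0, 0] == pytest.approx(np.exp(cfg.beta), rel=1e-12)
    assert g[1, 1, 0] == pytest.approx(np.exp(cfg.beta), rel=1e-12)
    assert g[1, 1, 1] == pytest.approx(1.0)


def test_m_step_hard_assignment_means(rng):
    x = np.array([0.0, 0.2, 1.0, 1.4])
    cfg = HGMMConfig(k=2)
    state = init_state(x.reshape(2, 2), cfg)
    state.z = np.array([[1, 0], [1, 0], [0, 1], [0, 1]], dtype=float)
    state.g = np.ones((4, 2))
    state = m_step(x, state, cfg)
    np.testing.assert_allclose(state.mu.ravel(), [0.1, 1.2])
    np.testing.assert_allclose(state.pi.sum(axis=1), 1.0)


def test_m_step_reseeds_empty_component(rng, caplog):
    x = rng.normal(0, 1, 16)
    cfg = HGMMConfig(k=2)
    state = init_state(x.reshape(4, 4), cfg)
    state.z = np.zeros((16, 2))
    state.z[:, 0] = 1.0  # component 1 empty
    state.g = np.ones((16, 2))
    state = m_step(x, state, cfg)
    assert np.isfinite(state.mu).all() and (state.sigma > 0).all()


def test_log_likelihood_single_pixel_single_class():
    x = np.array([0.7])
    state = init_state(x.reshape(1, 1), HGMMConfig(k=1))
    state.z = np.ones((1, 1))
    state.g = np.ones((1, 1))
    state.pi = np.ones((1, 1))
    want = np.log(component_density(0.7, 0, state))
    assert log_likelihood(x, state) == pytest.approx(want, rel=1e-12)


def test_log_likelihood_matches_direct_summation(rng):
    x = rng.random(9)
    cfg = HGMMConfig(k=2, seed=3)
    state = init_state(x.reshape(3, 3), cfg)
    state.z = rng.dirichlet(np.ones(2), size=9)
    state.g = rng.random((9, 2)) + 0.5
    want = 0.0
    for i in range(9):
        for j in range(2):
            d = component_density(x[i], j, state)
            want += state.z[i, j] * (np.log(state.pi[i, j]) + np.log(d))
            want += state.g[i, j] * np.log(state.pi[i, j])
    assert log_likelihood(x, state) == pytest.approx(want, rel=1e-10)


def test_fit_separable_two_regions(rng):
    x = np.zeros((10, 10))
    x[:, 5:] = 1.0
    x += rng.normal(0, 0.01, x.shape)
    state, labels = fit(x, HGMMConfig(k=2, beta=0.0, seed=0))
    truth = (np.arange(10)[None, :] >= 5).astype(int) * np.ones((10, 1), int)
    agreement = max((labels == truth).mean(), (labels == 1 - truth).mean())
    assert agreement == 1.0


def test_fit_single_class_converges_fast(rng):
    x = rng.normal(0, 1, (6, 6))
    state, labels = fit(x, HGMMConfig(k=1))
    assert np.all(labels == 0)
    assert state.converged and state.n_iter <= 2
    assert len(state.loglik_trace) == state.n_iter


def test_fit_deterministic_given_seed(rng):
    x = bimodal(rng)
    cfg = HGMMConfig(k=2, seed=11)
    s1, l1 = fit(x, cfg)
    s2, l2 = fit(x, cfg)
    np.testing.assert_array_equal(l1, l2)
    np.testing.assert_array_equal(s1.mu, s2.mu)


def test_fit_normalizations_every_iteration(rng):
    x = bimodal(rng)
    state, _ = fit(x, HGMMConfig(k=2, r=2, beta=1.0, seed=4), keep_history=True)
    for snap in state.history:
        np.testing.assert_allclose(snap["z"].sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(snap["pi"].sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(snap["eta"].sum(axis=1), 1.0, atol=1e-9)


def test_fit_label_permutation_invariance(rng):
    x = bimodal(rng)
    cfg = HGMMConfig(k=2, beta=1.0, seed=5)
    base = init_state(x, cfg)
    s1, l1 = fit(x, cfg, init=base.permuted([0, 1]))
    s2, l2 = fit(x, cfg, init=init_state(x, cfg).permuted([1, 0]))
    np.testing.assert_array_equal(l2, 1 - l1)
    np.testing.assert_allclose(s2.mu[::-1], s1.mu, atol=1e-9)


def test_shared_pi_reduction_matches_textbook_em(rng):
    x = bimodal(rng, n=600)
    cfg = HGMMConfig(k=2, beta=0.0, shared_pi=True, conv_tol=1e-5, max_iter=20)
    state, _ = fit(x, cfg, keep_history=True)
    ini = init_state(x, cfg)
    oracle = textbook_em(x, ini.mu.ravel(), ini.sigma.ravel(), ini.pi[0],
                         n_iter=len(state.history))
    for snap, (mu, var, pi, _) in zip(state.history, oracle):
        np.testing.assert_allclose(snap["mu"].ravel(), mu, atol=1e-6)
        np.testing.assert_allclose(snap["sigma"].ravel(), var, atol=1e-6)
        np.testing.assert_allclose(snap["pi"][0], pi, atol=1e-6)
    assert np.diff(state.data_loglik_trace).min() >= -1e-8


def test_fit_hierarchical_r2_recovers_bimodal_category(rng):
    """One K=1 category with R=2 sub-Gaussians should place its two
    sub-means near the two modes of a bimodal sample."""
    x = bimodal(rng, n=600)
    state, _ = fit(x, HGMMConfig(k=1, r=2, beta=0.0, seed=6, conv_tol=1e-4,
                                 max_iter=200))
    mus = np.sort(state.mu.ravel())
    assert mus[0] == pytest.approx(-2.0, abs=0.2)
    assert mus[1] == pytest.approx(2.0, abs=0.2)
    np.testing.assert_allclose(state.eta.sum(axis=1), 1.0)


def test_final_means_cross_checked_against_sklearn(rng):
    from sklearn.mixture import GaussianMixture

    x = bimodal(rng, n=800)
    state, _ = fit(x, HGMMConfig(k=2, beta=0.0, shared_pi=True,
                                 conv_tol=1e-6, max_iter=300))
    gm = GaussianMixture(2, random_state=0, tol=1e-8).fit(x.reshape(-1, 1))
    np.testing.assert_allclose(
        np.sort(state.mu.ravel()), np.sort(gm.means_.ravel()), atol=0.05
    )
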