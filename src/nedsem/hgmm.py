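"""MRF-regularized hierarchical Gaussian mixture model fitted by EM.

Each of the K pixel categories carries a density that is itself a mixture of
R univariate Gaussians,

    D_ij = f(x_i | category j) = Σ_r η_jr · G(x_i | μ_jr, Σ_jr),

and every pixel i has its own prior probability vector π_i· over categories.
Spatial coherence enters through a Markov-random-field prior on π: the
neighborhood weight

    g_ij = exp[ β / (2|N_i|) · Σ_{m ∈ N_i} (z_mj + π_mj) ]

(8-connected 3×3 neighborhood N_i, truncated at the image border) pulls a
pixel's prior toward the categories its neighbors favor, with smoothness
parameter β ≥ 0.  One EM sweep is

    E:  z_ij ∝ π_ij · D_ij
    g:  recompute neighborhood weights from fresh z and current π
    M:  μ, Σ (responsibility-weighted moments), η (nested responsibilities
        when R > 1), and π_ij ∝ z_ij + g_ij  — the MRF normalizing constant
        cancels in this self-normalizing update.

Iteration stops when the objective

    L = Σ_ij z_ij (log π_ij + log D_ij) + Σ_ij g_ij log π_ij

increases by less than ``conv_tol`` (default 0.1).  Labels are the per-pixel
posterior argmax.

With β = 0, R = 1 and ``shared_pi=True`` (a single global mixing-weight
vector updated as the mean responsibility) the sweep reduces exactly to
textbook GMM-EM, which is what the reduction tests check.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class HGMMConfig:
    k: int = 3                #: number of categories
    r: int = 1                #: Gaussians per category
    beta: float = 2.0         #: MRF smoothness, 0 = no spatial coupling
    w: float = 1.0            #: MRF prior weight (conventional value 1)
    conv_tol: float = 0.1     #: stop when the objective gains less than this
    max_iter: int = 100
    seed: int = 0
    shared_pi: bool = False   #: one global prior vector instead of per-pixel
    var_floor: float = 1e-8

    def __post_init__(self):
        if self.k < 1 or self.r < 1:
            raise ValueError("k and r must be >= 1")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.conv_tol <= 0 or self.max_iter < 1:
            raise ValueError("conv_tol must be > 0 and max_iter >= 1")


@dataclass
class HGMMState:
    """All mixture parameters plus posteriors and iteration bookkeeping."""

    pi: np.ndarray            # (N, K) per-pixel priors, rows sum to 1
    eta: np.ndarray           # (K, R) sub-component weights, rows sum to 1
    mu: np.ndarray            # (K, R) means
    sigma: np.ndarray         # (K, R) variances
    z: np.ndarray             # (N, K) posteriors
    g: np.ndarray             # (N, K) MRF neighborhood weights
    grid_shape: tuple[int, int]
    loglik_trace: list = field(default_factory=list)
    data_loglik_trace: list = field(default_factory=list)
    history: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False

    def permuted(self, perm) -> "HGMMState":
        """Return a copy with the K categories reordered by `perm`."""
        perm = np.asarray(perm)
        return HGMMState(
            pi=self.pi[:, perm].copy(), eta=self.eta[perm].copy(),
            mu=self.mu[perm].copy(), sigma=self.sigma[perm].copy(),
            z=self.z[:, perm].copy(), g=self.g[:, perm].copy(),
            grid_shape=self.grid_shape,
        )


def _as_flat(x) -> tuple[np.ndarray, tuple[int, int]]:
    values = getattr(x, "values", x)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected a 2-D feature matrix")
    return values.ravel(), values.shape


def init_state(x, cfg: HGMMConfig) -> HGMMState:
    """Deterministic seeded initialization.

    Category means start at the sorted centers of a seeded k-means run on
    the flattened feature (so they bracket the modes of any reasonably
    separated mixture even when the size of the modes is very unbalanced),
    jittered per sub-component; variances start at the global variance;
    priors are uniform.
    """
    flat, shape = _as_flat(x)
    n = flat.size
    if n < cfg.k:
        raise ValueError(f"need at least k={cfg.k} pixels, got {n}")
    rng = np.random.default_rng(cfg.seed)
    if flat.std() < 1e-12:
        labels = np.zeros(n, dtype=int)
        q = np.full(cfg.k, flat[0])
    else:
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=cfg.k, n_init=4, random_state=cfg.seed)
        labels = km.fit_predict(flat[:, None])
        order = np.argsort(km.cluster_centers_.ravel())
        q = km.cluster_centers_.ravel()[order]
        labels = np.argsort(order)[labels]  # relabel to sorted-center order
    spread = max(float(flat.std()), 1e-6)
    # sub-means spread over each category's own quantiles so that nested EM
    # starts off-symmetric and can split multimodal categories
    mu = np.empty((cfg.k, cfg.r))
    sub_q = (np.arange(cfg.r) + 0.5) / cfg.r
    for j in range(cfg.k):
        members = flat[labels == j]
        mu[j] = np.quantile(members, sub_q) if members.size else q[j]
    if cfg.r > 1:
        mu += 1e-3 * spread * rng.standard_normal((cfg.k, cfg.r))
    sigma = np.full((cfg.k, cfg.r), max(float(flat.var()), cfg.var_floor))
    pi = np.full((n, cfg.k), 1.0 / cfg.k)
    return HGMMState(
        pi=pi, eta=np.full((cfg.k, cfg.r), 1.0 / cfg.r), mu=mu, sigma=sigma,
        z=pi.copy(), g=np.ones((n, cfg.k)), grid_shape=shape,
    )


def _log_gauss(x: np.ndarray, mu: np.ndarray, var: np.ndarray) -> np.ndarray:
    # x: (N,), mu/var: (K, R) -> (N, K, R)
    d = x[:, None, None] - mu[None]
    return -0.5 * (d * d / var[None] + np.log(2.0 * np.pi * var[None]))


def _log_density(x: np.ndarray, state: HGMMState) -> np.ndarray:
    """log D_ij = log Σ_r η_jr G(x_i | μ_jr, Σ_jr), shape (N, K)."""
    lg = _log_gauss(x, state.mu, state.sigma)
    return logsumexp(lg + np.log(np.maximum(state.eta, _TINY))[None], axis=2)


def component_density(x_i: float, j: int, state: HGMMState) -> float:
    """Hierarchical category density D_ij for one sample value."""
    out = _log_density(np.atleast_1d(float(x_i)), state)
    return float(np.exp(out[0, j]))


def e_step(x: np.ndarray, state: HGMMState) -> np.ndarray:
    """Posterior responsibilities z_ij ∝ π_ij · D_ij (log-space, rows sum 1)."""
    log_post = np.log(np.maximum(state.pi, _TINY)) + _log_density(x, state)
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    return np.exp(log_post)


_NEIGH = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float)


def compute_g(state: HGMMState, cfg: HGMMConfig) -> np.ndarray:
    """MRF neighborhood weights from current z and π (β = 0 gives all ones)."""
    n, k = state.z.shape
    if cfg.beta == 0.0:
        return np.ones((n, k))
    h, w = state.grid_shape
    counts = ndimage.correlate(
        np.ones((h, w)), _NEIGH, mode="constant", cval=0.0
    )
    g = np.empty((n, k))
    for j in range(k):
        plane = (state.z[:, j] + state.pi[:, j]).reshape(h, w)
        s = ndimage.correlate(plane, _NEIGH, mode="constant", cval=0.0)
        g[:, j] = np.exp(cfg.beta / (2.0 * counts) * s).ravel()
    return g


def _reseed_empty(x, state, cfg, weights):
    """Re-seed any category with ~zero responsibility mass at the least
    explained data point."""
    for j in np.flatnonzero(weights < 1e-10):
        dens = np.exp(logsumexp(
            np.log(np.maximum(state.pi, _TINY)) + _log_density(x, state), axis=1
        ))
        idx = int(np.argmin(dens))
        logger.warning("re-seeding empty component %d at x=%g", j, x[idx])
        state.mu[j, :] = x[idx]
        state.sigma[j, :] = max(float(x.var()), cfg.var_floor)
        state.eta[j, :] = 1.0 / cfg.r
        state.z[:, j] = 1e-8
    return state


def m_step(x: np.ndarray, state: HGMMState, cfg: HGMMConfig) -> HGMMState:
    """Update μ, Σ, η and π from fresh z and g (in place, returns state)."""
    z = state.z
    nk = z.sum(axis=0)
    state = _reseed_empty(x, state, cfg, nk)
    z = state.z
    nk = np.maximum(z.sum(axis=0), _TINY)

    if cfg.r == 1:
        mu = (z.T @ x) / nk
        var = np.einsum("ij,ij->j", z, (x[:, None] - mu[None]) ** 2) / nk
        state.mu = mu[:, None]
        state.sigma = np.maximum(var, cfg.var_floor)[:, None]
    else:
        # nested responsibilities z_ijr = z_ij η_jr G_jr / D_ij
        lg = _log_gauss(x, state.mu, state.sigma)
        log_num = lg + np.log(np.maximum(state.eta, _TINY))[None]
        log_num -= logsumexp(log_num, axis=2, keepdims=True)
        zr = z[:, :, None] * np.exp(log_num)          # (N, K, R)
        wjr = np.maximum(zr.sum(axis=0), _TINY)       # (K, R)
        state.mu = np.einsum("nkr,n->kr", zr, x) / wjr
        dev2 = (x[:, None, None] - state.mu[None]) ** 2
        state.sigma = np.maximum(
            np.einsum("nkr,nkr->kr", zr, dev2) / wjr, cfg.var_floor
        )
        state.eta = wjr / nk[:, None]

    if cfg.shared_pi:
        state.pi = np.broadcast_to(nk / nk.sum(), z.shape).copy()
    else:
        num = z + state.g
        state.pi = num / num.sum(axis=1, keepdims=True)
    return state


def log_likelihood(x: np.ndarray, state: HGMMState) -> float:
    """MRF-augmented objective Σ z (log π + log D) + Σ g log π."""
    log_pi = np.log(np.maximum(state.pi, _TINY))
    log_d = _log_density(x, state)
    return float((state.z * (log_pi + log_d)).sum() + (state.g * log_pi).sum())


def data_log_likelihood(x: np.ndarray, state: HGMMState) -> float:
    """Incomplete-data log-likelihood Σ_i log Σ_j π_ij D_ij."""
    log_pi = np.log(np.maximum(state.pi, _TINY))
    return float(logsumexp(log_pi + _log_density(x, state), axis=1).sum())


def fit(x, cfg: HGMMConfig | None = None, init: HGMMState | None = None,
        keep_history: bool = False) -> tuple[HGMMState, np.ndarray]:
    """Run EM to convergence; return the state and the H×W label map.

    The label map is the per-pixel posterior argmax.  `init` lets callers
    start from a prepared (e.g. permuted) state; otherwise
    :func:`init_state` is used.  Deterministic given (x, cfg, init).
    """
    cfg = cfg or HGMMConfig()
    flat, shape = _as_flat(x)
    state = init if init is not None else init_state(x, cfg)

    prev = -np.inf
    for it in range(cfg.max_iter):
        state.z = e_step(flat, state)
        state.g = compute_g(state, cfg)
        state = m_step(flat, state, cfg)
        ll = log_likelihood(flat, state)
        state.loglik_trace.append(ll)
        state.data_loglik_trace.append(data_log_likelihood(flat, state))
        if keep_history:
            state.history.append({
                "mu": state.mu.copy(), "sigma": state.sigma.copy(),
                "pi": state.pi.copy(), "eta": state.eta.copy(),
                "z": state.z.copy(),
            })
        state.n_iter = it + 1
        if it > 0 and ll - prev < cfg.conv_tol:
            state.converged = True
            break
        prev = ll
    else:
        logger.warning("HGMM did not converge in %d iterations", cfg.max_iter)

    labels = np.argmax(state.z, axis=1).reshape(shape)
    return state, labels
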