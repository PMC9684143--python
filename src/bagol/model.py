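"""Probabilistic model and reference jump implementations.

The generative model: an unknown number K of static emitters at positions
mu_k, each optionally drifting linearly by a_k over the (normalized)
acquisition time.  Localization i, allocated to emitter Z_i, is a Gaussian
draw around mu_{Z_i} + a_{Z_i} * t_i with its own reported per-axis
precision.  The number of localizations produced by an emitter follows a
count prior: Poisson(lambda) (DNA-PAINT binding statistics) or a
gamma-mixed Poisson, i.e. negative binomial with shape eta and mean gamma
(dSTORM blinking, where eta = 1 gives a geometric law with mean gamma).
lambda itself can be learned hierarchically with a Gamma(eta, mean gamma)
hyperprior.

Priors: emitter positions are uniform over the analyzed region (area V);
drift components are zero-mean Gaussians with a weak 10 nm scale; the
prior over K is uniform, so model complexity is governed entirely by the
count prior through the allocation counts.

This module holds the readable numpy implementation of each reversible-jump
update (Move / Allocate / Birth / Death plus the hierarchical lambda step).
It defines the mathematical contract; `_kernels.py` implements the same
updates as fused numba loops for production runs, and the two are
cross-checked in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import gammaln, logsumexp

from .data import LocalizationSet


@dataclass
class SamplerConfig:
    """Tunable parameters of the reversible-jump sampler.

    Attributes
    ----------
    p_move, p_allocate, p_birth, p_death : float
        Jump-type selection probabilities (must sum to 1).
    n_samples : int
        Post-burn-in chain length (one recorded state per iteration).
    n_burnin : int or None
        Burn-in iterations; defaults to ``n_samples``.
    xi_mode : {'fixed', 'hierarchical'}
        Whether the mean localizations-per-emitter lambda is held at ``xi``
        or sampled under a Gamma(eta, mean gamma) hyperprior.
    xi : float
        Fixed lambda, and the initial value in hierarchical mode.
    xi_prior_eta, xi_prior_gamma : float
        Shape eta and mean gamma of the gamma (hyper)prior; eta = 1 makes
        it an exponential with mean gamma.
    xi_stride : int
        Reversible-jump iterations between consecutive lambda updates.
    xi_proposal_sd : float
        Log-scale random-walk step for the lambda Metropolis update.
    count_model : {'poisson', 'gamma_poisson'}
        Per-emitter localization-count prior.  'gamma_poisson' marginalizes
        a per-emitter rate over Gamma(eta, mean gamma), i.e. a negative
        binomial; used for dSTORM.
    drift_enabled : bool
        Estimate a per-emitter linear drift vector.
    drift_prior_sd : float, nm
        Scale of the zero-mean Gaussian drift prior.
    rng_seed : int
        Seed for the single RNG driving jump selection and all draws.
    k_max : int or None
        Hard cap on K (births beyond it are rejected); defaults to a
        generous multiple of the initial K.
    """

    p_move: float = 0.25
    p_allocate: float = 0.25
    p_birth: float = 0.25
    p_death: float = 0.25
    n_samples: int = 1000
    n_burnin: int = None
    xi_mode: str = "hierarchical"
    xi: float = 50.0
    xi_prior_eta: float = 1.0
    xi_prior_gamma: float = 5.0
    xi_stride: int = 10
    xi_proposal_sd: float = 0.05
    count_model: str = "poisson"
    drift_enabled: bool = False
    drift_prior_sd: float = 10.0
    rng_seed: int = 0
    k_max: int = None

    def __post_init__(self):
        probs = (self.p_move, self.p_allocate, self.p_birth, self.p_death)
        if any(p < 0 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError("jump probabilities must be non-negative and sum to 1")
        if self.xi_mode not in ("fixed", "hierarchical"):
            raise ValueError(f"unknown xi_mode {self.xi_mode!r}")
        if self.count_model not in ("poisson", "gamma_poisson"):
            raise ValueError(f"unknown count_model {self.count_model!r}")
        if self.xi_mode == "hierarchical" and self.count_model != "poisson":
            raise ValueError("hierarchical xi requires the poisson count model")
        if self.xi <= 0 or self.xi_prior_eta <= 0 or self.xi_prior_gamma <= 0:
            raise ValueError("xi, eta and gamma must be positive")

    @property
    def burnin(self):
        return self.n_samples if self.n_burnin is None else self.n_burnin


@dataclass
class ModelState:
    """One sampler state: K emitters, positions, drifts, allocations, lambda."""

    mu: np.ndarray          # (K, 2) nm
    a: np.ndarray           # (K, 2) nm per unit normalized time
    Z: np.ndarray           # (N,) emitter index of each localization
    xi: float               # current mean-localizations-per-emitter lambda

    def __post_init__(self):
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float)) \
            if np.size(self.mu) else np.empty((0, 2))
        self.a = np.atleast_2d(np.asarray(self.a, dtype=float)) \
            if np.size(self.a) else np.empty((0, 2))
        self.Z = np.asarray(self.Z, dtype=np.int64)

    @property
    def K(self):
        return self.mu.shape[0]

    def counts(self):
        return np.bincount(self.Z, minlength=self.K) if self.K else \
            np.zeros(0, dtype=np.int64)

    def validate(self, n_data):
        if self.mu.shape != (self.K, 2) or self.a.shape != (self.K, 2):
            raise ValueError("mu and a must both be (K, 2)")
        if self.Z.size != n_data:
            raise ValueError("Z must have one entry per localization")
        if self.K == 0 and n_data > 0:
            raise ValueError("empty model with non-empty data")
        if n_data and (self.Z.min() < 0 or self.Z.max() >= self.K):
            raise ValueError("allocation to nonexistent emitter")

    def copy(self):
        return ModelState(self.mu.copy(), self.a.copy(), self.Z.copy(), self.xi)


# ---------------------------------------------------------------------------
# densities
# ---------------------------------------------------------------------------

def count_logpmf(n, config, xi=None):
    """Log pmf of the per-emitter localization count under the count prior."""
    n = np.asarray(n, dtype=float)
    if config.count_model == "poisson":
        lam = config.xi if xi is None else xi
        return n * np.log(lam) - lam - gammaln(n + 1.0)
    eta, gam = config.xi_prior_eta, config.xi_prior_gamma
    return (gammaln(n + eta) - gammaln(eta) - gammaln(n + 1.0)
            + eta * np.log(eta / (eta + gam)) + n * np.log(gam / (eta + gam)))


def count_allocation_logterm(n, config, xi=None):
    """Per-emitter term of the allocation prior, log[P(n) * n!].

    Emitters generate unordered sets of localizations, so the prior over a
    labeled allocation vector Z with counts {n_k} is
    prod_k P(n_k) * n_k! / N!; the N! is common to all allocations and
    cancels from every Metropolis ratio.  For Poisson counts this term is
    simply n log(lam) - lam.
    """
    return count_logpmf(n, config, xi) + gammaln(np.asarray(n, float) + 1.0)


def _log_density_matrix(state, data):
    """(N, K) matrix of log N(x_i | mu_k + a_k t_i, sigma_i^2) per axis sum."""
    t = data.t_normalized()
    mx = state.mu[:, 0][None, :] + state.a[:, 0][None, :] * t[:, None]
    my = state.mu[:, 1][None, :] + state.a[:, 1][None, :] * t[:, None]
    wx = 1.0 / data.sigma_x ** 2
    wy = 1.0 / data.sigma_y ** 2
    dx = data.x[:, None] - mx
    dy = data.y[:, None] - my
    return (-0.5 * (wx[:, None] * dx ** 2 + wy[:, None] * dy ** 2)
            - np.log(2.0 * np.pi * data.sigma_x * data.sigma_y)[:, None])


def log_likelihood(state, data):
    """Gaussian log likelihood of the data under the current allocation."""
    state.validate(len(data))
    if len(data) == 0:
        return 0.0
    logf = _log_density_matrix(state, data)
    return float(logf[np.arange(len(data)), state.Z].sum())


def move_conditional(values, weights, t, drift_enabled, drift_prior_sd):
    """Closed-form Gaussian conditional of (mu, a) along one axis.

    With weights w_i = 1/sigma_i^2 the conditional posterior of the
    position (and drift, when enabled) is Gaussian with precision matrix
    [[sum w, sum w t], [sum w t, sum w t^2 + 1/tau^2]].

    Returns (mean, cov) with 2-vectors/2x2 matrices; without drift the
    second component is pinned at 0 with zero variance.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    t = np.asarray(t, dtype=float)
    sw = weights.sum()
    if not drift_enabled:
        mean = np.array([np.dot(weights, values) / sw, 0.0])
        cov = np.array([[1.0 / sw, 0.0], [0.0, 0.0]])
        return mean, cov
    tau2 = drift_prior_sd ** 2
    p11 = sw
    p12 = np.dot(weights, t)
    p22 = np.dot(weights, t ** 2) + 1.0 / tau2
    b1 = np.dot(weights, values)
    b2 = np.dot(weights, values * t)
    det = p11 * p22 - p12 ** 2
    mean = np.array([(p22 * b1 - p12 * b2) / det,
                     (p11 * b2 - p12 * b1) / det])
    cov = np.array([[p22, -p12], [-p12, p11]]) / det
    return mean, cov


# ---------------------------------------------------------------------------
# jumps (reference implementations)
# ---------------------------------------------------------------------------

def move_update(state, data, config, box, rng):
    """Gibbs update of all emitter positions (and drifts).

    Each emitter's (mu_k, a_k) is drawn from its exact Gaussian conditional
    posterior given the current allocation, so the jump is always accepted.
    Emitters with no allocated localizations draw their position from the
    flat prior over the region and have their drift reset to zero.
    """
    state = state.copy()
    t = data.t_normalized()
    counts = state.counts()
    for k in range(state.K):
        members = state.Z == k
        if counts[k] == 0:
            state.mu[k, 0] = rng.uniform(box[0], box[1])
            state.mu[k, 1] = rng.uniform(box[2], box[3])
            state.a[k] = 0.0
            continue
        for axis, (vals, sig) in enumerate(
                [(data.x, data.sigma_x), (data.y, data.sigma_y)]):
            mean, cov = move_conditional(vals[members],
                                         1.0 / sig[members] ** 2,
                                         t[members],
                                         config.drift_enabled,
                                         config.drift_prior_sd)
            if config.drift_enabled:
                L = np.linalg.cholesky(cov + 1e-15 * np.eye(2))
                draw = mean + L @ rng.standard_normal(2)
                state.mu[k, axis], state.a[k, axis] = draw
            else:
                state.mu[k, axis] = rng.normal(mean[0], np.sqrt(cov[0, 0]))
                state.a[k, axis] = 0.0
    return state


def _propose_allocation(logf, rng):
    """Draw Z_i independently from q(Z_i = k) proportional to the likelihood."""
    n, k = logf.shape
    g = rng.gumbel(size=(n, k))
    return np.argmax(logf + g, axis=1)


def allocate_update(state, data, config, rng):
    """Metropolis-Hastings reallocation of every localization.

    The proposal draws each Z_i from the likelihood-weighted categorical;
    the Hastings correction then reduces to the ratio of count priors over
    the old and new per-emitter counts.
    """
    if state.K < 1:
        raise ValueError("allocate requires at least one emitter")
    state = state.copy()
    logf = _log_density_matrix(state, data)
    z_new = _propose_allocation(logf, rng)
    n_old = state.counts()
    n_new = np.bincount(z_new, minlength=state.K)
    dlog = float(count_allocation_logterm(n_new, config, state.xi).sum()
                 - count_allocation_logterm(n_old, config, state.xi).sum())
    accepted = math.log(rng.uniform()) < dlog
    if accepted:
        state.Z = z_new
    return state, accepted


def _birth_density(pos, data, box):
    """Density of the birth position proposal: 50:50 uniform / data-centered."""
    V = (box[1] - box[0]) * (box[3] - box[2])
    wx = 1.0 / data.sigma_x ** 2
    wy = 1.0 / data.sigma_y ** 2
    g = (np.sqrt(wx * wy) / (2.0 * np.pi)
         * np.exp(-0.5 * (wx * (pos[0] - data.x) ** 2
                          + wy * (pos[1] - data.y) ** 2)))
    return 0.5 / V + 0.5 * g.mean()


def _alloc_log_normalizers(logf):
    """log sum_k f_ik per localization (log row normalizers)."""
    return logsumexp(logf, axis=1)


def birth_update(state, data, config, box, rng):
    """Propose adding an emitter and redistributing all localizations.

    The new position is drawn from a 50:50 mixture of the uniform prior and
    a Gaussian centered on a randomly chosen localization (with that
    localization's variance); the allocation is then redrawn from the
    likelihood-weighted proposal.  Accepted with the reversible-jump ratio;
    the likelihood and proposal terms collapse to a product of row-
    normalizer ratios.
    """
    k_max = config.k_max or np.inf
    if state.K + 1 > k_max:
        return state, False
    state_new = state.copy()
    V = (box[1] - box[0]) * (box[3] - box[2])

    if rng.uniform() < 0.5:
        pos = np.array([rng.uniform(box[0], box[1]), rng.uniform(box[2], box[3])])
    else:
        i = rng.integers(len(data))
        pos = np.array([rng.normal(data.x[i], data.sigma_x[i]),
                        rng.normal(data.y[i], data.sigma_y[i])])
    if not (box[0] <= pos[0] <= box[1] and box[2] <= pos[1] <= box[3]):
        return state, False  # outside the prior support
    if config.drift_enabled:
        a_new = rng.normal(0.0, config.drift_prior_sd, size=2)
    else:
        a_new = np.zeros(2)

    state_new.mu = np.vstack([state.mu, pos])
    state_new.a = np.vstack([state.a, a_new])

    logf_old = _log_density_matrix(state, data)
    logf_new = _log_density_matrix(state_new, data)
    z_new = _propose_allocation(logf_new, rng)
    state_new.Z = z_new

    log_ratio_c = float((_alloc_log_normalizers(logf_new)
                         - _alloc_log_normalizers(logf_old)).sum())
    dcount = float(count_allocation_logterm(state_new.counts(), config,
                                            state.xi).sum()
                   - count_allocation_logterm(state.counts(), config,
                                              state.xi).sum())
    b = _birth_density(pos, data, box)
    log_a = (log_ratio_c + dcount - math.log(V)
             + math.log(config.p_death) - math.log(config.p_birth)
             - math.log(b))
    accepted = math.log(rng.uniform()) < log_a
    return (state_new, True) if accepted else (state, False)


def death_update(state, data, config, box, rng):
    """Propose removing a uniformly chosen emitter (reverse of Birth).

    Death from K = 1 is auto-rejected for non-empty data: the empty model
    cannot explain any localization.
    """
    if state.K <= 1:
        return state, False
    V = (box[1] - box[0]) * (box[3] - box[2])
    j = int(rng.integers(state.K))
    keep = np.arange(state.K) != j
    state_new = ModelState(state.mu[keep], state.a[keep],
                           np.zeros(len(data), dtype=np.int64), state.xi)

    logf_old = _log_density_matrix(state, data)
    logf_new = _log_density_matrix(state_new, data)
    z_new = _propose_allocation(logf_new, rng)
    state_new.Z = z_new

    log_ratio_c = float((_alloc_log_normalizers(logf_new)
                         - _alloc_log_normalizers(logf_old)).sum())
    dcount = float(count_allocation_logterm(state_new.counts(), config,
                                            state.xi).sum()
                   - count_allocation_logterm(state.counts(), config,
                                              state.xi).sum())
    b = _birth_density(state.mu[j], data, box)
    log_a = (log_ratio_c + dcount + math.log(V)
             + math.log(config.p_birth) - math.log(config.p_death)
             + math.log(b))
    accepted = math.log(rng.uniform()) < log_a
    return (state_new, True) if accepted else (state, False)


def xi_update(state, config, rng):
    """Metropolis update of lambda under the gamma hyperprior.

    Log-normal random walk proposal; the target is
    Gamma(lambda; shape eta, mean gamma) x prod_k Poisson(n_k; lambda).
    """
    if config.xi_mode != "hierarchical":
        return state, False
    state = state.copy()
    counts = state.counts()
    eta, gam = config.xi_prior_eta, config.xi_prior_gamma
    rate = eta / gam

    def log_target(lam):
        return ((eta - 1.0) * math.log(lam) - rate * lam
                + float(np.sum(counts * math.log(lam) - lam)))

    lam_old = state.xi
    lam_new = lam_old * math.exp(rng.normal(0.0, config.xi_proposal_sd))
    # log-normal proposal: Hastings ratio contributes lam_new / lam_old
    log_a = (log_target(lam_new) - log_target(lam_old)
             + math.log(lam_new) - math.log(lam_old))
    accepted = math.log(rng.uniform()) < log_a
    if accepted:
        state.xi = lam_new
    return state, accepted
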