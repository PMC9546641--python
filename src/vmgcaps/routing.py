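"""Routing-by-agreement via variational-Bayes Gaussian mixture updates.

Each higher-level capsule k is one diagonal-precision Gaussian component;
the votes x_{k|n} cast by lower capsules for capsule k are the data that
component must explain. Routing alternates the mixture's E-step (soft
responsibilities r_nk over higher capsules, computed in the log domain) with
the conjugate M-step, where lower-capsule activations enter as per-point
weights a_n * r_nk. After the final update the evidence lower bound is split
into per-capsule shares L_k, and capsule k's activation is the sigmoid of
(L_k - beta_a_k) scaled by an inverse temperature: a capsule switches on
when its component explains its votes well enough to pay the fixed cost
beta_a.

Everything here operates on :class:`~vmgcaps.autodiff.Tensor` objects and is
differentiable end-to-end with respect to votes, lower activations, beta_a
and the routing prior mean; the capsule network trains through it. The
formulas are the diagonal-mode versions of :mod:`vmgcaps.vbgmm` (a shared-
code property the test suite checks numerically). The M-step is written in
"raw moment" form -- W_k^{-1} = W0^{-1} + sum_n w_nk v^2 + beta0 mu0^2
- (beta0 mu0 + t_k)^2 / (beta0 + y_k), with t_k the weighted vote sum -- which
is algebraically identical to the scatter form but has no 0/0 when a
component receives zero effective weight, so an empty capsule falls back to
its prior exactly and gradients stay finite.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import special

from . import autodiff as ad
from .autodiff import Tensor
from .vbgmm import InvalidInputError, PriorHyperparams

__all__ = ["VoteTensor", "RoutingConfig", "RoutingResult", "route",
           "route_batched", "capsule_activation"]

_LOG2 = math.log(2.0)
_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class VoteTensor:
    """Votes x_{k|n} in R^D from n lower capsules for K higher capsules
    (D = 16: flattened 4x4 pose predictions), with lower activations a_n."""

    votes: np.ndarray                 # (n_lower, K, D)
    lower_activations: np.ndarray     # (n_lower,)

    def __post_init__(self):
        self.votes = np.asarray(self.votes, dtype=np.float64)
        self.lower_activations = np.asarray(self.lower_activations,
                                            dtype=np.float64)
        if self.votes.ndim != 3:
            raise InvalidInputError("votes must be (n_lower, K, D)")
        if not np.all(np.isfinite(self.votes)):
            raise InvalidInputError("votes must be finite")
        n = self.votes.shape[0]
        if self.lower_activations.shape != (n,):
            raise InvalidInputError("one activation per lower capsule")
        if np.any((self.lower_activations < 0) | (self.lower_activations > 1)):
            raise InvalidInputError("activations must lie in [0, 1]")


@dataclass
class RoutingConfig:
    """Routing hyperparameters: iteration count, activation cost beta_a
    (scalar or per higher capsule), inverse temperature, diagonal priors."""

    n_iters: int = 3
    beta_a: float | np.ndarray = 0.0
    inv_temperature: float = 1.0
    priors: PriorHyperparams | None = None

    def __post_init__(self):
        if self.n_iters < 1:
            raise InvalidInputError("n_iters >= 1 required")
        if self.inv_temperature <= 0:
            raise InvalidInputError("inv_temperature must be positive")


@dataclass
class RoutingResult:
    """Higher-capsule poses, diagonal precisions, ELBO-derived activations."""

    poses: np.ndarray             # (K, D) posterior means mu_k
    precisions: np.ndarray        # (K, D) lambda_k = nu_k * w_kd
    activations: np.ndarray       # (K,) in (0, 1)
    responsibilities: np.ndarray  # (n_lower, K)
    per_capsule_elbo: np.ndarray  # (K,)

    def to_json(self) -> str:
        return json.dumps({k: np.asarray(v).tolist()
                           for k, v in self.__dict__.items()})


def capsule_activation(elbo_k, beta_a_k, inv_temperature: float = 1.0):
    """a_k = sigmoid(inv_temperature * (L_k - beta_a_k)); works on floats,
    arrays and Tensors."""
    if isinstance(elbo_k, Tensor) or isinstance(beta_a_k, Tensor):
        return ad.sigmoid((ad.astensor(elbo_k) - ad.astensor(beta_a_k))
                          * inv_temperature)
    return special.expit(inv_temperature * (np.asarray(elbo_k, dtype=float)
                                            - np.asarray(beta_a_k, dtype=float)))


def _expected_log_lambda(nu: Tensor, logW_sum: Tensor, D: int) -> Tensor:
    """E[ln|Lambda_k|] = sum_i psi((nu_k+1-i)/2) + D ln 2 + ln|W_k|.

    ``nu`` has shape (M, K); the digamma arguments are built per dimension.
    """
    M, K = nu.shape
    i = np.arange(1, D + 1, dtype=np.float64)
    args = (nu.reshape(M, K, 1) + Tensor(1.0 - i)) * 0.5
    return ad.tsum(ad.digamma(args), axis=2) + D * _LOG2 + logW_sum


def _log_wishart_B_diag(log_w: Tensor, nu: Tensor, D: int) -> Tensor:
    """ln B(W, nu) for diagonal W: log_w = sum_d ln w_kd, shapes (M, K)."""
    M, K = nu.shape
    i = np.arange(1, D + 1, dtype=np.float64)
    args = (nu.reshape(M, K, 1) + Tensor(1.0 - i)) * 0.5
    mg = ad.tsum(ad.gammaln(args), axis=2) + (D * (D - 1) / 4.0) * math.log(math.pi)
    return (-0.5 * nu) * log_w - (nu * (D / 2.0)) * _LOG2 - mg


def route_batched(votes: Tensor, lower_activations: Tensor, *,
                  n_iters: int = 3,
                  alpha0: float | None = None, beta0: float = 1.0,
                  mu0: Tensor | np.ndarray | float = 0.0,
                  w0: float = 1.0, nu0: float | None = None,
                  beta_a: Tensor | np.ndarray | float = 0.0,
                  inv_temperature: float = 1.0,
                  rng: np.random.Generator | None = None) -> dict:
    """Run VMG routing on a batch of routing problems.

    Parameters
    ----------
    votes
        Tensor of shape (M, n, K, D): M independent routing problems
        (batch x spatial positions), n lower capsules, K higher capsules.
    lower_activations
        Tensor of shape (M, n) in [0, 1].
    alpha0, beta0, mu0, w0, nu0
        Diagonal Gaussian--Wishart/Dirichlet prior; defaults alpha0=1/K,
        w0=1 (isotropic), nu0=D+1. ``mu0`` may be a scalar, a (D,) vector or
        a (K, D) per-capsule prior mean (possibly a trainable Parameter).
    beta_a, inv_temperature
        Activation cost (scalar or (K,), possibly trainable) and the fixed
        inverse temperature of the activation sigmoid.
    rng
        When given, the returned pose of every higher capsule is a draw from
        its variational posterior N(m_k, (beta_k Lambda-bar_k)^{-1}) with
        Lambda-bar_kd = nu_k w_kd, and the per-capsule ELBO (hence the
        activation) is evaluated at the sampled pose. Used for stochastic
        predictive runs; leave None for the deterministic mean pass.

    Returns
    -------
    dict with Tensors: ``poses`` (M,K,D), ``precisions`` (M,K,D),
    ``activations`` (M,K), ``responsibilities`` (M,n,K),
    ``per_capsule_elbo`` (M,K).
    """
    M, n, K, D = votes.shape
    if lower_activations.shape != (M, n):
        raise InvalidInputError("activation shape must match votes")
    if alpha0 is None:
        alpha0 = 1.0 / K
    if nu0 is None:
        nu0 = float(D + 1)

    mu0_t = ad.astensor(mu0)
    if mu0_t.ndim == 0:
        mu0_t = mu0_t.reshape(1, 1, 1)
    elif mu0_t.ndim == 1:
        mu0_t = mu0_t.reshape(1, 1, D)
    else:
        mu0_t = mu0_t.reshape(1, K, D)
    a = lower_activations.reshape(M, n, 1)

    # prior-initialized state; the first E-step already discriminates because
    # each component k scores its own votes x_{k|n}
    ones_MK = Tensor(np.ones((M, K)))
    alpha = ones_MK * alpha0
    beta = ones_MK * beta0
    nu = ones_MK * nu0
    m = mu0_t * Tensor(np.ones((M, K, D)))
    log_w = ones_MK * (D * math.log(w0))      # sum_d ln w_kd for W = w0 I
    w_diag = Tensor(np.full((M, K, D), w0))

    r = None
    for _ in range(n_iters):
        # ---- E-step (log domain) ----
        loglam = _expected_log_lambda(nu, log_w, D)          # (M, K)
        logpi = ad.digamma(alpha) - ad.digamma(ad.tsum(alpha, axis=1,
                                                       keepdims=True))
        quad = ad.weighted_sq_dist(votes, m, w_diag)          # (M, n, K)
        mahal = (D / beta).reshape(M, 1, K) + nu.reshape(M, 1, K) * quad
        log_rho = (logpi.reshape(M, 1, K) + 0.5 * loglam.reshape(M, 1, K)
                   - 0.5 * D * _LOG2PI - 0.5 * mahal)
        log_r = log_rho - ad.logsumexp(log_rho, axis=2, keepdims=True)
        r = ad.exp(log_r)                                     # (M, n, K)

        # ---- M-step with activation weights w_nk = a_n r_nk ----
        w_nk = a * r                                          # (M, n, K)
        y = ad.tsum(w_nk, axis=1)                             # (M, K)
        t = ad.weighted_moment(w_nk, votes, 1)                # (M, K, D)
        sq = ad.weighted_moment(w_nk, votes, 2)
        alpha = alpha0 + y
        beta = beta0 + y
        nu = nu0 + y
        m = (beta0 * mu0_t + t) / beta.reshape(M, K, 1)
        w_inv = (1.0 / w0 + sq + beta0 * mu0_t * mu0_t
                 - ((beta0 * mu0_t + t) * (beta0 * mu0_t + t))
                 / beta.reshape(M, K, 1))
        w_diag = 1.0 / w_inv
        log_w = -ad.tsum(ad.log(w_inv), axis=2)               # sum_d ln w_kd

    pose = m
    if rng is not None:
        prec = beta.reshape(M, K, 1) * nu.reshape(M, K, 1) * w_diag
        eps = Tensor(rng.standard_normal((M, K, D)))
        pose = m + eps / ad.sqrt(prec)

    elbo_k = _per_capsule_elbo(votes, a, r, log_r, y, t, sq, alpha, beta,
                               pose, m, w_diag, log_w, nu,
                               alpha0=alpha0, beta0=beta0, mu0=mu0_t, w0=w0,
                               nu0=nu0, D=D, n=n)
    act = capsule_activation(elbo_k, ad.astensor(beta_a), inv_temperature)
    lam = nu.reshape(M, K, 1) * w_diag
    return {"poses": pose, "precisions": lam, "activations": act,
            "responsibilities": r, "per_capsule_elbo": elbo_k}


def _per_capsule_elbo(votes, a, r, log_r, y, t, sq, alpha, beta, pose, m,
                      w_diag, log_w, nu, *, alpha0, beta0, mu0, w0, nu0, D, n):
    """Per-capsule shares L_k of the seven-term bound.

    Every term of the full ELBO either indexes k directly or (the two
    Dirichlet normalizers and the K ln B(W0, nu0) constant) is split evenly
    over K, so sum_k L_k equals the full activation-weighted ELBO. Terms
    involving the pose use ``pose`` (the posterior mean, or a posterior
    sample during stochastic passes).
    """
    M, K = y.shape
    loglam = _expected_log_lambda(nu, log_w, D)
    logpi = ad.digamma(alpha) - ad.digamma(ad.tsum(alpha, axis=1, keepdims=True))

    w_nk = a * r
    # sum_n w_nk (v - pose)^2 collapses scatter + mean-deviation in one pass
    Q = ad.weighted_sqdiff_sum(w_nk, votes, pose)                   # (M,K,D)
    log_px = 0.5 * (y * loglam - D * y / beta
                    - nu * ad.tsum(w_diag * Q, axis=2)
                    - y * (D * _LOG2PI))

    log_pz = y * logpi

    logC0 = float(special.gammaln(K * alpha0) - K * special.gammaln(alpha0))
    log_ppi = logC0 / K + (alpha0 - 1.0) * logpi

    dmu = pose - mu0
    logB0 = float(-0.5 * nu0 * D * math.log(w0) - 0.5 * nu0 * D * _LOG2
                  - special.multigammaln(nu0 / 2.0, D))
    log_pml = (0.5 * (D * math.log(beta0 / (2.0 * math.pi)) + loglam
                      - D * beta0 / beta
                      - beta0 * nu * ad.tsum(w_diag * dmu * dmu, axis=2))
               + logB0
               + 0.5 * (nu0 - D - 1.0) * loglam
               - 0.5 * nu * ad.tsum(w_diag, axis=2) * (1.0 / w0))

    # entropy of q(Z), weighted by lower activations; the log-softmax is
    # floored at -60 so an underflowed r_nk contributes 0 ln 0 := 0, not nan
    log_r_safe = ad.relu(log_r + 60.0) - 60.0
    log_qz = ad.tsum(w_nk * log_r_safe, axis=1)

    logC = (ad.gammaln(ad.tsum(alpha, axis=1, keepdims=True))
            - ad.tsum(ad.gammaln(alpha), axis=1, keepdims=True))
    log_qpi = (alpha - 1.0) * logpi + logC * (1.0 / K)

    logB = _log_wishart_B_diag(log_w, nu, D)
    H = -logB - 0.5 * (nu - D - 1.0) * loglam + nu * (D / 2.0)
    log_qml = 0.5 * loglam + 0.5 * D * ad.log(beta / (2.0 * math.pi)) \
        - 0.5 * D - H

    return (log_px + log_pz + log_ppi + log_pml
            - log_qz - log_qpi - log_qml)


def route(votes: VoteTensor, config: RoutingConfig | None = None,
          rng: np.random.Generator | None = None) -> RoutingResult:
    """Route one set of votes (library-level, non-batched API)."""
    if config is None:
        config = RoutingConfig()
    v = votes.votes
    n, K, D = v.shape
    pri = config.priors
    kwargs = dict(alpha0=None, beta0=1.0, mu0=0.0, w0=1.0, nu0=None)
    if pri is not None:
        if not pri.diagonal:
            raise InvalidInputError("routing requires diagonal priors")
        w0d = np.unique(pri.W0)
        if w0d.size != 1:
            raise InvalidInputError("routing priors must be isotropic (W0 = w0 I)")
        kwargs = dict(alpha0=pri.alpha0, beta0=pri.beta0, mu0=pri.mu0,
                      w0=float(w0d[0]), nu0=pri.nu0)
    out = route_batched(Tensor(v[None]), Tensor(votes.lower_activations[None]),
                        n_iters=config.n_iters, beta_a=config.beta_a,
                        inv_temperature=config.inv_temperature, rng=rng,
                        **kwargs)
    return RoutingResult(
        poses=out["poses"].data[0],
        precisions=out["precisions"].data[0],
        activations=out["activations"].data[0],
        responsibilities=out["responsibilities"].data[0],
        per_capsule_elbo=out["per_capsule_elbo"].data[0],
    )
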