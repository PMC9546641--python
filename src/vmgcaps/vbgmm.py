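"""Variational Bayesian inference for Gaussian mixture models.

Mean-field VB for a finite Gaussian mixture with a symmetric Dirichlet prior
on the mixing weights and independent Gaussian--Wishart priors on each
component's mean and precision. The E-step computes soft responsibilities in
the log domain; the M-step applies the conjugate updates; the evidence lower
bound (ELBO) is the sum of seven expectation terms and is guaranteed
non-decreasing under coordinate ascent.

Two covariance modes are supported and selected by the shape of the prior
scale matrix ``W0``: a 1-D ``W0`` stores the diagonal of the Wishart scale and
constrains all precisions to be diagonal (the default used by the capsule
routing layer); a 2-D ``W0`` runs the full-matrix updates. In diagonal mode
the off-diagonal entries of the weighted scatter are dropped, and all Wishart
normalizers keep the full multivariate form, so the two modes coincide
exactly whenever every scatter matrix is diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special
from scipy.special import logsumexp as _lse


class InvalidInputError(ValueError):
    """Raised for malformed data, shapes or hyperparameters."""


class NumericalDomainError(FloatingPointError):
    """Raised when a matrix that must be positive definite is not."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class PriorHyperparams:
    """Conjugate prior constants of the VB mixture.

    alpha0
        Symmetric Dirichlet concentration on the mixing weights.
    beta0
        Scaling of the prior mean's precision relative to the component
        precision.
    mu0
        Prior mean, shape (D,).
    W0
        Wishart scale; shape (D,) selects diagonal mode, (D, D) full mode.
    nu0
        Wishart degrees of freedom; must exceed D - 1.
    """

    alpha0: float
    beta0: float
    mu0: np.ndarray
    W0: np.ndarray
    nu0: float

    def __post_init__(self):
        self.mu0 = np.asarray(self.mu0, dtype=np.float64)
        self.W0 = np.asarray(self.W0, dtype=np.float64)
        D = self.mu0.shape[0]
        if self.alpha0 <= 0 or self.beta0 <= 0:
            raise InvalidInputError("alpha0 and beta0 must be positive")
        if self.nu0 <= D - 1:
            raise InvalidInputError("nu0 must exceed D - 1")
        if self.diagonal:
            if self.W0.shape != (D,) or np.any(self.W0 <= 0):
                raise InvalidInputError("diagonal W0 must be positive, shape (D,)")
        else:
            if self.W0.shape != (D, D):
                raise InvalidInputError("W0 must be (D,) or (D, D)")
            _chol(self.W0)

    @property
    def diagonal(self) -> bool:
        return self.W0.ndim == 1

    @property
    def D(self) -> int:
        return self.mu0.shape[0]


@dataclass
class VariationalState:
    """Per-component posterior parameters (alpha_k, beta_k, m_k, W_k, nu_k)."""

    alpha: np.ndarray
    beta: np.ndarray
    m: np.ndarray
    W: np.ndarray
    nu: np.ndarray

    @property
    def K(self) -> int:
        return self.alpha.shape[0]

    @property
    def D(self) -> int:
        return self.m.shape[1]

    @property
    def diagonal(self) -> bool:
        return self.W.ndim == 2


@dataclass
class Responsibilities:
    """N x K soft assignments; every row sums to one."""

    r: np.ndarray

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=np.float64)
        if np.any(self.r < -1e-12):
            raise InvalidInputError("responsibilities must be non-negative")
        if not np.allclose(self.r.sum(axis=1), 1.0, atol=1e-9):
            raise InvalidInputError("responsibility rows must sum to 1")


@dataclass
class SufficientStats:
    """Effective counts y_k, weighted means xbar_k and scatters S_k."""

    y: np.ndarray
    xbar: np.ndarray
    S: np.ndarray


@dataclass
class ExpectedStats:
    """E[ln|Lambda_k|] and E[ln pi_k] under the variational posterior."""

    log_lambda_tilde: np.ndarray
    log_pi_tilde: np.ndarray


@dataclass
class FitResult:
    state: VariationalState
    resp: Responsibilities
    elbo_trace: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


# ---------------------------------------------------------------------------
# linear-algebra helpers (mode-agnostic)
# ---------------------------------------------------------------------------

def _chol(a: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(a)
    except np.linalg.LinAlgError as e:
        raise NumericalDomainError("matrix is not positive definite") from e


def _logdet(W: np.ndarray, diagonal: bool) -> np.ndarray:
    """log|W_k| for stacked scale matrices (K,D) or (K,D,D)."""
    if diagonal:
        if np.any(W <= 0):
            raise NumericalDomainError("diagonal precision scale must be positive")
        return np.log(W).sum(axis=-1)
    sign, ld = np.linalg.slogdet(W)
    if np.any(sign <= 0):
        raise NumericalDomainError("W_k is not positive definite")
    return ld


def _quad(diff: np.ndarray, W: np.ndarray, diagonal: bool) -> np.ndarray:
    """diff^T W diff for stacked diffs (K,...,D) against (K,D[,D])."""
    if diagonal:
        return np.einsum("k...d,kd->k...", diff ** 2, W)
    return np.einsum("k...d,kde,k...e->k...", diff, W, diff)


def _trace_prod(S: np.ndarray, W: np.ndarray, diagonal: bool) -> np.ndarray:
    if diagonal:
        return np.einsum("kd,kd->k", S, W)
    return np.einsum("kde,ked->k", S, W)


def _log_wishart_B(W: np.ndarray, nu: np.ndarray, diagonal: bool) -> np.ndarray:
    """ln B(W, nu), the Wishart normalizer, for stacked parameters."""
    nu = np.atleast_1d(np.asarray(nu, dtype=np.float64))
    D = W.shape[-1] if not diagonal else W.shape[-1]
    ld = _logdet(np.atleast_2d(W) if diagonal else W.reshape(-1, D, D), diagonal)
    mg = np.array([special.multigammaln(n / 2.0, D) for n in nu])
    return -(nu / 2.0) * ld - (nu * D / 2.0) * np.log(2.0) - mg


def _log_dirichlet_C(alpha: np.ndarray) -> float:
    return float(special.gammaln(alpha.sum()) - special.gammaln(alpha).sum())


def _wishart_entropy(W: np.ndarray, nu: np.ndarray, log_lambda_tilde: np.ndarray,
                     diagonal: bool) -> np.ndarray:
    D = W.shape[-1]
    logB = _log_wishart_B(W, nu, diagonal)
    return -logB - (nu - D - 1.0) / 2.0 * log_lambda_tilde + nu * D / 2.0


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def default_priors(data: np.ndarray | None, K: int, D: int,
                   diagonal: bool = True) -> PriorHyperparams:
    """Weakly informative defaults: alpha0=1/K, beta0=1, mu0=data mean
    (zero without data), W0=I, nu0=D+1."""
    mu0 = np.zeros(D) if data is None else np.asarray(data).mean(axis=0)
    W0 = np.ones(D) if diagonal else np.eye(D)
    return PriorHyperparams(alpha0=1.0 / K, beta0=1.0, mu0=mu0, W0=W0,
                            nu0=float(D + 1))


def _seed_responsibilities(data: np.ndarray, K: int,
                           rng: np.random.Generator, method: str) -> np.ndarray:
    N = data.shape[0]
    if K == 1:
        return np.ones((N, 1))
    if method == "random":
        return rng.dirichlet(np.ones(K), size=N)
    if method == "points":
        # kmeans++-style seeding: spread K provisional centers over the data,
        # then assign each point to its nearest center (one-hot). Random
        # responsibilities barely break symmetry, so well-separated clusters
        # are frequently merged from that start; distance-spread seeding is
        # far more reliable at equal cost.
        centers = [data[rng.integers(N)]]
        for _ in range(K - 1):
            d2 = np.min([((data - c) ** 2).sum(axis=1) for c in centers], axis=0)
            total = d2.sum()
            p = None if total <= 0 else d2 / total
            centers.append(data[rng.choice(N, p=p)])
        C = np.asarray(centers)
        labels = np.argmin(((data[:, None, :] - C[None, :, :]) ** 2).sum(-1), axis=1)
        r = np.zeros((N, K))
        r[np.arange(N), labels] = 1.0
        return r
    raise InvalidInputError(f"unknown init method {method!r}")


def init_state(data: np.ndarray, K: int, priors: PriorHyperparams,
               seed: int = 0, method: str = "points",
               ) -> tuple[VariationalState, Responsibilities]:
    """Seeded initialization: responsibilities from kmeans++-style point
    seeding (default) or per-row symmetric Dirichlet(1,...,1) draws
    (``method="random"``), followed by one M-step."""
    data = np.asarray(data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise InvalidInputError("data must be finite")
    if data.ndim != 2:
        raise InvalidInputError("data must be an N x D matrix")
    N, D = data.shape
    if K < 1 or N < 1:
        raise InvalidInputError("need N >= 1 and K >= 1")
    if K > N:
        warnings.warn("more components than data points", stacklevel=2)
    rng = np.random.default_rng(seed)
    resp = Responsibilities(_seed_responsibilities(data, K, rng, method))
    state = m_step(priors, sufficient_stats(data, resp, mu0=priors.mu0))
    return state, resp


def compute_expected_stats(state: VariationalState) -> ExpectedStats:
    """E[ln|Lambda_k|] via digamma sums and E[ln pi_k] via the Dirichlet."""
    K, D = state.K, state.D
    i = np.arange(1, D + 1)
    psi_sum = special.digamma((state.nu[:, None] + 1.0 - i[None, :]) / 2.0).sum(axis=1)
    log_lambda = psi_sum + D * np.log(2.0) + _logdet(state.W, state.diagonal)
    log_pi = special.digamma(state.alpha) - special.digamma(state.alpha.sum())
    return ExpectedStats(log_lambda_tilde=log_lambda, log_pi_tilde=log_pi)


def compute_log_rho(state: VariationalState, data: np.ndarray) -> np.ndarray:
    """Unnormalized log responsibilities ln rho_nk."""
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2 or data.shape[1] != state.D:
        raise InvalidInputError("data dimension does not match state")
    D = state.D
    ex = compute_expected_stats(state)
    diff = data[None, :, :] - state.m[:, None, :]          # (K, N, D)
    quad = _quad(diff, state.W, state.diagonal)            # (K, N)
    mahal = D / state.beta[:, None] + state.nu[:, None] * quad
    log_rho = (ex.log_pi_tilde[:, None] + 0.5 * ex.log_lambda_tilde[:, None]
               - 0.5 * D * np.log(2.0 * np.pi) - 0.5 * mahal)
    return log_rho.T                                        # (N, K)


def responsibilities(log_rho: np.ndarray) -> Responsibilities:
    """Row-normalize in the log domain (log-sum-exp)."""
    log_rho = np.asarray(log_rho, dtype=np.float64)
    r = np.exp(log_rho - _lse(log_rho, axis=1, keepdims=True))
    return Responsibilities(r)


def sufficient_stats(data: np.ndarray, resp: Responsibilities,
                     mu0: np.ndarray | None = None) -> SufficientStats:
    """Weighted counts, means and scatters; an empty component (y_k ~ 0)
    gets xbar_k = mu0 and S_k = 0 so the M-step returns the prior."""
    data = np.asarray(data, dtype=np.float64)
    r = resp.r
    N, D = data.shape
    K = r.shape[1]
    diagonal_fallback = mu0 if mu0 is not None else np.zeros(D)
    y = r.sum(axis=0)
    empty = y < 1e-12
    y_safe = np.where(empty, 1.0, y)
    xbar = (r.T @ data) / y_safe[:, None]
    xbar[empty] = diagonal_fallback
    diff = data[None, :, :] - xbar[:, None, :]              # (K, N, D)
    S = np.einsum("nk,knd,kne->kde", r, diff, diff) / y_safe[:, None, None]
    S[empty] = 0.0
    return SufficientStats(y=y, xbar=xbar, S=S)


def _project_scatter(S: np.ndarray, diagonal: bool) -> np.ndarray:
    """Full (K,D,D) scatter, or its diagonal in diagonal mode."""
    return np.einsum("kdd->kd", S) if diagonal else S


def m_step(priors: PriorHyperparams, stats: SufficientStats) -> VariationalState:
    """Conjugate Dirichlet and Gaussian--Wishart updates."""
    y, xbar = stats.y, stats.xbar
    K, D = xbar.shape
    alpha = priors.alpha0 + y
    beta = priors.beta0 + y
    nu = priors.nu0 + y
    m = (priors.beta0 * priors.mu0[None, :] + y[:, None] * xbar) / beta[:, None]
    dev = xbar - priors.mu0[None, :]
    coeff = priors.beta0 * y / (priors.beta0 + y)
    if priors.diagonal:
        S = _project_scatter(stats.S, True) if stats.S.ndim == 3 else stats.S
        W_inv = 1.0 / priors.W0[None, :] + y[:, None] * S + coeff[:, None] * dev ** 2
        if np.any(W_inv <= 0):
            raise NumericalDomainError("singular diagonal W_k^{-1}")
        W = 1.0 / W_inv
    else:
        W0_inv = np.linalg.inv(priors.W0)
        W_inv = (W0_inv[None, :, :] + y[:, None, None] * stats.S
                 + coeff[:, None, None] * np.einsum("kd,ke->kde", dev, dev))
        W = np.zeros_like(W_inv)
        for k in range(K):
            L = _chol(W_inv[k])
            W[k] = np.linalg.inv(L).T @ np.linalg.inv(L)
    return VariationalState(alpha=alpha, beta=beta, m=m, W=W, nu=nu)


def elbo_terms(data: np.ndarray, resp: Responsibilities,
               state: VariationalState, priors: PriorHyperparams) -> dict:
    """The seven expectation terms of the ELBO, individually.

    Keys: ``log_px``, ``log_pz``, ``log_ppi``, ``log_pmu_lambda``,
    ``log_qz``, ``log_qpi``, ``log_qmu_lambda``. The bound is the sum of the
    first four minus the last three.
    """
    data = np.asarray(data, dtype=np.float64)
    r = resp.r
    N, D = data.shape
    K = state.K
    diagonal = state.diagonal
    stats = sufficient_stats(data, resp, mu0=priors.mu0)
    S = _project_scatter(stats.S, diagonal)
    ex = compute_expected_stats(state)
    loglam, logpi = ex.log_lambda_tilde, ex.log_pi_tilde
    y, xbar = stats.y, stats.xbar

    dxm = xbar - state.m
    log_px = 0.5 * np.sum(y * (
        loglam - D / state.beta
        - state.nu * _trace_prod(S, state.W, diagonal)
        - state.nu * _quad(dxm[:, None, :], state.W, diagonal)[:, 0]
        - D * np.log(2.0 * np.pi)))

    log_pz = float(np.sum(r * logpi[None, :]))

    alpha0_vec = np.full(K, priors.alpha0)
    log_ppi = _log_dirichlet_C(alpha0_vec) + (priors.alpha0 - 1.0) * logpi.sum()

    dmu = state.m - priors.mu0[None, :]
    if diagonal:
        trW0invW = np.einsum("kd,d->k", state.W, 1.0 / priors.W0)
        logB0 = _log_wishart_B(priors.W0[None, :], np.array([priors.nu0]), True)[0]
    else:
        W0_inv = np.linalg.inv(priors.W0)
        trW0invW = np.einsum("de,ked->k", W0_inv, state.W)
        logB0 = _log_wishart_B(priors.W0[None, :, :], np.array([priors.nu0]),
                               False)[0]
    log_pmu_lambda = (0.5 * np.sum(
        D * np.log(priors.beta0 / (2.0 * np.pi)) + loglam
        - D * priors.beta0 / state.beta
        - priors.beta0 * state.nu * _quad(dmu[:, None, :], state.W, diagonal)[:, 0])
        + K * logB0
        + (priors.nu0 - D - 1.0) / 2.0 * loglam.sum()
        - 0.5 * np.sum(state.nu * trW0invW))

    with np.errstate(divide="ignore", invalid="ignore"):
        rlogr = np.where(r > 0, r * np.log(np.where(r > 0, r, 1.0)), 0.0)
    log_qz = float(rlogr.sum())

    log_qpi = float(np.sum((state.alpha - 1.0) * logpi) + _log_dirichlet_C(state.alpha))

    H = _wishart_entropy(state.W, state.nu, loglam, diagonal)
    log_qmu_lambda = float(np.sum(
        0.5 * loglam + 0.5 * D * np.log(state.beta / (2.0 * np.pi))
        - 0.5 * D - H))

    return {
        "log_px": float(log_px),
        "log_pz": log_pz,
        "log_ppi": float(log_ppi),
        "log_pmu_lambda": float(log_pmu_lambda),
        "log_qz": log_qz,
        "log_qpi": log_qpi,
        "log_qmu_lambda": log_qmu_lambda,
    }


def elbo(data: np.ndarray, resp: Responsibilities, state: VariationalState,
         priors: PriorHyperparams) -> float:
    t = elbo_terms(data, resp, state, priors)
    return (t["log_px"] + t["log_pz"] + t["log_ppi"] + t["log_pmu_lambda"]
            - t["log_qz"] - t["log_qpi"] - t["log_qmu_lambda"])


def _fit_once(data: np.ndarray, K: int, priors: PriorHyperparams,
              max_iter: int, tol: float, seed: int, method: str) -> FitResult:
    state, resp = init_state(data, K, priors, seed=seed, method=method)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            resp = responsibilities(compute_log_rho(state, data))
            stats = sufficient_stats(data, resp, mu0=priors.mu0)
            state = m_step(priors, stats)
            L = elbo(data, resp, state, priors)
        except NumericalDomainError as e:
            raise NumericalDomainError(f"iteration {it}: {e}") from e
        trace.append(L)
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol * abs(trace[-1]):
            converged = True
            break
    return FitResult(state=state, resp=resp, elbo_trace=trace, n_iter=it,
                     converged=converged)


def fit(data: np.ndarray, K: int, priors: PriorHyperparams | None = None,
        max_iter: int = 200, tol: float = 1e-6, seed: int = 0,
        n_init: int = 4, init_method: str = "points") -> FitResult:
    """Coordinate-ascent VB: E-step, sufficient stats, M-step, ELBO, until
    the relative ELBO change drops below ``tol`` or ``max_iter`` is hit.

    The optimization restarts from ``n_init`` seeded initializations and the
    run with the highest final ELBO is returned (VB coordinate ascent only
    finds local optima; restarts make the recovered clustering stable
    across seeds).
    """
    data = np.asarray(data, dtype=np.float64)
    if max_iter < 1 or tol <= 0:
        raise InvalidInputError("max_iter >= 1 and tol > 0 required")
    if n_init < 1:
        raise InvalidInputError("n_init >= 1 required")
    N, D = data.shape
    if priors is None:
        priors = default_priors(data, K, D)
    child_seeds = np.random.default_rng(seed).integers(0, 2 ** 31 - 1,
                                                       size=n_init)
    best: FitResult | None = None
    for s in child_seeds:
        res = _fit_once(data, K, priors, max_iter, tol, int(s), init_method)
        if best is None or res.elbo_trace[-1] > best.elbo_trace[-1]:
            best = res
    return best
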