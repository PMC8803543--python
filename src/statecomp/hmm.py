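"""Gaussian hidden Markov modeling of reduced power-envelope series.

A K-state HMM with full-covariance Gaussian emissions is fit to the
principal-component time courses of concatenated, normalized power
envelopes. Two inference routes are provided:

``vb`` (default)
    Variational Bayes with conjugate priors: Dirichlet priors on the initial
    distribution and each transition row, and a Gaussian-Wishart prior on
    each state's (mean, precision). The objective trace is the evidence
    lower bound (negative free energy); the restart with the lowest final
    free energy (highest ELBO) is retained.
``em``
    Maximum-likelihood Baum-Welch; the objective trace is the
    log-likelihood.

Both routes share the same scaled forward-backward recursions (numba-jitted;
the VB E-step simply runs them with sub-normalized parameters
exp(E[log pi]), exp(E[log A])). Decoding into exclusive, complete binary
state time courses uses the Viterbi algorithm in the log domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from numba import njit
from scipy.special import digamma, gammaln, multigammaln

from .containers import ReductionBasis, StateActivation

__all__ = ["HmmModel", "DecodedStates", "fit_hmm", "viterbi_decode", "upsample_states"]


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=False)
def _forward_backward(logb, pi_eff, a_eff):
    """Scaled forward-backward. Returns (log-normalizer, gamma, xi_sum).

    ``logb`` is T x K log emission terms; ``pi_eff``/``a_eff`` may be
    sub-normalized (VB expected-parameter recursions); the per-step scaling
    constants then accumulate the correct log normalizer.
    """
    T, K = logb.shape
    b = np.empty((T, K))
    off = np.empty(T)
    for t in range(T):
        m = logb[t, 0]
        for k in range(1, K):
            if logb[t, k] > m:
                m = logb[t, k]
        off[t] = m
        for k in range(K):
            b[t, k] = np.exp(logb[t, k] - m)

    alpha = np.empty((T, K))
    c = np.empty(T)
    s = 0.0
    for k in range(K):
        alpha[0, k] = pi_eff[k] * b[0, k]
        s += alpha[0, k]
    c[0] = s
    for k in range(K):
        alpha[0, k] /= s
    for t in range(1, T):
        s = 0.0
        for k in range(K):
            acc = 0.0
            for j in range(K):
                acc += alpha[t - 1, j] * a_eff[j, k]
            alpha[t, k] = acc * b[t, k]
            s += alpha[t, k]
        c[t] = s
        for k in range(K):
            alpha[t, k] /= s

    beta = np.empty((T, K))
    for k in range(K):
        beta[T - 1, k] = 1.0
    gamma = np.empty((T, K))
    xi_sum = np.zeros((K, K))
    for k in range(K):
        gamma[T - 1, k] = alpha[T - 1, k]
    for t in range(T - 2, -1, -1):
        for j in range(K):
            acc = 0.0
            for k in range(K):
                acc += a_eff[j, k] * b[t + 1, k] * beta[t + 1, k]
            beta[t, j] = acc / c[t + 1]
        g = 0.0
        for j in range(K):
            gamma[t, j] = alpha[t, j] * beta[t, j]
            g += gamma[t, j]
        for j in range(K):
            gamma[t, j] /= g
        for j in range(K):
            for k in range(K):
                xi_sum[j, k] += (
                    alpha[t, j] * a_eff[j, k] * b[t + 1, k] * beta[t + 1, k]
                ) / c[t + 1]
    # renormalize gamma at T-1 (already normalized by construction)
    loglik = 0.0
    for t in range(T):
        loglik += np.log(c[t]) + off[t]
    return loglik, gamma, xi_sum


@njit(cache=False)
def _viterbi_path(logb, log_pi, log_a):
    """Most probable state path (log domain, ties to the lowest index)."""
    T, K = logb.shape
    delta = np.empty((T, K))
    psi = np.zeros((T, K), dtype=np.int64)
    for k in range(K):
        delta[0, k] = log_pi[k] + logb[0, k]
    for t in range(1, T):
        for k in range(K):
            best = delta[t - 1, 0] + log_a[0, k]
            arg = 0
            for j in range(1, K):
                v = delta[t - 1, j] + log_a[j, k]
                if v > best:
                    best = v
                    arg = j
            delta[t, k] = best + logb[t, k]
            psi[t, k] = arg
    path = np.empty(T, dtype=np.int64)
    best = delta[T - 1, 0]
    arg = 0
    for k in range(1, K):
        if delta[T - 1, k] > best:
            best = delta[T - 1, k]
            arg = k
    path[T - 1] = arg
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1, path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# model containers


@dataclass
class HmmModel:
    """Fitted K-state Gaussian HMM in reduced space."""

    means: np.ndarray  # K x d
    covariances: np.ndarray  # K x d x d, SPD
    transition_matrix: np.ndarray  # K x K row-stochastic
    initial_probs: np.ndarray  # K
    objective_trace: np.ndarray  # per-iteration ELBO or log-likelihood
    inference: str = "vb"
    basis: Optional[ReductionBasis] = None
    seed_used: int = 0
    state_names: Optional[List[str]] = None

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=np.float64)
        self.covariances = np.asarray(self.covariances, dtype=np.float64)
        A = np.asarray(self.transition_matrix, dtype=np.float64)
        if np.abs(A.sum(axis=1) - 1.0).max() > 1e-10:
            raise ValueError("transition rows must sum to 1")
        self.transition_matrix = A
        pi = np.asarray(self.initial_probs, dtype=np.float64)
        if abs(pi.sum() - 1.0) > 1e-10:
            raise ValueError("initial_probs must sum to 1")
        self.initial_probs = pi
        for S in self.covariances:
            if np.abs(S - S.T).max() > 1e-10:
                raise ValueError("covariances must be symmetric")
            if np.linalg.eigvalsh(S).min() <= 0:
                raise ValueError("covariances must be positive definite")
        if self.state_names is None:
            self.state_names = [f"state{k + 1}" for k in range(self.K)]

    @property
    def K(self) -> int:
        return self.means.shape[0]

    @property
    def dim(self) -> int:
        return self.means.shape[1]


@dataclass
class DecodedStates:
    """Exclusive, complete binary state activations from Viterbi decoding."""

    activation: StateActivation
    posteriors: Optional[np.ndarray] = None  # T x K smoothed marginals

    @property
    def labels(self) -> np.ndarray:
        return self.activation.labels


# ---------------------------------------------------------------------------
# shared numerics


def _log_gauss(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    L = np.linalg.cholesky(cov)
    sol = np.linalg.solve(L, (X - mean).T)
    quad = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (quad + logdet + d * np.log(2 * np.pi))


def _regularize(cov: np.ndarray) -> np.ndarray:
    d = cov.shape[0]
    eps = 1e-6 * np.trace(cov) / d
    if not np.isfinite(eps) or eps <= 0:
        eps = 1e-10
    return cov + eps * np.eye(d)


def _suff_stats(X, gamma):
    """Per-state counts, means and scatter from responsibilities."""
    Nk = gamma.sum(axis=0)  # K
    Nk_safe = np.maximum(Nk, 1e-10)
    xbar = (gamma.T @ X) / Nk_safe[:, None]
    S = np.empty((gamma.shape[1], X.shape[1], X.shape[1]))
    for k in range(gamma.shape[1]):
        D = X - xbar[k]
        S[k] = (gamma[:, k][:, None] * D).T @ D / Nk_safe[k]
    return Nk, xbar, S


def _kl_dirichlet(u: np.ndarray, u0: np.ndarray) -> float:
    su, su0 = u.sum(), u0.sum()
    return float(
        gammaln(su) - gammaln(su0)
        - np.sum(gammaln(u)) + np.sum(gammaln(u0))
        + np.sum((u - u0) * (digamma(u) - digamma(su)))
    )


def _e_logdet_lambda(W: np.ndarray, nu: float) -> float:
    d = W.shape[0]
    sign, logdet = np.linalg.slogdet(W)
    psi_sum = float(np.sum(digamma(0.5 * (nu - np.arange(d)))))
    return psi_sum + d * np.log(2.0) + logdet


def _kl_gauss_wishart(m, beta, W, nu, m0, beta0, W0inv, nu0) -> float:
    """KL( NW(m,beta,W,nu) || NW(m0,beta0,inv(W0inv),nu0) )."""
    d = W.shape[0]
    elog = _e_logdet_lambda(W, nu)
    dm = m - m0
    kl_normal = 0.5 * (
        d * beta0 / beta + beta0 * nu * dm @ W @ dm - d + d * np.log(beta / beta0)
    )
    sign0, logdetW0inv = np.linalg.slogdet(W0inv)
    logdetW0 = -logdetW0inv
    _, logdetW = np.linalg.slogdet(W)

    def ln_b(logdet_w, nu_):
        return (
            -0.5 * nu_ * logdet_w
            - 0.5 * nu_ * d * np.log(2.0)
            - multigammaln(0.5 * nu_, d)
        )

    kl_wishart = (
        0.5 * (nu - nu0) * elog
        - 0.5 * nu * d
        + 0.5 * nu * np.trace(W0inv @ W)
        + ln_b(logdetW, nu)
        - ln_b(logdetW0, nu0)
    )
    return float(kl_normal + kl_wishart)


# ---------------------------------------------------------------------------
# single-restart fits


def _init_params(X, K, rng):
    """Restart initialization: random data points as means, pooled covariance,
    sticky-diagonal (0.9) transitions."""
    T, d = X.shape
    idx = rng.choice(T, size=K, replace=False)
    means = X[idx].copy()
    pooled = np.cov(X.T, ddof=0).reshape(d, d)
    covs = np.stack([_regularize(pooled.copy()) for _ in range(K)])
    if K == 1:
        A = np.ones((1, 1))
    else:
        A = np.full((K, K), 0.1 / (K - 1))
        np.fill_diagonal(A, 0.9)
    pi = np.full(K, 1.0 / K)
    return means, covs, A, pi


def _fit_em(X, K, rng, max_iter, tol):
    means, covs, A, pi = _init_params(X, K, rng)
    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        logb = np.stack(
            [_log_gauss(X, means[k], covs[k]) for k in range(K)], axis=1
        )
        loglik, gamma, xi_sum = _forward_backward(logb, pi, A)
        trace.append(loglik)
        Nk, xbar, S = _suff_stats(X, gamma)
        means = xbar
        covs = np.stack([_regularize(S[k]) for k in range(K)])
        pi = gamma[0] / gamma[0].sum()
        if K > 1:
            rows = xi_sum.sum(axis=1, keepdims=True)
            A = np.where(rows > 0, xi_sum / np.maximum(rows, 1e-300), 1.0 / K)
            A /= A.sum(axis=1, keepdims=True)
        if (
            np.isfinite(loglik)
            and np.isfinite(prev)
            and abs(loglik - prev) <= tol * max(1.0, abs(prev))
        ):
            break
        prev = loglik
    model = dict(means=means, covs=covs, A=A, pi=pi)
    return np.array(trace), model


def _fit_vb(X, K, rng, max_iter, tol):
    T, d = X.shape
    # conjugate priors: unit Dirichlet counts; Gaussian-Wishart centred on the
    # pooled data statistics with minimal strength
    alpha0_pi = np.ones(K)
    alpha0_A = np.ones((K, K))
    m0 = X.mean(axis=0)
    beta0 = 1.0
    nu0 = d + 2.0
    pooled = _regularize(np.cov(X.T, ddof=0).reshape(d, d))
    W0inv = pooled * nu0  # so the prior mean precision is inv(pooled)

    # initialize posterior factors from the standard restart heuristic
    means, covs, A_init, pi_init = _init_params(X, K, rng)
    m = means.copy()
    beta = np.full(K, beta0 + 1.0)
    nu = np.full(K, nu0 + 1.0)
    W = np.stack([np.linalg.inv(_regularize(covs[k]) * nu[k]) for k in range(K)])
    u_pi = alpha0_pi + pi_init
    u_A = alpha0_A + (T / K) * A_init

    trace = []
    prev = -np.inf
    for _ in range(max_iter):
        # E-step with expected log parameters
        elog_pi = digamma(u_pi) - digamma(u_pi.sum())
        elog_A = digamma(u_A) - digamma(u_A.sum(axis=1, keepdims=True))
        logb = np.empty((T, K))
        for k in range(K):
            elogdet = _e_logdet_lambda(W[k], nu[k])
            D = X - m[k]
            quad = nu[k] * np.einsum("ti,ij,tj->t", D, W[k], D)
            logb[:, k] = 0.5 * (elogdet - d / beta[k] - quad - d * np.log(2 * np.pi))
        lnz, gamma, xi_sum = _forward_backward(
            logb, np.exp(elog_pi), np.exp(elog_A)
        )
        # ELBO = ln Z~ - KL(q || p) over all parameter factors
        kl = _kl_dirichlet(u_pi, alpha0_pi)
        for j in range(K):
            kl += _kl_dirichlet(u_A[j], alpha0_A[j])
        for k in range(K):
            kl += _kl_gauss_wishart(
                m[k], beta[k], W[k], nu[k], m0, beta0, W0inv, nu0
            )
        elbo = lnz - kl
        trace.append(elbo)
        # M-step (conjugate updates)
        Nk, xbar, S = _suff_stats(X, gamma)
        beta = beta0 + Nk
        nu = nu0 + Nk
        m = (beta0 * m0 + Nk[:, None] * xbar) / beta[:, None]
        for k in range(K):
            dm = xbar[k] - m0
            Winv = (
                W0inv
                + Nk[k] * S[k]
                + (beta0 * Nk[k] / (beta0 + Nk[k])) * np.outer(dm, dm)
            )
            W[k] = np.linalg.inv(_regularize(Winv))
        u_pi = alpha0_pi + gamma[0]
        u_A = alpha0_A + xi_sum
        if (
            np.isfinite(elbo)
            and np.isfinite(prev)
            and abs(elbo - prev) <= tol * max(1.0, abs(prev))
        ):
            break
        prev = elbo
    covs = np.stack(
        [np.linalg.inv(nu[k] * W[k]) for k in range(K)]
    )  # E[Lambda]^-1 as the point covariance
    A = u_A / u_A.sum(axis=1, keepdims=True)
    pi = u_pi / u_pi.sum()
    model = dict(means=m, covs=covs, A=A, pi=pi)
    return np.array(trace), model


# ---------------------------------------------------------------------------
# public operations


def fit_hmm(
    series: np.ndarray,
    K: int,
    n_restarts: int = 10,
    seed: int = 0,
    inference: str = "vb",
    basis: Optional[ReductionBasis] = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> HmmModel:
    """Fit a K-state Gaussian HMM with multi-restart inference.

    ``n_restarts`` independent initializations are seeded deterministically
    from ``seed``; the restart with the best final objective (lowest free
    energy for VB, highest log-likelihood for EM) is retained. Convergence:
    relative objective change below ``tol`` or ``max_iter`` iterations.
    """
    X = np.asarray(series, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if not np.isfinite(X).all():
        raise ValueError("series contains non-finite values")
    if K < 1 or n_restarts < 1:
        raise ValueError("need K >= 1 and n_restarts >= 1")
    if X.shape[0] < 10 * K:
        raise ValueError("series too short relative to K")
    if inference not in ("vb", "em"):
        raise ValueError("inference must be 'vb' or 'em'")
    fit_one = _fit_vb if inference == "vb" else _fit_em

    seeds = np.random.SeedSequence(seed).spawn(n_restarts)
    best: Optional[Tuple[float, np.ndarray, dict, int]] = None
    failures = []
    for i, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        try:
            trace, model = fit_one(X, K, rng, max_iter, tol)
            final = trace[-1]
            if not np.isfinite(final):
                raise FloatingPointError("non-finite objective")
        except (np.linalg.LinAlgError, FloatingPointError, ValueError) as exc:
            failures.append(f"restart {i}: {exc}")
            continue
        if best is None or final > best[0]:
            best = (final, trace, model, i)
    if best is None:
        raise RuntimeError(
            "all HMM restarts degenerated: " + "; ".join(failures)
        )
    _, trace, model, restart = best
    return HmmModel(
        means=model["means"],
        covariances=model["covs"],
        transition_matrix=model["A"],
        initial_probs=model["pi"],
        objective_trace=trace,
        inference=inference,
        basis=basis,
        seed_used=seed,
    )


def viterbi_decode(
    model: HmmModel, series: np.ndarray, fs: float = 40.0
) -> DecodedStates:
    """Most probable state path under the model (exclusive and complete)."""
    X = np.asarray(series, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] != model.dim:
        raise ValueError("series dimension does not match the model")
    K = model.K
    logb = np.stack(
        [_log_gauss(X, model.means[k], model.covariances[k]) for k in range(K)],
        axis=1,
    )
    with np.errstate(divide="ignore"):
        log_pi = np.log(np.maximum(model.initial_probs, 1e-300))
        log_a = np.log(np.maximum(model.transition_matrix, 1e-300))
    path = _viterbi_path(logb, log_pi, log_a)
    _, gamma, _ = _forward_backward(
        logb, model.initial_probs, model.transition_matrix
    )
    act = StateActivation(
        labels=path, n_states=K, fs=fs, smoothed=False,
        state_names=list(model.state_names),
    )
    return DecodedStates(activation=act, posteriors=gamma)


def upsample_states(decoded: DecodedStates, target_fs: float) -> DecodedStates:
    """Sample-and-hold upsampling of decoded states to an integer multiple rate.

    Each label is repeated fs_target/fs times; exclusivity, completeness and
    fractional occupancies are preserved exactly.
    """
    act = decoded.activation
    ratio = target_fs / act.fs
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError("target_fs must be an integer multiple of the state fs")
    if factor == 1:
        return decoded
    labels = np.repeat(act.labels, factor)
    post = (
        np.repeat(decoded.posteriors, factor, axis=0)
        if decoded.posteriors is not None
        else None
    )
    new_act = StateActivation(
        labels=labels, n_states=act.n_states, fs=target_fs,
        smoothed=act.smoothed, state_names=act.state_names,
    )
    return DecodedStates(activation=new_act, posteriors=post)
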