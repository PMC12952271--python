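"""Gaussian-process regression over sequence embeddings.

Exact GP with an RBF kernel k(u,v) = delta * exp(-||u-v||^2 / (2 lambda^2)),
constant prior mean C and i.i.d. Gaussian observation noise sigma_n^2.
Hyperparameters are fitted by maximizing the log marginal likelihood on the
mean-centered targets, with (delta, lambda, sigma_n) optimized on the log
scale. Prediction is exact via a Cholesky factorization of K + sigma_n^2 I
with escalating jitter.

The acquisition function mu + beta*sigma turns the posterior into the
scoring function used during generation: beta > 0 is the optimistic upper
confidence bound, beta < 0 the pessimistic lower confidence bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from . import encoders


def kd_to_affinity(kd_nm: float) -> float:
    """Log-affinity faff = log10(1 nM / Kd); 1 nM maps to 0, lower Kd is higher."""
    if kd_nm <= 0:
        raise ValueError("Kd must be positive")
    return -math.log10(kd_nm)


def affinity_to_kd(faff: float) -> float:
    """Inverse of :func:`kd_to_affinity`, in nM."""
    return 10.0 ** (-faff)


@dataclass(frozen=True)
class KernelParams:
    """RBF kernel output scale, length scale, noise sd and constant mean."""

    delta: float = 1.0
    lam: float = 1.0
    sigma_n: float = 0.1
    C: float = 0.0

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.lam <= 0:
            raise ValueError("delta and lam must be strictly positive")
        if self.sigma_n < 0:
            raise ValueError("sigma_n must be non-negative")


def rbf_kernel(u: np.ndarray, v: np.ndarray, p: KernelParams) -> float:
    u, v = np.asarray(u, float), np.asarray(v, float)
    if u.shape != v.shape:
        raise ValueError("dimension mismatch")
    d2 = float(np.sum((u - v) ** 2))
    return p.delta * math.exp(-d2 / (2.0 * p.lam**2))


def _sqdist(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    a2 = np.sum(A * A, axis=1)[:, None]
    b2 = np.sum(B * B, axis=1)[None, :]
    return np.maximum(a2 + b2 - 2.0 * A @ B.T, 0.0)


def _kernel_matrix(A: np.ndarray, B: np.ndarray, p: KernelParams) -> np.ndarray:
    return p.delta * np.exp(-_sqdist(A, B) / (2.0 * p.lam**2))


_JITTERS = (0.0, 1e-8, 1e-6, 1e-4)


def _factorize(K: np.ndarray):
    """Cholesky of K with escalating jitter; failure after escalation raises."""
    for jit in _JITTERS:
        try:
            return cho_factor(K + jit * np.eye(K.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        f"kernel matrix not positive definite after jitter up to {_JITTERS[-1]}"
    )


class GPModel:
    """Exact GP conditioned on an (embeddings, targets) training set.

    With no training data the posterior reduces to the prior (C, delta).
    """

    def __init__(self, params: KernelParams, X: np.ndarray | None = None,
                 Y: np.ndarray | None = None):
        self.params = params
        self.X = np.zeros((0, 0)) if X is None else np.asarray(X, float)
        self.Y = np.zeros(0) if Y is None else np.asarray(Y, float)
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError("X and Y row counts differ")
        self._refresh()

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def _refresh(self) -> None:
        if self.n == 0:
            self._chol = None
            self._alpha = None
            return
        K = _kernel_matrix(self.X, self.X, self.params)
        K[np.diag_indices_from(K)] += self.params.sigma_n**2
        self._chol = _factorize(K)
        self._alpha = cho_solve(self._chol, self.Y - self.params.C)

    def with_params(self, params: KernelParams) -> "GPModel":
        return GPModel(params, self.X, self.Y)

    def posterior(self, Z: np.ndarray, noisy: bool = False):
        """Posterior mean and variance at query embeddings ``Z``.

        mu = C + k(z,X)^T (K + sigma_n^2 I)^-1 (Y - C)
        sigma^2 = k(z,z) - k(z,X)^T (K + sigma_n^2 I)^-1 k(z,X)
        ``noisy=True`` adds sigma_n^2 for the noisy-observation predictive.
        """
        Z = np.atleast_2d(np.asarray(Z, float))
        p = self.params
        if self.n == 0:
            mu = np.full(Z.shape[0], p.C)
            var = np.full(Z.shape[0], p.delta)
        else:
            if Z.shape[1] != self.X.shape[1]:
                raise ValueError("query dimension differs from training data")
            Ks = _kernel_matrix(Z, self.X, p)  # (q, n)
            mu = p.C + Ks @ self._alpha
            V = cho_solve(self._chol, Ks.T)  # (n, q)
            var = p.delta - np.sum(Ks.T * V, axis=0)
            var = np.maximum(var, 0.0)
        if noisy:
            var = var + p.sigma_n**2
        return mu, var

    def acquisition(self, Z: np.ndarray, beta: float = 0.0) -> np.ndarray:
        """UCB/LCB score mu + beta * sigma (latent sigma by default)."""
        mu, var = self.posterior(Z)
        return mu + beta * np.sqrt(var)

    def log_marginal_likelihood(self) -> float:
        """ln p(Y|X) on mean-centered targets, including the n/2 ln 2pi term."""
        if self.n < 1:
            return 0.0
        r = self.Y - self.params.C
        c, low = self._chol
        logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
        return float(
            -0.5 * r @ self._alpha - 0.5 * logdet - 0.5 * self.n * math.log(2 * math.pi)
        )


def _mll_and_grads(X, Y, log_delta, log_lam, log_sn, C):
    """Normalized (per-datapoint) MLL and its gradients wrt log-params and C."""
    n = X.shape[0]
    delta, lam, sn = math.exp(log_delta), math.exp(log_lam), math.exp(log_sn)
    D2 = _sqdist(X, X)
    Krbf = delta * np.exp(-D2 / (2.0 * lam**2))
    K = Krbf + sn**2 * np.eye(n)
    chol = _factorize(K)
    r = Y - C
    alpha = cho_solve(chol, r)
    c, _ = chol
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    mll = -0.5 * float(r @ alpha) - 0.5 * logdet - 0.5 * n * math.log(2 * math.pi)
    Kinv = cho_solve(chol, np.eye(n))
    W = np.outer(alpha, alpha) - Kinv  # d mll / dK = W/2
    g_delta = 0.5 * float(np.sum(W * Krbf))
    g_lam = 0.5 * float(np.sum(W * (Krbf * (D2 / lam**2))))
    g_sn = 0.5 * float(np.trace(W)) * 2.0 * sn**2
    g_C = float(np.sum(alpha))
    return mll / n, np.array([g_delta, g_lam, g_sn, g_C]) / n


def fit_mll(
    model: GPModel,
    steps: int = 600,
    lr: float = 1e-3,
    optimizer: str = "adam",
    return_trace: bool = False,
):
    """Fit (delta, lambda, sigma_n, C) by gradient ascent on the normalized MLL.

    The budget is a fixed step count (no early stopping). ``optimizer`` is
    "adam" (default) or "gd" for plain gradient ascent. Non-finite loss
    aborts with the offending parameter state in the message.
    """
    if model.n < 2:
        raise ValueError("fitting requires at least 2 training points")
    X, Y = model.X, model.Y
    p = model.params
    theta = np.array([math.log(p.delta), math.log(p.lam), math.log(max(p.sigma_n, 1e-6)), p.C])
    m = np.zeros(4)
    v = np.zeros(4)
    trace = []
    for t in range(1, steps + 1):
        mll, g = _mll_and_grads(X, Y, *theta)
        if not np.isfinite(mll) or not np.all(np.isfinite(g)):
            raise FloatingPointError(
                f"non-finite MLL at step {t}; params (log d, log l, log sn, C) = {theta}"
            )
        trace.append(mll)
        if optimizer == "adam":
            m = 0.9 * m + 0.1 * g
            v = 0.999 * v + 0.001 * g * g
            mh = m / (1 - 0.9**t)
            vh = v / (1 - 0.999**t)
            theta = theta + lr * mh / (np.sqrt(vh) + 1e-8)
        elif optimizer == "gd":
            theta = theta + lr * g
        else:
            raise ValueError(f"unknown optimizer {optimizer!r}")
    fitted = model.with_params(
        KernelParams(
            delta=math.exp(theta[0]), lam=math.exp(theta[1]),
            sigma_n=math.exp(theta[2]), C=theta[3],
        )
    )
    return (fitted, trace) if return_trace else fitted


def initial_params(X: np.ndarray, Y: np.ndarray) -> KernelParams:
    """Data-driven initialization: median-distance length scale, target moments."""
    X, Y = np.asarray(X, float), np.asarray(Y, float)
    n = min(X.shape[0], 200)
    D2 = _sqdist(X[:n], X[:n])
    med = float(np.sqrt(np.median(D2[np.triu_indices(n, 1)])))
    var = float(np.var(Y))
    return KernelParams(
        delta=max(var, 1e-3),
        lam=max(med, 1e-3),
        sigma_n=max(0.3 * math.sqrt(max(var, 1e-6)), 1e-3),
        C=float(np.mean(Y)),
    )


def fit_gp_on_sequences(
    seqs, faff, encoder: encoders.Encoder | None = None,
    steps: int = 600, lr: float = 1e-3, optimizer: str = "adam",
) -> tuple[GPModel, encoders.Encoder]:
    """Encode sequences, initialize from the data and fit the GP."""
    seqs = list(seqs)
    if encoder is None:
        encoder = encoders.onehot_encoder(len(seqs[0]))
    X = encoder.encode_many(seqs)
    Y = np.asarray(faff, float)
    model = GPModel(initial_params(X, Y), X, Y)
    return fit_mll(model, steps=steps, lr=lr, optimizer=optimizer), encoder
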