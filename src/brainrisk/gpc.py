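"""Gaussian-process binary classification with a linear kernel.

The classifier places a zero-mean GP prior over the latent function with
covariance ``K = Xc @ Xc.T + jitter * I`` (``Xc`` is the training matrix after
subtracting the training voxelwise mean) and a probit likelihood
``p(y_i | f_i) = Phi(y_i f_i)``.  The non-Gaussian posterior over the latent
values is approximated either by expectation propagation (EP, the default) or
by a Laplace approximation; both yield a Gaussian latent posterior from which
the predictive probability of class +1 (at-risk) is the probit average
``Phi(mu* / sqrt(1 + s2*))``.

Because the kernel is linear and parameter-free, the posterior mean of the
latent function is an explicit hyperplane: ``weight_vector`` returns the
per-voxel weights ``w = Xc.T @ alpha`` whose inner product with a (centred)
test point reproduces the latent decision value exactly.  Positive weights
favour the at-risk class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

__all__ = [
    "GPConfig",
    "GPModel",
    "GPFitError",
    "fit_gpc",
    "predict_proba",
    "latent_values",
    "classify",
    "weight_vector",
]

_SQRT2 = math.sqrt(2.0)
_LOG2PI = math.log(2.0 * math.pi)


class GPFitError(RuntimeError):
    """Raised when the posterior approximation cannot be computed."""


@dataclass(frozen=True)
class GPConfig:
    """Configuration of the GP classifier.

    jitter is relative to the mean kernel diagonal; the probit likelihood and
    the linear kernel are the only supported (and paper-faithful) choices.
    """

    kernel: str = "linear"
    jitter: float = 1e-6
    likelihood: str = "probit"
    approximation: str = "expectation_propagation"
    max_iterations: int = 200
    convergence_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.kernel != "linear":
            raise ValueError(f"unsupported kernel: {self.kernel!r}")
        if self.likelihood != "probit":
            raise ValueError(f"unsupported likelihood: {self.likelihood!r}")
        if self.approximation not in ("expectation_propagation", "laplace"):
            raise ValueError(f"unsupported approximation: {self.approximation!r}")
        if self.jitter <= 0:
            raise ValueError("jitter must be positive")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class GPModel:
    """Fitted GP classifier state (linear kernel, probit likelihood)."""

    X_centered: np.ndarray      # (n, p) training matrix, column-centred
    column_mean: np.ndarray     # (p,) training voxelwise mean
    y: np.ndarray               # (n,) labels in {+1, -1}
    dual_coefficients: np.ndarray   # (n,) alpha: latent mean = k*.T @ alpha
    sqrt_site_precision: np.ndarray  # (n,) S^1/2 (EP sites or Laplace W)
    chol_B: np.ndarray          # cholesky of B = I + S^1/2 K S^1/2
    jitter_abs: float           # absolute jitter added to the kernel diagonal
    log_marginal_likelihood: float
    config: GPConfig
    n_iterations: int

    @property
    def n_features(self) -> int:
        return self.X_centered.shape[1]


# --------------------------------------------------------------------------
# numba-compiled numerics.  The EP site loop is inherently sequential, so it
# is compiled; everything else is small dense linear algebra.

@njit(cache=True)
def _ndtr(z):
    return 0.5 * math.erfc(-z / _SQRT2)


@njit(cache=True)
def _phi_over_ndtr(z):
    # phi(z) / Phi(z), robust in the lower tail (inverse Mills ratio).
    if z > -25.0:
        return math.exp(-0.5 * z * z - 0.5 * _LOG2PI) / (0.5 * math.erfc(-z / _SQRT2))
    zz = z * z
    return -z / (1.0 - 1.0 / zz + 3.0 / (zz * zz) - 15.0 / (zz * zz * zz))


@njit(cache=True)
def _log_ndtr(z):
    if z > -8.0:
        return math.log(0.5 * math.erfc(-z / _SQRT2))
    return -0.5 * z * z - 0.5 * _LOG2PI - math.log(_phi_over_ndtr(z))


@njit(cache=True)
def _ep_core(K, y, tol, max_iter):
    """Expectation propagation for GP probit classification.

    Sequential site updates with rank-1 posterior downdates, followed by a
    numerically stable recomputation of the posterior after every sweep.
    Returns (alpha, sqrt_site_prec, chol_B, log_Z, sweeps, converged).
    """
    n = K.shape[0]
    nu = np.zeros(n)
    tau = np.zeros(n)
    Sigma = K.copy()
    mu = np.zeros(n)
    st = np.zeros(n)
    L = np.eye(n)
    converged = False
    sweeps = 0
    for it in range(max_iter):
        sweeps = it + 1
        max_delta = 0.0
        for i in range(n):
            sii = Sigma[i, i]
            tau_cav = 1.0 / sii - tau[i]
            nu_cav = mu[i] / sii - nu[i]
            if tau_cav <= 1e-12:
                continue  # pathological cavity; skip this site update
            s2 = 1.0 / tau_cav
            m = nu_cav * s2
            denom = math.sqrt(1.0 + s2)
            zi = y[i] * m / denom
            r = _phi_over_ndtr(zi)
            mu_hat = m + y[i] * s2 * r / denom
            s2_hat = s2 - s2 * s2 * r * (r + zi) / (1.0 + s2)
            if s2_hat < 1e-14:
                s2_hat = 1e-14
            dtau = 1.0 / s2_hat - tau_cav - tau[i]
            dnu = mu_hat / s2_hat - nu_cav - nu[i]
            tau[i] += dtau
            nu[i] += dnu
            coef = dtau / (1.0 + dtau * sii)
            si = Sigma[:, i].copy()
            for a in range(n):
                for b in range(n):
                    Sigma[a, b] -= coef * si[a] * si[b]
            mu = Sigma @ nu
            ad = abs(dtau)
            if abs(dnu) > ad:
                ad = abs(dnu)
            if ad > max_delta:
                max_delta = ad
        # recompute posterior from site parameters (numerical hygiene)
        for i in range(n):
            st[i] = math.sqrt(tau[i]) if tau[i] > 0.0 else 0.0
        B = np.eye(n)
        SK = np.empty((n, n))
        for a in range(n):
            for b in range(n):
                SK[a, b] = st[a] * K[a, b]
                B[a, b] += st[a] * K[a, b] * st[b]
        L = np.linalg.cholesky(B)
        V = np.linalg.solve(L, SK)
        Sigma = K - V.T @ V
        mu = Sigma @ nu
        if max_delta < tol:
            converged = True
            break

    # dual coefficients: alpha = nu - S^1/2 B^-1 S^1/2 K nu
    t = st * (K @ nu)
    w1 = np.linalg.solve(L, t.reshape(n, 1))
    w2 = np.linalg.solve(L.T.copy(), w1).ravel()
    alpha = nu - st * w2

    # EP log marginal likelihood (independent-terms form), with vacuous
    # sites' precisions floored so every term stays finite.
    log_z = 0.0
    tau_c = np.empty(n)
    for i in range(n):
        tau_c[i] = tau[i] if tau[i] > 1e-10 else 1e-10
    # cavity parameters from the converged posterior
    for i in range(n):
        sii = Sigma[i, i]
        tau_cav = 1.0 / sii - tau[i]
        if tau_cav <= 1e-12:
            tau_cav = 1e-12
        nu_cav = mu[i] / sii - nu[i]
        s2_cav = 1.0 / tau_cav
        m_cav = nu_cav * s2_cav
        zi = y[i] * m_cav / math.sqrt(1.0 + s2_cav)
        mu_site = nu[i] / tau_c[i]
        v = s2_cav + 1.0 / tau_c[i]
        log_z += _log_ndtr(zi) + 0.5 * math.log(v) + (m_cav - mu_site) ** 2 / (2.0 * v)
    A = K.copy()
    for i in range(n):
        A[i, i] += 1.0 / tau_c[i]
    LA = np.linalg.cholesky(A)
    mu_site_vec = nu / tau_c
    sol = np.linalg.solve(LA, mu_site_vec.reshape(n, 1)).ravel()
    for i in range(n):
        log_z -= math.log(LA[i, i])
        log_z -= 0.5 * sol[i] * sol[i]
    return alpha, st, L, log_z, sweeps, converged


def _laplace_core(K: np.ndarray, y: np.ndarray, tol: float, max_iter: int):
    """Laplace approximation: Newton iteration on the latent mode."""
    n = len(y)
    f = np.zeros(n)
    eye = np.eye(n)
    converged = False
    it = 0
    a = np.zeros(n)
    for it in range(1, max_iter + 1):
        z = y * f
        r = np.array([_phi_over_ndtr(v) for v in z])
        grad = y * r
        W = r * r + z * r  # -d2 log Phi(y f) / df2, positive (log-concave)
        sW = np.sqrt(W)
        B = eye + sW[:, None] * K * sW[None, :]
        L = np.linalg.cholesky(B)
        b = W * f + grad
        c = np.linalg.solve(L, (sW * (K @ b))[:, None]).ravel()
        a = b - sW * np.linalg.solve(L.T, c[:, None]).ravel()
        f_new = K @ a
        delta = float(np.max(np.abs(f_new - f)))
        f = f_new
        if delta < tol:
            converged = True
            break
    z = y * f
    r = np.array([_phi_over_ndtr(v) for v in z])
    grad = y * r
    W = r * r + z * r
    sW = np.sqrt(W)
    B = eye + sW[:, None] * K * sW[None, :]
    L = np.linalg.cholesky(B)
    log_z = (
        -0.5 * float(a @ f)
        + float(sum(_log_ndtr(v) for v in z))
        - float(np.sum(np.log(np.diag(L))))
    )
    return grad, sW, L, log_z, it, converged


# --------------------------------------------------------------------------
# public API

def _validate_features(X: np.ndarray, name: str) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError(f"{name} contains non-finite values")
    return X


def fit_gpc(X_train: np.ndarray, y_train: np.ndarray, config: GPConfig | None = None) -> GPModel:
    """Fit the GP classifier.  Deterministic: no randomness is involved.

    Raises GPFitError if only one class is present or if the approximation
    fails to converge within ``config.max_iterations``.
    """
    config = config or GPConfig()
    X = _validate_features(X_train, "X_train")
    y = np.asarray(y_train, dtype=np.float64).ravel()
    if len(y) != X.shape[0]:
        raise ValueError("X_train and y_train have inconsistent lengths")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError("labels must be +1 or -1")
    if len(np.unique(y)) < 2:
        raise GPFitError("training labels contain a single class")

    col_mean = X.mean(axis=0)
    Xc = X - col_mean
    K = Xc @ Xc.T
    mean_diag = float(np.mean(np.diag(K)))
    jitter_abs = config.jitter * mean_diag if mean_diag > 0 else config.jitter
    K_j = K + jitter_abs * np.eye(len(y))

    if config.approximation == "expectation_propagation":
        alpha, st, L, log_z, iters, converged = _ep_core(
            K_j, y, config.convergence_tol, config.max_iterations
        )
    else:
        alpha, st, L, log_z, iters, converged = _laplace_core(
            K_j, y, config.convergence_tol, config.max_iterations
        )
    if not converged:
        raise GPFitError(
            f"{config.approximation} did not converge in {iters} iterations "
            f"(tol={config.convergence_tol})"
        )
    if not math.isfinite(log_z):
        raise GPFitError("log marginal likelihood is not finite")
    return GPModel(
        X_centered=Xc,
        column_mean=col_mean,
        y=y,
        dual_coefficients=alpha,
        sqrt_site_precision=st,
        chol_B=L,
        jitter_abs=jitter_abs,
        log_marginal_likelihood=log_z,
        config=config,
        n_iterations=iters,
    )


def latent_values(model: GPModel, X_test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and variance of the latent function at test points."""
    X = _validate_features(X_test, "X_test")
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"X_test has {X.shape[1]} columns, model expects {model.n_features}"
        )
    Xc = X - model.column_mean
    kstar = model.X_centered @ Xc.T                  # (n, m)
    kss = np.einsum("ij,ij->i", Xc, Xc) + model.jitter_abs
    mean = kstar.T @ model.dual_coefficients
    v = np.linalg.solve(model.chol_B, model.sqrt_site_precision[:, None] * kstar)
    var = np.maximum(kss - np.einsum("ij,ij->j", v, v), 0.0)
    return mean, var


def predict_proba(model: GPModel, X_test: np.ndarray) -> np.ndarray:
    """Predictive probability of the at-risk class (+1) for each test row.

    Values lie strictly inside (0, 1).
    """
    mean, var = latent_values(model, X_test)
    p = np.array([_ndtr(m / math.sqrt(1.0 + v)) for m, v in zip(mean, var)])
    tiny = np.finfo(float).tiny
    return np.clip(p, tiny, 1.0 - 1e-16)


def classify(p, threshold: float = 0.5):
    """Threshold predictive probabilities into labels.

    +1 (at-risk) iff p > threshold; a probability exactly equal to the
    threshold is assigned to the control class (-1) by convention.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie strictly between 0 and 1")
    p_arr = np.asarray(p, dtype=float)
    labels = np.where(p_arr > threshold, 1, -1)
    return labels if p_arr.ndim else int(labels)


def weight_vector(model: GPModel) -> np.ndarray:
    """Primal weights of the linear-kernel decision hyperplane.

    ``w @ (x - column_mean)`` equals the latent posterior mean at ``x``;
    positive weights favour the at-risk class.
    """
    if model.config.kernel != "linear":
        raise ValueError("weight vector is defined for the linear kernel only")
    return model.X_centered.T @ model.dual_coefficients
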