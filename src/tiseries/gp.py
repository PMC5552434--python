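"""Gaussian-process regression engine.

Supports two observation models on a shared squared-exponential prior:

* Gaussian targets (log reaction times): exact conjugate inference.
  Replicated observations at one input may be pre-averaged; a per-row
  count ``m`` scales the noise variance (sufficient-statistic
  aggregation).
* Binomial targets (choice accuracy): ``k`` successes out of ``m``
  Bernoulli trials per input through a logistic link, with the latent
  posterior approximated by Laplace's method at the Newton-located mode.

Both paths expose predictive means, latent-quantile credible intervals
mapped through the link (so probability intervals stay inside [0, 1] and
nest), and the posterior of the latent derivative — the learning rate in
log-odds per trial when the latent is a choice log-odds curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.special import expit

from .errors import ConfigError, ConvergenceError, GPNumericalError, OptimizationError

__all__ = [
    "KernelParams",
    "GPData",
    "LatentPosterior",
    "PredictionPoint",
    "DerivativeEstimate",
    "se_kernel",
    "fit_gaussian",
    "fit_bernoulli_laplace",
    "optimize_hyperparameters",
    "predict",
    "derivative",
    "Z80",
    "Z99",
]

# standard-normal quantiles for equal-tailed 80% / 99% intervals
Z80 = 1.2815515655446004
Z99 = 2.5758293035489004

_GH_NODES, _GH_WEIGHTS = hermegauss(40)
_GH_WEIGHTS = _GH_WEIGHTS / np.sqrt(2.0 * np.pi)


@dataclass(frozen=True)
class KernelParams:
    """Squared-exponential kernel with one lengthscale per input dimension."""

    variance: float
    lengthscales: tuple[float, ...]
    jitter: float = 1e-8

    def __post_init__(self):
        if self.variance <= 0.0:
            raise ConfigError(f"variance must be > 0, got {self.variance}")
        ls = tuple(float(l) for l in np.atleast_1d(self.lengthscales))
        object.__setattr__(self, "lengthscales", ls)
        if any(l <= 0.0 for l in ls):
            raise ConfigError(f"lengthscales must be > 0, got {ls}")
        if self.jitter < 0.0:
            raise ConfigError("jitter must be >= 0")


def _as2d(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ConfigError(f"inputs must be 1-D or 2-D, got shape {X.shape}")
    return X


def se_kernel(X1, X2, params: KernelParams) -> np.ndarray:
    """K[i, j] = variance * exp(-0.5 * sum_d ((x1_id - x2_jd) / l_d)^2)."""
    X1, X2 = _as2d(X1), _as2d(X2)
    if X1.shape[1] != X2.shape[1]:
        raise ConfigError(
            f"input dimensionality mismatch: {X1.shape[1]} vs {X2.shape[1]}"
        )
    ls = np.asarray(params.lengthscales)
    if ls.size == 1 and X1.shape[1] > 1:
        ls = np.full(X1.shape[1], ls[0])
    if ls.size != X1.shape[1]:
        raise ConfigError(
            f"{ls.size} lengthscales for {X1.shape[1]}-dimensional inputs"
        )
    diff = (X1[:, None, :] - X2[None, :, :]) / ls
    return params.variance * np.exp(-0.5 * np.einsum("ijd,ijd->ij", diff, diff))


def _training_kernel(X: np.ndarray, params: KernelParams) -> np.ndarray:
    K = se_kernel(X, X, params)
    return K + params.jitter * np.eye(len(K))


@dataclass(frozen=True)
class GPData:
    """Training inputs plus either binomial counts or real targets."""

    X: np.ndarray
    kind: str  # "gaussian" | "binomial"
    y: np.ndarray | None = None
    k: np.ndarray | None = None
    m: np.ndarray | None = None
    noise_variance: float | None = None

    @classmethod
    def gaussian(cls, X, y, noise_variance: float, m=None) -> "GPData":
        X = _as2d(X)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(X):
            raise ConfigError("X and y lengths differ")
        if not np.all(np.isfinite(y)):
            raise ConfigError("targets must be finite")
        if noise_variance <= 0.0:
            raise ConfigError(f"noise_variance must be > 0, got {noise_variance}")
        m = np.ones(len(y)) if m is None else np.asarray(m, dtype=float).ravel()
        if np.any(m < 1):
            raise ConfigError("replicate counts m must be >= 1")
        return cls(X=X, kind="gaussian", y=y, m=m, noise_variance=float(noise_variance))

    @classmethod
    def binomial(cls, X, k, m) -> "GPData":
        X = _as2d(X)
        k = np.asarray(k, dtype=float).ravel()
        m = np.asarray(m, dtype=float).ravel()
        if not (len(k) == len(m) == len(X)):
            raise ConfigError("X, k, m lengths differ")
        if np.any(m < 1):
            raise ConfigError("binomial totals m must be >= 1")
        if np.any(k < 0) or np.any(k > m):
            raise ConfigError("successes k must satisfy 0 <= k <= m")
        return cls(X=X, kind="binomial", k=k, m=m)

    def __len__(self) -> int:
        return len(self.X)


@dataclass
class LatentPosterior:
    """(Approximate) posterior over the latent function at the training inputs.

    ``alpha`` reproduces the predictive mean as ``K* . alpha + mean_const``;
    the stored Cholesky factors reproduce predictive variances.  For the
    Gaussian likelihood ``chol`` factors ``K + diag(noise/m)``; for the
    Laplace approximation it factors ``B = I + W^1/2 K W^1/2``.
    """

    data: GPData
    params: KernelParams
    mean_const: float
    f_hat: np.ndarray
    alpha: np.ndarray
    chol: np.ndarray
    w_sqrt: np.ndarray | None
    log_marginal: float
    kind: str
    cov: np.ndarray = field(repr=False, default=None)

    @property
    def likelihood(self) -> str:
        return "gaussian" if self.kind == "gaussian" else "bernoulli-logit"


def fit_gaussian(data: GPData, params: KernelParams) -> LatentPosterior:
    """Exact conjugate GP regression; prior mean is the sample mean of y."""
    if data.kind != "gaussian":
        raise ConfigError("fit_gaussian requires gaussian-kind data")
    n = len(data)
    if n == 0:
        return LatentPosterior(
            data=data, params=params, mean_const=0.0,
            f_hat=np.empty(0), alpha=np.empty(0),
            chol=np.empty((0, 0)), w_sqrt=None, log_marginal=0.0, kind="gaussian",
        )
    mean_const = float(np.mean(data.y))
    K = _training_kernel(data.X, params)
    noise = data.noise_variance / data.m
    Ky = K + np.diag(noise)
    try:
        L = np.linalg.cholesky(Ky)
    except np.linalg.LinAlgError as exc:
        raise GPNumericalError(
            f"Cholesky of K + noise failed after jitter {params.jitter}: {exc}"
        ) from exc
    resid = data.y - mean_const
    alpha = cho_solve((L, True), resid)
    f_hat = K @ alpha + mean_const
    log_marginal = float(
        -0.5 * resid @ alpha
        - np.sum(np.log(np.diag(L)))
        - 0.5 * n * np.log(2.0 * np.pi)
    )
    # posterior covariance at the training inputs: K - K (Ky)^-1 K
    v = solve_triangular(L, K, lower=True)
    cov = K - v.T @ v
    return LatentPosterior(
        data=data, params=params, mean_const=mean_const, f_hat=f_hat,
        alpha=alpha, chol=L, w_sqrt=None, log_marginal=log_marginal,
        kind="gaussian", cov=cov,
    )


def _binom_loglik(f: np.ndarray, k: np.ndarray, m: np.ndarray) -> float:
    # binomial log-likelihood through the logistic link, up to the
    # f-independent combinatorial constant
    return float(k @ f - m @ np.logaddexp(0.0, f))


def fit_bernoulli_laplace(
    data: GPData,
    params: KernelParams,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> LatentPosterior:
    """Laplace approximation for binomial counts with logistic link.

    Newton iteration locates the mode of p(f | k) under a zero-mean GP
    prior (latent 0 = chance probability 0.5); the curvature there gives
    the approximate Gaussian posterior and marginal likelihood.
    """
    if data.kind != "binomial":
        raise ConfigError("fit_bernoulli_laplace requires binomial-kind data")
    n = len(data)
    if n == 0:
        return LatentPosterior(
            data=data, params=params, mean_const=0.0,
            f_hat=np.empty(0), alpha=np.empty(0),
            chol=np.empty((0, 0)), w_sqrt=None, log_marginal=0.0, kind="binomial",
        )
    K = _training_kernel(data.X, params)
    k, m = data.k, data.m
    f = np.zeros(n)
    I = np.eye(n)
    change = np.inf
    for it in range(1, max_iter + 1):
        p = expit(f)
        W = m * p * (1.0 - p)
        W = np.maximum(W, 1e-12)
        w_sqrt = np.sqrt(W)
        grad = k - m * p
        B = I + (w_sqrt[:, None] * K) * w_sqrt[None, :]
        try:
            L = np.linalg.cholesky(B)
        except np.linalg.LinAlgError as exc:
            raise GPNumericalError(f"Cholesky of B failed at iteration {it}: {exc}") from exc
        b = W * f + grad
        a = b - w_sqrt * cho_solve((L, True), w_sqrt * (K @ b))
        f_new = K @ a
        change = float(np.max(np.abs(f_new - f)))
        f = f_new
        if change < tol:
            break
    else:
        raise ConvergenceError(
            f"Newton iteration for the latent mode did not converge within "
            f"{max_iter} iterations (last max |df| = {change:.3e}, n = {n})",
            iterations=max_iter,
            last_change=change,
        )
    p = expit(f)
    W = np.maximum(m * p * (1.0 - p), 1e-12)
    w_sqrt = np.sqrt(W)
    B = I + (w_sqrt[:, None] * K) * w_sqrt[None, :]
    L = np.linalg.cholesky(B)
    alpha = k - m * p  # gradient of the log-likelihood at the mode
    a = cho_solve((np.linalg.cholesky(K), True), f)
    log_marginal = float(
        _binom_loglik(f, k, m) - 0.5 * f @ a - np.sum(np.log(np.diag(L)))
    )
    # Laplace covariance at the training inputs: (K^-1 + W)^-1
    v = solve_triangular(L, w_sqrt[:, None] * K, lower=True)
    cov = K - v.T @ v
    return LatentPosterior(
        data=data, params=params, mean_const=0.0, f_hat=f, alpha=alpha,
        chol=L, w_sqrt=w_sqrt, log_marginal=log_marginal, kind="binomial",
        cov=cov,
    )


def fit(data: GPData, params: KernelParams, **kwargs) -> LatentPosterior:
    """Dispatch on the data kind."""
    if data.kind == "gaussian":
        return fit_gaussian(data, params)
    return fit_bernoulli_laplace(data, params, **kwargs)


def _latent_predict(
    post: LatentPosterior, Xstar: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Predictive mean and variance of the latent function at Xstar."""
    Xstar = _as2d(Xstar)
    n = len(post.data)
    prior_var = post.params.variance + post.params.jitter
    if n == 0:
        mu = np.full(len(Xstar), post.mean_const)
        return mu, np.full(len(Xstar), prior_var)
    Ks = se_kernel(post.data.X, Xstar, post.params)
    mu = Ks.T @ post.alpha + post.mean_const
    if post.kind == "gaussian":
        v = solve_triangular(post.chol, Ks, lower=True)
    else:
        v = solve_triangular(post.chol, post.w_sqrt[:, None] * Ks, lower=True)
    var = prior_var - np.einsum("ij,ij->j", v, v)
    return mu, np.maximum(var, 0.0)


@dataclass(frozen=True)
class PredictionPoint:
    """Response-scale estimate at one input with nested credible intervals."""

    x: tuple[float, ...]
    latent_mean: float
    latent_sd: float
    response_mean: float
    lo80: float
    hi80: float
    lo99: float
    hi99: float


def _gh_expect_expit(mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    # E[expit(f)] under f ~ N(mu, sd^2), by Gauss-Hermite quadrature
    grid = mu[:, None] + sd[:, None] * _GH_NODES[None, :]
    return expit(grid) @ _GH_WEIGHTS


def predict(post: LatentPosterior, Xstar) -> list[PredictionPoint]:
    """Response-scale predictions with 80%/99% credible intervals.

    Intervals are latent-Gaussian quantiles mapped through the link
    (identity for log RT, logistic for accuracy), so probability
    intervals respect [0, 1] and 80% bands nest inside 99% bands.  The
    response mean for the binomial path is the posterior expectation of
    the choice probability (Gauss-Hermite over the latent).
    """
    Xstar = _as2d(Xstar)
    if len(post.data) and Xstar.shape[1] != post.data.X.shape[1]:
        raise ConfigError(
            f"prediction inputs have dimension {Xstar.shape[1]}, "
            f"training inputs {post.data.X.shape[1]}"
        )
    mu, var = _latent_predict(post, Xstar)
    sd = np.sqrt(var)
    if post.kind == "gaussian":
        resp = mu
        lo80, hi80 = mu - Z80 * sd, mu + Z80 * sd
        lo99, hi99 = mu - Z99 * sd, mu + Z99 * sd
    else:
        resp = _gh_expect_expit(mu, sd)
        lo80, hi80 = expit(mu - Z80 * sd), expit(mu + Z80 * sd)
        lo99, hi99 = expit(mu - Z99 * sd), expit(mu + Z99 * sd)
    return [
        PredictionPoint(
            x=tuple(Xstar[i]),
            latent_mean=float(mu[i]),
            latent_sd=float(sd[i]),
            response_mean=float(resp[i]),
            lo80=float(lo80[i]),
            hi80=float(hi80[i]),
            lo99=float(lo99[i]),
            hi99=float(hi99[i]),
        )
        for i in range(len(Xstar))
    ]


@dataclass(frozen=True)
class DerivativeEstimate:
    """Posterior of the latent slope at one input (log-odds/trial for
    accuracy fits, log-seconds/trial for RT fits)."""

    x: tuple[float, ...]
    mean: float
    sd: float
    lo80: float
    hi80: float
    lo99: float
    hi99: float

    def ci(self, level: int) -> tuple[float, float]:
        if level == 80:
            return self.lo80, self.hi80
        if level == 99:
            return self.lo99, self.hi99
        raise ConfigError(f"only 80/99 intervals are stored, asked for {level}")


def derivative(post: LatentPosterior, Xstar, dim: int = 0) -> list[DerivativeEstimate]:
    """Posterior of df/dx_dim at each row of Xstar.

    Uses the cross-covariance between the latent at the training inputs
    and its derivative at the query point; for the squared-exponential
    kernel the derivative process has prior variance variance/l_dim^2.
    """
    Xstar = _as2d(Xstar)
    d_in = post.data.X.shape[1] if len(post.data) else Xstar.shape[1]
    if not 0 <= dim < d_in:
        raise ConfigError(f"derivative dimension {dim} out of range for {d_in}-D inputs")
    ls = np.asarray(post.params.lengthscales)
    if ls.size == 1 and d_in > 1:
        ls = np.full(d_in, ls[0])
    ell = ls[dim]
    prior_dvar = post.params.variance / ell**2
    out = []
    n = len(post.data)
    for xs in Xstar:
        if n == 0:
            out.append(_deriv_point(xs, 0.0, np.sqrt(prior_dvar)))
            continue
        ks = se_kernel(post.data.X, xs[None, :], post.params).ravel()
        # d k(x*, x_i) / d x*_dim
        dks = ks * (post.data.X[:, dim] - xs[dim]) / ell**2
        mean = float(dks @ post.alpha)
        if post.kind == "gaussian":
            v = solve_triangular(post.chol, dks, lower=True)
        else:
            v = solve_triangular(post.chol, post.w_sqrt * dks, lower=True)
        var = max(prior_dvar - float(v @ v), 0.0)
        out.append(_deriv_point(xs, mean, np.sqrt(var)))
    return out


def _deriv_point(x: np.ndarray, mean: float, sd: float) -> DerivativeEstimate:
    return DerivativeEstimate(
        x=tuple(x),
        mean=mean,
        sd=sd,
        lo80=mean - Z80 * sd,
        hi80=mean + Z80 * sd,
        lo99=mean - Z99 * sd,
        hi99=mean + Z99 * sd,
    )


def _log_marginal(data: GPData, params: KernelParams, noise_variance=None) -> float:
    if data.kind == "gaussian":
        d = replace(data, noise_variance=float(noise_variance))
        return fit_gaussian(d, params).log_marginal
    return fit_bernoulli_laplace(data, params).log_marginal


def optimize_hyperparameters(
    data: GPData,
    init: KernelParams,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 2,
    seed: int = 0,
    optimize_noise: bool = False,
) -> tuple[KernelParams, float] | tuple[KernelParams, float, float]:
    """Maximize the (approximate) log marginal likelihood.

    Works in log-parameter space with L-BFGS-B (finite-difference
    gradients); ``n_starts - 1`` extra starts are drawn log-uniformly
    inside the bounds.  The returned parameters never score worse than
    ``init``.  Returns (params, log_marginal) or, for the Gaussian path
    with ``optimize_noise``, (params, noise_variance, log_marginal).
    """
    bounds = dict(bounds or {})
    d = data.X.shape[1]
    ls0 = np.asarray(init.lengthscales)
    if ls0.size == 1 and d > 1:
        ls0 = np.full(d, ls0[0])
    span = np.ptp(data.X, axis=0)
    span = np.where(span > 0, span, 1.0)
    var_lo, var_hi = bounds.get("variance", (1e-3, 1e3))
    ls_lo, ls_hi = bounds.get("lengthscale", (None, None))
    noise_lo, noise_hi = bounds.get("noise_variance", (1e-6, 1e3))
    lo = [var_lo] + [ls_lo if ls_lo else s / 100.0 for s in span]
    hi = [var_hi] + [ls_hi if ls_hi else s * 10.0 for s in span]
    use_noise = data.kind == "gaussian" and optimize_noise
    theta0 = [init.variance] + list(ls0)
    if use_noise:
        theta0.append(data.noise_variance)
        lo.append(noise_lo)
        hi.append(noise_hi)
    log_lo, log_hi = np.log(lo), np.log(hi)

    def unpack(log_theta):
        theta = np.exp(log_theta)
        params = KernelParams(
            variance=float(theta[0]),
            lengthscales=tuple(theta[1 : 1 + d]),
            jitter=init.jitter,
        )
        noise = float(theta[1 + d]) if use_noise else data.noise_variance
        return params, noise

    def objective(log_theta):
        try:
            params, noise = unpack(log_theta)
            return -_log_marginal(data, params, noise)
        except (GPNumericalError, ConvergenceError):
            return np.inf

    x0 = np.clip(np.log(theta0), log_lo, log_hi)
    starts = [x0]
    rng = np.random.default_rng(seed)
    for _ in range(max(0, n_starts - 1)):
        starts.append(rng.uniform(log_lo, log_hi))
    best_x, best_val = None, np.inf
    failures = []
    for s in starts:
        try:
            res = minimize(
                objective, s, method="L-BFGS-B",
                bounds=list(zip(log_lo, log_hi)),
            )
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(repr(exc))
            continue
        if np.isfinite(res.fun) and res.fun < best_val:
            best_x, best_val = res.x, float(res.fun)
    init_val = objective(x0)
    if best_x is None and not np.isfinite(init_val):
        raise OptimizationError(
            f"all {len(starts)} optimization starts failed: {failures}"
        )
    if best_x is None or init_val < best_val:
        best_x, best_val = x0, float(init_val)
    params, noise = unpack(best_x)
    if use_noise:
        return params, noise, -best_val
    return params, -best_val
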