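"""Single-case inferential statistics.

A patient's score is compared to a control sample treated as a sample, not
a population: the frequentist route is the modified t-test (the case is an
extra observation from the control distribution under the null), and the
Bayesian route samples the posterior of the control-population parameters
under non-informative priors, yielding for each draw the probability that
a random control (conditioned on the case's covariates) would score below
the case.  Averaging that probability over draws gives the one-tailed
Bayesian p, which doubles as a point estimate of the case's abnormality
percentile; the 2.5th/97.5th percentiles of the per-draw probabilities give
a 95% credible interval on that percentile.

Two tests are provided with covariate support:

* a deficit test (is the case below the control population on one task,
  conditional on covariates such as age), and
* a standardized difference test (is the case's standardized gap between
  two tasks outside the control population's gap distribution), the
  machinery behind dissociation criteria.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SingleCaseResult",
    "DiffCaseResult",
    "crawford_howell_t",
    "btd_cov",
    "bsdt_cov",
]

Tail = str  # {"lower", "upper", "two"}
_TAILS = ("lower", "upper", "two")


def _tail_adjust(p_lower: float, tail: Tail) -> float:
    if tail == "lower":
        return p_lower
    if tail == "upper":
        return 1.0 - p_lower
    if tail == "two":
        return 2.0 * min(p_lower, 1.0 - p_lower)
    raise ValueError(f"tail must be one of {_TAILS}, got {tail!r}")


@dataclass
class SingleCaseResult:
    p: float                      # tail-adjusted probability
    abnormality_pct: float        # 100 * lower-tail probability
    abnormality_ci: tuple[float, float]   # 95% credible interval (pct)
    z_ccc: float                  # case-controls effect size at point estimates
    tail: Tail
    n_controls: int
    n_mc: int | None = None
    seed: int | None = None
    statistic: float | None = None   # t statistic when analytic
    df: float | None = None


@dataclass
class DiffCaseResult:
    p_diff: float
    z_x: float                    # case's conditional z on task X
    z_y: float
    rho: float                    # estimated conditional correlation
    tail: Tail
    n_controls: int
    n_mc: int
    seed: int


# ---------------------------------------------------------------------------
# Frequentist modified t
# ---------------------------------------------------------------------------

def crawford_howell_t(y: np.ndarray, y_star: float, tail: Tail = "lower") -> SingleCaseResult:
    """Modified t-test comparing a single case to a control sample.

    t = (y* - mean(y)) / (sd(y) * sqrt((n + 1) / n)) on n - 1 df; the
    lower-tail p estimates the proportion of the control population below
    the case.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 controls")
    m = y.mean()
    s = y.std(ddof=1)
    if not s > 0:
        raise ValueError("control sd is zero")
    t = (y_star - m) / (s * np.sqrt((n + 1) / n))
    df = n - 1
    p_lower = float(stats.t.cdf(t, df))
    return SingleCaseResult(
        p=_tail_adjust(p_lower, tail),
        abnormality_pct=100.0 * p_lower,
        abnormality_ci=(100.0 * p_lower, 100.0 * p_lower),
        z_ccc=float((y_star - m) / s),
        tail=tail, n_controls=n, statistic=float(t), df=float(df),
    )


# ---------------------------------------------------------------------------
# Bayesian deficit test with covariates
# ---------------------------------------------------------------------------

def _design(y: np.ndarray, X: np.ndarray | None):
    y = np.asarray(y, dtype=float)
    n = y.size
    if X is None or (hasattr(X, "size") and np.asarray(X).size == 0):
        X = np.empty((n, 0))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n:
        raise ValueError("covariate rows must match control scores")
    c = X.shape[1]
    for j in range(c):
        if X[:, j].std(ddof=1) <= 0:
            raise ValueError(f"covariate column {j} has zero variance")
    D = np.concatenate([np.ones((n, 1)), X], axis=1)
    return y, D, n, c


def btd_cov(y: np.ndarray, X: np.ndarray | None, y_star: float,
            x_star: np.ndarray | None = None, tail: Tail = "lower",
            n_mc: int = 100_000, seed: int | None = None) -> SingleCaseResult:
    """Bayesian deficit test for a single case, allowing for covariates.

    Controls' scores y are regressed on [1, X]; per Monte-Carlo draw the
    residual variance is drawn from its scaled inverse-chi-square posterior
    (sigma2 = SSE / g, g ~ chi2(n - c - 1)), the coefficients from their
    conditional Gaussian posterior, and the case is standardized against
    the drawn conditional distribution at its own covariate values.  The
    reported p is the tail-adjusted mean of the per-draw standard-normal
    tail probabilities; with no covariates this reproduces the modified
    t-test's p.  Deterministic given the seed.
    """
    y, D, n, c = _design(y, X)
    nu = n - c - 1
    if nu < 2 or n < c + 3:
        raise ValueError(f"need n >= c + 3 controls (n={n}, c={c})")
    if n_mc < 1:
        raise ValueError("n_mc must be positive")
    if x_star is None:
        x_star = np.empty(0)
    x_star = np.atleast_1d(np.asarray(x_star, dtype=float))
    if x_star.size != c:
        raise ValueError(f"x_star has {x_star.size} covariates, expected {c}")
    d_star = np.concatenate([[1.0], x_star])

    DtD = D.T @ D
    cond = np.linalg.cond(DtD)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("collinear covariate design")
    A = np.linalg.inv(DtD)
    b = A @ (D.T @ y)
    resid = y - D @ b
    sse = float(resid @ resid)
    if not sse > 0:
        raise ValueError("perfect fit: residual variance is zero")

    rng = np.random.default_rng(seed)
    g = rng.chisquare(nu, size=n_mc)
    sigma2 = sse / g
    LA = np.linalg.cholesky(A)
    zdraw = rng.standard_normal((n_mc, c + 1))
    # beta_i = b + sigma_i * L_A z_i ; conditional mean at case covariates
    cond_mean = b @ d_star + np.sqrt(sigma2) * (zdraw @ (LA.T @ d_star))
    z = (y_star - cond_mean) / np.sqrt(sigma2)
    p_i = stats.norm.cdf(z)
    p_lower = float(p_i.mean())
    lo, hi = np.percentile(p_i, [2.5, 97.5])

    s_hat = np.sqrt(sse / nu)
    return SingleCaseResult(
        p=_tail_adjust(p_lower, tail),
        abnormality_pct=100.0 * p_lower,
        abnormality_ci=(100.0 * float(lo), 100.0 * float(hi)),
        z_ccc=float((y_star - b @ d_star) / s_hat),
        tail=tail, n_controls=n, n_mc=n_mc, seed=seed,
    )


# ---------------------------------------------------------------------------
# Bayesian standardized difference test with covariates
# ---------------------------------------------------------------------------

def _chol2x2(S11, S12, S22):
    """Vectorized Cholesky of 2x2 SPD matrices."""
    L11 = np.sqrt(S11)
    L21 = S12 / L11
    L22 = np.sqrt(np.maximum(S22 - L21 ** 2, 1e-300))
    return L11, L21, L22


def bsdt_cov(Y: np.ndarray, X: np.ndarray | None, y_star: np.ndarray,
             x_star: np.ndarray | None = None, tail: Tail = "two",
             prior: str = "standard_theory", n_mc: int = 100_000,
             seed: int | None = None) -> DiffCaseResult:
    """Bayesian standardized difference test for a case on two tasks,
    allowing for covariates.

    Controls' score pairs Y (n x 2) are regressed on [1, X]; per draw the
    2x2 residual covariance is drawn from its inverse-Wishart posterior
    (scale = residual cross-product S, df = n - c - 1), the coefficient
    matrix from its matrix-normal posterior, the case's two scores are
    standardized against the drawn conditional distribution, and the
    standardized difference d = (z_x - z_y) / sqrt(2 - 2 rho) is referred
    to the standard normal.  The reported p_diff is the tail-adjusted mean
    over draws.  Only the ``standard_theory`` prior is implemented.
    """
    if prior != "standard_theory":
        raise NotImplementedError(
            f"prior {prior!r} not implemented; use 'standard_theory'"
        )
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != 2:
        raise ValueError("Y must be n x 2 control score pairs")
    n = Y.shape[0]
    _, D, _, c = _design(Y[:, 0], X)
    nu = n - c - 1
    if n < c + 4:
        raise ValueError(f"need n >= c + 4 controls (n={n}, c={c})")
    for col in range(2):
        if Y[:, col].std(ddof=1) <= 0:
            raise ValueError(f"score column {col} is constant")
    y_star = np.asarray(y_star, dtype=float)
    if y_star.shape != (2,):
        raise ValueError("y_star must hold the case's two scores")
    if x_star is None:
        x_star = np.empty(0)
    x_star = np.atleast_1d(np.asarray(x_star, dtype=float))
    if x_star.size != c:
        raise ValueError(f"x_star has {x_star.size} covariates, expected {c}")
    d_star = np.concatenate([[1.0], x_star])

    DtD = D.T @ D
    if np.linalg.cond(DtD) > 1e12:
        raise ValueError("collinear covariate design")
    A = np.linalg.inv(DtD)
    B = A @ (D.T @ Y)                      # (c+1) x 2
    E = Y - D @ B
    S = E.T @ E
    rho_hat = S[0, 1] / np.sqrt(S[0, 0] * S[1, 1])
    if abs(rho_hat) >= 1 - 1e-10:
        raise ValueError(
            "estimated conditional correlation is +/-1; the standardized "
            "difference is undefined"
        )

    rng = np.random.default_rng(seed)
    # inverse-Wishart(S, nu) draws via Bartlett on the Wishart(nu, S^-1):
    # Sigma = (L_P Phi Phi^T L_P^T)^-1 with P = S^-1, Phi lower-triangular,
    # diag sqrt(chi2(nu), chi2(nu-1)), off-diag N(0,1).
    P = np.linalg.inv(S)
    LP = np.linalg.cholesky(P)
    c11 = np.sqrt(rng.chisquare(nu, size=n_mc))
    c22 = np.sqrt(rng.chisquare(nu - 1, size=n_mc))
    n21 = rng.standard_normal(n_mc)
    # Omega = L_P Phi (2x2, vectorized); Wishart draw is Omega Omega^T
    O11 = LP[0, 0] * c11
    O21 = LP[1, 0] * c11 + LP[1, 1] * n21
    O22 = LP[1, 1] * c22
    # Sigma = (Omega Omega^T)^{-1}
    W11 = O11 ** 2
    W12 = O11 * O21
    W22 = O21 ** 2 + O22 ** 2
    det = W11 * W22 - W12 ** 2
    S11 = W22 / det
    S12 = -W12 / det
    S22 = W11 / det

    # B_i ~ matrix-normal(B, A, Sigma_i): B + L_A Z L_Sigma^T
    LA = np.linalg.cholesky(A)
    Z = rng.standard_normal((n_mc, c + 1, 2))
    LS11, LS21, LS22 = _chol2x2(S11, S12, S22)
    u = np.einsum("j,jk,ikl->il", d_star, LA, Z)   # n_mc x 2 (= d* L_A Z)
    m1 = d_star @ B[:, 0] + u[:, 0] * LS11
    m2 = d_star @ B[:, 1] + (u[:, 0] * LS21 + u[:, 1] * LS22)

    zx = (y_star[0] - m1) / np.sqrt(S11)
    zy = (y_star[1] - m2) / np.sqrt(S22)
    rho = S12 / np.sqrt(S11 * S22)
    dstat = (zx - zy) / np.sqrt(np.maximum(2.0 - 2.0 * rho, 1e-12))
    p_i = stats.norm.cdf(dstat)
    p_lower = float(p_i.mean())

    s1 = np.sqrt(S[0, 0] / nu)
    s2 = np.sqrt(S[1, 1] / nu)
    return DiffCaseResult(
        p_diff=_tail_adjust(p_lower, tail),
        z_x=float((y_star[0] - d_star @ B[:, 0]) / s1),
        z_y=float((y_star[1] - d_star @ B[:, 1]) / s2),
        rho=float(rho_hat),
        tail=tail, n_controls=n, n_mc=n_mc,
        seed=seed if seed is not None else -1,
    )
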