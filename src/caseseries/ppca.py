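"""Probabilistic PCA with missing data.

Model: x = W z + mu + eps with z ~ N(0, I_k) and isotropic noise
eps ~ N(0, sigma2 I).  Fitting is EM over the observed entries only
(missingness assumed at random): the E-step computes the posterior of each
row's latent z given its observed coordinates; the M-step jointly maximizes
the expected complete-data log-likelihood over (mu, W) per variable and
then sigma2.  The observed-data log-likelihood is tracked per iteration and
is monotone non-decreasing, the standard EM guarantee.

Missing cells are imputed by the posterior mean mu_m + W_m E[z | x_obs].
The latent dimension k is chosen by element-wise cross-validation: observed
entries are partitioned into folds, each fold is masked in turn, the model
is refit, and held-out RMSE is averaged; the k with the lowest mean RMSE
wins, ties going to the smaller k.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PPCAModel", "CVReport", "fit_ppca", "select_components_cv", "impute"]

_SIGMA2_FLOOR = 1e-12


@dataclass
class PPCAModel:
    k: int
    W: np.ndarray          # variables x k loading matrix
    mu: np.ndarray         # variable means
    sigma2: float          # isotropic noise variance
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int
    seed: int | None = None

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


@dataclass
class CVReport:
    k_grid: list[int]
    rmse_mean: np.ndarray
    rmse_sd: np.ndarray
    chosen_k: int
    folds: int
    repetitions: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "k_grid": list(map(int, self.k_grid)),
            "rmse_mean": [float(x) for x in self.rmse_mean],
            "rmse_sd": [float(x) for x in self.rmse_sd],
            "chosen_k": int(self.chosen_k),
            "folds": int(self.folds),
            "repetitions": int(self.repetitions),
            "seed": int(self.seed),
        }


def _check_mask(mask: np.ndarray) -> None:
    if not mask.any(axis=1).all():
        raise ValueError("every row must have at least one observed entry")
    if not mask.any(axis=0).all():
        raise ValueError("every column must have at least one observed entry")


def _estep(X, mask, W, mu, sigma2):
    """Posterior moments E[z], Cov[z] per row plus the observed-data
    log-likelihood, batched over rows.

    Uses the Woodbury identities on C_i = W_o W_o^T + sigma2 I:
    logdet C_i = (q_i - k) log sigma2 + logdet M_i and
    d^T C_i^-1 d = (d^T d - d^T W_o M_i^-1 W_o^T d) / sigma2,
    with M_i = W_o^T W_o + sigma2 I over row i's observed coordinates.
    """
    k = W.shape[1]
    maskf = mask.astype(float)
    Xc = np.where(mask, X - mu, 0.0)
    M = np.einsum("ij,ja,jb->iab", maskf, W, W) + sigma2 * np.eye(k)
    Minv = np.linalg.inv(M)
    proj = Xc @ W                                   # n x k
    Ez = np.einsum("iab,ib->ia", Minv, proj)
    Czz = sigma2 * Minv
    q = maskf.sum(axis=1)
    _, logdetM = np.linalg.slogdet(M)
    logdetC = (q - k) * np.log(sigma2) + logdetM
    quad = (np.einsum("ij,ij->i", Xc, Xc)
            - np.einsum("ia,iab,ib->i", proj, Minv, proj)) / sigma2
    ll = float(-0.5 * np.sum(q * np.log(2 * np.pi) + logdetC + quad))
    return Ez, Czz, ll


def fit_ppca(X: np.ndarray, mask: np.ndarray | None = None, k: int = 2,
             tol: float = 1e-6, max_iter: int = 1000,
             seed: int | None = None) -> PPCAModel:
    """Fit probabilistic PCA by EM on a matrix with an observed mask.

    Parameters
    ----------
    X, mask : (n, p) data and boolean observed mask (None = fully observed;
        NaN cells in X are also treated as missing).
    k : latent dimension, 1 <= k < p.
    tol : relative change in observed-data log-likelihood declaring
        convergence.
    max_iter : iteration cap.
    seed : seeds the random orthonormal initialization of W; the fit is
        deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if mask is None:
        mask = np.isfinite(X)
    mask = np.asarray(mask, dtype=bool)
    if not (1 <= k < p):
        raise ValueError(f"k must satisfy 1 <= k < {p}, got {k}")
    _check_mask(mask)

    rng = np.random.default_rng(seed)
    # init: observed column means, random orthonormal loadings, moment noise
    mu = np.array([X[mask[:, j], j].mean() for j in range(p)])
    col_var = np.array([
        X[mask[:, j], j].var(ddof=0) if mask[:, j].sum() > 1 else 1.0
        for j in range(p)
    ])
    scale = np.sqrt(max(col_var.mean(), 1e-8))
    Q, _ = np.linalg.qr(rng.standard_normal((p, k)))
    W = Q * scale
    sigma2 = max(col_var.mean() * 0.5, _SIGMA2_FLOOR)

    Xz = np.where(mask, X, 0.0)
    maskf = mask.astype(float)
    n_obs = int(mask.sum())
    trace: list[float] = []
    converged = False
    for it in range(max_iter + 1):
        Ez, Czz, ll = _estep(X, mask, W, mu, sigma2)
        trace.append(ll)
        if len(trace) > 1:
            denom = max(abs(trace[-2]), 1.0)
            if abs(ll - trace[-2]) / denom < tol:
                converged = True
                break
        if it == max_iter:
            break
        Ezz = Czz + Ez[:, :, None] * Ez[:, None, :]

        # M-step: per-variable joint update of (mu_j, w_j) from rows where
        # j is observed; then sigma2 from observed residual moments.
        # Augmented per-row moment matrix [[1, Ez],[Ez, Ezz]]:
        Aaug = np.empty((n, k + 1, k + 1))
        Aaug[:, 0, 0] = 1.0
        Aaug[:, 0, 1:] = Ez
        Aaug[:, 1:, 0] = Ez
        Aaug[:, 1:, 1:] = Ezz
        G = np.einsum("ij,ikl->jkl", maskf, Aaug)          # p x (k+1) x (k+1)
        Daug = np.concatenate([np.ones((n, 1)), Ez], axis=1)
        b = (Daug.T @ Xz).T                                # p x (k+1)
        theta = np.linalg.solve(G, b[..., None])[..., 0]
        mu = theta[:, 0]
        W = theta[:, 1:]

        # sigma2 = mean over observed cells of E[(x - mu_j - w_j z)^2]
        lin = Ez @ W.T                                     # n x p
        quad = np.einsum("ikl,jk,jl->ij", Ezz, W, W)       # n x p
        resid = float(np.sum(maskf * (
            Xz ** 2 - 2 * Xz * (mu + lin) + mu ** 2 + 2 * mu * lin + quad)))
        sigma2 = max(resid / n_obs, _SIGMA2_FLOOR)

    return PPCAModel(k=k, W=W, mu=mu, sigma2=float(sigma2),
                     loglik_trace=np.array(trace), converged=converged,
                     n_iter=len(trace) - 1, seed=seed)


def impute(X: np.ndarray, mask: np.ndarray, model: PPCAModel) -> np.ndarray:
    """Complete a matrix: observed cells pass through bitwise unchanged,
    missing cells get posterior-mean reconstructions."""
    X = np.asarray(X, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if X.shape[1] != model.W.shape[0]:
        raise ValueError(
            f"matrix has {X.shape[1]} variables but model was fit on {model.W.shape[0]}"
        )
    if mask.shape != X.shape:
        raise ValueError("mask shape must match matrix shape")
    out = X.copy()
    if mask.all():
        return out
    Ez, _, _ = _estep(X, mask, model.W, model.mu, model.sigma2)
    recon = model.mu + Ez @ model.W.T
    out[~mask] = recon[~mask]
    return out


def _fold_assignment(mask: np.ndarray, folds: int, rng: np.random.Generator,
                     max_tries: int = 200) -> np.ndarray:
    """Assign observed cells to folds such that masking any single fold
    leaves every row and column with >=1 observed entry."""
    obs_idx = np.flatnonzero(mask.ravel())
    n_obs = obs_idx.size
    for _ in range(max_tries):
        perm = rng.permutation(n_obs)
        assign = np.full(mask.size, -1, dtype=int)
        assign[obs_idx[perm]] = np.arange(n_obs) % folds
        assign = assign.reshape(mask.shape)
        ok = True
        for f in range(folds):
            train = mask & (assign != f)
            if not (train.any(axis=1).all() and train.any(axis=0).all()):
                ok = False
                break
        if ok:
            return assign
    raise ValueError(
        f"could not partition observed entries into {folds} folds keeping "
        "every row/column observed; try fewer folds"
    )


def select_components_cv(X: np.ndarray, mask: np.ndarray | None = None,
                         k_grid=(1, 2, 3, 4, 5), folds: int = 5,
                         repetitions: int = 100, seed: int = 0,
                         tol: float = 1e-5, max_iter: int = 300) -> CVReport:
    """Choose the PPCA latent dimension by repeated element-wise k-fold CV.

    Per repetition the observed cells are randomly partitioned into
    ``folds`` sets; each fold is masked in turn, the model refit on the
    rest at every candidate k, and RMSE measured on the held-out cells.
    ``chosen_k`` is the argmin of the mean RMSE over all (repetition, fold)
    pairs, ties broken toward smaller k.
    """
    X = np.asarray(X, dtype=float)
    if mask is None:
        mask = np.isfinite(X)
    mask = np.asarray(mask, dtype=bool)
    _check_mask(mask)
    k_grid = sorted(int(k) for k in k_grid)
    rng = np.random.default_rng(seed)

    errs = {k: [] for k in k_grid}
    for rep in range(repetitions):
        assign = _fold_assignment(mask, folds, rng)
        for f in range(folds):
            held = mask & (assign == f)
            train_mask = mask & ~held
            fit_seed = int(rng.integers(0, 2**31 - 1))
            for k in k_grid:
                model = fit_ppca(X, train_mask, k=k, tol=tol,
                                 max_iter=max_iter, seed=fit_seed)
                completed = impute(X, train_mask, model)
                diff = (completed - X)[held]
                errs[k].append(float(np.sqrt(np.mean(diff ** 2))))

    rmse_mean = np.array([np.mean(errs[k]) for k in k_grid])
    rmse_sd = np.array([np.std(errs[k], ddof=1) if len(errs[k]) > 1 else 0.0
                        for k in k_grid])
    chosen = k_grid[int(np.argmin(rmse_mean))]   # argmin takes first = smallest k
    return CVReport(k_grid=list(k_grid), rmse_mean=rmse_mean, rmse_sd=rmse_sd,
                    chosen_k=chosen, folds=folds, repetitions=repetitions,
                    seed=seed)
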