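"""Group PCA on the patient score matrix.

The pipeline mirrors standard exploratory practice in case-series
neuropsychology: sampling adequacy (Kaiser-Meyer-Olkin), eigenvalue > 1
extraction from the test correlation matrix, varimax rotation for
interpretability, regression-method factor scores, and projection of the
control group into the patient-defined factor space with a deficit cutoff
at two control SDs below the control mean on each factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ScoreMatrix

__all__ = [
    "PCASolution",
    "FactorScores",
    "kmo",
    "extract_components",
    "varimax",
    "factor_scores",
    "project_controls",
    "tucker_congruence",
]


@dataclass
class PCASolution:
    test_ids: list[str]
    R: np.ndarray                  # test correlation matrix
    eigenvalues: np.ndarray        # all p eigenvalues, descending
    n_retained: int
    loadings: np.ndarray           # tests x factors, rotated
    rotation: np.ndarray           # factors x factors orthogonal T
    var_explained: np.ndarray      # per retained factor, post-rotation
    total_var_explained: float
    kmo: float
    score_coefficients: np.ndarray  # Ws = R^-1 Lambda, tests x factors

    @property
    def communalities(self) -> np.ndarray:
        return (self.loadings ** 2).sum(axis=1)

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"factor{i + 1}" for i in range(self.loadings.shape[1])]
        return pd.DataFrame(self.loadings, index=self.test_ids, columns=cols)


@dataclass
class FactorScores:
    participant_ids: list[str]
    scores: np.ndarray             # participants x factors
    control_mean: np.ndarray | None = None
    control_sd: np.ndarray | None = None
    cutoff: np.ndarray | None = None   # control_mean - 2*control_sd

    def to_frame(self) -> pd.DataFrame:
        cols = [f"factor{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.participant_ids, columns=cols)


# ---------------------------------------------------------------------------
# Sampling adequacy
# ---------------------------------------------------------------------------

def kmo(R: np.ndarray) -> float:
    """Kaiser-Meyer-Olkin measure of sampling adequacy.

    KMO = sum(r_ij^2) / (sum(r_ij^2) + sum(q_ij^2)) over i != j, where
    q_ij = -r^{ij} / sqrt(r^{ii} r^{jj}) are the anti-image partial
    correlations obtained from the inverse correlation matrix.

    Any bivariate correlation matrix with r != 0 gives exactly 0.5 (the
    partial correlation equals the correlation when only two variables
    exist); an identity matrix is degenerate (0/0) and raises.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if R.shape != (p, p) or not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("R must be a symmetric correlation matrix")
    if not np.allclose(np.diag(R), 1.0, atol=1e-8):
        raise ValueError("R must have a unit diagonal")
    eigmin = float(np.linalg.eigvalsh(R)[0])
    if eigmin < 1e-10:
        raise ValueError(
            "correlation matrix is singular; KMO undefined — regularize or "
            "drop collinear tests upstream"
        )
    Rinv = np.linalg.inv(R)
    d = np.sqrt(np.diag(Rinv))
    Q = -Rinv / np.outer(d, d)
    off = ~np.eye(p, dtype=bool)
    num = float((R[off] ** 2).sum())
    den = num + float((Q[off] ** 2).sum())
    if den == 0.0:
        raise ValueError("KMO undefined for a diagonal correlation matrix (0/0)")
    return num / den


# ---------------------------------------------------------------------------
# Extraction and rotation
# ---------------------------------------------------------------------------

def extract_components(Z: ScoreMatrix | np.ndarray,
                       test_ids: list[str] | None = None) -> PCASolution:
    """Eigenvalue > 1 extraction from the correlation matrix of a
    standardized score matrix; loadings are eigenvectors scaled by
    sqrt(eigenvalue).  If no eigenvalue strictly exceeds 1, one component
    is retained.  The returned solution is unrotated (rotation = I)."""
    if isinstance(Z, ScoreMatrix):
        values = Z.values
        test_ids = list(Z.test_ids)
    else:
        values = np.asarray(Z, dtype=float)
        if test_ids is None:
            test_ids = [f"t{j}" for j in range(values.shape[1])]
    p = values.shape[1]
    if p < 2:
        raise ValueError("extraction needs >=2 tests")
    sds = values.std(axis=0, ddof=1)
    if np.any(sds <= 0):
        j = int(np.argmax(sds <= 0))
        raise ValueError(f"constant column {test_ids[j]!r}; standardize upstream")
    R = np.corrcoef(values, rowvar=False)
    lam, vec = np.linalg.eigh(R)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    vec = vec[:, order]
    n_ret = int((lam > 1.0).sum())
    if n_ret == 0:
        n_ret = 1
    L = vec[:, :n_ret] * np.sqrt(np.clip(lam[:n_ret], 0, None))
    L, _ = _fix_columns(L)
    var = (L ** 2).sum(axis=0) / p
    # pinv handles the collinear-tests boundary (singular R); for a
    # well-conditioned R this is exactly R^-1 Lambda
    Ws = np.linalg.pinv(R) @ L
    try:
        adequacy = kmo(R)
    except ValueError:          # singular or diagonal R: adequacy undefined
        adequacy = float("nan")
    return PCASolution(
        test_ids=test_ids, R=R, eigenvalues=lam, n_retained=n_ret,
        loadings=L, rotation=np.eye(n_ret), var_explained=var,
        total_var_explained=float(var.sum()), kmo=adequacy,
        score_coefficients=Ws,
    )


def varimax_criterion(L: np.ndarray) -> float:
    """Sum over factors of the variance of the squared loadings."""
    sq = L ** 2
    return float((sq.var(axis=0)).sum())


def _fix_columns(L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sign-fix (largest-|loading| entry positive) and order columns by
    explained variance, descending.  Returns (L, signed permutation)."""
    p, k = L.shape
    S = np.eye(k)
    for j in range(k):
        i = int(np.argmax(np.abs(L[:, j])))
        if L[i, j] < 0:
            S[j, j] = -1.0
    L = L @ S
    order = np.argsort(-(L ** 2).sum(axis=0), kind="stable")
    P = np.eye(k)[:, order]
    return L @ P, S @ P


def varimax(L0: np.ndarray, kaiser_normalize: bool = True, tol: float = 1e-12,
            max_iter: int = 2000) -> tuple[np.ndarray, np.ndarray]:
    """Varimax rotation of a loading matrix.

    Maximizes the varimax criterion (the summed per-factor variance of
    squared loadings, computed on Kaiser row-normalized loadings when
    ``kaiser_normalize`` is on) over orthogonal rotations, via the standard
    SVD fixed-point iteration.  Columns of the result are sign-fixed so the
    largest-|loading| entry is positive and ordered by post-rotation
    variance explained.

    Returns ``(L, T)`` with ``L = L0 @ T`` and ``T`` orthogonal.
    """
    L0 = np.asarray(L0, dtype=float)
    p, k = L0.shape
    if k < 1:
        raise ValueError("need at least one factor")
    if k == 1:
        L, S = _fix_columns(L0.copy())
        return L, S

    h = np.sqrt((L0 ** 2).sum(axis=1))
    if kaiser_normalize:
        if np.any(h <= 0):
            raise ValueError("zero-communality row; cannot Kaiser-normalize")
        A = L0 / h[:, None]
    else:
        A = L0

    T = np.eye(k)
    d_old = 0.0
    trace = []
    converged = False
    for _ in range(max_iter):
        B = A @ T
        G = A.T @ (B ** 3 - B @ np.diag((B ** 2).sum(axis=0)) / p)
        U, s, Vt = np.linalg.svd(G)
        T = U @ Vt
        d = s.sum()
        trace.append(d)
        if d_old != 0.0 and (d - d_old) < tol * d_old:
            converged = True
            break
        if d == 0.0:   # already optimal (e.g. perfectly simple structure)
            converged = True
            break
        d_old = d
    if not converged:
        raise RuntimeError(
            f"varimax failed to converge in {max_iter} iterations; "
            f"criterion trace tail: {trace[-5:]}"
        )

    L = L0 @ T
    L, SP = _fix_columns(L)
    return L, T @ SP


def rotate_solution(solution: PCASolution, kaiser_normalize: bool = True,
                    tol: float = 1e-12, max_iter: int = 2000) -> PCASolution:
    """Apply varimax to an extracted solution, refreshing the rotation
    matrix, variance explained, and score coefficients.  Communalities are
    conserved (orthogonal rotation)."""
    if solution.n_retained == 1:
        return solution
    L0 = solution.loadings @ np.linalg.inv(solution.rotation)  # back to unrotated
    L, T = varimax(L0, kaiser_normalize=kaiser_normalize, tol=tol,
                   max_iter=max_iter)
    p = len(solution.test_ids)
    var = (L ** 2).sum(axis=0) / p
    Ws = np.linalg.pinv(solution.R) @ L
    return PCASolution(
        test_ids=solution.test_ids, R=solution.R,
        eigenvalues=solution.eigenvalues, n_retained=solution.n_retained,
        loadings=L, rotation=T, var_explained=var,
        total_var_explained=float(var.sum()), kmo=solution.kmo,
        score_coefficients=Ws,
    )


# ---------------------------------------------------------------------------
# Factor scores and control projection
# ---------------------------------------------------------------------------

def factor_scores(solution: PCASolution, Z: ScoreMatrix) -> FactorScores:
    """Regression-method factor scores: scores = Z @ R^-1 Lambda.

    ``Z`` must be standardized against the patient reference used to fit
    the solution; the fitting rows then have mean-zero scores per factor.
    """
    if list(Z.test_ids) != list(solution.test_ids):
        raise ValueError("score matrix tests do not match the PCA solution")
    return FactorScores(
        participant_ids=list(Z.participant_ids),
        scores=Z.values @ solution.score_coefficients,
    )


def project_controls(solution: PCASolution, controls_Z: ScoreMatrix,
                     cutoff_mode: str = "score_sd") -> FactorScores:
    """Project control participants into the patient factor space and attach
    control norms.

    ``controls_Z`` must already be z-scored with the *patient* means/SDs.
    Per factor: control_mean and control_sd over the individual control
    scores.  The 2-SD deficit cutoff admits two constructions:

    * ``score_sd`` (default): cutoff = control_mean - 2 * SD of the
      individual control factor scores;
    * ``projected_pseudosubject``: project a pseudo-subject sitting at
      control mean - 2 * control SD on every test; by linearity the mean
      construction coincides but the SD construction does not.
    """
    if not np.isfinite(controls_Z.values).all():
        raise ValueError("control matrix has missing entries; impute first")
    fs = factor_scores(solution, controls_Z)
    m = fs.scores.mean(axis=0)
    s = fs.scores.std(axis=0, ddof=1)
    fs.control_mean = m
    fs.control_sd = s
    if cutoff_mode == "score_sd":
        fs.cutoff = m - 2.0 * s
    elif cutoff_mode == "projected_pseudosubject":
        pseudo = controls_Z.values.mean(axis=0) - 2.0 * controls_Z.values.std(axis=0, ddof=1)
        fs.cutoff = pseudo @ solution.score_coefficients
    else:
        raise ValueError(f"unknown cutoff_mode {cutoff_mode!r}")
    return fs


def tucker_congruence(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Column-wise Tucker congruence between two loading matrices after
    greedy column matching with sign freedom; returns the matched
    coefficients (one per column of A)."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    ka, kb = A.shape[1], B.shape[1]
    C = np.zeros((ka, kb))
    for i in range(ka):
        for j in range(kb):
            denom = np.sqrt((A[:, i] ** 2).sum() * (B[:, j] ** 2).sum())
            C[i, j] = np.abs(A[:, i] @ B[:, j]) / denom if denom > 0 else 0.0
    out = np.zeros(ka)
    used: set[int] = set()
    for i in np.argsort(-C.max(axis=1)):
        best, val = -1, -1.0
        for j in range(kb):
            if j not in used and C[i, j] > val:
                best, val = j, C[i, j]
        if best >= 0:
            used.add(best)
            out[i] = val
    return out
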