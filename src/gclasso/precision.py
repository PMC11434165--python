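"""Approximate inverse of the Gram matrix by graph-restricted node-wise regression.

Column j of the precision surrogate Theta_hat comes from regressing X_j on
its graph neighbors X_{D_j}:

    OLS regime (d_j <= k):    gamma_j = argmin ||X_j - X_{D_j} gamma||^2 / n
                              tau_j^2 = ||X_j - X_{D_j} gamma_j||^2 / n
    lasso regime (d_j > k):   gamma_j = argmin ||.||^2/(2n) + lam_j |gamma|_1
                              tau_j^2 = ||.||^2 / n + lam_j |gamma_j|_1

    Theta[j, j] = 1 / tau_j^2,   Theta[k, j] = -gamma_{k,j} / tau_j^2.

With small neighborhoods the OLS regime needs no tuning at all, which is
what makes the graph-constrained estimator fast; for hub nodes whose
neighborhoods approach the sample size, the lasso regime with per-node
cross-validated penalties takes over (threshold k, selectable by the
Frobenius diagnostic ||Theta Sigma_hat - I||_F).

Note Theta_hat is generally NOT symmetric: each column solves its own
regression and no symmetrization is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import lasso_path

from .errors import DegenerateDesignError, InputError
from .graphs import Neighborhoods
from .penalized import RegressionData

__all__ = [
    "NodewiseFit",
    "PrecisionEstimate",
    "nodewise_ols",
    "nodewise_lasso",
    "assemble_theta",
    "select_threshold_k",
    "frobenius_diagnostic",
]

#: below this, 1/tau_j^2 is considered numerically meaningless
TAU_SQ_FLOOR = 1e-10
#: relative singular-value cutoff for the OLS regime
RANK_RTOL = 1e-8


@dataclass
class NodewiseFit:
    """One node-wise regression: coefficients, residual scale, and regime."""

    j: int
    gamma_hat: np.ndarray
    tau_sq: float
    regime: str  # "ols" or "lasso"
    lambda_j: float = 0.0


@dataclass
class PrecisionEstimate:
    """Columns Theta_j assembled from node-wise fits.

    ``n_cv_calls`` counts per-node cross-validations performed; it is zero
    whenever every node ran in the OLS regime (no tuning needed).
    """

    Theta_hat: np.ndarray
    per_node: list[NodewiseFit]
    k_threshold: int | None
    n_cv_calls: int = 0


def nodewise_ols(data: RegressionData, D_j: Sequence[int], j: int) -> NodewiseFit:
    """Least-squares node-wise regression of X_j on its neighborhood.

    Empty neighborhoods give gamma = 0 and tau_j^2 = ||X_j||^2 / n.

    Raises
    ------
    DegenerateDesignError
        If X_{D_j} is numerically rank deficient, or the residual scale
        tau_j^2 falls below the collinearity floor (Theta[j, j] = 1/tau_j^2
        would blow up).
    """
    D_j = np.asarray(D_j, dtype=int)
    n = data.n
    Xj = data.X[:, j]
    if D_j.size == 0:
        tau_sq = float(Xj @ Xj) / n
        gamma = np.zeros(0)
    else:
        if D_j.size >= n:
            raise DegenerateDesignError(
                f"node {j}: neighborhood size {D_j.size} >= n={n}, OLS undefined"
            )
        XD = data.X[:, D_j]
        sv = np.linalg.svd(XD, compute_uv=False)
        if sv[-1] <= RANK_RTOL * sv[0]:
            raise DegenerateDesignError(
                f"node {j}: neighborhood design is rank deficient "
                f"(condition {sv[0] / max(sv[-1], 1e-300):.2e})"
            )
        gamma, *_ = np.linalg.lstsq(XD, Xj, rcond=None)
        r = Xj - XD @ gamma
        tau_sq = float(r @ r) / n
    if tau_sq < TAU_SQ_FLOOR:
        raise DegenerateDesignError(
            f"node {j}: residual scale tau^2={tau_sq:.2e} below floor; "
            "predictor is (nearly) collinear with its neighborhood"
        )
    return NodewiseFit(j=j, gamma_hat=np.asarray(gamma, float),
                       tau_sq=tau_sq, regime="ols", lambda_j=0.0)


def nodewise_lasso(data: RegressionData, D_j: Sequence[int], j: int,
                   lambda_j: float, *, tol: float = 1e-6,
                   max_iter: int = 10_000) -> NodewiseFit:
    """Penalized node-wise regression for large neighborhoods.

    The residual scale includes the penalty term:
    tau_j^2 = ||X_j - X_{D_j} gamma||^2 / n + lambda_j ||gamma||_1.
    """
    if lambda_j < 0:
        raise InputError("lambda_j must be nonnegative")
    D_j = np.asarray(D_j, dtype=int)
    n = data.n
    Xj = data.X[:, j]
    if float(Xj @ Xj) == 0.0:
        raise InputError(f"node {j}: zero predictor column")
    if D_j.size == 0 or lambda_j >= np.max(np.abs(data.X[:, D_j].T @ Xj / n), initial=0.0):
        gamma = np.zeros(D_j.size)
        tau_sq = float(Xj @ Xj) / n
        return NodewiseFit(j=j, gamma_hat=gamma, tau_sq=tau_sq,
                           regime="lasso", lambda_j=float(lambda_j))
    XD = data.X[:, D_j]
    if lambda_j == 0:
        fit = nodewise_ols(data, D_j, j)
        return NodewiseFit(j=j, gamma_hat=fit.gamma_hat, tau_sq=fit.tau_sq,
                           regime="lasso", lambda_j=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        _, coefs, _ = lasso_path(XD, Xj, alphas=[lambda_j], tol=tol,
                                 max_iter=max_iter)
    gamma = coefs[:, -1]
    r = Xj - XD @ gamma
    tau_sq = float(r @ r) / n + lambda_j * float(np.abs(gamma).sum())
    if tau_sq < TAU_SQ_FLOOR:
        raise DegenerateDesignError(f"node {j}: tau^2={tau_sq:.2e} below floor")
    return NodewiseFit(j=j, gamma_hat=gamma, tau_sq=tau_sq,
                       regime="lasso", lambda_j=float(lambda_j))


class _NodewiseCV:
    """Per-node lasso penalty selection with shared fold Grams.

    All node-wise problems on one design share cross-validation folds, so
    the fold Gram matrices are computed once and sliced per node; paths are
    solved on the Gram (cost independent of n per sweep).
    """

    def __init__(self, data: RegressionData, folds: int = 5, seed: int = 0,
                 n_alphas: int = 8, eps: float = 0.1, tol: float = 1e-3):
        self.data = data
        self.n_alphas = n_alphas
        self.eps = eps
        self.tol = tol
        n = data.n
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
        self.fold_idx = np.array_split(order, folds)
        self.G_full = data.X.T @ data.X
        self.G_train = []
        for f in self.fold_idx:
            Xf = data.X[f]
            self.G_train.append(self.G_full - Xf.T @ Xf)

    def select_and_fit(self, j: int, D_j: np.ndarray) -> NodewiseFit:
        X = self.data.X
        n = X.shape[0]
        Xj = X[:, j]
        XD = X[:, D_j]
        lam_max = float(np.max(np.abs(self.G_full[D_j, j])) / n)
        if lam_max == 0:
            return nodewise_lasso(self.data, D_j, j, 0.0)
        alphas = np.logspace(np.log10(lam_max), np.log10(self.eps * lam_max),
                             self.n_alphas)
        mse = np.zeros(self.n_alphas)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for fi, f in enumerate(self.fold_idx):
                G = self.G_train[fi][np.ix_(D_j, D_j)]
                Xy = self.G_train[fi][D_j, j]
                tr = np.ones(n, dtype=bool)
                tr[f] = False
                _, coefs, _ = lasso_path(XD[tr], Xj[tr], alphas=alphas,
                                         precompute=G, Xy=Xy,
                                         tol=self.tol, max_iter=2000)
                rr = Xj[f][:, None] - XD[f] @ coefs
                mse += (rr ** 2).sum(axis=0)
            best = int(np.argmin(mse))
            _, coefs, _ = lasso_path(XD, Xj, alphas=alphas[: best + 1],
                                     precompute=self.G_full[np.ix_(D_j, D_j)],
                                     Xy=self.G_full[D_j, j],
                                     tol=self.tol, max_iter=2000)
        lam = float(alphas[best])
        gamma = coefs[:, -1]
        r = Xj - XD @ gamma
        tau_sq = float(r @ r) / n + lam * float(np.abs(gamma).sum())
        if tau_sq < TAU_SQ_FLOOR:
            raise DegenerateDesignError(f"node {j}: tau^2={tau_sq:.2e} below floor")
        return NodewiseFit(j=j, gamma_hat=gamma, tau_sq=tau_sq,
                           regime="lasso", lambda_j=lam)


def assemble_theta(
    data: RegressionData,
    nbh: Neighborhoods,
    k_threshold: int | None = None,
    *,
    seed: int = 0,
    cv_folds: int = 5,
    lasso_fallback: bool = False,
) -> PrecisionEstimate:
    """Column-wise assembly of the precision surrogate Theta_hat.

    ``k_threshold=None`` runs every node in the OLS regime (the pure
    graph-restricted estimator); otherwise nodes with d_j > k use the lasso
    regime with per-node cross-validated penalties.

    ``lasso_fallback=True`` reroutes nodes whose OLS design is degenerate
    to the lasso regime instead of erroring.
    """
    p = data.p
    if len(nbh.sets) != p:
        raise InputError("neighborhood count does not match number of columns")
    Theta = np.zeros((p, p))
    fits: list[NodewiseFit] = []
    cv = None
    n_cv = 0
    col_ss = (data.X ** 2).sum(axis=0) / data.n
    for j in range(p):
        D = nbh.sets[j]
        if D.size == 0:
            if col_ss[j] < TAU_SQ_FLOOR:
                raise DegenerateDesignError(f"node {j}: zero column")
            fit = NodewiseFit(j=j, gamma_hat=np.zeros(0), tau_sq=float(col_ss[j]),
                              regime="ols", lambda_j=0.0)
        elif k_threshold is None or D.size <= k_threshold:
            try:
                fit = nodewise_ols(data, D, j)
            except DegenerateDesignError:
                if not lasso_fallback:
                    raise
                if cv is None:
                    cv = _NodewiseCV(data, folds=cv_folds, seed=seed)
                fit = cv.select_and_fit(j, D)
                n_cv += 1
        else:
            if cv is None:
                cv = _NodewiseCV(data, folds=cv_folds, seed=seed)
            fit = cv.select_and_fit(j, D)
            n_cv += 1
        Theta[j, j] = 1.0 / fit.tau_sq
        if D.size:
            Theta[D, j] = -fit.gamma_hat / fit.tau_sq
        fits.append(fit)
    return PrecisionEstimate(Theta_hat=Theta, per_node=fits,
                             k_threshold=k_threshold, n_cv_calls=n_cv)


def frobenius_diagnostic(theta: PrecisionEstimate | np.ndarray,
                         data: RegressionData) -> float:
    """||Theta_hat Sigma_hat - I||_F, the empirical inversion error."""
    T = theta.Theta_hat if isinstance(theta, PrecisionEstimate) else np.asarray(theta)
    if T.shape != (data.p, data.p):
        raise InputError("Theta shape does not match design")
    Sigma_hat = data.X.T @ data.X / data.n
    # columnwise: Theta_j' Sigma row-assembled -> (Theta' Sigma)' = Sigma Theta
    M = T @ Sigma_hat - np.eye(data.p)
    return float(np.linalg.norm(M, "fro"))


def select_threshold_k(
    data: RegressionData,
    nbh: Neighborhoods,
    k_grid: Sequence[int] | None = None,
    seed: int = 0,
) -> int:
    """Pick the OLS/lasso switching threshold k by the Frobenius diagnostic.

    Evaluates ||Theta_hat(k) Sigma_hat - I||_F over the candidate grid
    (default: the distinct neighborhood sizes up to min(n/2, max d_j)) and
    returns the minimizer, ties broken toward smaller k.
    """
    if k_grid is None:
        cap = min(data.n // 2, int(nbh.d))
        k_grid = sorted({int(d) for d in nbh.d_j if d <= cap})
        if not k_grid:
            k_grid = [0]
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise InputError("k grid is empty")
    best_k, best_val = None, np.inf
    errors = []
    for k in k_grid:
        try:
            est = assemble_theta(data, nbh, k_threshold=k, seed=seed)
        except DegenerateDesignError as exc:
            errors.append((k, exc))
            continue
        val = frobenius_diagnostic(est, data)
        if val < best_val - 1e-12:
            best_k, best_val = k, val
    if best_k is None:
        raise DegenerateDesignError(
            f"all threshold candidates failed: {errors!r}"
        )
    return int(best_k)
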