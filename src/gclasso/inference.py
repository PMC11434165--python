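"""Desparsified inference: debiased estimate, CIs, p-values, global max test.

The penalized initial estimate beta_hat is biased by shrinkage; the
one-step correction

    b = beta_hat + Theta' X' (Y - X beta_hat) / n

removes enough of that bias for coordinate-wise asymptotic normality:
sqrt(n) (b_j - beta_j) -> N(0, sigma^2 Theta_j' Sigma Theta_j).  With a
noise-variance estimate sigma2_hat (refitted cross-validation by default)
this yields Wald CIs and p-values per coordinate; the same interval is
asymptotically valid uniformly over sparse coefficient vectors.

The global null beta = 0 is tested with T_n = max_j n b_j^2 / se_j^2,
calibrated by its Gumbel-type limit: after recentering by
2 log p - log log p, the statistic has limiting CDF exp(-exp(-x/2)/pi).

For correlated predictor panels (gene pathways), the effective number of
tests E0 = 1 + (1/p) sum_{i,j} (1 - r_ij^2) converts a family-wise level
into a per-predictor threshold less conservative than Bonferroni.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LassoCV

from .errors import DegenerateDesignError, InputError
from .graphs import (LaplacianMatrix, PredictorGraph, build_laplacian,
                     neighborhoods)
from .penalized import (PenalizedFit, RegressionData, _pilot_lasso,
                        fit_initial, select_lambda2)
from .precision import PrecisionEstimate, assemble_theta

__all__ = [
    "NoiseVarianceEstimate",
    "InferenceResult",
    "desparsify",
    "rcv_sigma2",
    "confidence_intervals",
    "wald_pvalues",
    "global_test",
    "gumbel_critical_value",
    "effective_number_of_tests",
    "gene_wide_alpha",
    "run_pipeline",
]


@dataclass
class NoiseVarianceEstimate:
    """Error-variance estimate with the method and split record used."""

    sigma_sq: float
    method: str  # "rcv", "oracle", "plugin"
    seed: int | None = None
    support_sizes: tuple[int, ...] = ()

    def __post_init__(self):
        if self.sigma_sq < 0:
            raise InputError("sigma_sq must be nonnegative")


@dataclass
class InferenceResult:
    """Per-coordinate debiased inference plus the global max test."""

    b_hat: np.ndarray
    se: np.ndarray  # sigma_hat_j / sqrt(n)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p_values: np.ndarray
    alpha: float
    sigma_sq: float
    T_n: float | None = None
    C_alpha: float | None = None
    global_reject: bool | None = None
    beta_init: np.ndarray | None = None
    method: str = "gcdl"
    provenance: dict = field(default_factory=dict)


def desparsify(fit: PenalizedFit | np.ndarray, theta: PrecisionEstimate | np.ndarray,
               data: RegressionData) -> np.ndarray:
    """One-step bias correction b = beta_hat + Theta' X'(Y - X beta_hat)/n."""
    beta = fit.beta_hat if isinstance(fit, PenalizedFit) else np.asarray(fit, float)
    T = theta.Theta_hat if isinstance(theta, PrecisionEstimate) else np.asarray(theta)
    if beta.shape[0] != data.p or T.shape != (data.p, data.p):
        raise InputError("shape mismatch in desparsify")
    resid = data.Y - data.X @ beta
    return beta + T.T @ (data.X.T @ resid) / data.n


def rcv_sigma2(
    data: RegressionData,
    seed: int = 0,
    *,
    cv_folds: int = 5,
    n_alphas: int = 20,
    eps: float = 0.01,
    n_splits: int = 1,
) -> NoiseVarianceEstimate:
    """Refitted cross-validation estimate of the noise variance.

    The sample is split into halves (A, B); a cross-validated lasso on A
    selects a support S_A, an OLS refit of Y_B on X_{B, S_A} gives
    sigma2_(1) = RSS_B / (|B| - |S_A|), and the roles are swapped; the two
    estimates are averaged.  ``n_splits > 1`` averages over that many
    independent splits (variance reduction; off by default).

    A half whose selected support reaches the size of the refitting half is
    dropped; if both halves fail, an error is raised.
    """
    n = data.n
    if n < 20:
        raise InputError("refitted cross-validation needs n >= 20")
    rng = np.random.default_rng(seed)
    estimates = []
    supports: list[int] = []
    for _ in range(n_splits):
        perm = rng.permutation(n)
        half1, half2 = perm[: n // 2], perm[n // 2:]
        vals = []
        for A, B in ((half1, half2), (half2, half1)):
            XA, YA = data.X[A], data.Y[A]
            lam_max = float(np.max(np.abs(XA.T @ YA / len(A))))
            if lam_max == 0:
                vals.append(float(data.Y[B] @ data.Y[B]) / len(B))
                supports.append(0)
                continue
            alphas = np.logspace(np.log10(eps * lam_max), np.log10(lam_max),
                                 n_alphas)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                cv = LassoCV(alphas=alphas, cv=cv_folds, fit_intercept=False,
                             max_iter=5000, tol=1e-4)
                cv.fit(XA, YA)
            S = np.flatnonzero(cv.coef_)
            if S.size >= len(B):
                continue  # refit df would be nonpositive; drop this half
            XB = data.X[B][:, S]
            YB = data.Y[B]
            if S.size:
                coef, *_ = np.linalg.lstsq(XB, YB, rcond=None)
                r = YB - XB @ coef
            else:
                r = YB
            vals.append(float(r @ r) / (len(B) - S.size))
            supports.append(int(S.size))
        if vals:
            estimates.append(float(np.mean(vals)))
    if not estimates:
        raise DegenerateDesignError(
            "refitted cross-validation failed: selected supports exhaust "
            "both half-samples"
        )
    return NoiseVarianceEstimate(sigma_sq=float(np.mean(estimates)),
                                 method="rcv", seed=seed,
                                 support_sizes=tuple(supports))


def _variance_weights(theta, data: RegressionData) -> np.ndarray:
    """Diagonal of Theta' Sigma_hat Theta, computed as column sums of (X Theta)^2/n."""
    T = theta.Theta_hat if isinstance(theta, PrecisionEstimate) else np.asarray(theta)
    XT = data.X @ T
    return np.einsum("ij,ij->j", XT, XT) / data.n


def confidence_intervals(
    b_hat: np.ndarray,
    theta: PrecisionEstimate | np.ndarray,
    data: RegressionData,
    sigma_sq: float | NoiseVarianceEstimate,
    alpha: float = 0.05,
) -> InferenceResult:
    """Wald CIs b_j +/- z_{1-alpha/2} sigma_hat_j / sqrt(n).

    sigma_hat_j^2 = sigma2_hat * Theta_j' Sigma_hat Theta_j.  The same
    interval carries the uniform (over sparse beta) asymptotic guarantee.
    """
    if not 0 < alpha < 1:
        raise InputError("alpha must be in (0, 1)")
    s2 = sigma_sq.sigma_sq if isinstance(sigma_sq, NoiseVarianceEstimate) else float(sigma_sq)
    if s2 < 0:
        raise InputError("sigma_sq must be nonnegative")
    omega = _variance_weights(theta, data)
    if np.any(omega <= 0):
        raise DegenerateDesignError("nonpositive variance weight Theta_j' Sigma Theta_j")
    se = np.sqrt(s2 * omega / data.n)
    z = stats.norm.ppf(1 - alpha / 2)
    b_hat = np.asarray(b_hat, float)
    return InferenceResult(
        b_hat=b_hat, se=se,
        ci_lower=b_hat - z * se, ci_upper=b_hat + z * se,
        p_values=wald_pvalues(b_hat, se), alpha=alpha, sigma_sq=s2,
    )


def wald_pvalues(b_hat: np.ndarray, se: np.ndarray,
                 alternative: str = "two-sided") -> np.ndarray:
    """Wald p-values; two-sided p_j = 2 (1 - Phi(|b_j| / se_j)) by default.

    ``alternative`` may be "two-sided", "greater" or "less".
    """
    b_hat = np.asarray(b_hat, float)
    se = np.asarray(se, float)
    if np.any(se <= 0):
        raise InputError("standard errors must be positive")
    z = b_hat / se
    if alternative == "two-sided":
        return 2 * stats.norm.sf(np.abs(z))
    if alternative == "greater":
        return stats.norm.sf(z)
    if alternative == "less":
        return stats.norm.cdf(z)
    raise InputError(f"unknown alternative {alternative!r}")


def adjust_pvalues(p_values: np.ndarray, method: str = "bonferroni"
                   ) -> np.ndarray:
    """Multiplicity-adjusted p-values (Bonferroni or Benjamini-Hochberg).

    The package's default multiplicity handling for pathway screens is the
    effective-number-of-tests threshold (:func:`effective_tests_alpha`);
    these classical corrections are provided as alternatives.
    """
    from statsmodels.stats.multitest import multipletests

    p_values = np.asarray(p_values, float)
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise InputError(f"unknown adjustment {method!r}")
    return multipletests(p_values, method=key)[1]


def gumbel_critical_value(p: int, alpha: float) -> float:
    """Critical value C_alpha = 2 log p - log log p + q_alpha of the max test.

    q_alpha = -log(pi) - 2 log log 1/(1-alpha) is the upper-alpha quantile
    of the limiting CDF exp(-exp(-x/2)/pi).
    """
    if p < 2:
        raise InputError("global test needs p >= 2")
    if not 0 < alpha < 1:
        raise InputError("alpha must be in (0, 1)")
    q_alpha = -np.log(np.pi) - 2 * np.log(np.log(1.0 / (1.0 - alpha)))
    return float(2 * np.log(p) - np.log(np.log(p)) + q_alpha)


def global_test(b_hat: np.ndarray, se: np.ndarray, p: int | None = None,
                alpha: float = 0.05) -> tuple[float, float, bool]:
    """Max test of the global null beta = 0.

    T_n = max_j b_j^2 / se_j^2 (se_j already carries the 1/sqrt(n) scale),
    compared against the Gumbel-calibrated critical value.
    Returns (T_n, C_alpha, reject).
    """
    b_hat = np.asarray(b_hat, float)
    se = np.asarray(se, float)
    if p is None:
        p = b_hat.shape[0]
    if p < 2:
        raise InputError("global test needs p >= 2")
    if np.any(se <= 0):
        raise InputError("standard errors must be positive")
    T_n = float(np.max((b_hat / se) ** 2))
    C = gumbel_critical_value(p, alpha)
    return T_n, C, bool(T_n >= C)


def effective_number_of_tests(X: np.ndarray) -> float:
    """Effective number of tests E0 = 1 + (1/p) sum_{i,j} (1 - r_ij^2).

    r_ij are pairwise Pearson correlations of the predictor columns; the
    diagonal contributes nothing since r_ii = 1.  Uncorrelated columns give
    E0 = p, perfectly correlated columns give E0 = 1.
    """
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[1] < 1:
        raise InputError("X must be an n x p matrix with p >= 1")
    if np.any(X.std(axis=0) == 0):
        raise InputError("constant column has undefined correlation")
    R = np.corrcoef(X, rowvar=False)
    R = np.atleast_2d(R)
    p = X.shape[1]
    return float(1 + (1 - R ** 2).sum() / p)


def gene_wide_alpha(e0: float, family_alpha: float = 0.05) -> float:
    """Per-test level 1 - (1 - alpha)^(1/E0) controlling the family at alpha."""
    if e0 < 1:
        raise InputError("E0 must be >= 1")
    if not 0 < family_alpha < 1:
        raise InputError("family_alpha must be in (0, 1)")
    return float(1 - (1 - family_alpha) ** (1.0 / e0))


def effective_tests_alpha(X: np.ndarray, family_alpha: float = 0.05
                          ) -> tuple[float, float]:
    """(E0, per-test alpha) for a predictor panel."""
    e0 = effective_number_of_tests(X)
    return e0, gene_wide_alpha(e0, family_alpha)


def run_pipeline(
    data: RegressionData,
    graph: PredictorGraph | LaplacianMatrix | None,
    *,
    alpha: float = 0.05,
    k_threshold: int | None = None,
    auto_k: bool = False,
    seed: int = 0,
    sigma_method: str = "rcv",
    sigma_sq: float | None = None,
    lambda1: float | None = None,
    lambda2: float | None = None,
    pilot_folds: int = 5,
    nodewise_cv_folds: int = 5,
) -> InferenceResult:
    """End-to-end debiased inference on one dataset.

    Steps: penalized initial fit (pilot-CV lambda1, plug-in lambda2, one
    augmented lasso) -> node-wise precision assembly (OLS below the
    threshold, CV lasso above) -> desparsification -> noise variance ->
    CIs, p-values and (for p >= 2) the global max test.  All tuning choices
    and seeds are recorded in ``provenance``.
    """
    if graph is None:
        graph = PredictorGraph.empty([str(i) for i in range(data.p)])
    if isinstance(graph, LaplacianMatrix):
        L = graph
    else:
        if graph.p != data.p:
            raise InputError(
                f"graph has {graph.p} nodes but X has {data.p} columns")
        L = build_laplacian(graph)
    nbh = neighborhoods(L)

    # initial fit
    pilot = _pilot_lasso(data, folds=pilot_folds, seed=seed)
    lam1 = float(lambda1) if lambda1 is not None else pilot.lambda1
    lam2 = float(lambda2) if lambda2 is not None else select_lambda2(
        data, L, lam1, pilot.beta_hat, seed=seed)
    if lam2 > 0:
        fit = fit_initial(data, L, lam1, lam2, tol=1e-7, max_iter=50_000)
    else:
        fit = PenalizedFit(beta_hat=pilot.beta_hat, lambda1=lam1, lambda2=0.0,
                           active_set=pilot.active_set,
                           kkt_residual=pilot.kkt_residual) \
            if lambda1 is None else fit_initial(data, L, lam1, 0.0,
                                                tol=1e-7, max_iter=50_000)

    # precision surrogate
    if auto_k and k_threshold is None:
        from .precision import select_threshold_k
        k_threshold = select_threshold_k(data, nbh, seed=seed)
    theta = assemble_theta(data, nbh, k_threshold=k_threshold, seed=seed,
                           cv_folds=nodewise_cv_folds)

    b = desparsify(fit, theta, data)

    if sigma_method == "oracle":
        if sigma_sq is None:
            raise InputError("oracle sigma method needs sigma_sq")
        noise = NoiseVarianceEstimate(sigma_sq=float(sigma_sq), method="oracle")
    elif sigma_method == "plugin":
        dfree = max(data.n - fit.active_set.size, 1)
        r = data.Y - data.X @ fit.beta_hat
        noise = NoiseVarianceEstimate(sigma_sq=float(r @ r) / dfree,
                                      method="plugin")
    else:
        noise = rcv_sigma2(data, seed=seed)

    result = confidence_intervals(b, theta, data, noise, alpha=alpha)
    result.beta_init = fit.beta_hat
    result.method = "gcdl" if theta.n_cv_calls == 0 else "agcdl"
    if data.p >= 2:
        result.T_n, result.C_alpha, result.global_reject = global_test(
            result.b_hat, result.se, data.p, alpha)
    result.provenance = {
        "n": data.n, "p": data.p, "alpha": alpha, "seed": seed,
        "lambda1": fit.lambda1, "lambda2": fit.lambda2,
        "k_threshold": theta.k_threshold, "n_cv_calls": theta.n_cv_calls,
        "sigma_method": noise.method, "sigma_sq": noise.sigma_sq,
        "d_max": int(nbh.d), "standardized": data.standardized,
    }
    return result
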