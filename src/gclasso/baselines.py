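"""Reference estimators for comparison.

``dl_inference`` is a plain desparsified lasso: no graph, node-wise lasso
on ALL other predictors per coordinate.  Under high within-block
correlation its per-coordinate intervals on truly active coefficients are
known to undercover badly — the comparative claim the graph-constrained
estimator improves on.

``ls_oracle`` is the infeasible least-squares benchmark that is told the
true support: OLS on S0 with textbook intervals, defined only on S0.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .errors import DegenerateDesignError, InputError
from .graphs import Neighborhoods
from .inference import (InferenceResult, confidence_intervals, desparsify,
                        global_test, rcv_sigma2)
from .penalized import RegressionData, _pilot_lasso
from .precision import assemble_theta

__all__ = ["dl_inference", "ls_oracle"]


def dl_inference(
    data: RegressionData,
    *,
    alpha: float = 0.05,
    seed: int = 0,
    nodewise_cv_folds: int = 3,
    sigma_method: str = "rcv",
    sigma_sq: float | None = None,
) -> InferenceResult:
    """Standard desparsified-lasso inference (no graph information).

    Initial fit: plain lasso with CV-selected penalty.  Precision: full
    node-wise lasso per coordinate, per-node CV penalties, residual scale
    including the +lambda_j ||gamma_j||_1 term.  The debiasing, variance
    and interval formulas are shared with the graph-constrained path.
    """
    p = data.p
    all_idx = np.arange(p)
    nbh = Neighborhoods(sets=[all_idx[all_idx != j] for j in range(p)],
                        d_j=np.full(p, p - 1), d=p - 1)
    pilot = _pilot_lasso(data, folds=5, seed=seed)
    # k=-1 forces the lasso regime at every node
    theta = assemble_theta(data, nbh, k_threshold=-1, seed=seed,
                           cv_folds=nodewise_cv_folds)
    b = desparsify(pilot.beta_hat, theta, data)
    if sigma_method == "oracle":
        if sigma_sq is None:
            raise InputError("oracle sigma method needs sigma_sq")
        s2 = float(sigma_sq)
    else:
        s2 = rcv_sigma2(data, seed=seed).sigma_sq
    result = confidence_intervals(b, theta, data, s2, alpha=alpha)
    result.beta_init = pilot.beta_hat
    result.method = "dl"
    if p >= 2:
        result.T_n, result.C_alpha, result.global_reject = global_test(
            result.b_hat, result.se, p, alpha)
    result.provenance = {"n": data.n, "p": data.p, "alpha": alpha,
                         "seed": seed, "lambda1": pilot.lambda1,
                         "sigma_sq": s2, "method": "dl"}
    return result


def ls_oracle(
    data: RegressionData,
    true_support: np.ndarray,
    alpha: float = 0.05,
) -> InferenceResult:
    """Least squares on the (known) true support.

    beta_hat = (X_S0' X_S0)^-1 X_S0' Y; sigma2 with df n - |S0|;
    CI_j = beta_hat_j +/- z * sigma_hat sqrt(Theta_LS[j,j]) / sqrt(n) with
    Theta_LS = (X_S0' X_S0 / n)^-1.  Coordinates outside the support get
    NaN estimates and intervals: the oracle makes no statement there.
    """
    S = np.asarray(sorted(set(int(j) for j in true_support)), dtype=int)
    n, p = data.n, data.p
    if S.size >= n:
        raise InputError("support size must be below n")
    if S.size == 0:
        raise InputError("empty support")
    XS = data.X[:, S]
    G = XS.T @ XS / n
    try:
        Theta_ls = np.linalg.inv(G)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDesignError("singular support design") from exc
    cond = np.linalg.cond(G)
    if not np.isfinite(cond) or cond > 1e12:
        raise DegenerateDesignError("singular support design")
    coef = Theta_ls @ (XS.T @ data.Y) / n
    r = data.Y - XS @ coef
    s2 = float(r @ r) / (n - S.size)
    se_S = np.sqrt(s2 * np.diag(Theta_ls) / n)
    z = stats.norm.ppf(1 - alpha / 2)

    b = np.full(p, np.nan)
    se = np.full(p, np.nan)
    b[S] = coef
    se[S] = se_S
    pv = np.full(p, np.nan)
    pv[S] = 2 * stats.norm.sf(np.abs(coef) / se_S)
    res = InferenceResult(
        b_hat=b, se=se, ci_lower=b - z * se, ci_upper=b + z * se,
        p_values=pv, alpha=alpha, sigma_sq=s2, method="ls_oracle",
        provenance={"n": n, "p": p, "support_size": int(S.size)},
    )
    return res
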