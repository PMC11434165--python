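import numpy as np
import pytest

from gclasso import PredictorGraph, RegressionData


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_data(rng):
    """n=50, p=10 with two strong coefficients, unit noise."""
    X = rng.standard_normal((50, 10))
    beta = np.zeros(10)
    beta[0], beta[3] = 2.0, -1.5
    Y = X @ beta + rng.standard_normal(50)
    return RegressionData(X=X, Y=Y), beta


@pytest.fixture
def triangle_graph():
    return PredictorGraph.from_edges(["a", "b", "c"],
                                     [("a", "b"), ("b", "c"), ("a", "c")])


def brute_force_penalized(X, Y, L, lam1, lam2):
    """Independent convex oracle for the penalized objective.

    Splits beta into positive and negative parts, turning the l1 term into
    a linear function over the nonnegative orthant, and minimizes the
    resulting smooth convex program with L-BFGS-B.
    """
    from scipy.optimize import minimize

    n, p = X.shape

    def obj(z):
        b = z[:p] - z[p:]
        r = Y - X @ b
        val = 0.5 * (r @ r) / n + lam1 * z.sum()
        if lam2:
            val += 0.5 * lam2 * b @ (L @ b)
        return val

    def grad(z):
        b = z[:p] - z[p:]
        g = -X.T @ (Y - X @ b) / n
        if lam2:
            g = g + lam2 * (L @ b)
        return np.concatenate([g, -g]) + lam1

    z0 = np.zeros(2 * p)
    res = minimize(obj, z0, jac=grad, method="L-BFGS-B",
                   bounds=[(0, None)] * (2 * p),
                   options={"maxiter": 20000, "ftol": 1e-16, "gtol": 1e-12})
    return res.x[:p] - res.x[p:]
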