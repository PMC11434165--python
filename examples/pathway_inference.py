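"""Per-gene confidence intervals on a small synthetic pathway panel.

Builds a 120-sample, 12-gene expression panel in which genes g1-g3 form a
highly correlated connected module and g1, g2 carry real effects, runs the
full graph-constrained debiased pipeline, and prints the interval table
plus the effective-number-of-tests threshold.  Genes whose p-value falls
below the E0-corrected threshold would be reported in a pathway screen.
"""

import numpy as np

from gclasso import (PredictorGraph, RegressionData, effective_tests_alpha,
                     run_pipeline)

rng = np.random.default_rng(7)
n, p = 120, 12
labels = [f"g{j + 1}" for j in range(p)]

# correlated module g1-g3 (rho ~ 0.95), rest independent
Sigma = np.eye(p)
Sigma[:3, :3] = 0.95
np.fill_diagonal(Sigma, 1.0)
X = rng.standard_normal((n, p)) @ np.linalg.cholesky(Sigma).T

beta = np.zeros(p)
beta[0], beta[1] = 1.5, 1.0
Y = X @ beta + rng.standard_normal(n)

# the module is connected in the pathway graph
graph = PredictorGraph.from_edges(
    labels, [("g1", "g2"), ("g2", "g3"), ("g1", "g3")])

data = RegressionData(X=X, Y=Y, labels=labels)
res = run_pipeline(data, graph, alpha=0.05, seed=1)
e0, gene_alpha = effective_tests_alpha(X, 0.05)

print(f"sigma^2 estimate (refitted CV): {res.sigma_sq:.3f}")
print(f"effective number of tests E0 = {e0:.2f} "
      f"-> per-gene alpha = {gene_alpha:.2e}\n")
print(f"{'gene':<6}{'estimate':>10}{'ci_lower':>10}{'ci_upper':>10}"
      f"{'p_value':>12}  flagged")
for j, lab in enumerate(labels):
    flag = "*" if res.p_values[j] < gene_alpha else ""
    print(f"{lab:<6}{res.b_hat[j]:>10.3f}{res.ci_lower[j]:>10.3f}"
          f"{res.ci_upper[j]:>10.3f}{res.p_values[j]:>12.2e}  {flag}")
print("\nTrue effects sit on g1 (1.5) and g2 (1.0); intervals should cover"
      "\nthem and flagged genes should be confined to the active module.")
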