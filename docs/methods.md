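# Methods

## Model and problem

We observe n i.i.d. pairs (Y_i, X_i) from the sparse linear model
Y_i = X_i' beta + eps_i, with X_i ~ N(0, Sigma), Sigma_jj = 1, and
eps_i ~ N(0, sigma^2).  The number of predictors p may exceed n.  Alongside
the design we are given an undirected weighted graph G = (V, E, W) over the
p predictors — in genomic applications, the connectivity of a gene pathway.
The goal is not selection but *uncertainty quantification*: confidence
intervals and p-values for each beta_j, and a test of the global null
beta = 0, that remain valid when predictors are highly correlated.

## The estimator

**Initial fit.**  The graph enters through the combinatorial Laplacian
L(u,v) = d_u on the diagonal, -w(u,v) on edges, 0 elsewhere.  The initial
estimate solves

    min_beta  (1/2n)||Y - X beta||^2 + lambda1 ||beta||_1
              + (1/2) lambda2 beta' L beta.

The Laplacian quadratic sum_{u~v} w(u,v)(beta_u - beta_v)^2 / ... smooths
coefficients along edges, which is exactly what helps when a block of
predictors is nearly collinear: the l1 penalty alone picks one member of
the block arbitrarily, the quadratic spreads the signal across it.

*Solver.*  With L = Q'Q (eigendecomposition, zero eigenvalues dropped) the
problem is a plain lasso on the augmented design [X; sqrt(n lambda2) Q]
with m = rank(L) zero pseudo-responses and penalty lambda1 * n/(n+m); we
solve it with scikit-learn's coordinate descent and verify the KKT
stationarity residual of the *original* problem to 1e-4 in max norm before
returning.  The factor choice is irrelevant (only Q'Q enters), which a test
asserts.

*Tuning.*  lambda2 is anchored at the plug-in rule
lambda2 = 0.1 lambda1 / ||L beta||_inf.  The rule is stated at the true
beta, and precisely when the graph is informative — coefficients constant
across connected predictors — ||L beta||_inf is zero or tiny there, so any
sparse pilot estimate (never block-constant) grossly underestimates the
smoothing level the data support; iterating the plug-in does not escape
(the fixed point stays near the pilot value).  The package therefore
treats the pilot plug-in value as an anchor and selects a decade
multiplier in {1, 10, 100, 1e3, 1e4} by 3-fold prediction cross-
validation, spanning from the raw rule up to the saturated (effectively
graph-constrained) regime; large multipliers win only when graph-
smoothness genuinely predicts.  If L beta_pilot = 0 (null pilot, or empty
graph) lambda2 falls back to 0.  The pilot's lambda1 is
chosen by 5-fold CV over a 30-point log grid on [0.01 lambda_max,
lambda_max], lambda_max = ||X'Y/n||_inf, and is reused for the single
augmented refit, so a full fit costs one CV path plus one lasso.  The
standalone `select_lambda1` performs the joint grid search (lambda2
recomputed per candidate, 10-fold, 50-point grid to 0.001 lambda_max) for
users who want it; the pipeline default is the cheaper pilot route.

**Precision surrogate.**  Let D_j = {k : L_jk != 0, k != j} be the graph
neighborhood of predictor j, d_j = |D_j|.  Column j of the approximate
inverse Gram matrix comes from regressing X_j on X_{D_j} only:

* d_j <= k (OLS regime): gamma_j by least squares,
  tau_j^2 = ||X_j - X_{D_j} gamma_j||^2 / n.  No tuning parameter at all —
  this is why the graph-constrained method is faster than the classical
  desparsified lasso, whose node-wise regressions run on all p-1 other
  columns and each need a penalty.
* d_j > k (lasso regime, the "adjusted" variant): node-wise lasso with a
  per-node 5-fold-CV penalty over an 8-point log grid on
  [0.1 lambda_max_j, lambda_max_j]; tau_j^2 adds the penalty term
  lambda_j ||gamma_j||_1 to the mean squared residual, exactly as in the
  desparsified-lasso literature.

Then Theta[j,j] = 1/tau_j^2 and Theta[k,j] = -gamma_{k,j}/tau_j^2 for
k in D_j.  Theta_hat is deliberately not symmetrized.  Isolated nodes get
gamma = 0, tau_j^2 = ||X_j||^2/n.  Degenerate neighborhoods (rank
deficiency, tau_j^2 below 1e-10) raise an error naming the node rather than
silently pseudo-inverting, because Theta[j,j] = 1/tau_j^2 is exactly the
quantity that blows up; a flag reroutes such nodes to the lasso regime.
The switching threshold k can be chosen by minimizing the empirical
inversion error ||Theta_hat Sigma_hat - I||_F over the distinct d_j values
(ties toward smaller k).

**Debiasing and intervals.**  The one-step correction
b = beta_hat + Theta' X'(Y - X beta_hat)/n satisfies
sqrt(n)(b_j - beta_j) -> N(0, sigma^2 Theta_j' Sigma Theta_j).  With the
plug-ins Sigma_hat = X'X/n and sigma2_hat, the interval is
b_j +/- z_{1-alpha/2} sigma_hat_j / sqrt(n),
sigma_hat_j^2 = sigma2_hat Theta_j' Sigma_hat Theta_j; the same formula
carries the uniform (over s0-sparse beta) asymptotic guarantee, so the
package exposes one interval.  The z-quantile is used at full double
precision.  p-values are two-sided Wald by default (one-sided by flag).

**Noise variance.**  sigma^2 is estimated by refitted cross-validation:
split the sample into halves, select variables by CV lasso on one half,
refit OLS on the other restricted to the selected support with
df = n/2 - |S_hat| (floor/ceil split for odd n), swap, average.  A half
whose selection exhausts the refit half is dropped; one split+swap by
default, multiple random splits by flag.  Oracle and residual-plugin
variants exist for diagnostics.

**Global test.**  T_n = max_j n b_j^2 / sigma_hat_j^2 is compared against
C_alpha = 2 log p - log log p + q_alpha,
q_alpha = -log(pi) - 2 log log 1/(1-alpha), the upper-alpha quantile of the
limiting CDF exp(-exp(-x/2)/pi) of the recentered maximum.  Defined for
p >= 2 only.

**Multiplicity.**  For pathway screens the effective number of tests
E0 = 1 + (1/p) sum_{i,j} (1 - r_ij^2) (r_ij the pairwise predictor
correlations) converts a family level alpha into the per-gene threshold
1 - (1-alpha)^{1/E0}; the diagonal contributes nothing, so summing over
all pairs or only i != j coincide.  Bonferroni/BH remain available.

## Baselines

* **DL** — the classical desparsified lasso: no graph, node-wise lasso on
  all p-1 remaining columns per coordinate, per-node CV penalties (3-fold
  here; these full-dimensional regressions dominate the cost of every
  comparison run), same debiasing/interval formulas.  The node-wise CV
  grid is the package default (8 log-spaced points down to 0.1 lambda_max
  per node).  DL's absolute coverage/length numbers are notoriously
  sensitive to this choice: deeper grids select smaller penalties, which
  *lengthen* DL's intervals (tau_j^2 shrinks toward the residual variance,
  inflating Theta[j,j]) and partially mask its undercoverage, while the
  default grid reproduces the short-interval, collapsed-coverage behavior
  reference implementations show on near-collinear blocks.  Only
  bound-type comparative claims should be read off this baseline.  Forcing the graph method onto
  the complete graph with every node in the lasso regime reproduces DL
  exactly — a code-path equivalence the suite asserts.
* **LS oracle** — infeasible least squares told the true support, with
  sigma2 df-corrected by n - |S0|; the reference the coverage tables are
  read against.  It makes no statement off the support (NaN there).

## Synthetic designs

The three benchmark designs (all with S0 = {1..15}, beta constant on S0,
eps ~ N(0,1), X rows i.i.d. N(0, Sigma) via Cholesky):

* **example1** — n=200, p=500; five 3-variable blocks with pairwise
  correlation 1/1.01 ~ 0.9901 on indices 1-15; identity elsewhere;
  beta_j = 3.  The near-collinear regime where the plain desparsified
  lasso collapses.
* **example2** — same layout, block correlation 0.5, beta_j = 1.
* **example3** — n=200, p=200; the same five blocks plus
  Sigma[j,k] = exp(-|j-k|) on indices 16-200 (no cross-terms).  Nodes 1-15
  have degree <= 2 and 16-200 have degree >= 183, so the threshold k = 2
  separates the regimes.

The graph places a unit-weight edge wherever Sigma has a nonzero
off-diagonal entry — the only reading that reproduces the intended degrees
(d = 2 in the block-only designs).  Replication r uses seed
base_seed + r, making studies reproducible and trivially parallelizable.

What the generator does *not* emulate: non-Gaussian designs or errors,
heteroscedasticity, model misspecification, mismatch between the graph and
the true correlation structure, and weighted/noisy pathway annotations.
Passing coverage here demonstrates correctness of the machinery under the
stated Gaussian conditions, not robustness on real cohorts.

## Problem sizes and numerical choices

Replicated studies use 200 replications by default (the reference tables
were computed at 1000; at 200 the per-coordinate MC standard error of a
95% coverage is ~0.015 and the S0-averaged summaries are accurate to well
under the comparison tolerances).  The no-graph DL baseline study runs at
30 replications: its node-wise regressions are full-dimensional, so it is
~50x the cost per replication of the graph method, and the claim it
supports (active-set coverage far below 20% under ~0.99 block correlation)
is a coarse bound for which 30 replications give ample resolution.

Tolerances: coordinate-descent duality-gap tolerance 1e-6 to 1e-8
depending on context, KKT max-norm acceptance 1e-4, rank cutoff 1e-8
(relative smallest singular value), tau^2 floor 1e-10 (error, never clip).
CV fold splits are derived from seeded generators everywhere;
penalized-fit CV ties break toward the sparser (larger) penalty, threshold
selection ties toward smaller k.

## Known limitations

* Per-node CV penalties make Theta_hat (hence interval lengths) mildly
  dependent on the CV grid in the lasso regime; the OLS regime is entirely
  tuning-free.
* The lambda2 plug-in rule degenerates to 0 when the pilot is null; the
  debiasing step, whose asymptotics do not depend on L, carries the
  inference in that case.
* No finite-sample widening is applied to the uniform interval (the theory
  provides none); p = 1 disables the global test.
* The desparsified-ridge comparison and bootstrap refinements are out of
  scope, as are GLM extensions and learning L from data.
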