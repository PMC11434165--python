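"""Coverage of the graph-constrained intervals under near-collinearity.

Runs a scaled-down replication study on the hardest benchmark design
(five 3-gene blocks with pairwise correlation ~0.99, beta = 3 on the 15
block members, n=200, p=500) and prints the averaged per-coordinate
coverage and CI length, split by active set S0 vs its complement.  Nominal
coverage is 95%; the plain desparsified lasso collapses to ~16% on S0 in
this design, the graph-aware intervals do not.

Takes about a minute (40 replications; the reference tables use 200+).
"""

from gclasso import make_example, run_study

design = make_example("example1")
report = run_study(design, ["gcdl"], n_reps=40, alpha=0.05,
                   base_seed=100)["gcdl"]

print(f"design: {design.label}  n={design.n} p={design.p} "
      f"|S0|={design.S0.size}, 40 replications\n")
print(f"AveCP_S0  (coverage, active set)  = {report.ave_cp_s0:.4f}")
print(f"AveCP_S0c (coverage, null set)    = {report.ave_cp_s0c:.4f}")
print(f"AveAL_S0  (CI length, active set) = {report.ave_al_s0:.4f}")
print(f"AveAL_S0c (CI length, null set)   = {report.ave_al_s0c:.4f}")
print("\nBoth coverages should sit near 0.95.  Active-set intervals are"
      "\nwide (~2.3): with within-block correlation 0.99 each coefficient"
      "\nis genuinely hard to pin down individually, and honest intervals"
      "\nsay so rather than undercover.")
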