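"""Desk-scale Monte Carlo: when does the SEM beat the Wald ratio?

Runs two grid cells (outcome-instrument strength gamma22 = 0.1 vs 0.5) at
reduced size and compares the empirical spread of the beta21 estimates.
When x2 explains little of y2 the two methods are equivalent; when gamma22
is large the SEM uses x2 to absorb outcome variance and is visibly more
precise.  Expect ~1 minute.
"""

from feedbackmr import run_cell

for gamma22 in (0.1, 0.5):
    cell = dict(beta21=0.1, beta12=0.1, gamma11=0.3, gamma22=gamma22,
                target_r=0.3, n=5000)
    out = run_cell(cell, reps=200, root_seed=1, cell_index=int(gamma22 * 10),
                   methods=("wald", "sem_ml"))
    fwd = out[out["direction"] == "y1->y2"].set_index("method")
    ratio = fwd.loc['sem_ml', 'emp_sd'] / fwd.loc['wald', 'emp_sd']
    print(f"gamma22 = {gamma22}:")
    print(fwd[["mean_est", "emp_sd", "mean_se", "rejection_rate", "coverage"]]
          .round(4).to_string())
    print(f"  SEM/Wald empirical-SD ratio: {ratio:.3f}\n")
print("The ratio is ~1 at gamma22 = 0.1 and clearly below 1 at gamma22 = 0.5:")
print("modelling the outcome's own instrument buys power only when that")
print("instrument explains a sizable share of the outcome variance.")
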