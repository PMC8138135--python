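"""How much case/control variance does each feature bank explain?

Runs the inferential stage on a reduced synthetic cohort: pooled t-tests on
the stride-level features, PCA at 95% cumulative variance on the signal
banks, stepwise forward logistic regression, odds ratios and Nagelkerke's
pseudo-R^2 per bank.
"""

import warnings

from gaitdep import CohortConfig, RunConfig, run_analysis

warnings.filterwarnings("ignore")

config = RunConfig(
    cohort=CohortConfig(n_case=40, n_control=40, duration=60.0),
    seed=11,
    out_dir="scratch/logistic_demo",
    stages=("features", "infer"),
)
bundle = run_analysis(config)

gs = bundle["group_summary"].table
print("pooled t-tests (case vs control), selected features:")
for feat in ("arm_swing_left", "head_posture", "walking_speed"):
    row = gs.loc[feat]
    print(f"  {feat:18s} t({int(row.df)}) = {row.t: .2f}, p = {row.p:.3f}")

print("\nstepwise logistic fits:")
for block, fit in bundle["logistic_fits"].items():
    print(f"  {block:15s} Nagelkerke R^2 = {100 * fit.nagelkerke_r2:5.1f}%  "
          f"({len(fit.terms)} terms selected)")
    for term, row in fit.terms.head(3).iterrows():
        print(f"      {term}: beta {row.beta: .2f}, OR {row.odds_ratio:.3f}, "
              f"corrected p {row.p_corrected:.3f}")

# Signal-level banks (time / frequency PCs) explain far more variance than
# the 10 interpretable stride-level features -- the pipeline's core finding.
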