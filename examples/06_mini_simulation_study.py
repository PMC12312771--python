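"""A miniature replication study: one condition, all estimators, evaluated.

Runs a reduced number of replications of the high-ICC unequal scenario and
summarizes convergence, mean estimates, SE bias, and fit rejection — the
same criteria as the full 24-condition grid (see ipdmasem.runner.full_grid
and ipdmasem.report for the complete pipeline).
"""

import pathlib

from ipdmasem import ConditionSpec, mc_interval, report, run_condition, summarize

cond = ConditionSpec("S3_high_unequal", k=30, missing=False, master_seed=11)
records = run_condition(
    cond, methods=("NP", "CR", "PS", "2L", "MVMA", "OSMASEM"), reps=25
)
summary = summarize(records)

cols = [
    "method", "convergence_rate", "mean[INT~ATT]", "se_bias_pct[INT~ATT]",
    "exact_fit_rejection", "close_fit_rejection",
]
print(summary[cols].round(2).to_string(index=False))
print(
    f"\nwithin-study truth INT~ATT = 0.43; "
    f"MC band around 5% at 25 reps: {mc_interval(0.05, 25)}"
)
print(
    "expected pattern: NP/CR estimates drift toward the between-study value\n"
    "with hugely biased naive SEs; PS/2L/MVMA/OSMASEM stay on target."
)

outdir = pathlib.Path("scratch/mini_study")
files = report(summary, outdir)
print(f"\nwrote {len(files)} table/figure files under {outdir}/")
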