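"""Naive pooling vs cluster-robust estimation on clustered data.

Both share the same point estimates (a blend of within- and between-study
effects when the levels differ); the cluster-robust variant repairs the
standard errors with a sandwich estimator and rescales the exact-fit
chi-square. Under the high-ICC unequal scenario neither recovers the
within-study path values — that is the central caution of this package.
"""

from ipdmasem import ConditionSpec, cluster_robust_fit, naive_pooling_fit
from ipdmasem.generate import center_within, generate_replication

cond = ConditionSpec("S3_high_unequal", k=50, master_seed=1)
ds = generate_replication(cond, 0)

np_fit = naive_pooling_fit(ds)
cr_fit = cluster_robust_fit(ds)
cc_fit = cluster_robust_fit(center_within(ds))  # study-mean centered variant

print("within-study population values: INT~ATT = 0.43, BEH~INT = 0.07")
print(f"{'':14s}{'INT~ATT':>10s}{'se':>9s}{'BEH~INT':>10s}{'chi2':>9s}")
for label, f in [("naive", np_fit), ("cluster-rob.", cr_fit), ("centered", cc_fit)]:
    print(
        f"{label:14s}{f.estimates['INT~ATT']:10.3f}{f.se['INT~ATT']:9.4f}"
        f"{f.estimates['BEH~INT']:10.3f}{f.chi2:9.2f}"
    )
print(
    "\nnaive and cluster-robust points are identical and pulled toward the\n"
    "between-study values; centering the data per study restores the\n"
    "within-study coefficients."
)
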