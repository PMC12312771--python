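"""Simulate one meta-analytic IPD collection and inspect its structure.

Study means come from the between-level covariance, participants from the
within-level covariance around their study's mean; with the missingness
flag, the behavior variable is removed entirely from half of the studies.
"""

import numpy as np

from ipdmasem import ConditionSpec
from ipdmasem.generate import generate_replication, to_frame

cond = ConditionSpec("S2_medium_unequal", k=10, missing=True, master_seed=7)
ds = generate_replication(cond, replication=0)

print(f"condition: {cond.label}, total N = {ds.n_total}")
for s in ds.studies:
    print(f"  study {s.study_id}: n = {s.n_j:4d}, observes {s.observed_variables}")

df = to_frame(ds)
print("\nlong-format head (NaN behavior = variable never measured):")
print(df.head(3).round(2).to_string(index=False))

# The pooled covariance mixes within- and between-study variance; study-mean
# variance shows up on top of the within-level diagonal.
pooled = df[["ATT", "SN", "PBC", "INT", "BEH"]].cov()
print("\npooled variances:", np.round(np.diag(pooled), 2))
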