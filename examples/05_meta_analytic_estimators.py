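"""Two-stage MVMA and one-stage MASEM, including variable-level missingness.

MVMA fits the path model per study and pools the coefficient vectors by
fixed-effects GLS; studies without the behavior variable contribute only
the three intention paths. OSMASEM pools study correlation vectors and fits
the model-implied correlation structure to the pooled vector.
"""

from ipdmasem import ConditionSpec, fit_osmasem, fit_per_study, mvma_fixed
from ipdmasem.generate import generate_replication
from ipdmasem.meta import study_correlations

cond = ConditionSpec("S2_medium_unequal", k=30, missing=True, master_seed=5)
ds = generate_replication(cond, 0)

effects = fit_per_study(ds)
n_full = sum(len(e.beta) == 5 for e in effects)
print(f"stage 1: {len(effects)} studies fitted, {n_full} with all five paths")

pooled = mvma_fixed(effects)
print("\nMVMA pooled paths (within-study truth in parentheses):")
truth = {"INT~ATT": 0.43, "INT~SN": 0.16, "INT~PBC": 0.31, "BEH~PBC": 0.53, "BEH~INT": 0.07}
for name, b, se in zip(pooled.names, pooled.beta, pooled.se):
    print(f"  {name:8s} {b:7.3f} (se {se:.4f})  truth {truth[name]:.2f}")

osm = fit_osmasem(study_correlations(ds))
print(f"\nOSMASEM: chi2({osm.df}) = {osm.chi2:.2f}, p = {osm.chi2_p:.3f}")
for name in truth:
    print(f"  {name:8s} {osm.estimates[name]:7.3f} (se {osm.se[name]:.4f})")
print("\nboth estimators target the within-study coefficients and are\n"
      "unaffected by the half of studies that never measured behavior.")
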