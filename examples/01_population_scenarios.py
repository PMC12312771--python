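"""Population scenarios: implied covariances and intraclass correlations.

Each scenario stores path coefficients (B) and residual covariances (Psi)
for the within- and between-study levels of the five-variable behavior
model; the implied covariance of a level is (I-B)^-1 Psi (I-B)^-T, and a
variable's ICC is its between-level share of total variance.
"""

import numpy as np

from ipdmasem import VARIABLES, ScenarioID, get_scenario, icc_profile

for sid in ScenarioID:
    pop = get_scenario(sid)
    icc = icc_profile(pop)
    print(f"\n{sid.value}")
    print("  within Sigma diagonal: ", np.round(np.diag(pop.sigma_w), 2))
    print("  between Sigma diagonal:", np.round(np.diag(pop.sigma_b), 2))
    print("  ICC per variable:      ", dict(zip(VARIABLES, np.round(icc, 3))))

# Spot values used throughout: the within-level covariance of attitudes and
# intentions (0.61) and of perceived control and behavior (0.56) follow from
# the low-ICC scenario's B and Psi alone.
pop = get_scenario("S1_low_unequal")
print("\nS1 within Sigma[ATT, INT] =", round(pop.sigma_w[0, 3], 2))
print("S1 within Sigma[PBC, BEH] =", round(pop.sigma_w[2, 4], 2))
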