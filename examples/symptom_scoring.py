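"""Score interview items into analysis phenotypes.

Builds a bulimia-nervosa symptom count (BNSC) from raw section items, and
the broad diagnosis / combined substance-use variables.
"""

from twinchol import (
    BNSymptomProfile,
    DiagnosisFlags,
    classify_broad_bn,
    classify_chronology,
    classify_regular_smoker,
    combine_any_illicit,
    compute_bnsc,
)

# A woman who endorses the binge-eating entry question, vomits and fasts to
# compensate, feels completely out of control, and binges-and-vomits in the
# same episodes:
profile = BNSymptomProfile(
    binge_entry=True,
    purge_vomit=True,
    purge_fast=True,
    loss_of_control=3,
    amount_eaten=2,
    weight_shape_concern=3,
    binge_vomit_same_time=True,
)
print("BNSC =", compute_bnsc(profile))
print("  (entry 1 + two purge behaviours + 3 + 2 + 3 + co-occurrence 1 = 12;")
print("   non-endorsers of the entry question score 0 by construction)")

skipped = BNSymptomProfile(binge_entry=False, purge_vomit=True, loss_of_control=3)
print("entry question not endorsed ->", compute_bnsc(skipped))

flags = DiagnosisFlags(
    bn_wave1=False, bn_wave3=True,
    sud={"cannabis": True, "sedative": False, "stimulant": False,
         "cocaine": False, "opiate": False, "hallucinogen": False},
    smoking_episodes_per_month=12,
)
print("broad BN (diagnosis at either wave):", classify_broad_bn(flags))
print("any illicit drug disorder:", combine_any_illicit(flags))
print("regular smoker (>= 7 episodes/month):", classify_regular_smoker(12))
print("onset ordering (ED at 17, SUD at 20):", classify_chronology(17, 20))
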