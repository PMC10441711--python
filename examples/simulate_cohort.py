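"""Draw a synthetic ageing-cohort table and inspect its structure.

The generator emulates a household survey of adults aged 50+: 19 chronic
conditions drawn from a planted Ising dependence graph, hospitalisation /
readmission / length-of-stay outcomes, survey weights, and MAR missingness
driven by sex and age group.
"""

import numpy as np

from morbnet import DISEASES, elsi_like_truth, generate_cohort

truth = elsi_like_truth(seed=0)
cohort = generate_cohort(truth, n=9412, seed=0)

complete = cohort.dropna(subset=list(DISEASES))
print(f"rows drawn: {len(cohort)}, complete cases: {len(complete)}")
print(f"sex split: {complete['sex'].value_counts().to_dict()}")

print("\nweighted prevalence of the five most common conditions:")
w = complete["survey_weight"].to_numpy()
prev = {d: np.average(complete[d], weights=w) for d in DISEASES}
for d, p in sorted(prev.items(), key=lambda kv: -kv[1])[:5]:
    print(f"  {d:22s} {100 * p:5.1f}%")

counts = complete[list(DISEASES)].sum(axis=1)
print(f"\nmultimorbidity: {100 * (counts >= 2).mean():.1f}% with >=2 conditions, "
      f"{100 * (counts >= 3).mean():.1f}% with >=3")
print(f"hospitalised in the last 12 months: "
      f"{100 * complete['hospitalised'].mean():.1f}%")
# Prevalences mirror the study conditions (hypertension most common, rising
# with age; neurodegenerative disease rare); the hospitalisation rate sits
# near the ~10-14% band typical of 50+ cohorts.
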