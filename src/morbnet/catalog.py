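"""Canonical variable catalogue for the morbidity--hospitalisation analysis.

The 19 chronic conditions are self-reported physician diagnoses in adults
aged 50+. Their order is fixed: it defines node indexing in every network,
CSV column ordering, and the meaning of coupling-matrix rows everywhere in
the package.
"""

from __future__ import annotations

DISEASES: tuple[str, ...] = (
    "hypertension",
    "back_problems",
    "high_cholesterol",
    "cataract",
    "arthritis_rheumatism",
    "depression",
    "diabetes",
    "osteoporosis",
    "heart_problems",
    "glaucoma",
    "copd",
    "haemorrhagic_stroke",
    "cancer",
    "asthma",
    "renal_failure",
    "diabetic_retinopathy",
    "macular_degeneration",
    "parkinsons",
    "alzheimers",
)

N_DISEASES = len(DISEASES)
assert N_DISEASES == 19 and len(set(DISEASES)) == 19

#: Outcome / covariate column names used by every CohortTable.
HOSPITALISED = "hospitalised"
READMISSIONS = "readmissions"
LENGTH_OF_STAY = "length_of_stay"
SEX = "sex"
AGE_GROUP = "age_group"
SURVEY_WEIGHT = "survey_weight"

SEXES: tuple[str, ...] = ("female", "male")
AGE_GROUPS: tuple[str, ...] = ("50-59", "60-74", "75+")

#: Node set for network estimation: the 19 conditions plus hospitalisation.
NETWORK_NODES: tuple[str, ...] = DISEASES + (HOSPITALISED,)

#: Columns that may carry missing values (the maskable block); sex,
#: age_group and survey_weight are always observed.
MASKABLE_COLUMNS: tuple[str, ...] = DISEASES + (
    HOSPITALISED,
    READMISSIONS,
    LENGTH_OF_STAY,
)

REQUIRED_COLUMNS: tuple[str, ...] = DISEASES + (
    HOSPITALISED,
    READMISSIONS,
    LENGTH_OF_STAY,
    SEX,
    AGE_GROUP,
    SURVEY_WEIGHT,
)


def disease_index(name: str) -> int:
    """Position of a condition in the canonical ordering."""
    try:
        return DISEASES.index(name)
    except ValueError:
        raise KeyError(f"unknown condition: {name!r}") from None
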