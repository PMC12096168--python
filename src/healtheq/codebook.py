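"""Codebook for the migrant-survey microdata analyzed by this package.

Respondent-level records follow the coding scheme of the 2018 China
Migrants Dynamic Survey (CMDS) health-education analysis: fourteen
categorical covariates, a raw household income, a province label, and a
binary outcome (whether the respondent received any health education in
the past year).
"""

from __future__ import annotations

#: Binary outcome: received any health education in the past year.
OUTCOME = "health_education"

#: Raw (pre-quintile) household income and the province it is ranked within.
INCOME_RAW = "income_raw"
PROVINCE = "province"

#: Allowed codes per categorical field (outcome included).
CODE_SETS: dict[str, tuple[int, ...]] = {
    "gender": (0, 1),                 # 0 female, 1 male
    "age_group": (1, 2, 3, 4),        # 15-30, 31-45, 46-60, >=61
    "education": (1, 2, 3, 4, 5),     # illiterate ... university and above
    "marital": (0, 1),                # not in marriage, in marriage
    "working": (0, 1),                # no occupation, employed
    "hukou": (1, 2),                  # rural, urban household registration
    "mobility_range": (1, 2, 3),      # cross-county, cross-city, cross-province
    "mobility_reason": (1, 2, 3),     # family, work, other
    "income_quintile": (1, 2, 3, 4, 5),  # within-province income bands
    "insurance_location": (1, 2),     # place of domicile, place of inflow
    "sick": (0, 1),
    "health_level": (1, 2, 3),        # unhealthy, basically healthy, healthy
    "health_record": (0, 1),          # local health record established
    "family_doctor": (0, 1),          # signed up with a family doctor
    OUTCOME: (0, 1),
}

#: All fourteen candidate covariates, in the order they enter screening.
FACTORS: list[str] = [
    "gender",
    "age_group",
    "education",
    "marital",
    "working",
    "hukou",
    "mobility_range",
    "mobility_reason",
    "income_quintile",
    "insurance_location",
    "sick",
    "health_level",
    "health_record",
    "family_doctor",
]

#: The seven factors retained by the published selection, in the layout
#: order of the published regression table (income first, gender last).
MODEL_FACTORS: list[str] = [
    "income_quintile",
    "age_group",
    "education",
    "health_record",
    "mobility_range",
    "mobility_reason",
    "gender",
]

#: Omitted (reference) level per factor, matching the published layout
#: (lowest code is the reference throughout).
REFERENCE_LEVELS: dict[str, int] = {f: min(CODE_SETS[f]) for f in FACTORS}

#: Human-readable level labels (for report tables).
LEVEL_LABELS: dict[str, dict[int, str]] = {
    "gender": {0: "Female", 1: "Male"},
    "age_group": {1: "15-30", 2: "31-45", 3: "46-60", 4: ">=61"},
    "education": {1: "Illiterate", 2: "Elementary school", 3: "Middle school",
                  4: "High school", 5: "University and above"},
    "marital": {0: "Not in marriage", 1: "In marriage"},
    "working": {0: "No occupation", 1: "Employed"},
    "hukou": {1: "Rural", 2: "Urban"},
    "mobility_range": {1: "Cross-county within city",
                       2: "Cross-city within province", 3: "Cross-province"},
    "mobility_reason": {1: "Family", 2: "Work", 3: "Other"},
    "income_quintile": {1: "Lowest (<20%)", 2: "Lower (20-39%)",
                        3: "Medium (40-59%)", 4: "Higher (60-79%)",
                        5: "Highest (>=80%)"},
    "insurance_location": {1: "Place of domicile", 2: "Place of inflow"},
    "sick": {0: "No", 1: "Yes"},
    "health_level": {1: "Unhealthy", 2: "Basically healthy", 3: "Healthy"},
    "health_record": {0: "No", 1: "Yes"},
    "family_doctor": {0: "No", 1: "Yes"},
    OUTCOME: {0: "No", 1: "Yes"},
}


def dummy_name(factor: str, level: int) -> str:
    """Canonical design-matrix column name for a factor level."""
    return f"{factor}_{level}"
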