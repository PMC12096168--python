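"""Published summary statistics from the 2018 CMDS health-education study.

These are the printed descriptive counts, outcome cross-tabulations,
logistic-regression estimates, and concentration-index decomposition rows
reported for the restricted 2018 China Migrants Dynamic Survey sample
(N = 103,910).  The raw microdata are access-restricted, so these printed
aggregates serve two roles here:

* reproduction fixtures — quantities that are pure arithmetic over the
  printed numbers (chi-square statistics from counts, odds ratios from
  log-odds, decomposition products) are recomputed and checked;
* default generative parameters — the synthetic-data module uses the
  printed marginal frequencies and coefficients as its ground truth.

Several printed cross-tabulation panels are internally inconsistent with
the descriptive margins (their cells cannot all be simultaneously correct);
those are shipped with ``consistent=False`` and are not used in exact
arithmetic checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Published sample size after cleaning.
N_RESPONDENTS = 103_910

# ---------------------------------------------------------------------------
# Descriptive counts per factor level (the published characteristics table).
# ---------------------------------------------------------------------------

DESCRIPTIVE_COUNTS: dict[str, dict[int, int]] = {
    "health_level": {1: 2_384, 2: 12_080, 3: 89_446},
    "health_education": {0: 18_821, 1: 85_089},
    "health_record": {0: 70_226, 1: 33_684},
    "family_doctor": {0: 88_235, 1: 15_675},
    "gender": {0: 50_899, 1: 53_011},
    "age_group": {1: 29_641, 2: 48_358, 3: 21_396, 4: 4_515},
    "education": {1: 2_542, 2: 14_179, 3: 43_614, 4: 22_890, 5: 20_685},
    "marital": {0: 16_618, 1: 87_292},
    "working": {0: 17_723, 1: 86_187},
    "hukou": {1: 70_248, 2: 33_662},
    "mobility_range": {1: 18_533, 2: 35_347, 3: 50_030},
    "mobility_reason": {1: 14_985, 2: 87_036, 3: 1_889},
    "income_quintile": {1: 22_866, 2: 21_207, 3: 21_216, 4: 20_038, 5: 18_563},
    "insurance_location": {1: 72_588, 2: 31_322},
    "sick": {0: 91_544, 1: 12_366},
}


def descriptive_rates() -> dict[str, float]:
    """Headline percentages implied by the descriptive counts.

    Returns the health-education receipt rate and the health-record
    establishment rate on the percent scale.
    """
    n = N_RESPONDENTS
    return {
        "health_education_pct": 100.0 * DESCRIPTIVE_COUNTS["health_education"][1] / n,
        "health_record_pct": 100.0 * DESCRIPTIVE_COUNTS["health_record"][1] / n,
    }


def marginal_probs() -> dict[str, dict[int, float]]:
    """Per-factor category probabilities from the descriptive counts.

    Each factor's counts are renormalized to sum to one (a couple of
    printed panels are off by a respondent or a rounding step).  Used as
    the synthetic generator's default marginals.
    """
    out: dict[str, dict[int, float]] = {}
    for factor, counts in DESCRIPTIVE_COUNTS.items():
        total = float(sum(counts.values()))
        out[factor] = {lvl: c / total for lvl, c in counts.items()}
    return out


# ---------------------------------------------------------------------------
# Outcome cross-tabulation panels (counts are [outcome=0, outcome=1] per
# level, in ascending level order) with the published chi-square statistic.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrosstabPanel:
    """One published factor x outcome panel.

    ``consistent`` marks panels whose printed cells reproduce the printed
    chi-square statistic (and are compatible with the descriptive margins);
    discrepant panels are retained for completeness but excluded from
    exact arithmetic checks.
    """

    factor: str
    levels: tuple[int, ...]
    counts: tuple[tuple[int, int], ...]  # (outcome No, outcome Yes) per level
    printed_chi2: float
    consistent: bool

    def counts_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)


CROSSTAB_PANELS: dict[str, CrosstabPanel] = {
    p.factor: p
    for p in [
        CrosstabPanel("gender", (0, 1),
                      ((9_001, 41_989), (9_820, 43_191)), 12.365, False),
        CrosstabPanel("age_group", (1, 2, 3, 4),
                      ((4_561, 25_080), (8_172, 40_186),
                       (4_869, 16_257), (1_219, 3_296)), 747.923, False),
        CrosstabPanel("education", (1, 2, 3, 4, 5),
                      ((757, 1_785), (3_528, 10_651), (8_288, 35_326),
                       (3_343, 19_547), (2_905, 17_780)), 1.1e3, False),
        CrosstabPanel("marital", (0, 1),
                      ((2_671, 13_947), (16_150, 71_142)), 55.496, True),
        CrosstabPanel("working", (0, 1),
                      ((3_956, 13_767), (14_865, 71_322)), 255.154, True),
        CrosstabPanel("hukou", (1, 2),
                      ((13_491, 56_757), (5_330, 28_332)), 174.348, True),
        CrosstabPanel("mobility_range", (1, 2, 3),
                      ((2_823, 15_710), (5_329, 30_018),
                       (10_669, 39_361)), 671.508, True),
        CrosstabPanel("mobility_reason", (1, 2, 3),
                      ((3_021, 11_964), (15_405, 71_631),
                       (395, 1_494)), 62.338, True),
        CrosstabPanel("income_quintile", (1, 2, 3, 4, 5),
                      ((4_942, 17_944), (3_878, 17_329), (3_721, 17_495),
                       (3_140, 16_898), (3_140, 15_423)), 290.686, True),
        CrosstabPanel("insurance_location", (1, 2),
                      ((14_412, 58_176), (4_409, 26_913)), 492.533, True),
        # printed 399.049 does not follow from the printed cells (computes
        # ~339.05); retained as discrepant
        CrosstabPanel("sick", (0, 1),
                      ((15_841, 75_703), (2_980, 9_386)), 399.049, False),
        CrosstabPanel("family_doctor", (0, 1),
                      ((18_164, 70_071), (657, 15_018)), 2.4e3, False),
        CrosstabPanel("health_record", (0, 1),
                      ((16_428, 53_744), (2_339, 31_345)), 4.2e3, False),
        CrosstabPanel("health_level", (1, 2, 3),
                      ((746, 1_638), (2_880, 9_200),
                       (15_195, 74_251)), 622.733, True),
    ]
}


def consistent_panels() -> list[CrosstabPanel]:
    """The eight panels whose printed cells reproduce the printed statistic."""
    return [p for p in CROSSTAB_PANELS.values() if p.consistent]


# ---------------------------------------------------------------------------
# Published logistic-regression estimates (dummy column -> beta, OR, 95% CI).
# Reference levels (omitted dummies) carry no row.
# ---------------------------------------------------------------------------

LOGIT_ESTIMATES: dict[str, dict[str, float]] = {
    "income_quintile_2": {"beta": 0.140, "or": 1.150, "lo": 1.096, "hi": 1.208},
    "income_quintile_3": {"beta": 0.151, "or": 1.163, "lo": 1.107, "hi": 1.221},
    "income_quintile_4": {"beta": 0.229, "or": 1.257, "lo": 1.192, "hi": 1.324},
    "income_quintile_5": {"beta": 0.088, "or": 1.092, "lo": 1.034, "hi": 1.153},
    "age_group_2": {"beta": -0.038, "or": 0.962, "lo": 0.923, "hi": 1.003},
    "age_group_3": {"beta": -0.280, "or": 0.756, "lo": 0.719, "hi": 0.794},
    "age_group_4": {"beta": -0.557, "or": 0.573, "lo": 0.529, "hi": 0.629},
    "education_2": {"beta": 0.143, "or": 1.155, "lo": 1.048, "hi": 1.272},
    "education_3": {"beta": 0.369, "or": 1.447, "lo": 1.317, "hi": 1.588},
    "education_4": {"beta": 0.629, "or": 1.876, "lo": 1.699, "hi": 2.072},
    "education_5": {"beta": 0.628, "or": 1.873, "lo": 1.690, "hi": 2.076},
    "health_record_1": {"beta": 1.413, "or": 4.108, "lo": 3.924, "hi": 4.301},
    "mobility_range_2": {"beta": 0.428, "or": 1.535, "lo": 1.466, "hi": 1.606},
    "mobility_range_3": {"beta": 0.432, "or": 1.541, "lo": 1.486, "hi": 1.597},
    "mobility_reason_2": {"beta": 0.051, "or": 1.052, "lo": 0.934, "hi": 1.184},
    "mobility_reason_3": {"beta": 0.283, "or": 1.327, "lo": 1.185, "hi": 1.485},
    "gender_1": {"beta": 0.083, "or": 1.087, "lo": 1.052, "hi": 1.123},
}


def published_betas() -> dict[str, float]:
    """Log-odds coefficients of the published model (dummy column -> beta)."""
    return {k: v["beta"] for k, v in LOGIT_ESTIMATES.items()}


# ---------------------------------------------------------------------------
# Published concentration-index decomposition rows
# (elasticity, factor CI, contribution, contribution rate %).
# ---------------------------------------------------------------------------

DECOMPOSITION_ROWS: dict[str, dict[str, float]] = {
    "income_quintile_2": {"elasticity": 0.514, "factor_ci": 0.205,
                          "contribution": 0.105, "rate": 8.684},
    "income_quintile_3": {"elasticity": 0.554, "factor_ci": 0.199,
                          "contribution": 0.111, "rate": 9.156},
    "income_quintile_4": {"elasticity": 0.841, "factor_ci": 0.177,
                          "contribution": 0.149, "rate": 12.302},
    "income_quintile_5": {"elasticity": 0.323, "factor_ci": 0.192,
                          "contribution": 0.062, "rate": 5.136},
    "age_group_2": {"elasticity": -0.096, "factor_ci": 0.004,
                    "contribution": -0.001, "rate": -0.033},
    "age_group_3": {"elasticity": -0.708, "factor_ci": 0.016,
                    "contribution": -0.011, "rate": -0.926},
    "age_group_4": {"elasticity": -1.410, "factor_ci": 0.019,
                    "contribution": -0.028, "rate": -2.318},
    "education_2": {"elasticity": 0.622, "factor_ci": 0.012,
                    "contribution": 0.008, "rate": 0.617},
    "education_3": {"elasticity": 1.604, "factor_ci": 0.005,
                    "contribution": 0.008, "rate": 0.663},
    "education_5": {"elasticity": 2.730, "factor_ci": -0.012,
                    "contribution": -0.032, "rate": -2.663},
    "health_record_1": {"elasticity": 0.546, "factor_ci": 0.004,
                        "contribution": 0.002, "rate": 0.180},
    "mobility_range_2": {"elasticity": 1.239, "factor_ci": 0.015,
                         "contribution": 0.019, "rate": 1.557},
    "mobility_range_3": {"elasticity": 1.251, "factor_ci": 0.011,
                         "contribution": 0.013, "rate": 1.075},
    "mobility_reason_2": {"elasticity": 0.119, "factor_ci": 0.012,
                          "contribution": 0.001, "rate": 0.122},
    "mobility_reason_3": {"elasticity": 0.665, "factor_ci": 0.029,
                          "contribution": 0.019, "rate": 1.599},
    "gender_1": {"elasticity": 0.053, "factor_ci": 0.013,
                 "contribution": 0.001, "rate": 0.056},
}

#: Published overall concentration index of health-education utilization.
PUBLISHED_CI = 0.0121
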