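"""Indicator, domain and geography metadata for the CSE index.

Thirteen small-area indicators measure children's risk of social exclusion.
Most are proportions of dependent children aged 0-15 with a risk attribute
(larger = higher risk).  Three are service/outcome ratios where larger
initially means *better* conditions (GPs per 1,000 persons, dentists per
1,000 persons, the area's mean standardised-test score relative to the
national average); these are orientation-inverted before any scoring so that
larger always means higher risk.
"""

from __future__ import annotations

from dataclasses import dataclass

SOCIO_ECONOMIC = "Socio-economic"
EDUCATION = "Education"
CONNECTEDNESS = "Connectedness"
HOUSING = "Housing"
HEALTH_SERVICES = "Health services"

DOMAINS = (SOCIO_ECONOMIC, EDUCATION, CONNECTEDNESS, HOUSING, HEALTH_SERVICES)

PROPORTION_RISK = "proportion_risk"
RATIO_INVERTED = "ratio_inverted"


@dataclass(frozen=True)
class Indicator:
    name: str
    domain: str
    orientation: str  # PROPORTION_RISK or RATIO_INVERTED


INDICATORS: tuple[Indicator, ...] = (
    Indicator("sole_parent_family", SOCIO_ECONOMIC, PROPORTION_RISK),
    Indicator("bottom_income_quintile", SOCIO_ECONOMIC, PROPORTION_RISK),
    Indicator("no_parent_in_paid_work", SOCIO_ECONOMIC, PROPORTION_RISK),
    Indicator("no_year12_in_family", EDUCATION, PROPORTION_RISK),
    Indicator("naplan_score_ratio", EDUCATION, RATIO_INVERTED),
    Indicator("aedi_below_10th_percentile", EDUCATION, PROPORTION_RISK),
    Indicator("no_internet_at_home", CONNECTEDNESS, PROPORTION_RISK),
    Indicator("no_parent_volunteering", CONNECTEDNESS, PROPORTION_RISK),
    Indicator("no_motor_vehicle", CONNECTEDNESS, PROPORTION_RISK),
    Indicator("rent_stress_30_40", HOUSING, PROPORTION_RISK),
    Indicator("overcrowding", HOUSING, PROPORTION_RISK),
    Indicator("gp_ratio", HEALTH_SERVICES, RATIO_INVERTED),
    Indicator("dentist_ratio", HEALTH_SERVICES, RATIO_INVERTED),
)

INDICATOR_NAMES: tuple[str, ...] = tuple(i.name for i in INDICATORS)

DOMAIN_OF: dict[str, str] = {i.name: i.domain for i in INDICATORS}
ORIENTATION_OF: dict[str, str] = {i.name: i.orientation for i in INDICATORS}


def domain_indicators(domain: str) -> list[str]:
    """Names of the indicators belonging to ``domain``."""
    if domain not in DOMAINS:
        raise ValueError(f"unknown domain {domain!r}; expected one of {DOMAINS}")
    return [i.name for i in INDICATORS if i.domain == domain]


# ABS five-level remoteness structure, ordered least to most remote.
REMOTENESS_CATEGORIES = (
    "Major cities",
    "Inner regional",
    "Outer regional",
    "Remote",
    "Very remote",
)

# Age groups used for direct age standardisation of child hospitalisation rates.
AGE_GROUPS = ("0-4", "5-9", "10-14")
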