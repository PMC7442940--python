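"""Seeded synthetic user populations with the observed marginal structure.

Real calculator data cannot be redistributed, so every downstream module
is exercised against synthetic cohorts that emulate what the published
aggregates describe: the marginal risk-factor frequencies of the
anonymous sample, a truncated-normal age distribution on the 35–75 target
range, and the engagement funnel (anonymous users → report sign-ups →
survey respondents) in which later stages self-select towards older,
more risk-aware users.  Risk factors are drawn independently (their joint
correlations were never reported) and engagement uses a logistic
weighting with configurable covariate coefficients, calibrated so each
stage's expected size matches the configured rate.

A single integer seed drives independent substreams for user generation,
funnel selection and survey outcomes, so stages can be regenerated
independently and every run is exactly reproducible.

The deterministic :func:`table2_fixture` is separate from the samplers:
it assigns outcomes by exact count (no randomness) to rebuild the
follow-up outcome battery precisely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import truncnorm

from .errors import ConfigurationError

#: Published funnel stage sizes: anonymous -> report requested -> survey.
FUNNEL_SIZES = (361_044, 30_279, 1303)

#: Anonymous-sample marginal rates used as generator defaults.
DEFAULT_RATES = {
    "female": 0.6129,
    "smoker": 0.0983,
    "family_history": 0.3426,
    "diabetes": 0.0571,
    "on_bp_medication": 0.1785,
    "sbp_known": 0.4938,
    "cholesterol_known": 0.1635,
}


@dataclass
class TruncatedNormal:
    """Mean/SD with hard bounds, sampled via the truncated normal."""

    mean: float
    sd: float
    low: float
    high: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n,
                             random_state=rng)


@dataclass
class SyntheticCohortConfig:
    """All knobs of the generator; defaults emulate the published cohort.

    ``rates`` are Bernoulli marginals (anonymous-sample values by
    default).  ``signup_rate`` and ``survey_rate`` are the funnel stage
    probabilities (stage size ratios by default).  The ``*_engagement``
    dicts give logistic log-odds coefficients per covariate (age is per
    year, centred); the intercept is solved at run time so the expected
    stage size matches the configured rate.
    """

    n_anonymous: int = FUNNEL_SIZES[0]
    signup_rate: float = FUNNEL_SIZES[1] / FUNNEL_SIZES[0]
    survey_rate: float = FUNNEL_SIZES[2] / FUNNEL_SIZES[1]
    rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RATES))
    age: TruncatedNormal = field(
        default_factory=lambda: TruncatedNormal(49.37, 11.79, 35.0, 75.0)
    )
    sbp: TruncatedNormal = field(
        default_factory=lambda: TruncatedNormal(130.0, 17.0, 70.0, 250.0)
    )
    total_cholesterol: TruncatedNormal = field(
        default_factory=lambda: TruncatedNormal(5.4, 1.0, 2.0, 10.5)
    )
    bmi: TruncatedNormal = field(
        default_factory=lambda: TruncatedNormal(27.5, 5.0, 16.0, 55.0)
    )
    height_mean: dict[str, float] = field(
        default_factory=lambda: {"female": 164.0, "male": 178.0}
    )
    height_sd: float = 7.0
    #: Log-odds engagement weights: report sign-up skews older and
    #: risk-aware, away from smokers (the documented selection gradient).
    signup_engagement: dict[str, float] = field(
        default_factory=lambda: {
            "age_per_year": 0.04,
            "sbp_known": 0.5,
            "cholesterol_known": 0.6,
            "on_bp_medication": 0.2,
            "smoker": -0.3,
        }
    )
    survey_engagement: dict[str, float] = field(
        default_factory=lambda: {
            "age_per_year": 0.04,
            "sbp_known": 0.3,
            "cholesterol_known": 0.2,
            "smoker": -0.5,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name, p in {
            "signup_rate": self.signup_rate,
            "survey_rate": self.survey_rate,
            **self.rates,
        }.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability {name}={p} outside [0, 1]")
        if self.n_anonymous <= 0:
            raise ConfigurationError("n_anonymous must be positive")


def _substream(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


def generate_users(config: SyntheticCohortConfig) -> pd.DataFrame:
    """Draw the anonymous-user stage as one record per user.

    Columns match the user CSV schema plus the known/unknown flags; SBP
    and cholesterol values are present only where the matching flag is
    true (the calculator imputes the rest).
    """
    rng = _substream(config.seed, 0)
    n = config.n_anonymous
    rates = config.rates
    sex = np.where(rng.random(n) < rates["female"], "female", "male")
    age = np.round(config.age.sample(n, rng)).astype(int)
    flags = {
        name: rng.random(n) < rates[name]
        for name in (
            "smoker",
            "family_history",
            "diabetes",
            "on_bp_medication",
            "sbp_known",
            "cholesterol_known",
        )
    }
    height = np.where(
        sex == "female",
        rng.normal(config.height_mean["female"], config.height_sd, n),
        rng.normal(config.height_mean["male"], config.height_sd, n),
    )
    weight = config.bmi.sample(n, rng) * (height / 100.0) ** 2
    sbp = np.round(config.sbp.sample(n, rng), 0)
    tc = np.round(config.total_cholesterol.sample(n, rng), 1)
    users = pd.DataFrame(
        {
            "user_id": np.arange(n),
            "age": age,
            "sex": sex,
            "smoker": flags["smoker"],
            "diabetes": flags["diabetes"],
            "family_history": flags["family_history"],
            "on_bp_medication": flags["on_bp_medication"],
            "sbp_known": flags["sbp_known"],
            "cholesterol_known": flags["cholesterol_known"],
            "height": np.round(height, 1),
            "weight": np.round(weight, 1),
            "sbp": np.where(flags["sbp_known"], sbp, np.nan),
            "total_cholesterol": np.where(flags["cholesterol_known"], tc, np.nan),
        }
    )
    return users


def _engagement_probability(
    users: pd.DataFrame, rate: float, weights: dict[str, float]
) -> np.ndarray:
    """Per-user logistic selection probability with mean equal to ``rate``."""
    if rate <= 0.0:
        return np.zeros(len(users))
    if rate >= 1.0:
        return np.ones(len(users))
    score = np.zeros(len(users))
    for name, coef in weights.items():
        if coef == 0.0:
            continue
        if name == "age_per_year":
            score += coef * (users["age"].to_numpy(float) - users["age"].mean())
        else:
            score += coef * users[name].to_numpy(float)
    score -= score.mean()
    intercept = brentq(lambda c: expit(c + score).mean() - rate, -40.0, 40.0)
    return expit(intercept + score)


def simulate_funnel(
    users: pd.DataFrame, config: SyntheticCohortConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bernoulli-select the report-requested and survey stages.

    With nonzero engagement weights the later stages skew older and more
    risk-aware, matching the observed selection gradient; expected stage
    sizes equal ``len(users) * signup_rate`` and
    ``len(report) * survey_rate``.
    """
    rng = _substream(config.seed, 1)
    p_signup = _engagement_probability(users, config.signup_rate,
                                       config.signup_engagement)
    report = users[rng.random(len(users)) < p_signup]
    p_survey = _engagement_probability(report, config.survey_rate,
                                       config.survey_engagement)
    survey = report[rng.random(len(report)) < p_survey]
    return report.reset_index(drop=True), survey.reset_index(drop=True)


def simulate_survey_responses(
    survey_subset: pd.DataFrame,
    outcome_rates_by_category: dict[str, dict[str, float]],
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Draw Bernoulli survey outcomes at category-specific rates.

    ``outcome_rates_by_category`` maps outcome name -> {heart-age
    category -> probability}.  Each respondent needs a ``category``
    value covered by every outcome's rate map.
    """
    if rng is None:
        rng = _substream(seed or 0, 2)
    out = survey_subset.copy()
    categories = out["category"].to_numpy()
    for outcome, rates in outcome_rates_by_category.items():
        missing = set(categories) - set(rates)
        if missing:
            raise ConfigurationError(
                f"outcome {outcome!r} lacks rates for categories {sorted(missing)}"
            )
        for p in rates.values():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"rate {p} for {outcome!r} outside [0, 1]")
        p = np.array([rates[c] for c in categories])
        out[outcome] = rng.random(len(out)) < p
    return out


# --- deterministic fixtures -------------------------------------------------

#: Survey-sample heart-age category sizes (older / younger / equal).
TABLE2_GROUP_SIZES = {"older": 1055, "younger": 155, "equal": 93}

#: Correct-category recall is the one outcome reported per three-way category.
TABLE2_RECALL = {"older": 735, "younger": 104, "equal": 53}

#: Yes counts per outcome as (older, younger-or-equal combined).
TABLE2_YES_COUNTS: dict[str, tuple[int, int]] = {
    "very_motivated": (406, 101),
    "very_optimistic": (229, 95),
    "very_anxious": (159, 8),
    "very_worried": (151, 9),
    "spoke_to_family": (466, 89),
    "found_more_information": (669, 118),
    "told_others": (397, 95),
    "increased_physical_activity": (668, 141),
    "lost_weight": (537, 106),
    "improved_diet": (680, 141),
    "reduced_smoking": (19, 0),
    "reduced_stress": (333, 79),
    "limited_alcohol": (332, 74),
    "saw_gp": (538, 83),
    "heart_health_check": (314, 48),
    "blood_pressure_check": (809, 167),
    "cholesterol_test": (619, 118),
    "diabetes_test": (587, 110),
}


def _assign_exact(n: int, k: int, offset: int) -> np.ndarray:
    """Boolean vector of length n with exactly k True, cyclically offset."""
    out = np.zeros(n, dtype=bool)
    if k:
        out[(offset + np.arange(k)) % n] = True
    return out


def table2_fixture() -> pd.DataFrame:
    """Deterministic 1303-respondent table reproducing every outcome count.

    Categories are 1055 older, 155 younger, 93 equal; each outcome column
    carries exactly the published yes count per group (assignment rotates
    through each group so the outcome columns are not perfectly
    collinear).  No sampling is involved: the same frame is produced on
    every call.
    """
    n_older = TABLE2_GROUP_SIZES["older"]
    n_younger = TABLE2_GROUP_SIZES["younger"]
    n_equal = TABLE2_GROUP_SIZES["equal"]
    n_ye = n_younger + n_equal
    categories = (
        ["older"] * n_older + ["younger"] * n_younger + ["equal"] * n_equal
    )
    frame = pd.DataFrame(
        {
            "respondent_id": np.arange(len(categories)),
            "category": categories,
        }
    )
    frame["recall_correct_category"] = np.concatenate(
        [
            _assign_exact(n_older, TABLE2_RECALL["older"], 0),
            _assign_exact(n_younger, TABLE2_RECALL["younger"], 0),
            _assign_exact(n_equal, TABLE2_RECALL["equal"], 0),
        ]
    )
    for i, (outcome, (k_older, k_ye)) in enumerate(TABLE2_YES_COUNTS.items(), 1):
        offset = 37 * i
        frame[outcome] = np.concatenate(
            [
                _assign_exact(n_older, k_older, offset % n_older),
                _assign_exact(n_ye, k_ye, offset % n_ye),
            ]
        )
    return frame


#: Report-sample heart-age category counts (older / younger / remainder equal).
REPORT_CATEGORY_COUNTS = {"older": 23_840, "younger": 4163, "equal": 2276}


def category_fixture(counts: Optional[dict[str, int]] = None) -> pd.DataFrame:
    """Deterministic result frame with given category counts.

    Produces the minimal columns the distribution summary needs (age,
    heart_age_raw, category, sex) with a fixed ±5-year gap per category,
    for exercising category-percentage reporting at published counts.
    """
    counts = counts or REPORT_CATEGORY_COUNTS
    gaps = {"older": 5.0, "younger": -5.0, "equal": 0.0}
    rows_cat = []
    rows_gap = []
    for cat, n in counts.items():
        if cat not in gaps:
            raise ConfigurationError(f"unknown category {cat!r}")
        rows_cat += [cat] * n
        rows_gap += [gaps[cat]] * n
    n_total = len(rows_cat)
    age = np.full(n_total, 55.0)
    return pd.DataFrame(
        {
            "age": age,
            "heart_age_raw": age + np.array(rows_gap),
            "category": rows_cat,
            "sex": np.where(np.arange(n_total) % 2 == 0, "female", "male"),
        }
    )
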