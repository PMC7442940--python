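"""Heart-age conversion: validation, imputation, risk inversion, reporting.

Heart age is the chronological age at which a referent with *ideal* risk
factor levels — non-smoker, non-diabetic, untreated systolic blood
pressure 120 mmHg, total cholesterol 4 mmol/L — would carry the same
10-year absolute CVD risk as the user.  Because ideal risk is strictly
increasing in age (positive age beta), the conversion is a monotone
root-finding problem, solved here by bisection on a wide age bracket so
that arbitrary coefficient sets (including age interactions) remain
supported.  Displayed results are censored to "<35" and "≥85" and
classified as younger / equal / older than the user's current age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from scipy.optimize import bisect

from .errors import ConfigurationError
from .risk import CoefficientSet, RiskProfile, RiskValue, ten_year_risk

# ValidationMessage severities
RANGE_ERROR = "range_error"  # implausible value: blocks calculation
HIGH_RISK_ADVISORY = "high_risk_advisory"  # plausible but high: calc proceeds
ELIGIBILITY_WARNING = "eligibility_warning"  # outside the 35-75 target range


def _fmt(x: float) -> str:
    """Render a threshold the way the calculator prints it (2.0 -> '2')."""
    return f"{x:g}"


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    if x >= 0:
        return int(math.floor(x + 0.5))
    return -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ValidationMessage:
    severity: str
    field: str
    message: str

    @property
    def blocks_calculation(self) -> bool:
        return self.severity == RANGE_ERROR


@dataclass(frozen=True)
class ValidationRules:
    """Plausibility ranges and high-risk pop-up thresholds.

    The cholesterol numbers are the deployed tool's published rules; the
    SBP range and threshold were not published and are package defaults.
    """

    cholesterol_min: float = 2.0
    cholesterol_max: float = 10.5
    cholesterol_high: float = 7.5
    sbp_min: float = 70.0
    sbp_max: float = 250.0
    sbp_high: float = 180.0
    age_min: int = 35
    age_max: int = 75

    @classmethod
    def from_dict(cls, data: dict) -> "ValidationRules":
        chol = data.get("total_cholesterol", {})
        sbp = data.get("sbp", {})
        age = data.get("age", {})
        return cls(
            cholesterol_min=float(chol.get("min", 2.0)),
            cholesterol_max=float(chol.get("max", 10.5)),
            cholesterol_high=float(chol.get("high_risk", 7.5)),
            sbp_min=float(sbp.get("min", 70.0)),
            sbp_max=float(sbp.get("max", 250.0)),
            sbp_high=float(sbp.get("high_risk", 180.0)),
            age_min=int(age.get("min", 35)),
            age_max=int(age.get("max", 75)),
        )


def validate_inputs(
    profile: RiskProfile, rules: ValidationRules = ValidationRules()
) -> list[ValidationMessage]:
    """Check raw user inputs against plausibility and high-risk rules.

    Returns messages rather than raising: range errors block calculation,
    high-risk advisories and eligibility warnings do not (heart age is
    calculated once a plausible value is entered).
    """
    messages: list[ValidationMessage] = []
    if profile.age < rules.age_min or profile.age > rules.age_max:
        messages.append(
            ValidationMessage(
                ELIGIBILITY_WARNING,
                "age",
                f"This calculator is designed for people aged "
                f"{rules.age_min} to {rules.age_max} years.",
            )
        )
    tc = profile.total_cholesterol
    if profile.cholesterol_known and tc is not None:
        if not rules.cholesterol_min <= tc <= rules.cholesterol_max:
            messages.append(
                ValidationMessage(
                    RANGE_ERROR,
                    "total_cholesterol",
                    f"Please enter a number between "
                    f"{_fmt(rules.cholesterol_min)} and {_fmt(rules.cholesterol_max)}",
                )
            )
        elif tc > rules.cholesterol_high:
            messages.append(
                ValidationMessage(
                    HIGH_RISK_ADVISORY,
                    "total_cholesterol",
                    f"Total cholesterol above {_fmt(rules.cholesterol_high)} mmol/L "
                    "puts you at high risk of having a heart attack or stroke. "
                    "Please see your doctor as soon as possible about your "
                    "cholesterol.",
                )
            )
    sbp = profile.sbp
    if profile.sbp_known and sbp is not None:
        if not rules.sbp_min <= sbp <= rules.sbp_max:
            messages.append(
                ValidationMessage(
                    RANGE_ERROR,
                    "sbp",
                    f"Please enter a number between "
                    f"{_fmt(rules.sbp_min)} and {_fmt(rules.sbp_max)}",
                )
            )
        elif sbp > rules.sbp_high:
            messages.append(
                ValidationMessage(
                    HIGH_RISK_ADVISORY,
                    "sbp",
                    f"Blood pressure above {_fmt(rules.sbp_high)} mm Hg puts you "
                    "at high risk of having a heart attack or stroke. Please see "
                    "your doctor as soon as possible about your blood pressure.",
                )
            )
    return messages


@dataclass
class ImputationTable:
    """Population means by sex and 5-year age band for unknown values.

    ``bands`` maps (sex, band start age) to mean SBP (mmHg), mean total
    cholesterol (mmol/L) and mean HDL cholesterol (mmol/L).  Band starts
    must tile the 35-75 target range in 5-year steps (35, 40, ..., 70; the
    last band includes age 75).  Ages outside the target range clamp to
    the nearest band, mirroring how out-of-range users still receive a
    result alongside an eligibility warning.
    """

    bands: dict[tuple[str, int], dict[str, float]]
    source: str = "unspecified"

    _STARTS = tuple(range(35, 75, 5))

    def __post_init__(self) -> None:
        for sex in ("female", "male"):
            missing = [s for s in self._STARTS if (sex, s) not in self.bands]
            if missing:
                raise ConfigurationError(
                    f"imputation table is missing {sex} bands starting at {missing}"
                )
        for key, values in self.bands.items():
            for name in ("sbp", "total_cholesterol", "hdl_cholesterol"):
                if name not in values:
                    raise ConfigurationError(f"band {key} lacks {name!r}")

    def band_start(self, age: float) -> int:
        start = 5 * int(age // 5)
        return min(max(start, self._STARTS[0]), self._STARTS[-1])

    def lookup(self, sex: str, age: float) -> dict[str, float]:
        key = (sex, self.band_start(age))
        if key not in self.bands:
            raise ConfigurationError(f"no imputation band for {key}")
        return self.bands[key]

    @classmethod
    def from_dict(cls, data: dict) -> "ImputationTable":
        bands = {}
        for sex, by_start in data["bands"].items():
            for start, values in by_start.items():
                bands[(sex, int(start))] = {k: float(v) for k, v in values.items()}
        return cls(bands=bands, source=str(data.get("source", "unspecified")))


def impute_unknowns(profile: RiskProfile, table: ImputationTable) -> RiskProfile:
    """Fill unknown SBP/cholesterol with the sex and age-band population mean.

    Known values pass through unchanged; HDL cholesterol (never
    user-entered) is always taken from the table; the known/unknown flags
    are preserved so reports can state that averages were used.
    """
    means = table.lookup(profile.sex, profile.age)
    changes: dict = {"hdl_cholesterol": means["hdl_cholesterol"]}
    if not profile.sbp_known or profile.sbp is None:
        changes["sbp"] = means["sbp"]
        changes["sbp_known"] = False
    if not profile.cholesterol_known or profile.total_cholesterol is None:
        changes["total_cholesterol"] = means["total_cholesterol"]
        changes["cholesterol_known"] = False
    return profile.replace(**changes)


@dataclass(frozen=True)
class IdealProfile:
    """The ideal-risk referent against which heart age is measured.

    Fixed per configuration; only sex and the age being solved for vary.
    SBP 120 mmHg (untreated) and total cholesterol 4 mmol/L are the
    Australian ideal levels; the HDL and BMI ideals are configuration
    choices since they were never published for the deployed tool.
    """

    sbp: float = 120.0
    total_cholesterol: float = 4.0
    hdl_cholesterol: float = 1.3
    bmi: float = 22.5
    smoker: bool = False
    diabetes: bool = False
    family_history: bool = False

    def at_age(self, age: float, sex: str) -> RiskProfile:
        height = 170.0
        weight = self.bmi * (height / 100.0) ** 2
        return RiskProfile(
            age=age,
            sex=sex,
            smoker=self.smoker,
            diabetes=self.diabetes,
            height=height,
            weight=weight,
            sbp=self.sbp,
            on_bp_medication=False,
            total_cholesterol=self.total_cholesterol,
            hdl_cholesterol=self.hdl_cholesterol,
            family_history=self.family_history,
        )

    @classmethod
    def from_dict(cls, data: dict) -> "IdealProfile":
        return cls(
            sbp=float(data.get("sbp", 120.0)),
            total_cholesterol=float(data.get("total_cholesterol", 4.0)),
            hdl_cholesterol=float(data.get("hdl_cholesterol", 1.3)),
            bmi=float(data.get("bmi", 22.5)),
        )


@dataclass(frozen=True)
class HeartAgeBounds:
    """Display censoring limits and bisection bracket for the inversion."""

    display_min: int = 35
    display_max: int = 85
    solver_min: float = 20.0
    solver_max: float = 120.0
    tol_years: float = 1e-9

    @classmethod
    def from_dict(cls, data: dict) -> "HeartAgeBounds":
        return cls(
            display_min=int(data.get("display_min", 35)),
            display_max=int(data.get("display_max", 85)),
            solver_min=float(data.get("solver_min", 20.0)),
            solver_max=float(data.get("solver_max", 120.0)),
            tol_years=float(data.get("tol_years", 1e-9)),
        )


@dataclass
class HeartAgeResult:
    """Computed risk and heart age with display censoring and category."""

    risk: Optional[RiskValue]
    heart_age_raw: float
    heart_age_display: str
    category: Optional[str]  # 'younger' | 'equal' | 'older'
    advisories: list[ValidationMessage] = field(default_factory=list)
    bracket_censored: Optional[str] = None  # 'low' | 'high' when clamped
    sbp_imputed: bool = False
    cholesterol_imputed: bool = False

    @property
    def blocked(self) -> bool:
        return self.risk is None


def categorize(heart_age_raw: float, chronological_age: float) -> str:
    """Younger / equal / older: rounded heart age vs. integer current age."""
    rounded = round_half_away(heart_age_raw)
    current = round_half_away(float(chronological_age))
    if rounded > current:
        return "older"
    if rounded < current:
        return "younger"
    return "equal"


def ideal_risk_at_age(
    age: float,
    sex: str,
    coeffs: CoefficientSet,
    ideal: IdealProfile = IdealProfile(),
) -> RiskValue:
    """10-year risk of the ideal referent at a given age and sex."""
    return ten_year_risk(ideal.at_age(age, sex), coeffs)


def _display(raw: float, bounds: HeartAgeBounds) -> str:
    rounded = round_half_away(raw)
    if rounded < bounds.display_min:
        return f"<{bounds.display_min}"
    if rounded >= bounds.display_max:
        return f"≥{bounds.display_max}"
    return str(rounded)


def heart_age(
    profile: RiskProfile,
    coeffs: CoefficientSet,
    ideal: IdealProfile = IdealProfile(),
    bounds: HeartAgeBounds = HeartAgeBounds(),
) -> HeartAgeResult:
    """Invert absolute risk to heart age against the ideal referent.

    Solves ``ideal_risk_at_age(a) == ten_year_risk(profile)`` for ``a`` by
    monotone bisection on ``[solver_min, solver_max]``.  Risks outside the
    bracket's ideal-risk range clamp to the nearer bound and set
    ``bracket_censored`` instead of raising.  The profile must already be
    imputed (no unknowns).
    """
    risk = ten_year_risk(profile, coeffs)

    # Risk is strictly increasing in the linear predictor (0 < S0 < 1), so
    # matching risks is equivalent to matching linear predictors.  Bisecting
    # on the LP scale keeps full precision for extreme profiles whose risk
    # saturates to 1.0 in floating point.
    def ideal_lp(age: float) -> float:
        return ten_year_risk(ideal.at_age(age, profile.sex), coeffs).linear_predictor

    lo = ideal_lp(bounds.solver_min)
    hi = ideal_lp(bounds.solver_max)
    if lo >= hi:
        raise ConfigurationError(
            "ideal risk is not increasing over the solver bracket; the "
            "coefficient set needs a positive age effect for heart-age inversion"
        )
    target = risk.linear_predictor
    censored = None
    if target <= lo:
        raw = bounds.solver_min
        censored = "low"
    elif target >= hi:
        raw = bounds.solver_max
        censored = "high"
    else:
        raw = bisect(
            lambda a: ideal_lp(a) - target,
            bounds.solver_min,
            bounds.solver_max,
            xtol=bounds.tol_years,
        )
    return HeartAgeResult(
        risk=risk,
        heart_age_raw=float(raw),
        heart_age_display=_display(raw, bounds),
        category=categorize(raw, profile.age),
        bracket_censored=censored,
        sbp_imputed=not profile.sbp_known,
        cholesterol_imputed=not profile.cholesterol_known,
    )


def assess(profile: RiskProfile, model: "ModelConfig") -> HeartAgeResult:
    """Full pipeline: validate, impute, invert; blocked on range errors."""
    messages = validate_inputs(profile, model.validation)
    if any(m.blocks_calculation for m in messages):
        return HeartAgeResult(
            risk=None,
            heart_age_raw=float("nan"),
            heart_age_display="",
            category=None,
            advisories=messages,
            sbp_imputed=False,
            cholesterol_imputed=False,
        )
    imputed = impute_unknowns(profile, model.imputation)
    result = heart_age(imputed, model.coefficients, model.ideal, model.bounds)
    result.advisories = messages
    return result


@dataclass
class ModelConfig:
    """Bundle of everything one calculator deployment needs."""

    coefficients: CoefficientSet
    ideal: IdealProfile
    imputation: ImputationTable
    validation: ValidationRules
    bounds: HeartAgeBounds

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        return cls(
            coefficients=CoefficientSet.from_dict(data),
            ideal=IdealProfile.from_dict(data.get("ideal", {})),
            imputation=ImputationTable.from_dict(data["imputation"]),
            validation=ValidationRules.from_dict(data.get("validation", {})),
            bounds=HeartAgeBounds.from_dict(data.get("heart_age_bounds", {})),
        )


# --- report rendering -------------------------------------------------------

_CATEGORY_SENTENCES = {
    "older": "Your heart age is OLDER than your current age.",
    "equal": "Your heart age is the SAME as your current age.",
    "younger": "Your heart age is YOUNGER than your current age.",
}

#: Target age range for a Medicare heart health check recommendation.
HEALTH_CHECK_AGE_RANGE = (45, 75)


def render_report(result: HeartAgeResult, profile: RiskProfile) -> str:
    """Plain-text/Markdown report mirroring the emailed heart-age report.

    Contains the heart age and category, the 10-year risk, a per-factor
    summary noting where population averages were used, any advisories,
    and the heart-health-check recommendation for users in the target age
    group.
    """
    lines = ["# Your heart age report", ""]
    if result.blocked:
        lines.append("Your heart age could not be calculated:")
        lines += [f"- {m.message}" for m in result.advisories]
        return "\n".join(lines) + "\n"

    lines.append(f"Heart age: {result.heart_age_display}")
    lines.append(f"Current age: {round_half_away(float(profile.age))}")
    lines.append(_CATEGORY_SENTENCES[result.category])
    lines.append("")
    lines.append(
        f"Estimated risk of a heart attack or stroke in the next 10 years: "
        f"{100 * result.risk.risk:.1f}%"
    )
    lines.append("")
    lines.append("## Your risk factors")
    lines.append(f"- Sex: {profile.sex}")
    lines.append(f"- Smoker: {'yes' if profile.smoker else 'no'}")
    lines.append(f"- Diabetes: {'yes' if profile.diabetes else 'no'}")
    lines.append(
        f"- Family history of premature heart disease: "
        f"{'yes' if profile.family_history else 'no'}"
    )
    sbp_note = " (population average used)" if result.sbp_imputed else ""
    lines.append(f"- Systolic blood pressure: {profile.sbp:g} mmHg{sbp_note}")
    lines.append(
        f"- Taking blood pressure medication: "
        f"{'yes' if profile.on_bp_medication else 'no'}"
    )
    chol_note = " (population average used)" if result.cholesterol_imputed else ""
    lines.append(
        f"- Total cholesterol: {profile.total_cholesterol:g} mmol/L{chol_note}"
    )
    if result.sbp_imputed or result.cholesterol_imputed:
        lines.append("")
        lines.append(
            "Because you did not know some of your values, a population "
            "average for your age group was used. Your result may change "
            "once you know your own numbers."
        )
    for m in result.advisories:
        lines.append("")
        lines.append(f"**{m.message}**")
    low, high = HEALTH_CHECK_AGE_RANGE
    if low <= profile.age <= high:
        lines.append("")
        if result.category == "older":
            lines.append(
                "Your heart age is older than your current age. We recommend "
                "you see your doctor for a heart health check to get a full "
                "assessment of your risk."
            )
        else:
            lines.append(
                "You are in the target age group for a heart health check: "
                "ask your doctor for a full assessment of your risk."
            )
    return "\n".join(lines) + "\n"
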