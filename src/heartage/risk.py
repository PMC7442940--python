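"""Sex-specific 10-year absolute cardiovascular risk.

The risk engine evaluates a Framingham-type Cox proportional-hazards
equation of the form

    risk = 1 - S0 ** exp(LP - LP_mean)

where ``LP`` is a linear predictor over (possibly log-transformed)
covariates, ``LP_mean`` the population-mean linear predictor, and ``S0``
the sex-specific baseline 10-year event-free survival.  Every coefficient
is configuration data: the equations shipped with the package transcribe
the published general-CVD Framingham score (lipid-based by default, with a
BMI-based office variant), but any set of covariates, transforms, betas
and baseline survival can be supplied, so locally recalibrated weightings
drop in without code changes.

Units are Australian clinical units on the way in (mmol/L for lipids,
mmHg for systolic blood pressure, cm/kg for height and weight); when a
coefficient set declares mg/dL lipids the standard conversion
1 mmol/L = 38.67 mg/dL is applied before any transform.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

from .errors import ConfigurationError, InvalidInputError

#: mg/dL per mmol/L for total and HDL cholesterol.
MMOL_TO_MGDL = 38.67

#: Covariates measured in mmol/L that are unit-converted for mg/dL equations.
LIPID_COVARIATES = frozenset({"total_cholesterol", "hdl_cholesterol"})

_TRANSFORMS = ("identity", "log")
_SEXES = ("female", "male")


def bmi_from_height_weight(height: float, weight: float) -> float:
    """Body-mass index in kg/m^2 from height in cm and weight in kg.

    Raises
    ------
    InvalidInputError
        If height or weight is not strictly positive.
    """
    if height <= 0 or weight <= 0:
        raise InvalidInputError(
            f"height and weight must be positive, got height={height} cm, "
            f"weight={weight} kg"
        )
    return weight / (height / 100.0) ** 2


@dataclass
class RiskProfile:
    """One person's risk-factor vector in natural clinical units.

    ``sbp`` and ``total_cholesterol`` may be ``None`` when the user does
    not know them; the matching ``*_known`` flags default accordingly and
    are preserved through imputation so reports can say a population
    average was used.  HDL cholesterol is never user-entered by the
    calculator; it is filled from the imputation table.
    """

    age: float
    sex: str
    smoker: bool = False
    diabetes: bool = False
    height: float = 170.0  # cm
    weight: float = 70.0  # kg
    sbp: Optional[float] = None  # mmHg
    on_bp_medication: bool = False
    total_cholesterol: Optional[float] = None  # mmol/L
    hdl_cholesterol: Optional[float] = None  # mmol/L
    family_history: bool = False
    sbp_known: Optional[bool] = None
    cholesterol_known: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise InvalidInputError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.height <= 0 or self.weight <= 0:
            raise InvalidInputError("height and weight must be positive")
        if self.sbp_known is None:
            self.sbp_known = self.sbp is not None
        if self.cholesterol_known is None:
            self.cholesterol_known = self.total_cholesterol is not None

    @property
    def bmi(self) -> float:
        return bmi_from_height_weight(self.height, self.weight)

    def covariate(self, name: str) -> float:
        """Raw (untransformed, mmol/L-scale) value of a named covariate."""
        if name == "age":
            return float(self.age)
        if name == "smoker":
            return 1.0 if self.smoker else 0.0
        if name == "diabetes":
            return 1.0 if self.diabetes else 0.0
        if name == "bmi":
            return self.bmi
        if name in ("sbp", "total_cholesterol", "hdl_cholesterol"):
            value = getattr(self, name)
            if value is None:
                raise ConfigurationError(
                    f"covariate {name!r} is required by the coefficient set but "
                    "missing from the profile; impute unknowns first"
                )
            return float(value)
        raise ConfigurationError(f"unknown covariate {name!r}")

    def replace(self, **changes) -> "RiskProfile":
        return replace(self, **changes)


@dataclass(frozen=True)
class CovariateTerm:
    """One beta term of a sex-specific equation.

    ``beta_treated`` applies in place of ``beta`` for the systolic blood
    pressure term when the user takes blood-pressure-lowering medication
    (the treated/untreated split of the published equations).
    """

    name: str
    transform: str
    beta: float
    beta_treated: Optional[float] = None

    def __post_init__(self) -> None:
        if self.transform not in _TRANSFORMS:
            raise ConfigurationError(
                f"transform must be one of {_TRANSFORMS}, got {self.transform!r}"
            )

    def effective_beta(self, on_bp_medication: bool) -> float:
        if self.name == "sbp" and on_bp_medication and self.beta_treated is not None:
            return self.beta_treated
        return self.beta


@dataclass
class SexEquation:
    """Per-sex equation: terms, baseline survival and the mean linear predictor.

    The mean linear predictor may be given directly (``mean_linear_predictor``,
    as published for the default equations) or via per-covariate reference
    means on the transformed scale (``covariate_means``), in which case it is
    the beta-weighted sum of those means (untreated SBP beta).
    """

    terms: list[CovariateTerm]
    baseline_survival: float
    mean_linear_predictor: Optional[float] = None
    covariate_means: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 < self.baseline_survival <= 1.0:
            raise ConfigurationError(
                f"baseline survival must be in (0, 1], got {self.baseline_survival}"
            )
        if self.mean_linear_predictor is None:
            missing = [t.name for t in self.terms if t.name not in self.covariate_means]
            if missing:
                raise ConfigurationError(
                    "coefficient set gives neither mean_linear_predictor nor "
                    f"covariate means for {missing}"
                )

    @property
    def lp_mean(self) -> float:
        if self.mean_linear_predictor is not None:
            return self.mean_linear_predictor
        return sum(t.beta * self.covariate_means[t.name] for t in self.terms)


@dataclass
class CoefficientSet:
    """Sex-specific risk-equation parameters, loaded from configuration.

    ``lipid_units`` declares the unit system of the lipid betas; profiles
    always carry mmol/L and are converted on evaluation when the set
    declares ``mg/dL``.  ``family_history_hazard_multiplier`` scales the
    hazard when a family history of premature heart disease is reported
    (default 1.0: collected but not scored, matching the deployed tool's
    unstated handling).
    """

    equations: dict[str, SexEquation]
    lipid_units: str = "mg/dL"
    family_history_hazard_multiplier: float = 1.0
    name: str = "custom"

    def __post_init__(self) -> None:
        for sex in self.equations:
            if sex not in _SEXES:
                raise ConfigurationError(f"unknown sex key {sex!r} in coefficient set")
        if self.lipid_units not in ("mg/dL", "mmol/L"):
            raise ConfigurationError(
                f"lipid_units must be 'mg/dL' or 'mmol/L', got {self.lipid_units!r}"
            )
        if self.family_history_hazard_multiplier <= 0:
            raise ConfigurationError("family_history_hazard_multiplier must be > 0")

    def equation_for(self, sex: str) -> SexEquation:
        try:
            return self.equations[sex]
        except KeyError:
            raise ConfigurationError(f"coefficient set has no equation for sex {sex!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "CoefficientSet":
        equations = {}
        for sex, eq in data["equations"].items():
            terms = [
                CovariateTerm(
                    name=t["covariate"],
                    transform=t.get("transform", "identity"),
                    beta=float(t["beta"]),
                    beta_treated=(
                        float(t["beta_treated"]) if "beta_treated" in t else None
                    ),
                )
                for t in eq["terms"]
            ]
            equations[sex] = SexEquation(
                terms=terms,
                baseline_survival=float(eq["baseline_survival"]),
                mean_linear_predictor=(
                    float(eq["mean_linear_predictor"])
                    if "mean_linear_predictor" in eq
                    else None
                ),
                covariate_means={
                    k: float(v) for k, v in eq.get("covariate_means", {}).items()
                },
            )
        return cls(
            equations=equations,
            lipid_units=data.get("lipid_units", "mg/dL"),
            family_history_hazard_multiplier=float(
                data.get("family_history_hazard_multiplier", 1.0)
            ),
            name=data.get("name", "custom"),
        )


@dataclass(frozen=True)
class RiskValue:
    """Absolute probability of a first CVD event over 10 years."""

    risk: float
    linear_predictor: float


def to_model_units(profile: RiskProfile, coeffs: CoefficientSet) -> dict[str, float]:
    """Transformed covariate vector for the profile under a coefficient set.

    Applies the declared lipid unit conversion first, then the declared
    transform (identity or natural log) per covariate.
    """
    equation = coeffs.equation_for(profile.sex)
    out: dict[str, float] = {}
    for term in equation.terms:
        value = profile.covariate(term.name)
        if term.name in LIPID_COVARIATES and coeffs.lipid_units == "mg/dL":
            value *= MMOL_TO_MGDL
        if term.transform == "log":
            if value <= 0:
                raise ConfigurationError(
                    f"log transform of nonpositive {term.name}={value}"
                )
            value = math.log(value)
        out[term.name] = value
    return out


def linear_predictor(profile: RiskProfile, coeffs: CoefficientSet) -> float:
    """Beta-weighted sum over transformed covariates.

    Uses the treated-SBP beta when the profile is on blood-pressure
    medication, and adds ln(family_history_hazard_multiplier) when a
    family history is reported.
    """
    equation = coeffs.equation_for(profile.sex)
    x = to_model_units(profile, coeffs)
    lp = sum(
        term.effective_beta(profile.on_bp_medication) * x[term.name]
        for term in equation.terms
    )
    if profile.family_history:
        lp += math.log(coeffs.family_history_hazard_multiplier)
    return lp


def ten_year_risk(profile: RiskProfile, coeffs: CoefficientSet) -> RiskValue:
    """10-year absolute CVD risk: ``1 - S0 ** exp(LP - LP_mean)``.

    Strictly increasing in any covariate with a positive beta; equals
    ``1 - S0`` exactly when the profile sits at the equation's reference
    means.
    """
    equation = coeffs.equation_for(profile.sex)
    lp = linear_predictor(profile, coeffs)
    risk = 1.0 - equation.baseline_survival ** math.exp(lp - equation.lp_mean)
    return RiskValue(risk=risk, linear_predictor=lp)
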