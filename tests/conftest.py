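from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pytest

from heartage import load_model_config
from heartage.risk import CoefficientSet, CovariateTerm, SexEquation


def printed_1dp(x: float) -> float:
    """Round a statistic the way the published tables did: half-up to 2 dp
    (the statistics package's displayed precision) and then half-up to the
    1 dp that was printed.  The two-stage chain matters for values such as
    5.347, which display as 5.35 and were printed as 5.4."""
    two = Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    return float(two.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@pytest.fixture(scope="session")
def model():
    """Packaged default lipid model configuration."""
    return load_model_config()


@pytest.fixture(scope="session")
def coeffs(model):
    return model.coefficients


@pytest.fixture()
def rng():
    return np.random.default_rng(20190219)


def make_coeffs(terms_by_sex, s0=0.95, lp_mean=0.0, lipid_units="mmol/L", **kw):
    """Small helper to build ad-hoc coefficient sets in tests."""
    equations = {
        sex: SexEquation(
            terms=[CovariateTerm(*t) for t in terms],
            baseline_survival=s0,
            mean_linear_predictor=lp_mean,
        )
        for sex, terms in terms_by_sex.items()
    }
    return CoefficientSet(equations=equations, lipid_units=lipid_units, **kw)


@pytest.fixture()
def zero_beta_coeffs():
    terms = [("age", "log", 0.0), ("sbp", "log", 0.0), ("smoker", "identity", 0.0)]
    return make_coeffs({"female": terms, "male": terms}, s0=0.9)


@pytest.fixture(scope="session")
def log_age_coeffs():
    """Equation whose only age dependence is beta * ln(age): closed-form
    heart-age inversion exists for cross-checking the bisection."""
    terms = [
        ("age", "log", 2.5),
        ("sbp", "log", 1.8),
        ("total_cholesterol", "log", 0.9),
        ("hdl_cholesterol", "log", -0.6),
        ("smoker", "identity", 0.6),
        ("diabetes", "identity", 0.5),
    ]
    return make_coeffs({"female": terms, "male": terms}, s0=0.92, lp_mean=12.0)
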