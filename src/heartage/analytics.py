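"""Cohort descriptive statistics: risk-factor summaries and heart-age gaps.

Summaries follow the reporting conventions of population heart-age
studies: counts with percentages (2 dp) per user sample, mean and sample
(n−1) standard deviation for age, 10-year age bands 35–44 / 45–54 /
55–64 / 65–75, and the distribution of the heart-age gap (heart age minus
chronological age) with the share of users whose heart age is older,
equal to, or younger than their current age, overall and by stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyCohortError

AGE_BANDS: list[tuple[int, int]] = [(35, 44), (45, 54), (55, 64), (65, 75)]

RATE_FIELDS = [
    "smoker",
    "family_history",
    "diabetes",
    "on_bp_medication",
    "sbp_known",
    "cholesterol_known",
]

CATEGORIES = ["older", "equal", "younger"]


def age_band_label(age: float) -> str:
    """Band label for an age; ages outside 35-75 clamp to the edge bands."""
    for low, high in AGE_BANDS:
        if age <= high:
            return f"{low}-{high}"
    low, high = AGE_BANDS[-1]
    return f"{low}-{high}"


def _pct(count: int, n: int) -> float:
    return round(100.0 * count / n, 2)


@dataclass
class CohortSummary:
    """Risk-factor profile of one user sample (counts and 2-dp percentages)."""

    label: str
    n: int
    sex_counts: dict[str, int]
    sex_pcts: dict[str, float]
    age_mean: float
    age_sd: float
    band_counts: dict[str, int]
    band_pcts: dict[str, float]
    rate_counts: dict[str, int]
    rate_pcts: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"sample": self.label, "item": "n", "count": self.n, "pct": 100.0}]
        for sex in ("female", "male"):
            rows.append(
                {
                    "sample": self.label,
                    "item": sex,
                    "count": self.sex_counts[sex],
                    "pct": self.sex_pcts[sex],
                }
            )
        rows.append(
            {
                "sample": self.label,
                "item": "age_mean_sd",
                "count": round(self.age_mean, 2),
                "pct": round(self.age_sd, 2),
            }
        )
        for band, count in self.band_counts.items():
            rows.append(
                {
                    "sample": self.label,
                    "item": f"age_{band}",
                    "count": count,
                    "pct": self.band_pcts[band],
                }
            )
        for name in RATE_FIELDS:
            rows.append(
                {
                    "sample": self.label,
                    "item": name,
                    "count": self.rate_counts[name],
                    "pct": self.rate_pcts[name],
                }
            )
        return pd.DataFrame(rows)


def summarize_risk_factors(records: pd.DataFrame, sample_label: str) -> CohortSummary:
    """Tabulate one sample's risk factors: gender, age bands, binary rates."""
    if len(records) == 0:
        raise EmptyCohortError(f"no records in sample {sample_label!r}")
    n = len(records)
    sex_counts = {
        sex: int((records["sex"] == sex).sum()) for sex in ("female", "male")
    }
    bands = records["age"].map(age_band_label)
    band_counts = {
        f"{low}-{high}": int((bands == f"{low}-{high}").sum())
        for low, high in AGE_BANDS
    }
    rate_counts = {
        name: int(records[name].astype(bool).sum()) for name in RATE_FIELDS
    }
    age = records["age"].to_numpy(dtype=float)
    return CohortSummary(
        label=sample_label,
        n=n,
        sex_counts=sex_counts,
        sex_pcts={k: _pct(v, n) for k, v in sex_counts.items()},
        age_mean=round(float(age.mean()), 2),
        age_sd=round(float(age.std(ddof=1)) if n > 1 else 0.0, 2),
        band_counts=band_counts,
        band_pcts={k: _pct(v, n) for k, v in band_counts.items()},
        rate_counts=rate_counts,
        rate_pcts={k: _pct(v, n) for k, v in rate_counts.items()},
    )


@dataclass
class HeartAgeDistribution:
    """Distribution of the heart-age gap and result categories."""

    n: int
    gap_mean: float
    gap_sd: float
    category_counts: dict[str, int]
    category_pcts: dict[str, float]
    by_sex: dict[str, dict[str, int]] = field(default_factory=dict)
    by_age_band: dict[str, dict[str, int]] = field(default_factory=dict)


def heart_age_distribution(results: pd.DataFrame) -> HeartAgeDistribution:
    """Mean/SD heart-age gap and category shares, stratified by sex and band.

    ``results`` needs columns ``heart_age_raw``, ``age``, ``category`` and
    ``sex``.  The gap uses the raw (uncensored) heart age; SD is the
    sample (n−1) standard deviation.
    """
    if len(results) == 0:
        raise EmptyCohortError("no heart-age results to summarize")
    n = len(results)
    gap = (results["heart_age_raw"] - results["age"]).to_numpy(dtype=float)
    category_counts = {
        c: int((results["category"] == c).sum()) for c in CATEGORIES
    }
    by_sex = {}
    for sex in ("female", "male"):
        sub = results[results["sex"] == sex]
        if len(sub):
            by_sex[sex] = {c: int((sub["category"] == c).sum()) for c in CATEGORIES}
    by_band = {}
    bands = results["age"].map(age_band_label)
    for low, high in AGE_BANDS:
        label = f"{low}-{high}"
        sub = results[bands == label]
        if len(sub):
            by_band[label] = {c: int((sub["category"] == c).sum()) for c in CATEGORIES}
    return HeartAgeDistribution(
        n=n,
        gap_mean=float(np.mean(gap)),
        gap_sd=float(np.std(gap, ddof=1)) if n > 1 else 0.0,
        category_counts=category_counts,
        category_pcts={k: _pct(v, n) for k, v in category_counts.items()},
        by_sex=by_sex,
        by_age_band=by_band,
    )
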