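"""Contingency tables and Pearson chi-square comparisons of survey outcomes.

Follow-up survey outcomes (psychological responses, lifestyle changes,
clinical checks) are compared between heart-age result groups — older
versus younger/equal, or all three categories — with the plain Pearson
chi-square statistic, Σ(O−E)²/E on (r−1)(c−1) degrees of freedom, without
continuity correction (a corrected variant is available but off by
default).  Significance is read against the usual P<.05 convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from scipy.stats.contingency import expected_freq

from .errors import DegenerateTableError, InvalidInputError

logger = logging.getLogger(__name__)


@dataclass
class ContingencyTable:
    """Observed counts with row (outcome level) and column (group) labels."""

    observed: np.ndarray
    row_labels: Sequence[str] = ()
    col_labels: Sequence[str] = ()

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=float)
        if self.observed.ndim != 2 or min(self.observed.shape) < 2:
            raise InvalidInputError(
                f"need at least a 2x2 table, got shape {self.observed.shape}"
            )
        if (self.observed < 0).any():
            raise InvalidInputError("counts must be nonnegative")
        if self.observed.sum() <= 0:
            raise InvalidInputError("grand total must be positive")
        if not self.row_labels:
            self.row_labels = [f"row{i}" for i in range(self.observed.shape[0])]
        if not self.col_labels:
            self.col_labels = [f"col{j}" for j in range(self.observed.shape[1])]


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def pearson_chi_square(
    table: ContingencyTable, correction: bool = False
) -> ChiSquareResult:
    """Pearson chi-square test of independence for a contingency table.

    ``correction=True`` applies the Yates continuity correction on 2x2
    tables; the default (no correction) is what reproduces the published
    statistics from their printed counts.

    Raises
    ------
    DegenerateTableError
        If any expected count is zero (empty row or column margin).
    """
    expected = expected_freq(table.observed)
    if (expected == 0).any():
        raise DegenerateTableError(
            "table has a zero expected count (empty row or column margin)"
        )
    res = chi2_contingency(table.observed, correction=correction)
    return ChiSquareResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
    )


@dataclass
class OutcomeComparison:
    """Yes/total per group for one outcome, with the chi-square test."""

    outcome: str
    group_labels: list[str]
    yes_counts: list[int]
    totals: list[int]
    percentages: list[float]
    chi_square: ChiSquareResult
    section: Optional[str] = None


def compare_outcome(
    yes_counts: Sequence[int],
    totals: Sequence[int],
    outcome: str = "",
    group_labels: Optional[Sequence[str]] = None,
    correction: bool = False,
) -> OutcomeComparison:
    """Compare a binary outcome across groups given yes counts and totals.

    Builds the yes/no-by-group table, runs the Pearson test, and reports
    per-group percentages to 2 decimal places.
    """
    yes = [int(y) for y in yes_counts]
    tot = [int(t) for t in totals]
    if len(yes) != len(tot):
        raise InvalidInputError("yes_counts and totals must have equal length")
    for y, t in zip(yes, tot):
        if y > t:
            raise InvalidInputError(f"yes count {y} exceeds group total {t}")
        if y < 0 or t < 0:
            raise InvalidInputError("counts must be nonnegative")
    if group_labels is None:
        group_labels = [f"group{i}" for i in range(len(yes))]
    table = ContingencyTable(
        observed=np.array([yes, [t - y for y, t in zip(yes, tot)]]),
        row_labels=["yes", "no"],
        col_labels=list(group_labels),
    )
    result = pearson_chi_square(table, correction=correction)
    pct = [round(100.0 * y / t, 2) if t else float("nan") for y, t in zip(yes, tot)]
    return OutcomeComparison(
        outcome=outcome,
        group_labels=list(group_labels),
        yes_counts=yes,
        totals=tot,
        percentages=pct,
        chi_square=result,
    )


#: Follow-up outcome battery, in report order: (section, column, label).
TABLE2_ROWS: list[tuple[str, str, str]] = [
    ("psychological", "recall_correct_category", "Recall of correct heart age category"),
    ("psychological", "very_motivated", "Very motivated (a great deal/a lot)"),
    ("psychological", "very_optimistic", "Very optimistic (a great deal/a lot)"),
    ("psychological", "very_anxious", "Very anxious (a great deal/a lot)"),
    ("psychological", "very_worried", "Very worried (a great deal/a lot)"),
    ("psychological", "spoke_to_family", "Spoke to family about familial history"),
    ("psychological", "found_more_information", "Found out more information"),
    ("psychological", "told_others", "Told others about the calculator"),
    ("lifestyle", "increased_physical_activity", "Increased physical activity"),
    ("lifestyle", "lost_weight", "Lost weight"),
    ("lifestyle", "improved_diet", "Improved diet"),
    ("lifestyle", "reduced_smoking", "Reduced or quit smoking"),
    ("lifestyle", "reduced_stress", "Reduced stress"),
    ("lifestyle", "limited_alcohol", "Limited alcohol intake"),
    ("clinical", "saw_gp", "Saw general practitioner"),
    ("clinical", "heart_health_check", "Had a heart health check up"),
    ("clinical", "blood_pressure_check", "Had a blood pressure check"),
    ("clinical", "cholesterol_test", "Had a blood test for cholesterol"),
    ("clinical", "diabetes_test", "Had a test for diabetes or sugar levels"),
]

GROUP_LABELS = ["older", "younger_or_equal"]


def build_table2(records: pd.DataFrame) -> list[OutcomeComparison]:
    """One older-vs-younger/equal comparison per follow-up outcome.

    ``records`` needs a ``category`` column ('older', 'younger', 'equal')
    and one boolean column per outcome in :data:`TABLE2_ROWS` (missing
    outcome columns are skipped).  Records without a category are excluded
    with a logged count.  The emotion items ('a great deal / a lot') are
    taken as precomputed booleans.
    """
    valid = records["category"].isin(["older", "younger", "equal"])
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.warning("excluding %d records with missing category", n_excluded)
    records = records[valid]
    older = records[records["category"] == "older"]
    younger_equal = records[records["category"].isin(["younger", "equal"])]
    comparisons = []
    for section, column, label in TABLE2_ROWS:
        if column not in records.columns:
            continue
        comparison = compare_outcome(
            yes_counts=[int(older[column].sum()), int(younger_equal[column].sum())],
            totals=[len(older), len(younger_equal)],
            outcome=label,
            group_labels=GROUP_LABELS,
        )
        comparison.section = section
        comparisons.append(comparison)
    return comparisons


def comparisons_to_frame(comparisons: Sequence[OutcomeComparison]) -> pd.DataFrame:
    """Flatten comparisons to a tidy frame for CSV output."""
    rows = []
    for c in comparisons:
        row: dict = {"section": c.section, "outcome": c.outcome}
        for label, y, t, p in zip(c.group_labels, c.yes_counts, c.totals, c.percentages):
            row[f"{label}_yes"] = y
            row[f"{label}_total"] = t
            row[f"{label}_pct"] = p
        row["chi2"] = c.chi_square.statistic
        row["df"] = c.chi_square.df
        row["p_value"] = c.chi_square.p_value
        rows.append(row)
    return pd.DataFrame(rows)
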