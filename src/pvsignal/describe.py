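"""Descriptive summary of an analysis set, in the layout of a
characteristics table: category counts with percentages, median/IQR age,
age groups, multi-criterion seriousness tallies, suspected-drug
multiplicity and treatment indications.
"""

from __future__ import annotations

import dataclasses
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

from .icsr import (
    REGIONS,
    REPORTERS,
    SERIOUSNESS_CRITERIA,
    SEXES,
    IcsrDatabase,
    is_drug_of_interest,
)

__all__ = [
    "UNDER_CUT",
    "AT_LEAST_CUT",
    "round_half_up",
    "percent",
    "age_group",
    "SummaryTable",
    "summarize",
    "DEFAULT_INDICATIONS",
]

UNDER_CUT = "under_cut"
AT_LEAST_CUT = "at_least_cut"

#: Canonical treatment indications of the drug of interest; anything else
#: non-missing is bucketed as "other".
DEFAULT_INDICATIONS = (
    "chronic lymphocytic leukemia",
    "mantle cell lymphoma",
    "waldenstrom macroglobulinemia",
    "graft versus host disease",
    "marginal zone lymphoma",
)

_MISSING_LABEL = "missing"


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal round-half-up (5 always rounds away from zero)."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def percent(count: int, denominator: int, decimals: int = 1) -> float:
    """Printed-table percentage: 100·count/denominator, half-up rounded."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100.0 * count / denominator, decimals)


def age_group(age_years: float, cut: float) -> str:
    """Classify an age against a cut: strictly below vs at-least (inclusive)."""
    if age_years is None:
        raise ValueError("age must be present; exclude missing ages upstream")
    return UNDER_CUT if age_years < cut else AT_LEAST_CUT


@dataclasses.dataclass
class SummaryTable:
    """Rows of (section, label, count, percent) over one denominator.

    Mutually exclusive sections (region, reporter, sex, age group,
    indication) sum to the denominator; the seriousness section may
    exceed it because a report can satisfy several criteria at once.
    """

    rows: list[tuple[str, str, int, float]]
    age_stats: tuple[float, float, float, float, float]  # median, q1, q3, min, max
    denominator: int

    def section(self, name: str) -> list[tuple[str, int, float]]:
        return [(label, n, pct) for sec, label, n, pct in self.rows if sec == name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["section", "label", "count", "percent"]
        )


def _categorical_rows(
    section: str,
    values: list[str | None],
    ordered_labels: tuple[str, ...],
    denominator: int,
) -> list[tuple[str, str, int, float]]:
    rows = []
    for label in ordered_labels:
        n = sum(1 for v in values if v == label)
        rows.append((section, label, n, percent(n, denominator)))
    n_missing = sum(1 for v in values if v is None)
    rows.append((section, _MISSING_LABEL, n_missing, percent(n_missing, denominator)))
    return rows


def summarize(
    included: IcsrDatabase,
    age_cut: float = 75.0,
    target_atc: str = "L01XE27",
    quartile_method: str = "median_unbiased",
    canonical_indications: tuple[str, ...] = DEFAULT_INDICATIONS,
) -> SummaryTable:
    """Build the characteristics table of an analysis set.

    Requires a non-empty database with all ages present (both guaranteed
    after case selection).  The suspected-drug multiplicity and
    indication sections describe reports carrying the target drug; all
    percentages use the full database size as denominator, matching the
    convention of a single-drug characteristics table.  The quartile
    convention is configurable (any :func:`numpy.quantile` method);
    median-unbiased interpolation is the default.
    """
    if not included.reports:
        raise ValueError("cannot summarize an empty database")
    reports = included.reports
    denominator = len(reports)
    ages = np.array([r.age_years for r in reports], dtype=float)
    if np.isnan(ages).any():
        raise ValueError("all ages must be present; run case selection first")

    rows: list[tuple[str, str, int, float]] = []

    region_values = [r.region for r in reports]
    for label in REGIONS:
        n = sum(1 for v in region_values if v == label)
        rows.append(("region", label, n, percent(n, denominator)))

    rows.extend(
        _categorical_rows("reporter", [r.reporter for r in reports], REPORTERS, denominator)
    )

    q1, median, q3 = np.quantile(ages, [0.25, 0.5, 0.75], method=quartile_method)
    age_stats = (
        float(median),
        float(q1),
        float(q3),
        float(ages.min()),
        float(ages.max()),
    )

    n_under = int(np.sum(ages < age_cut))
    n_at_least = denominator - n_under
    rows.append(("age_group", UNDER_CUT, n_under, percent(n_under, denominator)))
    rows.append(("age_group", AT_LEAST_CUT, n_at_least, percent(n_at_least, denominator)))

    rows.extend(
        _categorical_rows("sex", [r.sex for r in reports], SEXES, denominator)
    )

    for criterion in SERIOUSNESS_CRITERIA:
        n = sum(1 for r in reports if criterion in r.seriousness)
        rows.append(("seriousness", criterion, n, percent(n, denominator)))
    n_no_criterion = sum(1 for r in reports if not r.seriousness)
    rows.append(
        ("seriousness", _MISSING_LABEL, n_no_criterion, percent(n_no_criterion, denominator))
    )

    causal_roles = {"suspected", "interacting"}
    multiplicity = {"only_target": 0, "target_plus_1": 0, "target_plus_2_or_more": 0}
    indication_values: list[str | None] = []
    for report in reports:
        target_entries = [
            e for e in report.drugs if is_drug_of_interest(e, target_atc)
        ]
        if not target_entries:
            continue
        others = sum(
            1
            for e in report.drugs
            if e.role in causal_roles and not is_drug_of_interest(e, target_atc)
        )
        if others == 0:
            multiplicity["only_target"] += 1
        elif others == 1:
            multiplicity["target_plus_1"] += 1
        else:
            multiplicity["target_plus_2_or_more"] += 1
        indication_values.append(target_entries[0].indication)
    for label, n in multiplicity.items():
        rows.append(("suspected_drugs", label, n, percent(n, denominator)))

    indication_counts: dict[str, int] = {
        label: 0 for label in (*canonical_indications, "other", _MISSING_LABEL)
    }
    for value in indication_values:
        if value is None:
            indication_counts[_MISSING_LABEL] += 1
        elif value in canonical_indications:
            indication_counts[value] += 1
        else:
            indication_counts["other"] += 1
    for label, n in indication_counts.items():
        rows.append(("indication", label, n, percent(n, denominator)))

    return SummaryTable(rows=rows, age_stats=age_stats, denominator=denominator)
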