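"""Inclusion/exclusion of reports and assignment to analysis arms.

The analysis set keeps serious reports received within the study window
that involve either the drug of interest or a comparator-class drug with
a causal role, with a known age of at least the adult threshold and at
least one informative preferred term.  Every excluded report is logged
under the first rule it fails, in a fixed rule order, so that the sizes
conserve: ``|included| + Σ counts_by_rule == |input|``.
"""

from __future__ import annotations

import dataclasses
import datetime

from .icsr import (
    ICSR,
    NO_ADVERSE_EVENT,
    IcsrDatabase,
    is_comparator_drug,
    is_drug_of_interest,
)

__all__ = [
    "SelectionCriteria",
    "SelectionResult",
    "RULE_ORDER",
    "select_cases",
    "split_arms",
]

#: Exclusion rules in evaluation order; the first failing rule is logged.
RULE_ORDER = (
    "window",
    "serious",
    "no_qualifying_drug",
    "missing_age",
    "age_under_min",
    "no_pt",
)


@dataclasses.dataclass(frozen=True)
class SelectionCriteria:
    """Study inclusion parameters.

    The defaults reproduce a serious-only extract for ATC L01XE27 against
    the antineoplastic class L01, received between 2013-11-13 (first
    marketing authorisation of the target) and 2020-12-31, restricted to
    adults: exclusion of missing age, age strictly below 18 years, and
    reports whose only preferred term is absent or the
    ``"no adverse event"`` sentinel.
    """

    date_start: datetime.date = datetime.date(2013, 11, 13)
    date_end: datetime.date = datetime.date(2020, 12, 31)
    require_serious: bool = True
    target_atc: str = "L01XE27"
    comparator_atc_prefix: str = "L01"
    min_age_years: float = 18.0
    excluded_pt_sentinel: str = NO_ADVERSE_EVENT

    def __post_init__(self) -> None:
        if self.date_start > self.date_end:
            raise ValueError("date_start must be <= date_end")


@dataclasses.dataclass
class SelectionResult:
    included: IcsrDatabase
    exclusion_log: list[tuple[str, str]]
    counts_by_rule: dict[str, int]


def _first_failed_rule(report: ICSR, criteria: SelectionCriteria) -> str | None:
    if not criteria.date_start <= report.received_date <= criteria.date_end:
        return "window"
    if criteria.require_serious and not report.seriousness:
        return "serious"
    qualifying = any(
        is_drug_of_interest(entry, criteria.target_atc)
        or is_comparator_drug(
            entry, criteria.comparator_atc_prefix, criteria.target_atc
        )
        for entry in report.drugs
    )
    if not qualifying:
        return "no_qualifying_drug"
    if report.age_years is None:
        return "missing_age"
    if report.age_years < criteria.min_age_years:
        return "age_under_min"
    informative_pt = any(
        reaction.pt and reaction.pt != criteria.excluded_pt_sentinel
        for reaction in report.reactions
    )
    if not informative_pt:
        return "no_pt"
    return None


def select_cases(db: IcsrDatabase, criteria: SelectionCriteria) -> SelectionResult:
    """Apply the selection rules, never raising on report content.

    The included set does not depend on the rule order; only the rule
    attributed to a multiply-failing report does.
    """
    included: list[ICSR] = []
    exclusion_log: list[tuple[str, str]] = []
    counts: dict[str, int] = {}
    for report in db.reports:
        rule = _first_failed_rule(report, criteria)
        if rule is None:
            included.append(report)
        else:
            exclusion_log.append((report.report_id, rule))
            counts[rule] = counts.get(rule, 0) + 1
    provenance = dict(db.provenance)
    provenance["selection"] = {
        "included": len(included),
        "excluded": len(exclusion_log),
    }
    return SelectionResult(
        included=IcsrDatabase(reports=included, provenance=provenance),
        exclusion_log=exclusion_log,
        counts_by_rule=counts,
    )


def split_arms(
    included: IcsrDatabase,
    target_atc: str = "L01XE27",
    comparator_prefix: str = "L01",
) -> tuple[list[ICSR], list[ICSR]]:
    """Partition selected reports into target and comparator arms.

    A report carrying the drug of interest (suspected or interacting)
    belongs to the target arm even when comparator-class drugs are
    co-suspected; otherwise any causal comparator-class drug puts it in
    the comparator arm.  The arms are disjoint and cover every report
    with a qualifying drug.
    """
    target_arm: list[ICSR] = []
    comparator_arm: list[ICSR] = []
    for report in included.reports:
        if any(is_drug_of_interest(entry, target_atc) for entry in report.drugs):
            target_arm.append(report)
        elif any(
            is_comparator_drug(entry, comparator_prefix, target_atc)
            for entry in report.drugs
        ):
            comparator_arm.append(report)
    return target_arm, comparator_arm
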