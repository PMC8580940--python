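"""SDR decision rule, triage against expectedness lists, and overlaps.

A signal of disproportionate reporting (SDR) is declared for a
drug–event–stratum triple when the disproportionality statistics are
jointly significant — by default the IC credibility bound above 0 *and*
the PRR 95% lower confidence limit above 1 — with at least 3 observed
cases.  The default IC threshold of 0 is the standard operating
criterion for the shrunk information component; the threshold, the PRR
bound and the conjunction/disjunction are all configurable.

Detected SDRs are then triaged against two user-supplied reference
lists emulating expert review of the product label: PTs well described
in the Summary of Product Characteristics are *expected*; PTs with an
alternative explanation are *non-signals*; everything else is a
*potential safety signal*.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections import Counter
from typing import Iterable, Sequence

import pandas as pd

from .describe import percent
from .dispro import DisproResult, STRATUM_UNDER, STRATUM_AT_LEAST
from .icsr import ICSR, IcsrDatabase

__all__ = [
    "EXPECTED",
    "NON_SIGNAL",
    "POTENTIAL_SAFETY_SIGNAL",
    "SdrCriteria",
    "SDRDecision",
    "TriageOutcome",
    "decide_sdr",
    "decide_all",
    "triage",
    "unique_pairs",
    "OverlapCounts",
    "overlap_counts",
    "format_results_table",
]

EXPECTED = "expected"
NON_SIGNAL = "non_signal"
POTENTIAL_SAFETY_SIGNAL = "potential_safety_signal"

#: Display order of strata in rendered tables (younger group first).
_STRATUM_ORDER = {STRATUM_UNDER: 0, STRATUM_AT_LEAST: 1, "all": 2}


@dataclasses.dataclass(frozen=True)
class SdrCriteria:
    """Thresholds of the SDR rule.

    ``combination="both"`` requires IC *and* PRR significance (the
    conservative dual criterion); ``"either"`` accepts one.
    """

    ic025_threshold: float = 0.0
    prr_low_threshold: float = 1.0
    min_cases: int = 3
    combination: str = "both"

    def __post_init__(self) -> None:
        if self.min_cases < 1:
            raise ValueError("min_cases must be >= 1")
        if self.combination not in ("both", "either"):
            raise ValueError("combination must be 'both' or 'either'")


@dataclasses.dataclass(frozen=True)
class SDRDecision:
    """Per-triple significance flags and combined verdict.

    A ``None`` flag means the statistic was not estimable for the
    triple; ``is_sdr`` is always ``False`` below the minimum case
    count.
    """

    pt: str
    stratum: str
    n_obs: int
    ic_significant: bool | None
    prr_significant: bool | None
    is_sdr: bool


@dataclasses.dataclass(frozen=True)
class TriageOutcome:
    pt: str
    stratum: str
    label: str


def decide_sdr(result: DisproResult, criteria: SdrCriteria = SdrCriteria()) -> SDRDecision:
    """Apply the SDR rule to one disproportionality result."""
    ic_significant = result.ic025 > criteria.ic025_threshold
    prr_significant = (
        None if result.prr_low is None else result.prr_low > criteria.prr_low_threshold
    )
    flags = (ic_significant, prr_significant)
    if criteria.combination == "both":
        combined = all(flag is True for flag in flags)
    else:
        combined = any(flag is True for flag in flags)
    return SDRDecision(
        pt=result.pt,
        stratum=result.stratum,
        n_obs=result.n_obs,
        ic_significant=ic_significant,
        prr_significant=prr_significant,
        is_sdr=bool(combined and result.n_obs >= criteria.min_cases),
    )


def decide_all(
    results: Sequence[DisproResult], criteria: SdrCriteria = SdrCriteria()
) -> list[SDRDecision]:
    return [decide_sdr(result, criteria) for result in results]


def triage(
    decisions: Sequence[SDRDecision],
    expected_pts: Iterable[str],
    non_signal_pts: Iterable[str],
) -> tuple[list[TriageOutcome], pd.DataFrame]:
    """Classify every SDR and tally outcomes per stratum.

    Order of precedence: expected (PT on the label list), then
    non-signal (PT with an alternative explanation), then potential
    safety signal.  The two reference lists must be disjoint.  The
    returned tally frame has columns (stratum, label, count, percent)
    with percentages of assessed SDRs within the stratum; counts
    conserve: the three labels sum to the SDR count of the stratum.
    """
    expected_set = set(expected_pts)
    non_signal_set = set(non_signal_pts)
    clash = expected_set & non_signal_set
    if clash:
        raise ValueError(
            f"reference lists overlap on PT {sorted(clash)[0]!r}"
        )

    outcomes: list[TriageOutcome] = []
    for decision in decisions:
        if not decision.is_sdr:
            continue
        if decision.pt in expected_set:
            label = EXPECTED
        elif decision.pt in non_signal_set:
            label = NON_SIGNAL
        else:
            label = POTENTIAL_SAFETY_SIGNAL
        outcomes.append(TriageOutcome(pt=decision.pt, stratum=decision.stratum, label=label))

    tally_rows = []
    strata = sorted(
        {o.stratum for o in outcomes}, key=lambda s: _STRATUM_ORDER.get(s, 99)
    )
    for stratum in strata:
        in_stratum = [o for o in outcomes if o.stratum == stratum]
        counts = Counter(o.label for o in in_stratum)
        for label in (EXPECTED, NON_SIGNAL, POTENTIAL_SAFETY_SIGNAL):
            tally_rows.append(
                {
                    "stratum": stratum,
                    "label": label,
                    "count": counts.get(label, 0),
                    "percent": percent(counts.get(label, 0), len(in_stratum))
                    if in_stratum
                    else 0.0,
                }
            )
    tally = pd.DataFrame(tally_rows, columns=["stratum", "label", "count", "percent"])
    return outcomes, tally


def unique_pairs(outcomes: Sequence[TriageOutcome]) -> list[tuple[str, str]]:
    """Collapse per-stratum outcomes to unique drug–event pairs.

    A PT flagged in either stratum appears once, with its triage label
    (the label depends only on the PT, so strata agree)."""
    return sorted({(o.pt, o.label) for o in outcomes})


@dataclasses.dataclass
class OverlapCounts:
    """Report counts per PT group and per group intersection."""

    singles: dict[str, int]
    pairs: dict[tuple[str, str], int]
    triples: dict[tuple[str, str, str], int]

    def count(self, *names: str) -> int:
        for name in names:
            if name not in self.singles:
                raise KeyError(f"unknown group name: {name!r}")
        key = tuple(sorted(set(names)))
        if len(key) == 1:
            return self.singles[key[0]]
        if len(key) == 2:
            return self.pairs[key]  # type: ignore[index]
        if len(key) == 3:
            return self.triples[key]  # type: ignore[index]
        raise KeyError("at most three groups can be intersected")


def overlap_counts(
    included: IcsrDatabase | Sequence[ICSR], groups: dict[str, Iterable[str]]
) -> OverlapCounts:
    """Report-level co-reporting between named PT groups.

    A report belongs to a group when it mentions at least one of the
    group's PTs; intersections use set semantics at the report level
    (the same report counts once however many matching PTs it lists).
    """
    if not groups:
        raise ValueError("at least one group is required")
    group_sets = {name: set(pts) for name, pts in groups.items()}
    for name, pts in group_sets.items():
        if not pts:
            raise ValueError(f"group {name!r} must be non-empty")

    reports = included.reports if isinstance(included, IcsrDatabase) else included
    membership: dict[str, set[str]] = {name: set() for name in group_sets}
    for report in reports:
        pt_set = report.pt_set()
        for name, pts in group_sets.items():
            if pt_set & pts:
                membership[name].add(report.report_id)

    names = sorted(group_sets)
    singles = {name: len(membership[name]) for name in names}
    pairs = {
        (x, y): len(membership[x] & membership[y])
        for x, y in itertools.combinations(names, 2)
    }
    triples = {
        (x, y, z): len(membership[x] & membership[y] & membership[z])
        for x, y, z in itertools.combinations(names, 3)
    }
    return OverlapCounts(singles=singles, pairs=pairs, triples=triples)


def _fmt(value: float | None, decimals: int = 2) -> str:
    return "NA" if value is None else f"{value:.{decimals}f}"


def format_results_table(
    results: Sequence[DisproResult],
    decisions: Sequence[SDRDecision],
) -> pd.DataFrame:
    """Render results in the printed-table style.

    Not-estimable statistics print as ``NA``; estimable statistics on a
    triple that is not an SDR print as ``NS`` (not significant); SDR
    rows print ``IC/IC025`` and ``PRR (low–high)`` with 2 decimals.
    """
    by_key = {(d.pt, d.stratum): d for d in decisions}
    rows = []
    for result in sorted(
        results, key=lambda r: (_STRATUM_ORDER.get(r.stratum, 99), r.pt)
    ):
        decision = by_key.get((result.pt, result.stratum))
        if decision is None:
            continue
        if decision.is_sdr:
            ic_text = f"{result.ic:.2f}/{result.ic025:.2f}"
            prr_text = (
                f"{result.prr:.2f} ({result.prr_low:.2f}–{result.prr_high:.2f})"
            )
        else:
            ic_text = "NS" if decision.n_obs >= 1 else "NA"
            prr_text = "NA" if result.prr is None else "NS"
        rows.append(
            {
                "pt": result.pt,
                "stratum": result.stratum,
                "n": result.n_obs,
                "ic_ic025": ic_text,
                "prr_95ci": prr_text,
                "is_sdr": decision.is_sdr,
            }
        )
    return pd.DataFrame(
        rows, columns=["pt", "stratum", "n", "ic_ic025", "prr_95ci", "is_sdr"]
    )
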