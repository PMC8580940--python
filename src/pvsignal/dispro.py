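"""Report-level 2×2 contingency tables and disproportionality statistics.

For one drug of interest against a comparator class, within one age
stratum, each preferred term (PT) yields a 2×2 table of report counts

    ============================  ==========  ==============
                                  PT present  PT absent
    ============================  ==========  ==============
    target-arm reports            a           b
    comparator-arm reports        c           d
    ============================  ==========  ==============

A report mentioning a PT several times counts once (report-level
counting).  Two measures are computed per table:

* the proportional reporting ratio,
  ``PRR = [a/(a+b)] / [c/(c+d)]``, with the log-normal Wald interval
  ``exp(ln PRR ± z·sqrt(1/a − 1/(a+b) + 1/c − 1/(c+d)))``;
  not estimable when ``a = 0`` or ``c = 0`` (no continuity correction);

* the information component, a shrunk log2 observed-to-expected ratio
  with ``O = a``, ``E = (a+b)(a+c)/N``, ``N = a+b+c+d``:
  ``IC = log2((O+0.5)/(E+0.5))`` and the 2.5% credibility bound
  ``IC025 = IC − 3.3·(O+0.5)^−1/2 − 2·(O+0.5)^−3/2``.
  The shrinkage constant 0.5 keeps the IC finite at ``O = 0``.

The expected count E is computed within the stratum analysis set formed
by the two arms passed in (the comparator class is the reference group);
passing a broader comparator set widens the reference accordingly.
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter
from typing import Iterable, Sequence

import pandas as pd

from .icsr import ICSR, NO_ADVERSE_EVENT, IntegrityError

__all__ = [
    "STRATUM_ALL",
    "STRATUM_UNDER",
    "STRATUM_AT_LEAST",
    "Z_95",
    "ContingencyTable",
    "DisproResult",
    "build_tables",
    "prr_with_ci",
    "ic_with_credibility",
    "analyze_stratum",
    "analyze_strata",
    "results_to_frame",
]

STRATUM_ALL = "all"
STRATUM_UNDER = "under_75"
STRATUM_AT_LEAST = "at_least_75"
_STRATA = (STRATUM_ALL, STRATUM_UNDER, STRATUM_AT_LEAST)

#: Two-sided 97.5% normal quantile used for the 95% PRR interval.
Z_95 = 1.959964


@dataclasses.dataclass(frozen=True)
class ContingencyTable:
    """Report-level 2×2 counts for one PT within one stratum."""

    pt: str
    stratum: str
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.stratum not in _STRATA:
            raise ValueError(f"invalid stratum: {self.stratum!r}")


@dataclasses.dataclass(frozen=True)
class DisproResult:
    """IC and PRR for one drug–event–stratum triple.

    ``prr``/``prr_low``/``prr_high`` are ``None`` when the PRR is not
    estimable (``a = 0`` or ``c = 0``).
    """

    pt: str
    stratum: str
    n_obs: int
    expected: float
    ic: float
    ic025: float
    prr: float | None
    prr_low: float | None
    prr_high: float | None

    @property
    def prr_estimable(self) -> bool:
        return self.prr is not None


def _stratum_filter(reports: Sequence[ICSR], stratum: str, age_cut: float) -> list[ICSR]:
    if stratum == STRATUM_ALL:
        return list(reports)
    for report in reports:
        if report.age_years is None:
            raise ValueError(
                f"report {report.report_id!r} has missing age; "
                "stratified analysis requires selected reports"
            )
    if stratum == STRATUM_UNDER:
        return [r for r in reports if r.age_years < age_cut]
    return [r for r in reports if r.age_years >= age_cut]


def build_tables(
    target_reports: Sequence[ICSR],
    comparator_reports: Sequence[ICSR],
    stratum: str = STRATUM_ALL,
    pt_universe: Iterable[str] | None = None,
    age_cut: float = 75.0,
) -> list[ContingencyTable]:
    """One 2×2 table per PT observed in either arm within the stratum.

    When ``pt_universe`` is given, exactly those PTs are tabulated (PTs
    absent from the data yield ``a = c = 0`` rows).  The
    ``"no adverse event"`` sentinel is never tabulated.  Margins
    ``a+b`` and ``c+d`` are constant across PTs within a stratum.
    """
    target_ids = {r.report_id for r in target_reports}
    overlap = target_ids.intersection(r.report_id for r in comparator_reports)
    if overlap:
        raise IntegrityError(
            f"arms overlap on report_id {sorted(overlap)[0]!r}"
        )

    target_in = _stratum_filter(target_reports, stratum, age_cut)
    comparator_in = _stratum_filter(comparator_reports, stratum, age_cut)

    target_counts: Counter[str] = Counter()
    for report in target_in:
        target_counts.update(report.pt_set())
    comparator_counts: Counter[str] = Counter()
    for report in comparator_in:
        comparator_counts.update(report.pt_set())
    target_counts.pop(NO_ADVERSE_EVENT, None)
    comparator_counts.pop(NO_ADVERSE_EVENT, None)

    if pt_universe is None:
        pts = sorted(set(target_counts) | set(comparator_counts))
    else:
        pts = sorted(set(pt_universe) - {NO_ADVERSE_EVENT})

    n_target = len(target_in)
    n_comparator = len(comparator_in)
    return [
        ContingencyTable(
            pt=pt,
            stratum=stratum,
            a=target_counts.get(pt, 0),
            b=n_target - target_counts.get(pt, 0),
            c=comparator_counts.get(pt, 0),
            d=n_comparator - comparator_counts.get(pt, 0),
        )
        for pt in pts
    ]


def prr_with_ci(
    t: ContingencyTable, z: float = Z_95
) -> tuple[float, float, float] | None:
    """PRR point estimate with its 95% log-normal Wald interval.

    Returns ``None`` (not estimable) when ``a = 0`` or ``c = 0``.
    Requires non-empty margins on both arms.
    """
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise ValueError("both arm margins must be positive")
    if t.a == 0 or t.c == 0:
        return None
    prr = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    se = math.sqrt(1.0 / t.a - 1.0 / (t.a + t.b) + 1.0 / t.c - 1.0 / (t.c + t.d))
    log_prr = math.log(prr)
    return (prr, math.exp(log_prr - z * se), math.exp(log_prr + z * se))


def ic_with_credibility(t: ContingencyTable) -> tuple[float, float, float]:
    """Information component, its 2.5% credibility bound, and E.

    Finite for ``O = 0`` thanks to the +0.5 shrinkage; ``IC025 < IC``
    always.
    """
    n_total = t.a + t.b + t.c + t.d
    if n_total <= 0:
        raise ValueError("table is empty")
    observed = t.a
    expected = (t.a + t.b) * (t.a + t.c) / n_total
    shrunk = observed + 0.5
    ic = math.log2(shrunk / (expected + 0.5))
    ic025 = ic - 3.3 * shrunk ** -0.5 - 2.0 * shrunk ** -1.5
    return ic, ic025, expected


def analyze_stratum(
    target_reports: Sequence[ICSR],
    comparator_reports: Sequence[ICSR],
    stratum: str = STRATUM_ALL,
    pt_universe: Iterable[str] | None = None,
    age_cut: float = 75.0,
) -> list[DisproResult]:
    """Both disproportionality measures for every PT of one stratum.

    Deterministic output, ordered by ascending PT label; invariant to
    the order of the input reports.
    """
    results = []
    for table in build_tables(
        target_reports, comparator_reports, stratum, pt_universe, age_cut
    ):
        ic, ic025, expected = ic_with_credibility(table)
        prr_triple = prr_with_ci(table)
        prr, prr_low, prr_high = prr_triple if prr_triple is not None else (None,) * 3
        results.append(
            DisproResult(
                pt=table.pt,
                stratum=stratum,
                n_obs=table.a,
                expected=expected,
                ic=ic,
                ic025=ic025,
                prr=prr,
                prr_low=prr_low,
                prr_high=prr_high,
            )
        )
    return results


def analyze_strata(
    target_reports: Sequence[ICSR],
    comparator_reports: Sequence[ICSR],
    strata: Sequence[str] = (STRATUM_UNDER, STRATUM_AT_LEAST),
    pt_universe: Iterable[str] | None = None,
    age_cut: float = 75.0,
) -> list[DisproResult]:
    """Age-stratified analysis over the requested strata, concatenated."""
    results: list[DisproResult] = []
    for stratum in strata:
        results.extend(
            analyze_stratum(
                target_reports, comparator_reports, stratum, pt_universe, age_cut
            )
        )
    return results


def results_to_frame(results: Sequence[DisproResult]) -> pd.DataFrame:
    """Tabular view with columns (pt, stratum, n, expected, ic, ic025,
    prr, prr_low, prr_high); not-estimable PRRs are NaN."""
    return pd.DataFrame(
        {
            "pt": [r.pt for r in results],
            "stratum": [r.stratum for r in results],
            "n": [r.n_obs for r in results],
            "expected": [r.expected for r in results],
            "ic": [r.ic for r in results],
            "ic025": [r.ic025 for r in results],
            "prr": [r.prr for r in results],
            "prr_low": [r.prr_low for r in results],
            "prr_high": [r.prr_high for r in results],
        }
    )
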