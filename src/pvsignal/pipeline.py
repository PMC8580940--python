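"""End-to-end pipeline: simulate (or load) → select → describe →
analyze → decide → triage.

One call runs the whole signal-detection study on a database and
returns every intermediate product, so scripts and the command line
stay thin wrappers.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import pandas as pd

from . import dispro, signals
from .describe import SummaryTable, summarize
from .dispro import DisproResult, STRATUM_AT_LEAST, STRATUM_UNDER
from .icsr import ICSR, IcsrDatabase
from .selection import SelectionCriteria, SelectionResult, select_cases, split_arms
from .signals import SdrCriteria, SDRDecision, TriageOutcome

__all__ = ["PipelineResult", "run_pipeline"]


@dataclasses.dataclass
class PipelineResult:
    selection: SelectionResult
    target_arm: list[ICSR]
    comparator_arm: list[ICSR]
    summary: SummaryTable
    results: list[DisproResult]
    decisions: list[SDRDecision]
    outcomes: list[TriageOutcome]
    tally: pd.DataFrame

    @property
    def sdrs(self) -> list[SDRDecision]:
        return [d for d in self.decisions if d.is_sdr]

    @property
    def unique_pairs(self) -> list[tuple[str, str]]:
        return signals.unique_pairs(self.outcomes)

    def results_frame(self) -> pd.DataFrame:
        return dispro.results_to_frame(self.results)


def run_pipeline(
    db: IcsrDatabase,
    selection_criteria: SelectionCriteria = SelectionCriteria(),
    sdr_criteria: SdrCriteria = SdrCriteria(),
    expected_pts: Iterable[str] = (),
    non_signal_pts: Iterable[str] = (),
    strata: Sequence[str] = (STRATUM_UNDER, STRATUM_AT_LEAST),
    age_cut: float = 75.0,
) -> PipelineResult:
    """Run selection, description, disproportionality and triage.

    The descriptive summary covers the target arm (the population of
    interest); the disproportionality analysis compares the arms within
    each requested age stratum.
    """
    selection = select_cases(db, selection_criteria)
    target_arm, comparator_arm = split_arms(
        selection.included,
        selection_criteria.target_atc,
        selection_criteria.comparator_atc_prefix,
    )
    summary = summarize(
        IcsrDatabase(reports=target_arm, provenance=dict(db.provenance)),
        age_cut=age_cut,
        target_atc=selection_criteria.target_atc,
    )
    results = dispro.analyze_strata(
        target_arm, comparator_arm, strata=strata, age_cut=age_cut
    )
    decisions = signals.decide_all(results, sdr_criteria)
    outcomes, tally = signals.triage(decisions, expected_pts, non_signal_pts)
    return PipelineResult(
        selection=selection,
        target_arm=target_arm,
        comparator_arm=comparator_arm,
        summary=summary,
        results=results,
        decisions=decisions,
        outcomes=outcomes,
        tally=tally,
    )
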