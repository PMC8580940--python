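import datetime

import pytest

from pvsignal import ICSR, DrugEntry, IcsrDatabase, ReactionEntry


def make_report(
    report_id="R0000001",
    date=datetime.date(2018, 6, 1),
    region="north_america",
    reporter="healthcare_professional",
    age=70.0,
    sex="male",
    seriousness=("hospitalization",),
    drugs=None,
    reactions=None,
    outcome=None,
):
    """Handcrafted ICSR with a suspected target drug and one PT by default."""
    if drugs is None:
        drugs = [DrugEntry("ibrutinib", "L01XE27", "suspected", "chronic lymphocytic leukemia")]
    if reactions is None:
        reactions = [ReactionEntry("atrial fibrillation", "cardiac disorders")]
    return ICSR(
        report_id=report_id,
        received_date=date,
        region=region,
        reporter=reporter,
        age_years=age,
        sex=sex,
        seriousness=frozenset(seriousness),
        drugs=list(drugs),
        reactions=list(reactions),
        outcome=outcome,
    )


@pytest.fixture
def report_factory():
    return make_report


@pytest.fixture
def tiny_db():
    """Three reports: two target-arm sharing a PT, one comparator-arm."""
    comparator = [DrugEntry("rituximab", "L01FA01", "suspected")]
    return IcsrDatabase(
        reports=[
            make_report("R1"),
            make_report("R2", age=80.0),
            make_report("R3", drugs=comparator, reactions=[ReactionEntry("nausea", None)]),
        ]
    )
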