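"""Report-level co-reporting between clinically related event groups.

Counts how many reports mention at least one term of each group and how
many fall in the pairwise (and triple) intersections — the numbers
behind a Venn diagram of, say, pericarditis-type and pleurisy-type
serious reactions.
"""

from pvsignal import IcsrDatabase, ReactionEntry, overlap_counts
from pvsignal.icsr import ICSR, DrugEntry
import datetime


def report(rid, pts):
    return ICSR(
        report_id=rid,
        received_date=datetime.date(2019, 1, 1),
        region="europe",
        reporter="healthcare_professional",
        age_years=70.0,
        sex="male",
        seriousness=frozenset({"hospitalization"}),
        drugs=[DrugEntry("ibrutinib", "L01XE27", "suspected")],
        reactions=[ReactionEntry(pt) for pt in pts],
    )


db = IcsrDatabase(
    reports=[
        report("R1", ["pericardial effusion", "pleural effusion"]),
        report("R2", ["pericarditis"]),
        report("R3", ["pleural effusion"]),
        report("R4", ["cardiac tamponade", "pleurisy"]),
        report("R5", ["cataract"]),
    ]
)

groups = {
    "pericarditis": ["pericarditis", "pericardial effusion", "cardiac tamponade",
                     "pericardial hemorrhage"],
    "pleurisy": ["pleurisy", "pleural effusion"],
}
counts = overlap_counts(db, groups)
for name, n in counts.singles.items():
    print(f"reports with {name:<13} events: {n}")
for pair, n in counts.pairs.items():
    print(f"reports with both {' and '.join(pair)}: {n}")
print("\n(a report counts once per group however many matching terms it lists)")
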