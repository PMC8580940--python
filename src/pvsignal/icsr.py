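"""Individual case safety report (ICSR) data model and extract I/O.

An ICSR is one spontaneous report of suspected adverse drug reactions in
one patient.  It carries anonymous administrative information (receive
date, region of origin, reporter qualification), patient characteristics
(age, sex), seriousness criteria, the drugs involved (with their ATC code,
their role in the reaction, and the treatment indication), and the
reactions coded as MedDRA preferred terms (PTs) with their system organ
class (SOC).

Databases are exchanged as a three-table relational extract:

* ``reports.tsv``   — one row per ICSR,
* ``drugs.tsv``     — one row per drug entry, keyed by ``report_id``,
* ``reactions.tsv`` — one row per reaction entry, keyed by ``report_id``.

The dialect is UTF-8, tab-separated with a mandatory header row.  An empty
cell encodes a missing value, and the seriousness criteria of a report are
joined by ``"|"`` within a single cell.
"""

from __future__ import annotations

import dataclasses
import datetime
import re
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

__all__ = [
    "REGIONS",
    "REPORTERS",
    "SEXES",
    "SERIOUSNESS_CRITERIA",
    "DRUG_ROLES",
    "NO_ADVERSE_EVENT",
    "FormatError",
    "IntegrityError",
    "DrugEntry",
    "ReactionEntry",
    "ICSR",
    "IcsrDatabase",
    "read_database",
    "write_database",
    "is_drug_of_interest",
    "is_comparator_drug",
]

REGIONS = (
    "north_america",
    "europe",
    "asia",
    "oceania",
    "south_america",
    "africa",
)
REPORTERS = ("healthcare_professional", "non_healthcare_professional")
SEXES = ("male", "female")
SERIOUSNESS_CRITERIA = (
    "death",
    "life_threatening",
    "hospitalization",
    "disability",
    "other_medically_important",
)
DRUG_ROLES = ("suspected", "interacting", "concomitant")

#: Sentinel preferred term used by reporting systems for reports that in
#: the end describe no adverse event; such reports are excluded upstream.
NO_ADVERSE_EVENT = "no adverse event"

# Roles that tie a drug to the reported reaction.  Purely concomitant
# involvement never qualifies a report for either analysis arm.
_CAUSAL_ROLES = frozenset({"suspected", "interacting"})

# ATC codes follow letter, 2 digits, letter, letter, 2 digits; any prefix
# cut at a hierarchy level (lengths 1, 3, 4, 5, 7) is also valid.
_ATC_LEVEL_PATTERNS = {
    1: re.compile(r"^[A-Z]$"),
    3: re.compile(r"^[A-Z]\d{2}$"),
    4: re.compile(r"^[A-Z]\d{2}[A-Z]$"),
    5: re.compile(r"^[A-Z]\d{2}[A-Z]{2}$"),
    7: re.compile(r"^[A-Z]\d{2}[A-Z]{2}\d{2}$"),
}


def _valid_atc(code: str) -> bool:
    pattern = _ATC_LEVEL_PATTERNS.get(len(code))
    return pattern is not None and pattern.match(code) is not None


class FormatError(ValueError):
    """A TSV extract does not conform to the documented layout."""


class IntegrityError(ValueError):
    """Referential integrity of a database is violated."""


@dataclasses.dataclass(frozen=True)
class DrugEntry:
    """One drug on a report: INN identifier, ATC code, role, indication."""

    drug_code: str
    atc_code: str
    role: str
    indication: str | None = None

    def __post_init__(self) -> None:
        if not self.drug_code:
            raise ValueError("drug_code must be non-empty")
        if not _valid_atc(self.atc_code):
            raise ValueError(f"invalid ATC code: {self.atc_code!r}")
        if self.role not in DRUG_ROLES:
            raise ValueError(f"invalid drug role: {self.role!r}")


@dataclasses.dataclass(frozen=True)
class ReactionEntry:
    """One coded reaction: MedDRA preferred term and its organ class."""

    pt: str
    soc: str | None = None

    def __post_init__(self) -> None:
        if not self.pt:
            raise ValueError("pt must be a non-empty string")


@dataclasses.dataclass
class ICSR:
    """One individual case safety report."""

    report_id: str
    received_date: datetime.date
    region: str
    reporter: str | None
    age_years: float | None
    sex: str | None
    seriousness: frozenset[str]
    drugs: list[DrugEntry]
    reactions: list[ReactionEntry]
    outcome: str | None = None

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be non-empty")
        if self.region not in REGIONS:
            raise ValueError(f"invalid region: {self.region!r}")
        if self.reporter is not None and self.reporter not in REPORTERS:
            raise ValueError(f"invalid reporter: {self.reporter!r}")
        if self.age_years is not None and not 0.0 <= self.age_years <= 130.0:
            raise ValueError(f"age_years out of range: {self.age_years!r}")
        if self.sex is not None and self.sex not in SEXES:
            raise ValueError(f"invalid sex: {self.sex!r}")
        unknown = set(self.seriousness) - set(SERIOUSNESS_CRITERIA)
        if unknown:
            raise ValueError(f"invalid seriousness criteria: {sorted(unknown)}")

    @property
    def is_serious(self) -> bool:
        return bool(self.seriousness)

    def pt_set(self) -> set[str]:
        """Distinct preferred terms on the report (report-level counting)."""
        return {r.pt for r in self.reactions}


@dataclasses.dataclass
class IcsrDatabase:
    """A collection of ICSRs plus free-text provenance metadata."""

    reports: list[ICSR]
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for report in self.reports:
            if report.report_id in seen:
                raise IntegrityError(f"duplicate report_id: {report.report_id!r}")
            seen.add(report.report_id)

    def __len__(self) -> int:
        return len(self.reports)

    def __iter__(self) -> Iterator[ICSR]:
        return iter(self.reports)


_REPORT_COLUMNS = [
    "report_id",
    "received_date",
    "region",
    "reporter",
    "age_years",
    "sex",
    "seriousness",
    "outcome",
]
_DRUG_COLUMNS = ["report_id", "drug_code", "atc_code", "role", "indication"]
_REACTION_COLUMNS = ["report_id", "pt", "soc"]

_SERIOUSNESS_SEP = "|"


def _read_table(path: Path | str, required: Sequence[str], label: str) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8")
    for column in required:
        if column not in frame.columns:
            raise FormatError(f"{label} file is missing column {column!r}")
    return frame


def _opt(cell: str) -> str | None:
    return cell if cell != "" else None


def read_database(
    reports_path: Path | str,
    drugs_path: Path | str,
    reactions_path: Path | str,
) -> IcsrDatabase:
    """Read a three-table TSV extract into an :class:`IcsrDatabase`.

    Every row of the drugs and reactions files must reference a report id
    present in the reports file; a dangling id raises
    :class:`IntegrityError` naming the id.  Empty cells become missing
    values.
    """
    reports_frame = _read_table(reports_path, _REPORT_COLUMNS, "reports")
    drugs_frame = _read_table(drugs_path, _DRUG_COLUMNS, "drugs")
    reactions_frame = _read_table(reactions_path, _REACTION_COLUMNS, "reactions")

    known_ids = set(reports_frame["report_id"])
    for label, frame in (("drugs", drugs_frame), ("reactions", reactions_frame)):
        dangling = set(frame["report_id"]) - known_ids
        if dangling:
            raise IntegrityError(
                f"{label} file references unknown report_id {sorted(dangling)[0]!r}"
            )

    drugs_by_report: dict[str, list[DrugEntry]] = {rid: [] for rid in known_ids}
    for row in drugs_frame.itertuples(index=False):
        drugs_by_report[row.report_id].append(
            DrugEntry(
                drug_code=row.drug_code,
                atc_code=row.atc_code,
                role=row.role,
                indication=_opt(row.indication),
            )
        )
    reactions_by_report: dict[str, list[ReactionEntry]] = {rid: [] for rid in known_ids}
    for row in reactions_frame.itertuples(index=False):
        reactions_by_report[row.report_id].append(
            ReactionEntry(pt=row.pt, soc=_opt(row.soc))
        )

    reports = []
    for row in reports_frame.itertuples(index=False):
        seriousness = frozenset(
            token for token in row.seriousness.split(_SERIOUSNESS_SEP) if token
        )
        age_cell = _opt(row.age_years)
        reports.append(
            ICSR(
                report_id=row.report_id,
                received_date=datetime.date.fromisoformat(row.received_date),
                region=row.region,
                reporter=_opt(row.reporter),
                age_years=float(age_cell) if age_cell is not None else None,
                sex=_opt(row.sex),
                seriousness=seriousness,
                drugs=drugs_by_report[row.report_id],
                reactions=reactions_by_report[row.report_id],
                outcome=_opt(row.outcome),
            )
        )
    return IcsrDatabase(reports=reports, provenance={"source": str(reports_path)})


def write_database(db: IcsrDatabase, out_dir: Path | str) -> tuple[Path, Path, Path]:
    """Write ``db`` as reports.tsv / drugs.tsv / reactions.tsv in ``out_dir``.

    Round-trip guarantee: ``read_database(*write_database(db, d))``
    reproduces every field of ``db``, including missing sentinels.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def blank(value: object | None) -> object:
        return "" if value is None else value

    report_rows = []
    drug_rows = []
    reaction_rows = []
    for report in db.reports:
        report_rows.append(
            {
                "report_id": report.report_id,
                "received_date": report.received_date.isoformat(),
                "region": report.region,
                "reporter": blank(report.reporter),
                "age_years": blank(report.age_years),
                "sex": blank(report.sex),
                "seriousness": _SERIOUSNESS_SEP.join(sorted(report.seriousness)),
                "outcome": blank(report.outcome),
            }
        )
        for drug in report.drugs:
            drug_rows.append(
                {
                    "report_id": report.report_id,
                    "drug_code": drug.drug_code,
                    "atc_code": drug.atc_code,
                    "role": drug.role,
                    "indication": blank(drug.indication),
                }
            )
        for reaction in report.reactions:
            reaction_rows.append(
                {
                    "report_id": report.report_id,
                    "pt": reaction.pt,
                    "soc": blank(reaction.soc),
                }
            )

    paths = (
        out_dir / "reports.tsv",
        out_dir / "drugs.tsv",
        out_dir / "reactions.tsv",
    )
    for path, rows, columns in zip(
        paths,
        (report_rows, drug_rows, reaction_rows),
        (_REPORT_COLUMNS, _DRUG_COLUMNS, _REACTION_COLUMNS),
    ):
        pd.DataFrame(rows, columns=columns).to_csv(
            path, sep="\t", index=False, encoding="utf-8"
        )
    return paths


def is_drug_of_interest(entry: DrugEntry, target_atc: str) -> bool:
    """Whether a drug entry qualifies a report for the target arm.

    The entry must carry the exact target ATC code and be suspected in,
    or interacting with, the reported reaction.
    """
    if not target_atc:
        raise ValueError("target_atc must be non-empty")
    return entry.atc_code == target_atc and entry.role in _CAUSAL_ROLES


def is_comparator_drug(
    entry: DrugEntry, comparator_atc_prefix: str, target_atc: str
) -> bool:
    """Whether a drug entry qualifies a report for the comparator arm.

    The entry's ATC code must fall under the comparator class prefix
    without being the target code itself, with a causal (suspected or
    interacting) role.  For any ``(target, prefix)`` pair this partitions
    drug entries: no entry is both drug-of-interest and comparator.
    """
    if not comparator_atc_prefix:
        raise ValueError("comparator_atc_prefix must be non-empty")
    return (
        entry.atc_code.startswith(comparator_atc_prefix)
        and entry.atc_code != target_atc
        and entry.role in _CAUSAL_ROLES
    )
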