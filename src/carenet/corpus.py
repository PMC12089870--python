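"""Domain types for patients, known contacts, providers, and text records,
plus readers/writers for the on-disk schemas.

On-disk layout (all plain text):

* ``patients.csv`` — study_id,first_name,last_name,age_years,sex,race
* ``contacts.csv`` — contact_id,patient_id,first_name,last_name,contact_types,relationship
  (contact_types is a semicolon-separated flag list)
* ``providers.csv`` — provider_id,patient_id,first_name,last_name,last_encounter_date (ISO-8601)
* ``notes.jsonl`` — one JSON object per line:
  record_id,patient_id,source,timestamp,text,author_is_proxy
"""

from __future__ import annotations

import csv
import datetime as dt
import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .errors import ConsistencyError, RecordValidationError, SchemaError
from .name_match import CostTable, DEFAULT_COSTS, DEFAULT_CUTOFF, accept


class Sex(str, Enum):
    female = "female"
    male = "male"
    other_unknown = "other_unknown"


class Race(str, Enum):
    """Race/ethnicity categories as reported for the study cohort."""

    aian_nhpi = "aian_nhpi"  # American Indian, Alaska Native, Pacific Islander, Native Hawaiian
    asian = "asian"
    black = "black"
    hispanic = "hispanic"
    white = "white"
    other = "other"
    unknown = "unknown"


class ContactType(str, Enum):
    general = "general"
    emergency = "emergency"
    guardian = "guardian"
    health_agent = "health_agent"
    portal_proxy = "portal_proxy"
    transportation = "transportation"


class Relationship(str, Enum):
    child = "child"
    parent = "parent"
    spouse = "spouse"
    other = "other"
    unknown = "unknown"


#: Priority used when merging duplicate contacts with conflicting codes.
RELATIONSHIP_PRIORITY = [
    Relationship.child,
    Relationship.spouse,
    Relationship.parent,
    Relationship.other,
    Relationship.unknown,
]


class Source(str, Enum):
    encounter = "encounter"
    appointment = "appointment"
    hospital = "hospital"
    permanent_comment = "permanent_comment"
    problem_list = "problem_list"
    portal_message = "portal_message"


SOURCES: tuple[Source, ...] = tuple(Source)


@dataclass(frozen=True)
class Patient:
    study_id: str
    first_name: str
    last_name: str
    age_years: int
    sex: Sex
    race: Race


@dataclass(frozen=True)
class KnownContact:
    contact_id: str
    patient_id: str
    first_name: str
    last_name: str
    contact_types: frozenset[ContactType]
    relationship: Relationship

    def same_surname(self, patient: Patient) -> bool:
        return self.last_name.lower() == patient.last_name.lower()


@dataclass(frozen=True)
class Provider:
    provider_id: str
    patient_id: str
    first_name: str
    last_name: str
    last_encounter_date: dt.date

    def is_recent(self, analysis_date: dt.date, years: int = 3) -> bool:
        """A provider is "known" iff seen within ``years`` before the analysis date."""
        window_start = analysis_date - dt.timedelta(days=round(365.25 * years))
        return window_start <= self.last_encounter_date <= analysis_date


@dataclass(frozen=True)
class TextRecord:
    record_id: str
    patient_id: str
    source: Source
    timestamp: dt.date
    text: str
    author_is_proxy: bool = False


# ---------------------------------------------------------------------------
# Readers / writers


def _check_columns(fieldnames, required: Sequence[str], path) -> None:
    missing = [c for c in required if fieldnames is None or c not in fieldnames]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_patients(path: str | Path) -> list[Patient]:
    cols = ["study_id", "first_name", "last_name", "age_years", "sex", "race"]
    out: list[Patient] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_columns(reader.fieldnames, cols, path)
        for row in reader:
            out.append(
                Patient(
                    study_id=row["study_id"],
                    first_name=row["first_name"],
                    last_name=row["last_name"],
                    age_years=int(row["age_years"]),
                    sex=Sex(row["sex"]),
                    race=Race(row["race"]),
                )
            )
    return out


def parse_relationship(raw: str) -> Relationship:
    """Map a free-form relationship string onto the enum; anything outside
    {child, parent, spouse, other} falls through to ``unknown``."""
    try:
        return Relationship(raw.strip().lower())
    except ValueError:
        return Relationship.unknown


def read_contacts(path: str | Path) -> list[KnownContact]:
    cols = [
        "contact_id",
        "patient_id",
        "first_name",
        "last_name",
        "contact_types",
        "relationship",
    ]
    out: list[KnownContact] = []
    bad_rows: list[int] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_columns(reader.fieldnames, cols, path)
        for i, row in enumerate(reader, start=2):  # 1-based incl. header
            if not row["first_name"].strip() or not row["last_name"].strip():
                bad_rows.append(i)
                continue
            types = frozenset(
                ContactType(t.strip())
                for t in row["contact_types"].split(";")
                if t.strip()
            )
            out.append(
                KnownContact(
                    contact_id=row["contact_id"],
                    patient_id=row["patient_id"],
                    first_name=row["first_name"],
                    last_name=row["last_name"],
                    contact_types=types,
                    relationship=parse_relationship(row["relationship"]),
                )
            )
    if bad_rows:
        raise RecordValidationError(
            f"{path}: empty name field(s) in row(s) {bad_rows}", rows=bad_rows
        )
    return out


def write_contacts(contacts: Iterable[KnownContact], path: str | Path) -> None:
    cols = [
        "contact_id",
        "patient_id",
        "first_name",
        "last_name",
        "contact_types",
        "relationship",
    ]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(cols)
        for c in contacts:
            w.writerow(
                [
                    c.contact_id,
                    c.patient_id,
                    c.first_name,
                    c.last_name,
                    ";".join(sorted(t.value for t in c.contact_types)),
                    c.relationship.value,
                ]
            )


def read_providers(path: str | Path) -> list[Provider]:
    cols = ["provider_id", "patient_id", "first_name", "last_name", "last_encounter_date"]
    out: list[Provider] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        _check_columns(reader.fieldnames, cols, path)
        for row in reader:
            out.append(
                Provider(
                    provider_id=row["provider_id"],
                    patient_id=row["patient_id"],
                    first_name=row["first_name"],
                    last_name=row["last_name"],
                    last_encounter_date=dt.date.fromisoformat(row["last_encounter_date"]),
                )
            )
    return out


def read_text_records(path: str | Path) -> list[TextRecord]:
    """Read newline-delimited JSON text records, preserving file order."""
    out: list[TextRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as e:
                raise RecordValidationError(f"{path}: malformed JSON on line {lineno}: {e}")
            try:
                source = Source(obj["source"])
            except ValueError:
                raise RecordValidationError(
                    f"{path}: record {obj.get('record_id')!r}: unknown source "
                    f"{obj.get('source')!r}"
                )
            except KeyError as e:
                raise RecordValidationError(
                    f"{path}: line {lineno}: missing key {e}"
                )
            out.append(
                TextRecord(
                    record_id=obj["record_id"],
                    patient_id=obj["patient_id"],
                    source=source,
                    timestamp=dt.date.fromisoformat(obj["timestamp"]),
                    text=obj["text"],
                    author_is_proxy=bool(obj.get("author_is_proxy", False)),
                )
            )
    return out


def write_text_records(records: Iterable[TextRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            fh.write(
                json.dumps(
                    {
                        "record_id": r.record_id,
                        "patient_id": r.patient_id,
                        "source": r.source.value,
                        "timestamp": r.timestamp.isoformat(),
                        "text": r.text,
                        "author_is_proxy": r.author_is_proxy,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Dedup and referential integrity


def dedupe_contacts(
    contacts: Sequence[KnownContact],
    costs: CostTable = DEFAULT_COSTS,
    cutoff: int = DEFAULT_CUTOFF,
) -> list[KnownContact]:
    """Merge duplicate contacts per patient.

    Two contacts of the same patient are duplicates when both first and last
    names match under the fuzzy acceptance rule.  Merged contacts union their
    contact-type flags; conflicting relationship codes resolve by priority
    child > spouse > parent > other > unknown.  Idempotent; keeps first-seen
    identity and name spelling.
    """
    merged: list[dict] = []
    for c in contacts:
        target = None
        for m in merged:
            rep = m["contact"]
            if rep.patient_id != c.patient_id:
                continue
            if accept(c.first_name, rep.first_name, costs, cutoff) and accept(
                c.last_name, rep.last_name, costs, cutoff
            ):
                target = m
                break
        if target is None:
            merged.append(
                {
                    "contact": c,
                    "types": set(c.contact_types),
                    "rel": c.relationship,
                }
            )
        else:
            target["types"] |= c.contact_types
            cur, new = target["rel"], c.relationship
            if RELATIONSHIP_PRIORITY.index(new) < RELATIONSHIP_PRIORITY.index(cur):
                target["rel"] = new
    return [
        KnownContact(
            contact_id=m["contact"].contact_id,
            patient_id=m["contact"].patient_id,
            first_name=m["contact"].first_name,
            last_name=m["contact"].last_name,
            contact_types=frozenset(m["types"]),
            relationship=m["rel"],
        )
        for m in merged
    ]


@dataclass(frozen=True)
class Corpus:
    """A cross-validated bundle of one synthetic or real study extract."""

    patients: list[Patient]
    contacts: list[KnownContact]
    providers: list[Provider]
    records: list[TextRecord]

    @property
    def patients_by_id(self) -> dict[str, Patient]:
        return {p.study_id: p for p in self.patients}

    @property
    def analysis_date(self) -> dt.date:
        """Default analysis anchor: latest record timestamp in the corpus."""
        if not self.records:
            raise ConsistencyError("empty corpus has no analysis date")
        return max(r.timestamp for r in self.records)


def load_corpus(directory: str | Path) -> Corpus:
    """Load patients/contacts/providers/notes from a directory and enforce
    referential integrity: every patient_id referenced anywhere must exist."""
    d = Path(directory)
    patients = read_patients(d / "patients.csv")
    contacts = read_contacts(d / "contacts.csv")
    providers = read_providers(d / "providers.csv") if (d / "providers.csv").exists() else []
    records = read_text_records(d / "notes.jsonl")
    ids = {p.study_id for p in patients}
    if len(ids) != len(patients):
        raise ConsistencyError("duplicate study_id in patients table")
    for c in contacts:
        if c.patient_id not in ids:
            raise ConsistencyError(f"contact {c.contact_id} references unknown patient {c.patient_id}")
    for pr in providers:
        if pr.patient_id not in ids:
            raise ConsistencyError(f"provider {pr.provider_id} references unknown patient {pr.patient_id}")
    for r in records:
        if r.patient_id not in ids:
            raise ConsistencyError(f"record {r.record_id} references unknown patient {r.patient_id}")
    return Corpus(patients=patients, contacts=contacts, providers=providers, records=records)
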