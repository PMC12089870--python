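"""Readers/writers, relationship mapping, dedup, and referential integrity."""

import datetime as dt

import pytest

from carenet.corpus import (
    ContactType,
    Corpus,
    KnownContact,
    Patient,
    Provider,
    Race,
    Relationship,
    Sex,
    Source,
    TextRecord,
    dedupe_contacts,
    load_corpus,
    parse_relationship,
    read_contacts,
    read_text_records,
    write_contacts,
)
from carenet.errors import ConsistencyError, RecordValidationError, SchemaError


def _contact(cid, pid, first, last, types=("general",), rel=Relationship.child):
    return KnownContact(
        contact_id=cid,
        patient_id=pid,
        first_name=first,
        last_name=last,
        contact_types=frozenset(ContactType(t) for t in types),
        relationship=rel,
    )


class TestReadContacts:
    HEADER = "contact_id,patient_id,first_name,last_name,contact_types,relationship\n"

    def test_row_parses_flags_and_relationship(self, tmp_path):
        p = tmp_path / "contacts.csv"
        p.write_text(self.HEADER + "C1,P1,John,Smith,general;emergency,child\n")
        [c] = read_contacts(p)
        assert c.contact_types == {ContactType.general, ContactType.emergency}
        assert c.relationship is Relationship.child

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "contacts.csv"
        p.write_text(self.HEADER)
        assert read_contacts(p) == []

    def test_unlisted_relationship_maps_to_unknown(self, tmp_path):
        p = tmp_path / "contacts.csv"
        p.write_text(self.HEADER + "C1,P1,Ann,Lee,general,son-in-law\n")
        [c] = read_contacts(p)
        assert c.relationship is Relationship.unknown

    @pytest.mark.parametrize(
        "raw,expected",
        [("child", "child"), ("SPOUSE", "spouse"), ("sibling", "unknown"), ("", "unknown")],
    )
    def test_relationship_mapping_table(self, raw, expected):
        assert parse_relationship(raw).value == expected

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "contacts.csv"
        p.write_text("contact_id,patient_id,first_name,last_name,contact_types\nC1,P1,A,B,general\n")
        with pytest.raises(SchemaError, match="relationship"):
            read_contacts(p)

    def test_empty_names_reported_with_row_numbers(self, tmp_path):
        p = tmp_path / "contacts.csv"
        p.write_text(
            self.HEADER
            + "C1,P1,John,Smith,general,child\n"
            + "C2,P1,,Smith,general,child\n"
            + "C3,P1,Ann,,general,child\n"
        )
        with pytest.raises(RecordValidationError) as exc:
            read_contacts(p)
        assert exc.value.rows == [3, 4]

    def test_round_trip(self, tmp_path):
        contacts = [
            _contact("C1", "P1", "John", "Smith", ("general", "emergency")),
            _contact("C2", "P2", "Ann", "Lee", ("health_agent",), Relationship.spouse),
        ]
        p = tmp_path / "contacts.csv"
        write_contacts(contacts, p)
        assert read_contacts(p) == contacts


class TestReadTextRecords:
    def test_valid_lines_preserve_order(self, tmp_path):
        p = tmp_path / "notes.jsonl"
        lines = [
            '{"record_id":"N%d","patient_id":"P1","source":"portal_message",'
            '"timestamp":"2024-01-0%d","text":"hello"}' % (i, i)
            for i in (1, 2, 3)
        ]
        p.write_text("\n".join(lines) + "\n")
        recs = read_text_records(p)
        assert [r.record_id for r in recs] == ["N1", "N2", "N3"]
        assert recs[0].source is Source.portal_message

    def test_unknown_source_rejected_with_record_id(self, tmp_path):
        p = tmp_path / "notes.jsonl"
        p.write_text(
            '{"record_id":"N9","patient_id":"P1","source":"fax",'
            '"timestamp":"2024-01-01","text":"x"}\n'
        )
        with pytest.raises(RecordValidationError, match="N9"):
            read_text_records(p)

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "notes.jsonl"
        p.write_text(
            '{"record_id":"N1","patient_id":"P1","source":"encounter",'
            '"timestamp":"2024-01-01","text":"x"}\n{not json}\n'
        )
        with pytest.raises(RecordValidationError, match="line 2"):
            read_text_records(p)


class TestDedupeContacts:
    def test_fuzzy_duplicates_merge_types(self):
        a = _contact("C1", "P1", "John", "Smith", ("emergency",))
        b = _contact("C2", "P1", "Jhon", "Smith", ("health_agent",))
        [m] = dedupe_contacts([a, b])
        assert m.contact_types == {ContactType.emergency, ContactType.health_agent}
        assert m.contact_id == "C1"

    def test_same_name_different_patients_kept_apart(self):
        a = _contact("C1", "P1", "John", "Smith")
        b = _contact("C2", "P2", "John", "Smith")
        assert len(dedupe_contacts([a, b])) == 2

    def test_relationship_priority(self):
        a = _contact("C1", "P1", "John", "Smith", rel=Relationship.unknown)
        b = _contact("C2", "P1", "John", "Smith", rel=Relationship.spouse)
        c = _contact("C3", "P1", "John", "Smith", rel=Relationship.parent)
        [m] = dedupe_contacts([a, b, c])
        assert m.relationship is Relationship.spouse

    def test_idempotent(self, small_corpus):
        corpus, _ = small_corpus
        once = dedupe_contacts(corpus.contacts)
        assert dedupe_contacts(once) == once
        assert len(once) <= len(corpus.contacts)

    def test_no_duplicates_is_identity(self):
        contacts = [
            _contact("C1", "P1", "Margaret", "Wilson"),
            _contact("C2", "P1", "Theodore", "Banks"),
        ]
        assert dedupe_contacts(contacts) == contacts


class TestCorpusIntegrity:
    def test_unknown_patient_reference_fails_at_load(self, tmp_path):
        (tmp_path / "patients.csv").write_text(
            "study_id,first_name,last_name,age_years,sex,race\n"
            "P1,Alice,Smith,81,female,white\n"
        )
        (tmp_path / "contacts.csv").write_text(
            "contact_id,patient_id,first_name,last_name,contact_types,relationship\n"
            "C1,P2,John,Smith,general,child\n"
        )
        (tmp_path / "notes.jsonl").write_text(
            '{"record_id":"N1","patient_id":"P1","source":"encounter",'
            '"timestamp":"2024-01-01","text":"ok"}\n'
        )
        with pytest.raises(ConsistencyError, match="P2"):
            load_corpus(tmp_path)

    def test_generated_corpus_round_trips_through_disk(self, tmp_path, small_corpus):
        from carenet.simulate import GeneratorConfig, generate

        corpus, _ = generate(GeneratorConfig(n_patients=5, seed=11), out_dir=tmp_path)
        loaded = load_corpus(tmp_path)
        assert loaded.patients == corpus.patients
        assert loaded.contacts == corpus.contacts
        assert loaded.providers == corpus.providers
        assert loaded.records == corpus.records

    def test_provider_recency_window(self):
        anchor = dt.date(2024, 6, 30)
        recent = Provider("V1", "P1", "Anya", "Patel", anchor - dt.timedelta(days=2 * 365))
        old = Provider("V2", "P1", "Anya", "Patel", anchor - dt.timedelta(days=4 * 365))
        assert recent.is_recent(anchor)
        assert not old.is_recent(anchor)
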