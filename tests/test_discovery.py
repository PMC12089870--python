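"""Name recognition, exclusion, scrubbing, and per-patient consolidation."""

import datetime as dt

import pytest

from carenet.caregiver_text import ContextWindow
from carenet.corpus import (
    ContactType,
    KnownContact,
    Patient,
    Provider,
    Race,
    Relationship,
    Sex,
    Source,
    TextRecord,
)
from carenet.discovery import (
    NameSpan,
    StopVocab,
    consolidate,
    exclude_known,
    recognize_names,
    scrub,
)
from carenet.errors import ConfigError
from carenet.lexicon import TermCategory, TermHit

ANCHOR = dt.date(2024, 6, 30)


def _rec(text, rid="R1", source=Source.encounter):
    return TextRecord(rid, "P1", source, dt.date(2024, 1, 1), text)


def _patient(first="Alice", last="Stafford"):
    return Patient("P1", first, last, 82, Sex.female, Race.white)


def _contact(first, last, cid="C1"):
    return KnownContact(cid, "P1", first, last, frozenset({ContactType.general}),
                        Relationship.child)


def _provider(first, last, years_ago):
    return Provider("V1", "P1", first, last,
                    ANCHOR - dt.timedelta(days=round(365.25 * years_ago)))


def _span(surface, tokens, indices, rid="R1", source="encounter"):
    return NameSpan(rid, "P1", source, 0, len(surface), surface,
                    tuple(tokens), tuple(indices), 1.0)


class TestRecognizeNames:
    def test_two_token_name_after_term(self):
        spans = recognize_names(_rec("Daughter Mary Jones will visit"))
        assert [s.surface for s in spans] == ["Mary Jones"]
        assert spans[0].confidence == 1.0
        assert spans[0].token_indices == (1, 2)

    def test_medication_not_a_name(self):
        assert recognize_names(_rec("Patient tolerated Lasix well")) == []

    def test_empty_text(self):
        assert recognize_names(_rec("")) == []

    def test_unregistered_backend_is_config_error(self):
        with pytest.raises(ConfigError, match="nonsense"):
            recognize_names(_rec("x"), backend="nonsense")

    def test_surface_equals_text_slice(self):
        rec = _rec("Spoke with Dr Patel and daughter Mary Jones about care.")
        for s in recognize_names(rec):
            assert rec.text[s.start : s.end] == s.surface

    def test_sentence_initial_capital_needs_gazetteer(self):
        # "Today" opens a sentence: not a name. "Mary" opens one too but is
        # gazetteer-listed.
        spans = recognize_names(_rec("Today went well. Mary called again"))
        assert [s.surface for s in spans] == ["Mary"]

    def test_title_joins_span(self):
        spans = recognize_names(_rec("seen by Dr Patel yesterday"))
        assert [s.surface for s in spans] == ["Dr Patel"]

    def test_mixed_stopword_capital_joins_gazetteer_token(self):
        spans = recognize_names(_rec("spoke with Hope Davis about the plan"))
        assert [s.surface for s in spans] == ["Hope Davis"]


class TestExcludeKnown:
    def test_exact_contact_excluded(self):
        spans = [_span("John Smith", ("John", "Smith"), (3, 4))]
        out = exclude_known(spans, [_contact("John", "Smith")], _patient(), [], ANCHOR)
        assert out == []

    def test_recent_provider_excluded_by_last_name(self):
        spans = [_span("Dr Patel", ("Dr", "Patel"), (3, 4))]
        out = exclude_known(spans, [], _patient(), [_provider("Anya", "Patel", 2)], ANCHOR)
        assert out == []

    def test_stale_provider_does_not_exclude(self):
        spans = [_span("Anya Patel", ("Anya", "Patel"), (3, 4))]
        out = exclude_known(spans, [], _patient(), [_provider("Anya", "Patel", 4)], ANCHOR)
        assert len(out) == 1

    def test_patient_name_excluded(self):
        spans = [_span("Alice", ("Alice",), (2,))]
        assert exclude_known(spans, [], _patient(), [], ANCHOR) == []

    def test_misspelled_contact_still_excluded(self):
        spans = [_span("Jhon Smith", ("Jhon", "Smith"), (3, 4))]
        out = exclude_known(spans, [_contact("John", "Smith")], _patient(), [], ANCHOR)
        assert out == []

    def test_unrelated_name_retained(self):
        spans = [_span("Gloria Vasquez", ("Gloria", "Vasquez"), (3, 4))]
        out = exclude_known(spans, [_contact("John", "Smith")], _patient(), [], ANCHOR)
        assert len(out) == 1


class TestScrub:
    def test_place_name_removed(self):
        assert scrub([_span("Denver", ("Denver",), (5,))]) == []

    def test_mixed_span_with_surname_retained(self):
        spans = [_span("Hope Davis", ("Hope", "Davis"), (5, 6))]
        out = scrub(spans)
        assert [s.surface for s in out] == ["Hope Davis"]

    def test_common_word_pair_removed(self):
        assert scrub([_span("Hope Today", ("Hope", "Today"), (5, 6))]) == []

    def test_empty_input(self):
        assert scrub([]) == []


def _window(rid, term_index, category, indices, tokens=None):
    return ContextWindow(
        record_id=rid,
        patient_id="P1",
        source="encounter",
        hit=TermHit(rid, term_index, "daughter", category),
        window_tokens=tuple(tokens or ("t%d" % i for i in indices)),
        window_token_indices=tuple(indices),
    )


class TestConsolidate:
    def test_counts_accumulate_per_category(self):
        spans = [
            _span("Mary Jones", ("Mary", "Jones"), (4, 5), rid=f"R{i}")
            for i in range(3)
        ]
        wins = [_window(f"R{i}", 2, TermCategory.child, (3, 4, 5, 6)) for i in range(3)]
        [cand] = consolidate(spans, wins)
        assert cand.per_category_counts == {"child": 3}
        assert cand.per_source_counts == {"encounter": 3}
        assert cand.total_near_term_count == 3

    def test_transposed_variant_merges(self):
        spans = [
            _span("Mary Jones", ("Mary", "Jones"), (4, 5), rid="R0"),
            _span("Mray Jones", ("Mray", "Jones"), (4, 5), rid="R1"),
        ]
        wins = [_window(f"R{i}", 2, TermCategory.child, (3, 4, 5, 6)) for i in range(2)]
        cands = consolidate(spans, wins)
        assert len(cands) == 1
        assert cands[0].first_name == "Mary"  # higher-frequency form is canonical
        assert cands[0].total_near_term_count == 2

    def test_span_outside_every_window_dropped(self):
        spans = [_span("Mary Jones", ("Mary", "Jones"), (20, 21))]
        wins = [_window("R1", 2, TermCategory.child, (3, 4, 5, 6))]
        assert consolidate(spans, wins) == []

    def test_order_independent(self, small_corpus):
        from carenet.pipeline import PipelineConfig, run_pipeline

        corpus, _ = small_corpus
        res = run_pipeline(PipelineConfig(), corpus=corpus, write_outputs=False)
        forward = consolidate(res.new_spans, res.windows)
        backward = consolidate(list(reversed(res.new_spans)), res.windows)
        key = lambda c: (c.patient_id, c.first_name.lower(), c.last_name.lower())
        assert {key(c): (c.per_source_counts, c.per_category_counts) for c in forward} == {
            key(c): (c.per_source_counts, c.per_category_counts) for c in backward
        }


class TestExclusionSoundness:
    def test_planted_known_names_never_survive_and_new_names_do(self, small_corpus):
        """On synthetic data every planted patient/contact/recent-provider
        span is excluded, and planted new-caregiver spans that share no name
        with them survive exclusion."""
        from carenet.pipeline import PipelineConfig, run_pipeline

        corpus, truth = small_corpus
        res = run_pipeline(PipelineConfig(), corpus=corpus, write_outputs=False)
        surviving = {
            (s.record_id, s.start, s.end) for s in res.new_spans
        }
        providers = {p.provider_id: p for p in corpus.providers}
        for rid, tr in truth["records"].items():
            for name in tr["names"]:
                key_hit = any(
                    s[0] == rid and s[1] < name["end"] and name["start"] < s[2]
                    for s in surviving
                )
                if name["label"] == "contact" and name["misspell"] in (
                    "none",
                    "replacement",
                    "addition",
                    "deletion",
                    "single_transposition",
                    "double_transposition",
                ):
                    assert not key_hit, (rid, name)
                elif name["label"] == "provider":
                    pr = providers[name["person_id"]]
                    if pr.is_recent(res.corpus.analysis_date):
                        assert not key_hit, (rid, name)
                elif name["label"] == "new_caregiver":
                    assert key_hit, (rid, name)
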