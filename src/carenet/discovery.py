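"""Discovery of "new" caregiver names in caregiver text.

A name recognizer proposes person-name spans; spans matching the patient, a
known contact, or a provider seen within the last 3 years are excluded; spans
made of common English words, place names, or medication names are scrubbed;
what survives — grouped per patient, fuzzy-merged, and counted inside the
±5-token caregiver-term windows — are the "new" candidate caregiver names.

The default recognizer is a deterministic capitalization + gazetteer + context
rule backend, so the pipeline runs and is testable with no trained model; a
trained statistical recognizer can be registered under the same contract and
swapped in via configuration.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Iterable

from .caregiver_text import ContextWindow
from .corpus import KnownContact, Patient, Provider, TextRecord
from .errors import ConfigError
from .lexicon import Lexicon, load_lexicon, tokenize
from .name_match import CostTable, DEFAULT_COSTS, DEFAULT_CUTOFF, accept

#: Honorific/title tokens stripped from spans before name comparison.
TITLES = frozenset({"dr", "mr", "mrs", "ms", "miss", "prof", "rn", "md", "np", "pa"})


def _load_wordlist(name: str) -> frozenset[str]:
    ref = resources.files("carenet.data").joinpath(name)
    words = set()
    with ref.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip().lower()
            if line and not line.startswith("#"):
                words.add(line)
    return frozenset(words)


_CACHE: dict[str, frozenset[str]] = {}


def wordlist(name: str) -> frozenset[str]:
    if name not in _CACHE:
        _CACHE[name] = _load_wordlist(name)
    return _CACHE[name]


def first_name_gazetteer() -> frozenset[str]:
    return wordlist("first_names.txt")


def surname_gazetteer() -> frozenset[str]:
    return wordlist("surnames.txt")


@dataclass(frozen=True)
class StopVocab:
    """Non-name vocabulary used for recognition filtering and scrubbing."""

    common_words: frozenset[str]
    place_names: frozenset[str]
    medications: frozenset[str]

    @classmethod
    def default(cls) -> "StopVocab":
        return cls(
            common_words=wordlist("common_words.txt"),
            place_names=wordlist("place_names.txt"),
            medications=wordlist("medications.txt"),
        )

    @property
    def all_words(self) -> frozenset[str]:
        return self.common_words | self.place_names | self.medications


@dataclass(frozen=True)
class NameSpan:
    """A person-name span proposed by a recognizer backend."""

    record_id: str
    patient_id: str
    source: str
    start: int
    end: int
    surface: str
    tokens: tuple[str, ...]
    token_indices: tuple[int, ...]
    confidence: float


RecognizerFn = Callable[..., list[NameSpan]]
_BACKENDS: dict[str, RecognizerFn] = {}


def register_backend(name: str) -> Callable[[RecognizerFn], RecognizerFn]:
    """Register a recognizer backend under ``name``.

    Backends take ``(record, lexicon=..., stop_vocab=...)`` and return spans
    ordered by position; any trained recognizer honoring this contract can
    replace the default rules backend.
    """

    def deco(fn: RecognizerFn) -> RecognizerFn:
        _BACKENDS[name] = fn
        return fn

    return deco


def recognize_names(
    record: TextRecord,
    backend: str = "rules",
    lexicon: Lexicon | None = None,
    stop_vocab: StopVocab | None = None,
) -> list[NameSpan]:
    """Run the named recognizer backend on one record."""
    if backend not in _BACKENDS:
        raise ConfigError(
            f"unknown recognizer backend {backend!r}; registered: {sorted(_BACKENDS)}"
        )
    return _BACKENDS[backend](record, lexicon=lexicon, stop_vocab=stop_vocab)


_SENTENCE_BREAK = frozenset(".!?\n;")

#: Maximum tokens in one recognized span.
_MAX_SPAN_TOKENS = 4


@register_backend("rules")
def rules_backend(
    record: TextRecord,
    lexicon: Lexicon | None = None,
    stop_vocab: StopVocab | None = None,
) -> list[NameSpan]:
    """Deterministic capitalization + gazetteer recognizer.

    A token is a *strong* name candidate if it is gazetteer-listed and
    capitalized, or capitalized mid-sentence and outside all stop
    vocabularies.  Capitalized stop-vocabulary words and titles are *weak*
    candidates that may join a span but cannot form one alone.  Caregiver-term
    surfaces and medication tokens never enter spans.  Confidence is 1.0 for
    spans containing a gazetteer token, else 0.6.
    """
    lexicon = lexicon if lexicon is not None else load_lexicon()
    vocab = stop_vocab if stop_vocab is not None else StopVocab.default()
    gaz = first_name_gazetteer() | surname_gazetteer()
    term_words = lexicon.surface_words
    text = record.text
    tokens = tokenize(text)

    def sentence_initial(i: int) -> bool:
        if i == 0:
            return True
        gap = text[tokens[i - 1].end : tokens[i].start]
        return any(c in _SENTENCE_BREAK for c in gap)

    def excluded(i: int) -> bool:
        low = tokens[i].lower
        if low in gaz:
            return False
        if low in term_words or low in vocab.medications:
            return True
        t = tokens[i].text
        if not any(c.isalpha() for c in t):
            return True
        if t.isupper() and len(t) > 1:  # clinical acronyms (MRI, CHF, ...)
            return True
        return False

    def capitalized(i: int) -> bool:
        t = tokens[i].text
        return t[:1].isupper()

    def strong(i: int) -> bool:
        if excluded(i) or not capitalized(i):
            return False
        low = tokens[i].lower
        if low in gaz:
            return True
        return not sentence_initial(i) and low not in vocab.all_words and low not in TITLES

    def weak(i: int) -> bool:
        if excluded(i) or not capitalized(i):
            return False
        return not sentence_initial(i) or tokens[i].lower in TITLES

    spans: list[NameSpan] = []
    run: list[int] = []

    def flush(run: list[int]) -> None:
        if not run or not any(strong(i) for i in run):
            return
        run = run[:_MAX_SPAN_TOKENS]
        start = tokens[run[0]].start
        end = tokens[run[-1]].end
        conf = 1.0 if any(tokens[i].lower in gaz for i in run) else 0.6
        spans.append(
            NameSpan(
                record_id=record.record_id,
                patient_id=record.patient_id,
                source=record.source.value,
                start=start,
                end=end,
                surface=text[start:end],
                tokens=tuple(tokens[i].text for i in run),
                token_indices=tuple(run),
                confidence=conf,
            )
        )

    for i in range(len(tokens)):
        is_cand = strong(i) or weak(i)
        contiguous = bool(run) and run[-1] == i - 1 and not sentence_initial(i)
        if is_cand and (not run or contiguous):
            run.append(i)
        elif is_cand:
            flush(run)
            run = [i]
        else:
            flush(run)
            run = []
    flush(run)
    return spans


def _strip_titles(span: NameSpan) -> tuple[str, ...]:
    return tuple(t for t in span.tokens if t.lower() not in TITLES)


def exclude_known(
    spans: Iterable[NameSpan],
    contacts: list[KnownContact],
    patient: Patient,
    providers: list[Provider],
    analysis_date: dt.date,
    costs: CostTable = DEFAULT_COSTS,
    cutoff: int = DEFAULT_CUTOFF,
) -> list[NameSpan]:
    """Drop spans matching the patient, a contact, or a recent provider.

    Title tokens are stripped first.  A single-token span is compared against
    both first and last names; a multi-token span is excluded when its first
    token matches a first name, or its first+last tokens match a full name,
    under the fuzzy acceptance rule.  Providers whose last encounter falls
    outside the 3-year window before ``analysis_date`` never exclude.
    """
    people: list[tuple[str, str]] = [(patient.first_name, patient.last_name)]
    people += [(c.first_name, c.last_name) for c in contacts]
    people += [
        (p.first_name, p.last_name)
        for p in providers
        if p.is_recent(analysis_date)
    ]

    kept: list[NameSpan] = []
    for span in spans:
        toks = _strip_titles(span)
        if not toks:
            continue
        first, last = toks[0], toks[-1] if len(toks) > 1 else None
        drop = False
        for pf, pl in people:
            if last is None:
                if _safe_accept(first, pf, costs, cutoff) or _safe_accept(
                    first, pl, costs, cutoff
                ):
                    drop = True
                    break
            else:
                if _safe_accept(first, pf, costs, cutoff):
                    drop = True
                    break
                if _safe_accept(first, pf, costs, cutoff) and _safe_accept(
                    last, pl, costs, cutoff
                ):
                    drop = True
                    break
        if not drop:
            kept.append(span)
    return kept


def _safe_accept(a: str, b: str, costs: CostTable, cutoff: int) -> bool:
    if not a or not b:
        return False
    from .name_match import normalize_name

    if not normalize_name(a) or not normalize_name(b):
        return False
    return accept(a, b, costs, cutoff)


def scrub(spans: Iterable[NameSpan], stop_vocab: StopVocab | None = None) -> list[NameSpan]:
    """Remove spans that are only common words / place names / medications.

    A span whose every token is stop vocabulary is removed.  A mixed span is
    retained whole as long as a plausible name token remains (gazetteer-listed
    or capitalized non-stop); otherwise it is removed.
    """
    vocab = stop_vocab if stop_vocab is not None else StopVocab.default()
    gaz = first_name_gazetteer() | surname_gazetteer()
    stop = vocab.all_words
    kept: list[NameSpan] = []
    for span in spans:
        toks = _strip_titles(span) or span.tokens
        plausible = any(
            t.lower() in gaz or (t[:1].isupper() and t.lower() not in stop)
            for t in toks
        )
        if plausible:
            kept.append(span)
    return kept


@dataclass
class CandidateName:
    """A unique (patient, name) candidate with per-source/category counts."""

    patient_id: str
    first_name: str
    last_name: str  # may be empty
    is_new: bool = True
    per_source_counts: dict[str, int] = field(default_factory=dict)
    per_category_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_near_term_count(self) -> int:
        return sum(self.per_category_counts.values())

    def key(self) -> tuple[str, str, str]:
        return (self.patient_id, self.first_name.lower(), self.last_name.lower())


def _names_match(
    a: CandidateName, b: CandidateName, costs: CostTable, cutoff: int
) -> bool:
    if not _safe_accept(a.first_name, b.first_name, costs, cutoff):
        return False
    if a.last_name and b.last_name:
        return _safe_accept(a.last_name, b.last_name, costs, cutoff)
    return True  # first-name-only span merges into a full name


def consolidate(
    spans: Iterable[NameSpan],
    windows: list[ContextWindow],
    costs: CostTable = DEFAULT_COSTS,
    cutoff: int = DEFAULT_CUTOFF,
) -> list[CandidateName]:
    """Group surviving spans into unique per-patient candidate names.

    Each (span, window) overlap — the span shares a token index with a window
    on the same record — contributes one count to the window's source and term
    category.  Spans never inside any window are dropped.  Exact-key grouping
    is followed by a deterministic fuzzy merge: names are processed by
    descending total count and merged into the first canonical form they
    match under the acceptance rule.
    """
    win_by_record: dict[str, list[ContextWindow]] = {}
    for w in windows:
        win_by_record.setdefault(w.record_id, []).append(w)

    exact: dict[tuple[str, str, str], CandidateName] = {}
    for span in spans:
        toks = _strip_titles(span)
        if not toks:
            continue
        first = toks[0]
        last = toks[-1] if len(toks) > 1 else ""
        overlaps = [
            w
            for w in win_by_record.get(span.record_id, [])
            if set(span.token_indices) & set(w.window_token_indices)
        ]
        if not overlaps:
            continue
        key = (span.patient_id, first.lower(), last.lower())
        cand = exact.get(key)
        if cand is None:
            cand = CandidateName(span.patient_id, first, last)
            exact[key] = cand
        for w in overlaps:
            cand.per_source_counts[w.source] = cand.per_source_counts.get(w.source, 0) + 1
            cat = w.hit.category.value
            cand.per_category_counts[cat] = cand.per_category_counts.get(cat, 0) + 1

    # Fuzzy merge per patient, high-frequency names become canonical forms.
    by_patient: dict[str, list[CandidateName]] = {}
    for cand in exact.values():
        by_patient.setdefault(cand.patient_id, []).append(cand)

    out: list[CandidateName] = []
    for pid in sorted(by_patient):
        cands = sorted(
            by_patient[pid],
            key=lambda c: (-c.total_near_term_count, c.first_name.lower(), c.last_name.lower()),
        )
        canon: list[CandidateName] = []
        for c in cands:
            target = None
            for rep in canon:
                if _names_match(c, rep, costs, cutoff):
                    target = rep
                    break
            if target is None:
                canon.append(c)
            else:
                for k, v in c.per_source_counts.items():
                    target.per_source_counts[k] = target.per_source_counts.get(k, 0) + v
                for k, v in c.per_category_counts.items():
                    target.per_category_counts[k] = target.per_category_counts.get(k, 0) + v
                if not target.last_name and c.last_name:
                    target.last_name = c.last_name
        out.extend(canon)
    return [c for c in out if c.total_near_term_count > 0]
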