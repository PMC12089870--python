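"""Selection of caregiver text and ±5-token context windows.

"Caregiver text" is any unstructured record containing at least one caregiver
term.  Records longer than 2^15 characters are excluded outright (not
truncated), mirroring how overlong strings are dropped from analysis.  Around
every term hit, the five word-tokens before and after form the context window
within which contact names are matched; the window never includes the term
token(s) and is simply shorter at record boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass

from .corpus import TextRecord
from .errors import ConsistencyError
from .lexicon import Lexicon, TermHit, find_terms, tokenize

#: Character cap on a single text string: 2**15.
DEFAULT_CAP = 32768

#: Context half-width in word tokens.
WINDOW_RADIUS = 5


@dataclass(frozen=True)
class ContextWindow:
    """The up-to-±5-token context around one caregiver-term hit."""

    record_id: str
    patient_id: str
    source: str
    hit: TermHit
    window_tokens: tuple[str, ...]
    window_token_indices: tuple[int, ...]


def filter_overlong(
    records: list[TextRecord], cap: int = DEFAULT_CAP
) -> tuple[list[TextRecord], list[TextRecord]]:
    """Split records into (kept, excluded) by character length.

    A record is excluded iff it is strictly over the cap; a record of exactly
    ``cap`` characters is kept.  Order is preserved on both sides.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    kept = [r for r in records if len(r.text) <= cap]
    excluded = [r for r in records if len(r.text) > cap]
    return kept, excluded


def extract_caregiver_text(
    records: list[TextRecord], lexicon: Lexicon
) -> dict[str, list[TermHit]]:
    """Map record_id → term hits, for records with at least one hit."""
    out: dict[str, list[TermHit]] = {}
    for r in records:
        hits = find_terms(tokenize(r.text), lexicon, record_id=r.record_id)
        if hits:
            out[r.record_id] = hits
    return out


def source_hit_rates(
    records: list[TextRecord], hitmap: dict[str, list[TermHit]]
) -> dict[str, float]:
    """Fraction of records per source containing ≥1 caregiver term."""
    totals: dict[str, int] = {}
    with_hits: dict[str, int] = {}
    for r in records:
        s = r.source.value
        totals[s] = totals.get(s, 0) + 1
        if r.record_id in hitmap:
            with_hits[s] = with_hits.get(s, 0) + 1
    return {s: with_hits.get(s, 0) / n for s, n in totals.items()}


def windows(record: TextRecord, hits: list[TermHit]) -> list[ContextWindow]:
    """One context window per hit; shorter (never padded) at boundaries."""
    tokens = tokenize(record.text)
    out: list[ContextWindow] = []
    for hit in hits:
        if hit.token_index < 0 or hit.token_index + hit.n_tokens > len(tokens):
            raise ConsistencyError(
                f"hit at token {hit.token_index} outside record {record.record_id}"
            )
        lo = max(0, hit.token_index - WINDOW_RADIUS)
        before = range(lo, hit.token_index)
        hi = min(len(tokens), hit.token_index + hit.n_tokens + WINDOW_RADIUS)
        after = range(hit.token_index + hit.n_tokens, hi)
        idx = tuple(list(before) + list(after))
        out.append(
            ContextWindow(
                record_id=record.record_id,
                patient_id=record.patient_id,
                source=record.source.value,
                hit=hit,
                window_tokens=tuple(tokens[i].text for i in idx),
                window_token_indices=idx,
            )
        )
    return out


def all_windows(
    records: list[TextRecord], hitmap: dict[str, list[TermHit]]
) -> list[ContextWindow]:
    """Windows for every hit of every caregiver-text record, in record order."""
    out: list[ContextWindow] = []
    for r in records:
        hits = hitmap.get(r.record_id)
        if hits:
            out.extend(windows(r, hits))
    return out
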