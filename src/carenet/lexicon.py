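"""Caregiver-term lexicon and term matching inside tokenized clinical text.

The lexicon assigns each informal-care relationship word ("daughter", "dtr",
"carer", ...) to one of four relationship categories: parent, child, spouse,
other.  Formal paid-care vocabulary (nurse, aide, ...) is deliberately absent,
and so are the ambiguous kinship acronyms "dil"/"bil"/"sil", which collide
with common medical-procedure abbreviations.  Term matching is exact and
case-insensitive; abbreviations are never fuzzy-matched.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable

from .errors import RecordValidationError


class TermCategory(str, Enum):
    parent = "parent"
    child = "child"
    spouse = "spouse"
    other = "other"


#: Kinship acronyms removed from the default lexicon: they collide with
#: medical abbreviations (e.g. "dil" = dilation) and are never loaded.
BANNED_ABBREVIATIONS = frozenset({"dil", "bil", "sil"})

#: Formal paid-caregiver vocabulary, excluded from the default lexicon.
FORMAL_PAID_TERMS = frozenset({"nurse", "aide", "cna", "home health"})


@dataclass(frozen=True)
class CaregiverTerm:
    """One lexicon entry.

    ``surface`` is lower-case and may contain a single internal space for
    two-word phrases ("in law", "son in law").
    """

    surface: str
    category: TermCategory
    is_abbreviation: bool = False

    def __post_init__(self) -> None:
        if not self.surface:
            raise ValueError("term surface must be nonempty")


@dataclass(frozen=True)
class Token:
    """A word token with 0-based half-open character offsets."""

    text: str
    start: int
    end: int

    @property
    def lower(self) -> str:
        return self.text.lower()


@dataclass(frozen=True)
class TermHit:
    """A caregiver-term occurrence at a token position.

    ``n_tokens`` is 2 for two-word surfaces matched across adjacent tokens,
    else 1 (including matches found inside a hyphenated token).
    """

    record_id: str
    token_index: int
    surface: str
    category: TermCategory
    n_tokens: int = 1


_TOKEN_RE = re.compile(r"[A-Za-z0-9'’-]+")


def tokenize(text: str) -> list[Token]:
    """Split ``text`` into word tokens.

    Tokens are maximal runs of letters, digits, apostrophes, and hyphens;
    everything else separates.  Offsets index the original string.
    """
    return [Token(m.group(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]


class Lexicon:
    """An immutable surface → term lookup with one- and two-word surfaces."""

    def __init__(self, terms: Iterable[CaregiverTerm]):
        self._by_surface: dict[str, CaregiverTerm] = {}
        for t in terms:
            prev = self._by_surface.get(t.surface)
            if prev is not None and prev.category != t.category:
                raise RecordValidationError(
                    f"surface {t.surface!r} appears with conflicting categories "
                    f"{prev.category.value!r} and {t.category.value!r}"
                )
            self._by_surface[t.surface] = t
        self._single = {s: t for s, t in self._by_surface.items() if " " not in s}
        self._phrases: dict[int, dict[str, CaregiverTerm]] = {}
        for s, t in self._by_surface.items():
            n = s.count(" ") + 1
            if n > 1:
                self._phrases.setdefault(n, {})[s] = t

    def __contains__(self, surface: str) -> bool:
        return surface.lower() in self._by_surface

    def __len__(self) -> int:
        return len(self._by_surface)

    def get(self, surface: str) -> CaregiverTerm | None:
        return self._by_surface.get(surface.lower())

    @property
    def terms(self) -> list[CaregiverTerm]:
        return list(self._by_surface.values())

    @property
    def surfaces(self) -> frozenset[str]:
        return frozenset(self._by_surface)

    @property
    def surface_words(self) -> frozenset[str]:
        """Every single word occurring in any surface (incl. phrase parts)."""
        words: set[str] = set()
        for s in self._by_surface:
            words.update(s.split())
        return frozenset(words)


def load_lexicon(path: str | Path | None = None) -> Lexicon:
    """Load a lexicon from ``lexicon.csv`` (surface,category,is_abbreviation).

    With no path, the bundled default lexicon is returned.  Duplicate surfaces
    with conflicting categories raise :class:`RecordValidationError`.
    """
    if path is None:
        ref = resources.files("carenet.data").joinpath("lexicon.csv")
        with ref.open("r", encoding="utf-8") as fh:
            return _parse_lexicon(fh)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        return _parse_lexicon(fh)


def _parse_lexicon(fh) -> Lexicon:
    reader = csv.DictReader(fh)
    required = {"surface", "category", "is_abbreviation"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise RecordValidationError(
            f"lexicon file must have columns {sorted(required)}"
        )
    terms = []
    for row in reader:
        terms.append(
            CaregiverTerm(
                surface=row["surface"].strip().lower(),
                category=TermCategory(row["category"].strip().lower()),
                is_abbreviation=row["is_abbreviation"].strip().lower()
                in ("1", "true", "yes"),
            )
        )
    return Lexicon(terms)


def find_terms(tokens: list[Token], lexicon: Lexicon, record_id: str = "") -> list[TermHit]:
    """Locate caregiver terms among ``tokens``.

    Matching is case-insensitive and exact per token.  Multi-word surfaces
    match runs of adjacent tokens.  Hyphenated tokens are additionally matched
    after splitting on hyphens, so "mother-in-law" yields hits for both
    "mother" and "in law".  Overlapping shorter and longer hits are all
    reported, in token order.
    """
    single = lexicon._single
    phrases = lexicon._phrases
    hits: list[TermHit] = []
    for i, tok in enumerate(tokens):
        low = tok.lower
        if low in single:
            hits.append(TermHit(record_id, i, low, single[low].category))
        for n, table in phrases.items():
            if i + n <= len(tokens):
                gram = " ".join(tokens[i + k].lower for k in range(n))
                if gram in table:
                    hits.append(TermHit(record_id, i, gram, table[gram].category, n_tokens=n))
        if "-" in low:
            parts = [p for p in low.split("-") if p]
            for j, part in enumerate(parts):
                if part in single and part != low:
                    hits.append(TermHit(record_id, i, part, single[part].category))
                for n, table in phrases.items():
                    if j + n <= len(parts):
                        gram = " ".join(parts[j + k] for k in range(n))
                        if gram in table:
                            hits.append(TermHit(record_id, i, gram, table[gram].category))
    return hits
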