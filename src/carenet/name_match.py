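"""Operation-cost spelling distance and windowed matching of contact names.

Clinical free text misspells names; exact matching misses them.  The distance
here is an asymmetric generalized edit distance over a configurable cost
table, in the tradition of spelling-oriented distances: operations at the end
of a word (appending or truncating letters) are cheaper than the same
operation mid-word, and swapping two adjacent letters is cheaper than a
replacement.  The default costs and cutoff are calibrated so that the
acceptance class is exactly: one letter replacement, one letter addition (or
deletion), or up to two disjoint adjacent transpositions.  Anything heavier —
a replacement plus a swap, two substitutions — is rejected.

Distances are computed on lower-cased strings with non-alphabetic characters
stripped, left-to-right over edit scripts (each original letter is consumed
once; a swapped pair is consumed together).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

_INF = float("inf")


@dataclass(frozen=True)
class CostTable:
    """Per-operation costs for the spelling distance.

    All costs are non-negative integers; ``match`` must be 0.  ``append`` and
    ``truncate`` apply only at the end of the word being transformed (once
    every original letter has been consumed, respectively once the target is
    fully produced).
    """

    match: int = 0
    adjacent_transposition: int = 50
    append_at_end: int = 35
    truncate_at_end: int = 50
    delete: int = 100
    insert: int = 100
    replace: int = 100

    def __post_init__(self) -> None:
        if self.match != 0:
            raise ValueError("match cost must be 0")
        for name in (
            "adjacent_transposition",
            "append_at_end",
            "truncate_at_end",
            "delete",
            "insert",
            "replace",
        ):
            v = getattr(self, name)
            if not isinstance(v, int) or v <= 0:
                raise ValueError(f"cost {name} must be a positive integer, got {v!r}")


DEFAULT_COSTS = CostTable()

#: Default acceptance cutoff: one replacement (100), one insertion/deletion
#: (100) or two adjacent transpositions (2x50) pass; combinations do not.
DEFAULT_CUTOFF = 100


def normalize_name(s: str) -> str:
    """Lower-case and strip non-alphabetic characters for comparison."""
    return "".join(c for c in s.lower() if c.isalpha())


def spelling_distance(word: str, name: str, costs: CostTable = DEFAULT_COSTS) -> int:
    """Minimal total cost of transforming ``word`` into ``name``.

    Computed by dynamic programming over left-to-right edit scripts with an
    adjacent-transposition operation.  Symmetric only if the cost table is;
    identical strings score 0.  Raises ``ValueError`` on an empty argument.
    """
    if not word or not name:
        raise ValueError("spelling_distance requires nonempty strings")
    w = normalize_name(word)
    t = normalize_name(name)
    n, m = len(w), len(t)
    # D[i][j] = min cost transforming w[:i] -> t[:j]
    D = [[_INF] * (m + 1) for _ in range(n + 1)]
    D[0][0] = 0
    for i in range(n + 1):
        row = D[i]
        for j in range(m + 1):
            cur = row[j]
            if cur is _INF:
                continue
            if i < n and j < m:
                step = costs.match if w[i] == t[j] else costs.replace
                if cur + step < D[i + 1][j + 1]:
                    D[i + 1][j + 1] = cur + step
            if j < m:  # insert t[j]; at end of word it is an append
                step = costs.append_at_end if i == n else costs.insert
                if cur + step < row[j + 1]:
                    row[j + 1] = cur + step
            if i < n:  # delete w[i]; past end of target it is a truncation
                step = costs.truncate_at_end if j == m else costs.delete
                if cur + step < D[i + 1][j]:
                    D[i + 1][j] = cur + step
            if (
                i + 1 < n
                and j + 1 < m
                and w[i] == t[j + 1]
                and w[i + 1] == t[j]
                and w[i] != w[i + 1]
            ):
                step = costs.adjacent_transposition
                if cur + step < D[i + 2][j + 2]:
                    D[i + 2][j + 2] = cur + step
    return int(D[n][m])


def accept(
    word: str,
    name: str,
    costs: CostTable = DEFAULT_COSTS,
    cutoff: int = DEFAULT_CUTOFF,
) -> bool:
    """True iff the spelling distance from ``word`` to ``name`` is ≤ cutoff."""
    return spelling_distance(word, name, costs) <= cutoff


class MatchKind:
    first_name = "first_name"
    full_name = "full_name"


@dataclass(frozen=True)
class MatchResult:
    """One accepted match between a window token (pair) and a contact name."""

    contact_id: str
    record_id: str
    source: str
    match_kind: str
    distance_cost: int
    matched_tokens: tuple[int, ...]
    term_category: str
    term_surface: str


#: Max absolute token-index gap for a first+last pair to count as a full name
#: (adjacent in either order, or separated by at most one token).
_FULL_NAME_MAX_GAP = 2


def match_window(
    window,
    contacts,
    costs: CostTable = DEFAULT_COSTS,
    cutoff: int = DEFAULT_CUTOFF,
    term_surfaces: frozenset[str] = frozenset(),
) -> list[MatchResult]:
    """Match known-contact names against one caregiver-term context window.

    Every window token is compared against every contact's first and last
    name.  Per token, only the lowest-cost accepted contact name is kept
    (ties: lower contact_id, then input order).  A ``first_name`` result is
    reported whenever a token is assigned to some contact's first name; a
    ``full_name`` result is additionally reported when a token assigned to
    the same contact's last name sits within one intervening token.  Tokens
    that are themselves caregiver-term surfaces are never matched as names.
    """
    # token index -> (cost, tie-rank, contact, part)
    assign: dict[int, tuple[int, tuple, object, str]] = {}
    for rank, contact in enumerate(contacts):
        names = (("first", contact.first_name), ("last", contact.last_name))
        for abs_idx, tok in zip(window.window_token_indices, window.window_tokens):
            low = tok.lower()
            if low in term_surfaces:
                continue
            if not normalize_name(tok):
                continue
            for part, cname in names:
                if not cname or not normalize_name(cname):
                    continue
                d = spelling_distance(tok, cname, costs)
                if d > cutoff:
                    continue
                key = (d, (str(contact.contact_id), rank))
                prev = assign.get(abs_idx)
                if prev is None or key < (prev[0], prev[1]):
                    assign[abs_idx] = (d, key[1], contact, part)

    results: list[MatchResult] = []
    firsts = {
        idx: (cost, c)
        for idx, (cost, _, c, part) in assign.items()
        if part == "first"
    }
    tok_by_idx = dict(zip(window.window_token_indices, window.window_tokens))
    for idx in sorted(firsts):
        cost, contact = firsts[idx]
        results.append(
            MatchResult(
                contact_id=contact.contact_id,
                record_id=window.record_id,
                source=window.source,
                match_kind=MatchKind.first_name,
                distance_cost=cost,
                matched_tokens=(idx,),
                term_category=window.hit.category.value,
                term_surface=window.hit.surface,
            )
        )
        # Full name: a token within one intervening position matches this
        # contact's last name at least as well as its best assigned match
        # (so a cost tie with a same-surname relative does not block it).
        if not contact.last_name or not normalize_name(contact.last_name):
            continue
        for lidx in sorted(tok_by_idx):
            if lidx == idx or abs(lidx - idx) > _FULL_NAME_MAX_GAP:
                continue
            tok = tok_by_idx[lidx]
            if tok.lower() in term_surfaces or not normalize_name(tok):
                continue
            d = spelling_distance(tok, contact.last_name, costs)
            if d > cutoff:
                continue
            if lidx in assign and d > assign[lidx][0]:
                continue
            results.append(
                MatchResult(
                    contact_id=contact.contact_id,
                    record_id=window.record_id,
                    source=window.source,
                    match_kind=MatchKind.full_name,
                    distance_cost=cost + d,
                    matched_tokens=tuple(sorted((idx, lidx))),
                    term_category=window.hit.category.value,
                    term_surface=window.hit.surface,
                )
            )
            break
    return results


def raise_cost(costs: CostTable, **kwargs: int) -> CostTable:
    """Return a copy of ``costs`` with the named operation costs replaced."""
    return replace(costs, **kwargs)
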