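"""Spelling distance, the acceptance rule, and windowed contact matching."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from carenet.caregiver_text import ContextWindow
from carenet.corpus import KnownContact, Relationship
from carenet.lexicon import TermCategory, TermHit
from carenet.name_match import (
    CostTable,
    DEFAULT_COSTS,
    MatchKind,
    accept,
    match_window,
    raise_cost,
    spelling_distance,
)
from oracles import oracle_distance


class TestSpellingDistance:
    # Expected values frozen from the exhaustive edit-script oracle.
    @pytest.mark.parametrize(
        "word,name,expected",
        [
            ("john", "john", 0),
            ("jhon", "john", 50),  # one adjacent transposition
            ("johm", "john", 100),  # one replacement
            ("jhonsmtih", "johnsmith", 100),  # two disjoint transpositions
            ("jahn", "jhon", 200),  # two replacements; no cheaper script
            ("jon", "john", 100),  # one mid-word insertion
            ("margret", "margaret", 100),  # one letter addition
            ("john", "johns", 35),  # append at end
            ("johns", "john", 50),  # truncate at end
        ],
    )
    def test_frozen_oracle_values(self, word, name, expected):
        assert oracle_distance(word, name, DEFAULT_COSTS) == expected
        assert spelling_distance(word, name) == expected

    def test_case_insensitive(self):
        assert spelling_distance("JHON", "john") == 50

    def test_empty_argument_rejected(self):
        with pytest.raises(ValueError):
            spelling_distance("", "john")
        with pytest.raises(ValueError):
            spelling_distance("john", "")

    def test_asymmetric_costs_make_it_asymmetric(self):
        # append (35) vs truncate (50)
        assert spelling_distance("ann", "anna") == 35
        assert spelling_distance("anna", "ann") == 50

    @given(
        st.text(alphabet="abc", min_size=1, max_size=4),
        st.text(alphabet="abc", min_size=1, max_size=4),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_oracle_on_random_pairs(self, w, t):
        assert spelling_distance(w, t) == oracle_distance(w, t, DEFAULT_COSTS)

    @given(
        st.text(alphabet="abcd", min_size=1, max_size=5),
        st.text(alphabet="abcd", min_size=1, max_size=5),
        st.sampled_from(
            ["adjacent_transposition", "append_at_end", "truncate_at_end",
             "delete", "insert", "replace"]
        ),
    )
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_raising_a_cost_never_decreases_distance(self, w, t, op):
        base = spelling_distance(w, t)
        bumped = raise_cost(DEFAULT_COSTS, **{op: getattr(DEFAULT_COSTS, op) + 30})
        assert spelling_distance(w, t, bumped) >= base

    def test_identity_and_positivity(self):
        for s in ("a", "anna", "margaret"):
            assert spelling_distance(s, s) == 0
        assert spelling_distance("anna", "anne") > 0

    def test_invalid_cost_table(self):
        with pytest.raises(ValueError):
            CostTable(match=1)
        with pytest.raises(ValueError):
            CostTable(replace=0)


class TestAccept:
    @pytest.mark.parametrize(
        "word,name,expected",
        [
            ("margret", "margaret", True),  # one letter addition
            ("jhon", "john", True),  # one transposition
            ("johm", "john", True),  # one replacement
            ("jhonsmtih", "johnsmith", True),  # two disjoint transpositions
            ("jahn", "jhon", False),  # heavier than any accepted class
            ("x", "x", True),
            ("anne", "ann", True),  # single deletion, lenient by default
        ],
    )
    def test_acceptance_rule(self, word, name, expected):
        assert accept(word, name) is expected

    def test_cutoff_is_configurable(self):
        assert not accept("jahn", "jhon", cutoff=100)
        assert accept("jahn", "jhon", cutoff=200)


def _window(tokens, term_index=0, category=TermCategory.child, surface="son"):
    """Build a window whose term sits just before the given tokens."""
    idx = tuple(range(term_index + 1, term_index + 1 + len(tokens)))
    return ContextWindow(
        record_id="R1",
        patient_id="P1",
        source="encounter",
        hit=TermHit("R1", term_index, surface, category),
        window_tokens=tuple(tokens),
        window_token_indices=idx,
    )


def _contact(cid, first, last, pid="P1"):
    return KnownContact(
        contact_id=cid,
        patient_id=pid,
        first_name=first,
        last_name=last,
        contact_types=frozenset(),
        relationship=Relationship.child,
    )


class TestMatchWindow:
    def test_full_name_with_misspelled_first(self):
        w = _window(["per", "Jhon", "Smith", "will", "drive"])
        results = match_window(w, [_contact("C1", "John", "Smith")])
        full = [r for r in results if r.match_kind == MatchKind.full_name]
        assert len(full) == 1
        assert full[0].distance_cost == 50  # Jhon->John 50, Smith->Smith 0
        first = [r for r in results if r.match_kind == MatchKind.first_name]
        assert len(first) == 1 and first[0].distance_cost == 50

    def test_lowest_cost_contact_wins_per_token(self):
        w = _window(["Jhon", "arrived"])
        c1 = _contact("C1", "John", "Smith")
        c2 = _contact("C2", "Jon", "Smyth")
        d1 = spelling_distance("jhon", "john")
        d2 = spelling_distance("jhon", "jon")
        results = match_window(w, [c1, c2])
        winner = "C1" if d1 < d2 else ("C2" if d2 < d1 else "C1")
        assert {r.contact_id for r in results} == {winner}

    def test_cost_tie_broken_by_contact_id(self):
        w = _window(["John", "arrived"])
        results = match_window(
            w, [_contact("C2", "John", "Smith"), _contact("C1", "John", "Doe")]
        )
        firsts = [r for r in results if r.match_kind == MatchKind.first_name]
        assert [r.contact_id for r in firsts] == ["C1"]

    def test_no_accepted_distance_gives_no_match(self):
        w = _window(["the", "van", "arrives", "at", "nine"])
        assert match_window(w, [_contact("C1", "Margaret", "Wilson")]) == []

    def test_term_surface_token_never_matches_as_name(self, lexicon):
        # Contact first name "Son" would otherwise match the term token.
        w = _window(["son", "visited"])
        results = match_window(
            w, [_contact("C1", "Son", "Ly")], term_surfaces=lexicon.surfaces
        )
        assert results == []

    def test_full_name_requires_proximity(self):
        # Last name three tokens away from the first name: first-only match.
        w = _window(["Mary", "will", "call", "about", "Jones"])
        results = match_window(w, [_contact("C1", "Mary", "Jones")])
        kinds = {r.match_kind for r in results}
        assert kinds == {MatchKind.first_name}

    def test_full_name_allows_one_intervening_token(self):
        w = _window(["Mary", "R", "Jones", "will", "call"])
        results = match_window(w, [_contact("C1", "Mary", "Jones")])
        assert MatchKind.full_name in {r.match_kind for r in results}


class TestAcceptanceClasses:
    """The verbal acceptance contract on generated realistic names."""

    @staticmethod
    def variants(name, rng):
        letters = "abcdefghijklmnopqrstuvwxyz"
        n = len(name)
        i = rng.randrange(n)
        c = letters[rng.randrange(26)]
        while c == name[i]:
            c = letters[rng.randrange(26)]
        replacement = name[:i] + c + name[i + 1 :]
        j = rng.randrange(n + 1)
        addition = name[:j] + letters[rng.randrange(26)] + name[j:]
        swaps = [k for k in range(n - 1) if name[k] != name[k + 1]]
        pairs = [(a, b) for a in swaps for b in swaps if b >= a + 2]
        double_swap = None
        if pairs:
            a, b = pairs[rng.randrange(len(pairs))]
            s = list(name)
            s[a], s[a + 1] = s[a + 1], s[a]
            s[b], s[b + 1] = s[b + 1], s[b]
            double_swap = "".join(s)
        # Two substitutions at non-adjacent positions, using letters absent
        # from the name so neither can be repaired by a cheap transposition.
        two_sub = None
        spots = [(a, b) for a in range(n) for b in range(a + 2, n)]
        fresh = [c for c in letters if c not in name]
        if spots and fresh:
            a, b = spots[rng.randrange(len(spots))]
            s = list(name)
            s[a] = fresh[rng.randrange(len(fresh))]
            s[b] = fresh[rng.randrange(len(fresh))]
            two_sub = "".join(s)
        return replacement, addition, double_swap, two_sub

    def test_classes_on_generated_names(self):
        import random

        rng = random.Random(1234)
        letters = "abcdefghijklmnopqrstuvwxyz"
        for _ in range(250):
            name = "".join(
                letters[rng.randrange(26)] for _ in range(rng.randrange(4, 13))
            )
            replacement, addition, double_swap, two_sub = self.variants(name, rng)
            assert accept(replacement, name)
            assert accept(addition, name)
            if double_swap is not None and double_swap != name:
                assert accept(double_swap, name)
            if two_sub is not None:
                assert not accept(two_sub, name)
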