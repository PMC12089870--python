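"""Seeded synthetic EHR corpus generator with planted ground truth.

Emulates the documented characteristics of a dementia-cohort EHR extract:
contacts-per-patient distribution, relationship mix, shared-surname rate,
per-source caregiver-term prevalence, misspellings of the accepted fuzzy-match
classes, decoy tokens (provider names, place names, medication lookalikes),
and "new" caregiver names absent from the structured contact fields.  Note
text is template-based so every planted term and name sits at an exact,
recorded token offset; clinical realism is deliberately sacrificed for
offset-exact ground truth.

Determinism: one numpy Generator seeded from the config drives every draw,
so the same config and seed reproduce the corpus byte for byte.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .caregiver_text import WINDOW_RADIUS
from .corpus import (
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
    write_contacts,
    write_text_records,
)
from .discovery import first_name_gazetteer, surname_gazetteer
from .errors import ConfigError, ConsistencyError
from .lexicon import Lexicon, load_lexicon
from .name_match import CostTable, DEFAULT_COSTS, DEFAULT_CUTOFF, accept

ANALYSIS_DATE = dt.date(2024, 6, 30)

MISSPELL_CLASSES = (
    "replacement",
    "addition",
    "deletion",
    "single_transposition",
    "double_transposition",
    "heavy",
)


class GeneratorConfig(BaseModel):
    """Study conditions emulated by the generator (all rates per source)."""

    n_patients: int = 100
    seed: int = 0
    contacts_mean: float = 2.1
    contacts_sd: float = 1.1
    relationship_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "child": 0.45,
            "parent": 0.092,
            "spouse": 0.156,
            "other": 0.171,
            "unknown": 0.131,
        }
    )
    same_surname_prob: float = 0.471
    records_per_patient: dict[str, int] = Field(
        default_factory=lambda: {
            "encounter": 8,
            "appointment": 3,
            "hospital": 1,
            "problem_list": 2,
            "permanent_comment": 1,
            "portal_message": 3,
        }
    )
    term_plant_prob: dict[str, float] = Field(
        default_factory=lambda: {
            "encounter": 0.26,
            "appointment": 0.20,
            "hospital": 0.22,
            "problem_list": 0.14,
            "permanent_comment": 0.99,
            "portal_message": 0.34,
        }
    )
    misspelling_rates: dict[str, float] = Field(
        default_factory=lambda: {
            "replacement": 0.05,
            "addition": 0.03,
            "deletion": 0.02,
            "single_transposition": 0.03,
            "double_transposition": 0.01,
            "heavy": 0.01,
        }
    )
    n_new_caregivers: int = 2
    new_name_occurrences: dict[int, float] = Field(
        default_factory=lambda: {1: 0.3, 2: 0.4, 3: 0.2, 4: 0.1}
    )
    n_providers_per_patient: int = 3
    provider_decoy_prob: float = 0.15
    place_decoy_prob: float = 0.10
    medication_decoy_prob: float = 0.20
    name_plant_prob: float = 0.75
    far_plant_prob: float = 0.10
    full_name_prob: float = 0.8

    @model_validator(mode="after")
    def _check(self) -> "GeneratorConfig":
        probs = (
            [self.same_surname_prob, self.provider_decoy_prob, self.place_decoy_prob,
             self.medication_decoy_prob, self.name_plant_prob, self.far_plant_prob,
             self.full_name_prob]
            + list(self.term_plant_prob.values())
            + list(self.misspelling_rates.values())
        )
        for p in probs:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"probability {p} outside [0, 1]")
        if abs(sum(self.relationship_mix.values()) - 1.0) > 1e-9:
            raise ConfigError("relationship_mix must sum to 1")
        if abs(sum(self.new_name_occurrences.values()) - 1.0) > 1e-9:
            raise ConfigError("new_name_occurrences must sum to 1")
        if sum(self.misspelling_rates.values()) > 1.0:
            raise ConfigError("misspelling rates sum above 1")
        return self

    def zero_noise(self) -> "GeneratorConfig":
        """Copy with no misspellings and no decoys (negative-control setting)."""
        return self.model_copy(
            update={
                "misspelling_rates": {k: 0.0 for k in self.misspelling_rates},
                "provider_decoy_prob": 0.0,
                "place_decoy_prob": 0.0,
                "medication_decoy_prob": 0.0,
            }
        )


# Lower-case filler vocabulary; must contain no lexicon surface, gazetteer
# name, or stop-list collision that would perturb planted offsets.
_FILLER = (
    "seen today for routine follow up visit and medication review "
    "reports doing well at home with some confusion in the evening "
    "plan to continue current regimen and recheck in three months "
    "ambulating with a cane appetite fair sleep improved discussed goals "
    "of care and safety at home during the day needs reminders for"
).split()

_PLACES = ("denver", "aurora", "boulder", "littleton", "lakewood", "pueblo")
_MEDS = ("lasix", "aricept", "namenda", "seroquel", "trazodone", "donepezil")

#: Every word a template can place inside or near a term window.  Planted
#: names are sampled to be outside the fuzzy-acceptance cutoff of all of
#: these, so a filler word can never pass for a caregiver name (e.g. "plan"
#: is one replacement from "Alan").
_TEMPLATE_VOCAB = frozenset(_FILLER) | frozenset(
    "his her is involved in care stopped by to assist seen dr relocated "
    "from continue nightly called the office".split()
)


@dataclass
class _PlannedMention:
    kind: str  # "contact" | "new"
    person_idx: int


class _RecordBuilder:
    """Accumulates word tokens and renders text with exact char offsets."""

    def __init__(self) -> None:
        self.words: list[str] = []
        self.suffixes: list[str] = []

    def add(self, word: str, suffix: str = "") -> int:
        self.words.append(word)
        self.suffixes.append(suffix)
        return len(self.words) - 1

    def add_all(self, words, end_sentence: bool = False) -> int:
        start = len(self.words)
        for w in words:
            self.add(w)
        if end_sentence and self.suffixes:
            self.suffixes[-1] = "."
        return start

    def n_tokens(self) -> int:
        return len(self.words)

    def render(self) -> tuple[str, list[tuple[int, int]]]:
        parts: list[str] = []
        offsets: list[tuple[int, int]] = []
        pos = 0
        for i, (w, s) in enumerate(zip(self.words, self.suffixes)):
            if i > 0:
                pos += 1  # separating space
            offsets.append((pos, pos + len(w)))
            parts.append(w + s)
            pos += len(w) + len(s)
        return " ".join(parts), offsets


def _misspell(rng: np.random.Generator, name: str, cls: str) -> str:
    """Apply one misspelling class; preserves the leading capital."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    low = name.lower()
    n = len(low)

    def recap(s: str) -> str:
        return s[:1].upper() + s[1:] if name[:1].isupper() else s

    if cls == "replacement" and n >= 2:
        i = int(rng.integers(0, n))
        c = letters[int(rng.integers(0, 26))]
        while c == low[i]:
            c = letters[int(rng.integers(0, 26))]
        return recap(low[:i] + c + low[i + 1 :])
    if cls == "addition":
        i = int(rng.integers(0, n + 1))
        c = letters[int(rng.integers(0, 26))]
        return recap(low[:i] + c + low[i:])
    if cls == "deletion" and n >= 3:
        i = int(rng.integers(0, n))
        return recap(low[:i] + low[i + 1 :])
    if cls == "single_transposition" and n >= 2:
        idx = [i for i in range(n - 1) if low[i] != low[i + 1]]
        if idx:
            i = idx[int(rng.integers(0, len(idx)))]
            return recap(low[:i] + low[i + 1] + low[i] + low[i + 2 :])
    if cls == "double_transposition" and n >= 4:
        idx = [i for i in range(n - 1) if low[i] != low[i + 1]]
        pairs = [(i, j) for i in idx for j in idx if j >= i + 2]
        if pairs:
            i, j = pairs[int(rng.integers(0, len(pairs)))]
            s = list(low)
            s[i], s[i + 1] = s[i + 1], s[i]
            s[j], s[j + 1] = s[j + 1], s[j]
            return recap("".join(s))
    if cls == "heavy" and n >= 4:
        positions = [0, 2] if n >= 3 else [0, 1]
        s = list(low)
        for i in positions:
            c = letters[int(rng.integers(0, 26))]
            while c == s[i]:
                c = letters[int(rng.integers(0, 26))]
            s[i] = c
        return recap("".join(s))
    return name  # class not applicable at this length


def _pick_distinct_first(
    rng: np.random.Generator,
    pool: list[str],
    taken: list[str],
    costs: CostTable,
    cutoff: int,
) -> str:
    """Sample a first name not fuzzy-matching any already-taken family name.

    Keeps distinct people distinguishable to the matcher: without this, two
    relatives named e.g. Jon and John would be one name to any fuzzy rule, a
    confusion the framework explicitly does not attempt to resolve.
    """
    for _ in range(200):
        cand = pool[int(rng.integers(0, len(pool)))]
        if any(
            accept(cand, t, costs, cutoff) or accept(t, cand, costs, cutoff)
            for t in taken
        ):
            continue
        return cand
    raise ConsistencyError("could not sample a distinct first name")


@lru_cache(maxsize=4)
def _vocab_safe_pool(pool: tuple[str, ...], cutoff: int) -> tuple[str, ...]:
    """Pool names outside the acceptance cutoff of every template word."""
    return tuple(
        n
        for n in pool
        if not any(accept(w, n, DEFAULT_COSTS, cutoff) for w in _TEMPLATE_VOCAB)
    )


_CATEGORY_FOR_REL = {
    "child": "child",
    "parent": "parent",
    "spouse": "spouse",
    "other": "other",
    "unknown": "other",
}


def generate(
    config: GeneratorConfig,
    out_dir: str | Path | None = None,
    lexicon: Lexicon | None = None,
) -> tuple[Corpus, dict]:
    """Generate a corpus and its ground truth; optionally write both to disk.

    Writes ``patients.csv``, ``contacts.csv``, ``providers.csv``,
    ``notes.jsonl`` and ``truth.json`` when ``out_dir`` is given.
    """
    rng = np.random.default_rng(config.seed)
    lex = lexicon if lexicon is not None else load_lexicon()
    costs, cutoff = DEFAULT_COSTS, DEFAULT_CUTOFF

    first_pool = list(_vocab_safe_pool(tuple(sorted(first_name_gazetteer())), cutoff))
    last_pool = sorted(surname_gazetteer())
    terms_by_cat: dict[str, list[str]] = {}
    for t in lex.terms:
        terms_by_cat.setdefault(t.category.value, []).append(t.surface)
    for v in terms_by_cat.values():
        v.sort()

    rel_names = list(config.relationship_mix)
    rel_probs = np.array([config.relationship_mix[r] for r in rel_names])
    occ_vals = sorted(config.new_name_occurrences)
    occ_probs = np.array([config.new_name_occurrences[k] for k in occ_vals])
    race_names = ["white", "hispanic", "other", "unknown", "black", "asian", "aian_nhpi"]
    race_probs = np.array([0.795, 0.112, 0.076, 0.057, 0.037, 0.02, 0.016])
    race_probs = race_probs / race_probs.sum()
    ms_classes = list(config.misspelling_rates)
    ms_probs = np.array([config.misspelling_rates[c] for c in ms_classes])
    p_none = 1.0 - ms_probs.sum()

    patients: list[Patient] = []
    contacts: list[KnownContact] = []
    providers: list[Provider] = []
    records: list[TextRecord] = []
    truth_patients: dict[str, dict] = {}
    truth_records: dict[str, dict] = {}

    def cap(s: str) -> str:
        return s[:1].upper() + s[1:]

    for pi in range(config.n_patients):
        pid = f"P{pi:04d}"
        taken_firsts: list[str] = []
        surname = cap(last_pool[int(rng.integers(0, len(last_pool)))])
        pfirst = cap(_pick_distinct_first(rng, first_pool, taken_firsts, costs, cutoff))
        taken_firsts.append(pfirst)
        age = int(np.clip(round(rng.normal(84.3, 8.1)), 60, 105))
        sex = Sex.female if rng.random() < 0.624 else Sex.male
        race = Race(race_names[int(rng.choice(len(race_names), p=race_probs))])
        patients.append(Patient(pid, pfirst, surname, age, sex, race))

        n_contacts = max(1, int(round(rng.normal(config.contacts_mean, config.contacts_sd))))
        pat_contacts: list[KnownContact] = []
        for ci in range(n_contacts):
            cfirst = cap(_pick_distinct_first(rng, first_pool, taken_firsts, costs, cutoff))
            taken_firsts.append(cfirst)
            if rng.random() < config.same_surname_prob:
                clast = surname
            else:
                clast = cap(last_pool[int(rng.integers(0, len(last_pool)))])
            rel = Relationship(rel_names[int(rng.choice(len(rel_names), p=rel_probs))])
            types = {
                t
                for t, p in (
                    (ContactType.general, 0.966),
                    (ContactType.emergency, 0.442),
                    (ContactType.guardian, 0.034),
                    (ContactType.health_agent, 0.301),
                    (ContactType.portal_proxy, 0.053),
                    (ContactType.transportation, 0.25),
                )
                if rng.random() < p
            } or {ContactType.general}
            pat_contacts.append(
                KnownContact(
                    contact_id=f"{pid}C{ci}",
                    patient_id=pid,
                    first_name=cfirst,
                    last_name=clast,
                    contact_types=frozenset(types),
                    relationship=rel,
                )
            )
        contacts.extend(pat_contacts)

        pat_providers: list[Provider] = []
        for vi in range(config.n_providers_per_patient):
            vfirst = cap(_pick_distinct_first(rng, first_pool, taken_firsts, costs, cutoff))
            taken_firsts.append(vfirst)
            vlast = cap(last_pool[int(rng.integers(0, len(last_pool)))])
            days_ago = int(rng.integers(30, int(365.25 * 5)))
            pat_providers.append(
                Provider(
                    provider_id=f"{pid}V{vi}",
                    patient_id=pid,
                    first_name=vfirst,
                    last_name=vlast,
                    last_encounter_date=ANALYSIS_DATE - dt.timedelta(days=days_ago),
                )
            )
        providers.extend(pat_providers)

        new_caregivers: list[dict] = []
        for ni in range(config.n_new_caregivers):
            nfirst = cap(_pick_distinct_first(rng, first_pool, taken_firsts, costs, cutoff))
            taken_firsts.append(nfirst)
            nlast = cap(last_pool[int(rng.integers(0, len(last_pool)))])
            rel = rel_names[int(rng.choice(len(rel_names), p=rel_probs))]
            k = int(occ_vals[int(rng.choice(len(occ_vals), p=occ_probs))])
            new_caregivers.append(
                {
                    "first_name": nfirst,
                    "last_name": nlast,
                    "category": _CATEGORY_FOR_REL[rel],
                    "planned_occurrences": k,
                    "near_term_count": 0,
                }
            )

        # Planned near-term mentions, consumed by term-bearing records.
        plan: list[_PlannedMention] = []
        for idx, nc in enumerate(new_caregivers):
            plan += [_PlannedMention("new", idx)] * nc["planned_occurrences"]
        for idx, _c in enumerate(pat_contacts):
            n_events = 1 + int(rng.random() < 0.6)
            plan += [_PlannedMention("contact", idx)] * n_events
        order = rng.permutation(len(plan))
        queue = [plan[i] for i in order]

        contact_near: dict[str, int] = {}
        truth_patients[pid] = {
            "patient_name": f"{pfirst} {surname}",
            "contacts": [
                {
                    "contact_id": c.contact_id,
                    "first_name": c.first_name,
                    "last_name": c.last_name,
                    "relationship": c.relationship.value,
                }
                for c in pat_contacts
            ],
            "new_caregivers": new_caregivers,
            "contacts_near_term": contact_near,
        }

        ri = 0
        for source_name, n_rec in sorted(config.records_per_patient.items()):
            source = Source(source_name)
            for _ in range(n_rec):
                rid = f"{pid}R{ri:03d}"
                ri += 1
                b = _RecordBuilder()
                names_truth: list[dict] = []
                terms_truth: list[dict] = []

                plant_term = rng.random() < config.term_plant_prob.get(source_name, 0.0)

                # Leading filler sentence (keeps decoys >window away from terms).
                n_fill = int(rng.integers(4, 9))
                fill = [
                    _FILLER[int(rng.integers(0, len(_FILLER)))] for _ in range(n_fill)
                ]
                fill[0] = cap(fill[0])
                b.add_all(fill, end_sentence=True)

                # Decoys, inside the leading sentence region.
                if rng.random() < config.provider_decoy_prob and pat_providers:
                    pr = pat_providers[int(rng.integers(0, len(pat_providers)))]
                    b.add("seen")
                    b.add("by")
                    b.add("Dr")
                    j = b.add(pr.last_name, suffix=".")
                    names_truth.append(
                        {"label": "provider", "person_id": pr.provider_id,
                         "token_start": j, "token_end": j + 1,
                         "surface": pr.last_name, "near_term": False,
                         "misspell": "none"}
                    )
                if rng.random() < config.place_decoy_prob:
                    b.add("relocated")
                    b.add("from")
                    place = _PLACES[int(rng.integers(0, len(_PLACES)))]
                    j = b.add(cap(place), suffix=".")
                    names_truth.append(
                        {"label": "decoy", "person_id": None,
                         "token_start": j, "token_end": j + 1,
                         "surface": cap(place), "near_term": False,
                         "misspell": "none"}
                    )
                if rng.random() < config.medication_decoy_prob:
                    b.add("continue")
                    med = _MEDS[int(rng.integers(0, len(_MEDS)))]
                    b.add(cap(med))
                    b.add("nightly", suffix=".")

                # Spacer so any decoy is at least window+1 tokens from a term.
                spacer = [
                    _FILLER[int(rng.integers(0, len(_FILLER)))]
                    for _ in range(WINDOW_RADIUS + 2)
                ]
                b.add_all(spacer, end_sentence=True)

                if plant_term:
                    mention = None
                    if source is Source.permanent_comment and pat_contacts:
                        # Permanent comments duplicate structured entries.
                        mention = _PlannedMention(
                            "contact", int(rng.integers(0, len(pat_contacts)))
                        )
                    elif queue and rng.random() < config.name_plant_prob:
                        mention = queue.pop()
                    if mention is not None and mention.kind == "contact":
                        person = pat_contacts[mention.person_idx]
                        category = _CATEGORY_FOR_REL[person.relationship.value]
                        first, last = person.first_name, person.last_name
                        label, person_id = "contact", person.contact_id
                    elif mention is not None:
                        nc = new_caregivers[mention.person_idx]
                        category = nc["category"]
                        first, last = nc["first_name"], nc["last_name"]
                        label, person_id = "new_caregiver", f"{pid}N{mention.person_idx}"
                    else:
                        category = ("child", "parent", "spouse", "other")[
                            int(rng.integers(0, 4))
                        ]
                        first = last = label = person_id = None  # term only

                    surf_pool = terms_by_cat[category]
                    surface = surf_pool[int(rng.integers(0, len(surf_pool)))]
                    term_words = surface.split()
                    t0 = b.add_all(["his" if sex is Sex.male else "her"] + term_words)
                    term_start = t0 + 1
                    terms_truth.append(
                        {"token_index": term_start, "surface": surface,
                         "category": category, "n_tokens": len(term_words)}
                    )

                    if first is not None:
                        gap = int(rng.integers(1, 5))  # first token ≤5 inside window
                        gap_words = [
                            _FILLER[int(rng.integers(0, len(_FILLER)))]
                            for _ in range(gap - 1)
                        ]
                        b.add_all(gap_words)
                        ms = "none"
                        shown_first = first
                        if label == "contact" and p_none < 1.0:
                            u = rng.random()
                            if u >= p_none:
                                acc = p_none
                                for c_name, c_p in zip(ms_classes, ms_probs):
                                    acc += c_p
                                    if u < acc:
                                        ms = c_name
                                        break
                                shown_first = _misspell(rng, first, ms)
                                if shown_first == first:
                                    ms = "none"
                        j = b.add(shown_first)
                        tok_end = j + 1
                        if rng.random() < config.full_name_prob and gap <= 4:
                            b.add(last)
                            tok_end = j + 2
                        b.add_all(
                            ["stopped", "by", "to", "assist"], end_sentence=True
                        )
                        names_truth.append(
                            {"label": label, "person_id": person_id,
                             "token_start": j, "token_end": tok_end,
                             "surface": " ".join(b.words[j:tok_end]),
                             "near_term": True, "misspell": ms,
                             "category": category}
                        )
                        if label == "contact":
                            contact_near[person_id] = contact_near.get(person_id, 0) + 1
                        else:
                            new_caregivers[mention.person_idx]["near_term_count"] += 1
                    else:
                        b.add_all(["is", "involved", "in", "care"], end_sentence=True)

                    if new_caregivers and rng.random() < config.far_plant_prob:
                        # Negative control: a name planted outside any window.
                        pad = [
                            _FILLER[int(rng.integers(0, len(_FILLER)))]
                            for _ in range(WINDOW_RADIUS + 2)
                        ]
                        b.add_all(pad)
                        far = new_caregivers[int(rng.integers(0, len(new_caregivers)))]
                        j = b.add(far["first_name"])
                        b.add(far["last_name"])
                        b.add_all(["called", "the", "office"], end_sentence=True)
                        names_truth.append(
                            {"label": "new_caregiver", "person_id": None,
                             "token_start": j, "token_end": j + 2,
                             "surface": f"{far['first_name']} {far['last_name']}",
                             "near_term": False, "misspell": "none"}
                        )

                text, offsets = b.render()
                # Convert token spans to char spans for the truth record.
                for nt in names_truth:
                    nt["start"] = offsets[nt.pop("token_start")][0]
                    nt["end"] = offsets[nt.pop("token_end") - 1][1]
                days = int(rng.integers(0, 365 * 2))
                records.append(
                    TextRecord(
                        record_id=rid,
                        patient_id=pid,
                        source=source,
                        timestamp=ANALYSIS_DATE - dt.timedelta(days=days),
                        text=text,
                        author_is_proxy=source is Source.portal_message
                        and rng.random() < 0.11,
                    )
                )
                truth_records[rid] = {"terms": terms_truth, "names": names_truth}

    corpus = Corpus(patients=patients, contacts=contacts, providers=providers, records=records)
    truth = {
        "seed": config.seed,
        "n_patients": config.n_patients,
        "analysis_date": ANALYSIS_DATE.isoformat(),
        "patients": truth_patients,
        "records": truth_records,
    }
    if out_dir is not None:
        d = Path(out_dir)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "patients.csv", "w", newline="", encoding="utf-8") as fh:
            fh.write("study_id,first_name,last_name,age_years,sex,race\n")
            for p in patients:
                fh.write(
                    f"{p.study_id},{p.first_name},{p.last_name},{p.age_years},"
                    f"{p.sex.value},{p.race.value}\n"
                )
        write_contacts(contacts, d / "contacts.csv")
        with open(d / "providers.csv", "w", newline="", encoding="utf-8") as fh:
            fh.write("provider_id,patient_id,first_name,last_name,last_encounter_date\n")
            for v in providers:
                fh.write(
                    f"{v.provider_id},{v.patient_id},{v.first_name},{v.last_name},"
                    f"{v.last_encounter_date.isoformat()}\n"
                )
        write_text_records(records, d / "notes.jsonl")
        with open(d / "truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return corpus, truth


# ---------------------------------------------------------------------------
# Evaluation against ground truth


def _prf(tp: int, fp: int, fn: int) -> dict:
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "precision": round(precision, 6),
        "recall": round(recall, 6),
        "f1": round(f1, 6),
        "undefined": tp + fp == 0 or tp + fn == 0,
    }


def evaluate(result, truth: dict) -> dict:
    """Score pipeline outputs against the generator's ground truth.

    * span level — recognizer spans vs. planted person-name spans (any label
      except place/medication decoys), overlap-matched on character ranges,
      over caregiver-text records;
    * caregiver level — identified known contacts vs. contacts planted within
      a term window, and identified new names vs. planted new caregivers with
      at least one near-term occurrence.
    """
    truth_recs = truth["records"]
    corpus_ids = {r.record_id for r in result.corpus.records}
    missing = [rid for rid in truth_recs if rid not in corpus_ids]
    if missing:
        raise ConsistencyError(f"truth references unknown records: {missing[:5]}")

    # --- span level (on caregiver-text records, where recognition runs)
    analyzed = set(result.hitmap)
    pred_by_rec: dict[str, list] = {}
    for s in result.recognized_spans:
        pred_by_rec.setdefault(s.record_id, []).append(s)
    tp = fp = fn = 0
    for rid in analyzed:
        gold = [
            n
            for n in truth_recs.get(rid, {}).get("names", [])
            if n["label"] in ("contact", "new_caregiver", "patient", "provider")
        ]
        preds = pred_by_rec.get(rid, [])
        matched_gold = set()
        for p in preds:
            hit = None
            for gi, g in enumerate(gold):
                if p.start < g["end"] and g["start"] < p.end:
                    hit = gi
                    break
            if hit is None:
                fp += 1
            else:
                tp += 1
                matched_gold.add(hit)
        fn += len(gold) - len(matched_gold)
    span = _prf(tp, fp, fn)

    # --- caregiver level: known contacts
    identified_contacts = set()
    for r in result.caregivers:
        if not r.is_new_name and sum(r.text_counts.values()) > 0:
            identified_contacts.add(
                (r.patient_study_id, r.first_name.lower(), r.last_name.lower())
            )
    contact_by_id = {
        c.contact_id: c for c in result.corpus.contacts
    }
    truth_contacts = set()
    for pid, pt in truth["patients"].items():
        for cid in pt["contacts_near_term"]:
            c = contact_by_id[cid]
            truth_contacts.add((pid, c.first_name.lower(), c.last_name.lower()))
    tp_c = len(identified_contacts & truth_contacts)
    contact = _prf(
        tp_c,
        len(identified_contacts - truth_contacts),
        len(truth_contacts - identified_contacts),
    )

    # --- caregiver level: new names.  A first-name-only identification of a
    # planted caregiver counts (names are matched by first or full name).
    identified_new = [
        (r.patient_study_id, r.first_name, r.last_name)
        for r in result.caregivers
        if r.is_new_name
    ]
    truth_new = []
    for pid, pt in truth["patients"].items():
        for nc in pt["new_caregivers"]:
            if nc["near_term_count"] > 0:
                truth_new.append((pid, nc["first_name"], nc["last_name"]))

    def _matches(ident, gold) -> bool:
        if ident[0] != gold[0]:
            return False
        if not accept(ident[1], gold[1]):
            return False
        return not ident[2] or accept(ident[2], gold[2])

    matched_truth: set[int] = set()
    tp_n = fp_n = 0
    for ident in identified_new:
        hit = None
        for gi, gold in enumerate(truth_new):
            if _matches(ident, gold):
                hit = gi
                break
        if hit is None:
            fp_n += 1
        else:
            tp_n += 1
            matched_truth.add(hit)
    new_names = _prf(tp_n, fp_n, len(truth_new) - len(matched_truth))

    return {"span": span, "contacts": contact, "new_names": new_names}
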