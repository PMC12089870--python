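"""Caregiver-level merge, cohort summaries, and pipeline orchestration.

The pipeline runs: caregiver-text extraction → windowed contact matching →
new-name discovery → recurrence/model selection → caregiver-level merge →
cohort summary.  The merged dataset has exactly one row per unique
(patient, canonical name): known contacts carry their structured-field flags
and window-match counts; surviving new names carry their occurrence counts
and selection results.  Caregiver ids are content hashes, so reruns agree.
"""

from __future__ import annotations

import csv
import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field

from . import caregiver_text as ct
from . import discovery as dsc
from .corpus import (
    Corpus,
    KnownContact,
    Patient,
    Source,
    dedupe_contacts,
    load_corpus,
)
from .errors import ConfigError, ConsistencyError
from .lexicon import Lexicon, load_lexicon
from .name_match import (
    CostTable,
    DEFAULT_CUTOFF,
    MatchKind,
    MatchResult,
    match_window,
)
from .selection import (
    SelectionResult,
    contact_candidates,
    run_selection,
)

logger = logging.getLogger("carenet")

SOURCE_NAMES = tuple(s.value for s in Source)
CATEGORY_NAMES = ("parent", "child", "spouse", "other")
FLAG_NAMES = (
    "general",
    "emergency",
    "guardian",
    "health_agent",
    "portal_proxy",
    "transportation",
)


@dataclass(frozen=True)
class CaregiverRecord:
    """One row of the final merged caregiver-level dataset."""

    caregiver_id: str
    patient_study_id: str
    patient_name: str
    first_name: str
    last_name: str
    structured_flags: dict[str, int]
    is_new_name: bool
    text_counts: dict[str, int]
    associated_terms: tuple[str, ...]
    recurrent_selected: Optional[bool] = None
    model_probability: Optional[float] = None
    model_selected: Optional[bool] = None

    @property
    def full_name(self) -> str:
        return f"{self.first_name} {self.last_name}".strip()

    @property
    def both_selected(self) -> Optional[bool]:
        if self.recurrent_selected is None or self.model_selected is None:
            return None
        return self.recurrent_selected and self.model_selected


def caregiver_id(patient_id: str, first: str, last: str) -> str:
    """Stable content hash identifying one (patient, canonical name)."""
    key = f"{patient_id}|{first.lower()}|{last.lower()}"
    return hashlib.md5(key.encode("utf-8")).hexdigest()[:12]


def merge(
    contacts: list[KnownContact],
    matches: list[MatchResult],
    candidates: list[dsc.CandidateName],
    selection: dict[tuple[str, str, str], SelectionResult],
    patients_by_id: dict[str, Patient],
) -> list[CaregiverRecord]:
    """Assemble the caregiver-level merged dataset.

    Known contacts become rows with structured flags and window-match counts;
    surviving new names become rows with ``is_new_name`` set and their
    selection results attached.  A new name that exactly coincides with a
    contact of the same patient indicates a failed exclusion upstream and
    raises :class:`ConsistencyError`.
    """
    contact_names = {
        (c.patient_id, c.first_name.lower(), c.last_name.lower()) for c in contacts
    }
    for cand in candidates:
        if cand.key() in contact_names:
            raise ConsistencyError(
                f"name {cand.first_name} {cand.last_name} for patient "
                f"{cand.patient_id} appears both as known contact and new name"
            )

    by_contact: dict[str, dict] = {
        c.contact_id: {"sources": {}, "terms": set()} for c in contacts
    }
    for m in matches:
        if m.match_kind != MatchKind.first_name:
            continue
        slot = by_contact.get(m.contact_id)
        if slot is None:
            continue
        slot["sources"][m.source] = slot["sources"].get(m.source, 0) + 1
        slot["terms"].add(f"{m.term_surface}:{m.term_category}")

    records: list[CaregiverRecord] = []
    for c in contacts:
        patient = patients_by_id.get(c.patient_id)
        pname = f"{patient.first_name} {patient.last_name}" if patient else ""
        slot = by_contact[c.contact_id]
        counts = {s: slot["sources"].get(s, 0) for s in SOURCE_NAMES}
        records.append(
            CaregiverRecord(
                caregiver_id=caregiver_id(c.patient_id, c.first_name, c.last_name),
                patient_study_id=c.patient_id,
                patient_name=pname,
                first_name=c.first_name,
                last_name=c.last_name,
                structured_flags={
                    f: int(f in {t.value for t in c.contact_types}) for f in FLAG_NAMES
                },
                is_new_name=False,
                text_counts=counts,
                associated_terms=tuple(sorted(slot["terms"])),
            )
        )

    for cand in candidates:
        patient = patients_by_id.get(cand.patient_id)
        pname = f"{patient.first_name} {patient.last_name}" if patient else ""
        sel = selection.get(cand.key())
        terms = tuple(
            sorted(f":{cat}" for cat in cand.per_category_counts if cand.per_category_counts[cat])
        )
        records.append(
            CaregiverRecord(
                caregiver_id=caregiver_id(cand.patient_id, cand.first_name, cand.last_name),
                patient_study_id=cand.patient_id,
                patient_name=pname,
                first_name=cand.first_name,
                last_name=cand.last_name,
                structured_flags={f: 0 for f in FLAG_NAMES},
                is_new_name=True,
                text_counts={s: cand.per_source_counts.get(s, 0) for s in SOURCE_NAMES},
                associated_terms=terms,
                recurrent_selected=None if sel is None else sel.recurrent_selected,
                model_probability=None if sel is None else sel.model_probability,
                model_selected=None if sel is None else sel.model_selected,
            )
        )
    records.sort(key=lambda r: (r.patient_study_id, r.is_new_name, r.caregiver_id))
    return records


def _pct(num: int, den: int) -> float:
    return round(100.0 * num / den, 4) if den else 0.0


def summarize(
    patients: list[Patient],
    contacts: list[KnownContact],
    corpus_records,
    hitmap: dict[str, list],
    matches: list[MatchResult],
    records: list[CaregiverRecord],
) -> dict:
    """Cohort summary tables.

    Match-rate cells are reported under both denominator conventions: percent
    of the patient cohort with at least one qualifying name, and percent of
    names qualifying.
    """
    n_pat = len(patients)
    by_pid: dict[str, list[KnownContact]] = {}
    for c in contacts:
        by_pid.setdefault(c.patient_id, []).append(c)
    n_contacts = len(contacts)
    counts_per_patient = [len(by_pid.get(p.study_id, [])) for p in patients]
    patients_by_id = {p.study_id: p for p in patients}
    same_surname = sum(
        1
        for c in contacts
        if c.patient_id in patients_by_id and c.same_surname(patients_by_id[c.patient_id])
    )

    summary: dict = {
        "cohort": {
            "n_patients": n_pat,
            "n_contacts": n_contacts,
            "pct_with_any_contact": _pct(sum(1 for k in counts_per_patient if k > 0), n_pat),
            "contacts_per_patient_mean": round(float(np.mean(counts_per_patient)), 4)
            if n_pat
            else 0.0,
            "contacts_per_patient_sd": round(float(np.std(counts_per_patient, ddof=1)), 4)
            if n_pat > 1
            else 0.0,
            "contacts_per_patient_median": float(np.median(counts_per_patient))
            if n_pat
            else 0.0,
            "pct_contacts_same_surname": _pct(same_surname, n_contacts),
        },
        "contact_types_pct": {
            f: _pct(
                sum(1 for c in contacts if f in {t.value for t in c.contact_types}),
                n_contacts,
            )
            for f in FLAG_NAMES
        },
        "relationship_pct": {},
        "term_hit_rates_pct": {},
        "contact_matches": {},
        "new_names": {},
    }

    rel_counts: dict[str, int] = {}
    for c in contacts:
        rel_counts[c.relationship.value] = rel_counts.get(c.relationship.value, 0) + 1
    summary["relationship_pct"] = {
        r: _pct(rel_counts.get(r, 0), n_contacts)
        for r in ("child", "parent", "spouse", "other", "unknown")
    }
    summary["relationship_pct"]["child_or_parent"] = _pct(
        rel_counts.get("child", 0) + rel_counts.get("parent", 0), n_contacts
    )

    totals: dict[str, int] = {}
    with_hits: dict[str, int] = {}
    for r in corpus_records:
        s = r.source.value
        totals[s] = totals.get(s, 0) + 1
        if r.record_id in hitmap:
            with_hits[s] = with_hits.get(s, 0) + 1
    summary["term_hit_rates_pct"] = {
        s: _pct(with_hits.get(s, 0), totals.get(s, 0)) for s in SOURCE_NAMES
    }

    contact_patient = {c.contact_id: c.patient_id for c in contacts}
    for kind in (MatchKind.first_name, MatchKind.full_name):
        cell: dict = {"pct_cohort_by_source": {}, "pct_contacts_by_source": {}}
        for s in SOURCE_NAMES:
            pats = {
                contact_patient[m.contact_id]
                for m in matches
                if m.match_kind == kind and m.source == s and m.contact_id in contact_patient
            }
            cons = {
                m.contact_id
                for m in matches
                if m.match_kind == kind and m.source == s
            }
            cell["pct_cohort_by_source"][s] = _pct(len(pats), n_pat)
            cell["pct_contacts_by_source"][s] = _pct(len(cons), n_contacts)
        cats: dict = {"pct_cohort_by_category": {}, "pct_contacts_by_category": {}}
        for cat in CATEGORY_NAMES:
            pats = {
                contact_patient[m.contact_id]
                for m in matches
                if m.match_kind == kind and m.term_category == cat and m.contact_id in contact_patient
            }
            cons = {
                m.contact_id for m in matches if m.match_kind == kind and m.term_category == cat
            }
            cats["pct_cohort_by_category"][cat] = _pct(len(pats), n_pat)
            cats["pct_contacts_by_category"][cat] = _pct(len(cons), n_contacts)
        summary["contact_matches"][kind] = {**cell, **cats}

    new_rows = [r for r in records if r.is_new_name]
    pats_any = {r.patient_study_id for r in new_rows}
    recurrent = [r for r in new_rows if r.recurrent_selected]
    model_sel = [r for r in new_rows if r.model_selected]
    both = [r for r in new_rows if r.both_selected]
    summary["new_names"] = {
        "n_names": len(new_rows),
        "pct_cohort_any": _pct(len(pats_any), n_pat),
        "n_recurrent": len(recurrent),
        "pct_cohort_recurrent": _pct(len({r.patient_study_id for r in recurrent}), n_pat),
        "n_model_selected": len(model_sel),
        "n_both_selected": len(both),
        "pct_names_by_source": {
            s: _pct(sum(1 for r in new_rows if r.text_counts.get(s, 0) > 0), len(new_rows))
            for s in SOURCE_NAMES
        },
    }
    return summary


# ---------------------------------------------------------------------------
# Orchestration


class PipelineConfig(BaseModel):
    """All inputs and parameters of one pipeline run."""

    notes: Optional[str] = None
    patients: Optional[str] = None
    contacts: Optional[str] = None
    providers: Optional[str] = None
    corpus_dir: Optional[str] = None
    lexicon: Optional[str] = None
    out_dir: str = "carenet_out"
    cap: int = ct.DEFAULT_CAP
    cutoff: int = DEFAULT_CUTOFF
    costs: dict[str, int] = Field(default_factory=dict)
    min_count: int = 2
    percentile: float = 10
    backend: str = "rules"
    analysis_date: Optional[dt.date] = None
    seed: int = 0


@dataclass
class PipelineResult:
    corpus: Corpus
    contacts: list[KnownContact]
    kept_records: list
    excluded_records: list
    hitmap: dict
    windows: list
    matches: list[MatchResult]
    recognized_spans: list[dsc.NameSpan]
    new_spans: list[dsc.NameSpan]
    candidates: list[dsc.CandidateName]
    selection: dict
    caregivers: list[CaregiverRecord]
    summary: dict
    caregivers_csv: Optional[Path] = None
    summary_json: Optional[Path] = None


def run_pipeline(
    config: PipelineConfig,
    corpus: Corpus | None = None,
    write_outputs: bool = True,
) -> PipelineResult:
    """Execute the full pipeline under one configuration.

    ``corpus`` may be passed in-memory (e.g. fresh from the synthetic
    generator); otherwise it is loaded from ``corpus_dir`` or the individual
    paths in the config.
    """
    if corpus is None:
        if config.corpus_dir:
            corpus = load_corpus(config.corpus_dir)
        elif config.notes and config.patients and config.contacts:
            from .corpus import read_contacts, read_patients, read_providers, read_text_records

            corpus = Corpus(
                patients=read_patients(config.patients),
                contacts=read_contacts(config.contacts),
                providers=read_providers(config.providers) if config.providers else [],
                records=read_text_records(config.notes),
            )
        else:
            missing = [
                k for k in ("notes", "patients", "contacts") if not getattr(config, k)
            ]
            raise ConfigError(
                f"config must name corpus_dir or all of notes/patients/contacts; "
                f"missing: {missing}"
            )

    costs = CostTable(**config.costs) if config.costs else CostTable()
    lex: Lexicon = load_lexicon(config.lexicon)
    analysis_date = config.analysis_date or corpus.analysis_date
    patients_by_id = corpus.patients_by_id

    contacts = dedupe_contacts(corpus.contacts, costs, config.cutoff)
    logger.info("stage=dedupe contacts_in=%d contacts_out=%d", len(corpus.contacts), len(contacts))

    kept, excluded = ct.filter_overlong(corpus.records, config.cap)
    logger.info("stage=length_filter kept=%d excluded=%d", len(kept), len(excluded))

    hitmap = ct.extract_caregiver_text(kept, lex)
    windows = ct.all_windows(kept, hitmap)
    logger.info("stage=extract caregiver_records=%d windows=%d", len(hitmap), len(windows))

    contacts_by_pid: dict[str, list[KnownContact]] = {}
    for c in contacts:
        contacts_by_pid.setdefault(c.patient_id, []).append(c)
    matches: list[MatchResult] = []
    for w in windows:
        matches.extend(
            match_window(
                w,
                contacts_by_pid.get(w.patient_id, []),
                costs,
                config.cutoff,
                term_surfaces=lex.surfaces,
            )
        )
    logger.info("stage=match results=%d", len(matches))

    stop_vocab = dsc.StopVocab.default()
    providers_by_pid: dict[str, list] = {}
    for p in corpus.providers:
        providers_by_pid.setdefault(p.patient_id, []).append(p)
    recognized: list[dsc.NameSpan] = []
    new_spans: list[dsc.NameSpan] = []
    for r in kept:
        if r.record_id not in hitmap:
            continue
        spans = dsc.recognize_names(r, backend=config.backend, lexicon=lex, stop_vocab=stop_vocab)
        recognized.extend(spans)
        patient = patients_by_id.get(r.patient_id)
        if patient is None:
            continue
        spans = dsc.exclude_known(
            spans,
            contacts_by_pid.get(r.patient_id, []),
            patient,
            providers_by_pid.get(r.patient_id, []),
            analysis_date,
            costs,
            config.cutoff,
        )
        spans = dsc.scrub(spans, stop_vocab)
        new_spans.extend(spans)
    candidates = dsc.consolidate(new_spans, windows, costs, config.cutoff)
    logger.info(
        "stage=discover recognized=%d new_spans=%d candidates=%d",
        len(recognized),
        len(new_spans),
        len(candidates),
    )

    known_cands = contact_candidates(contacts, matches)
    selection, model = run_selection(
        candidates, known_cands, min_count=config.min_count, percentile=config.percentile
    )
    logger.info(
        "stage=select recurrent=%d model=%d both=%d",
        sum(1 for s in selection.values() if s.recurrent_selected),
        sum(1 for s in selection.values() if s.model_selected),
        sum(1 for s in selection.values() if s.both_selected),
    )

    caregivers = merge(contacts, matches, candidates, selection, patients_by_id)
    summary = summarize(corpus.patients, contacts, kept, hitmap, matches, caregivers)
    logger.info("stage=merge caregivers=%d", len(caregivers))

    result = PipelineResult(
        corpus=corpus,
        contacts=contacts,
        kept_records=kept,
        excluded_records=excluded,
        hitmap=hitmap,
        windows=windows,
        matches=matches,
        recognized_spans=recognized,
        new_spans=new_spans,
        candidates=candidates,
        selection=selection,
        caregivers=caregivers,
        summary=summary,
    )
    if write_outputs:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.caregivers_csv = write_caregivers_csv(caregivers, out / "caregivers.csv")
        result.summary_json = write_summary_json(summary, out / "summary.json")
    return result


CSV_COLUMNS = (
    ["caregiver_id", "patient_study_id", "patient_name", "first_name", "last_name", "full_name"]
    + [f"flag_{f}" for f in FLAG_NAMES]
    + ["is_new_name"]
    + [f"count_{s}" for s in SOURCE_NAMES]
    + ["associated_terms", "recurrent_selected", "model_probability", "model_selected", "both_selected"]
)


def write_caregivers_csv(records: list[CaregiverRecord], path: Path) -> Path:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_COLUMNS)
        for r in records:
            row = [
                r.caregiver_id,
                r.patient_study_id,
                r.patient_name,
                r.first_name,
                r.last_name,
                r.full_name,
            ]
            row += [r.structured_flags[f] for f in FLAG_NAMES]
            row += [int(r.is_new_name)]
            row += [r.text_counts.get(s, 0) for s in SOURCE_NAMES]
            row += [
                ";".join(r.associated_terms),
                "" if r.recurrent_selected is None else int(r.recurrent_selected),
                ""
                if r.model_probability is None
                else f"{r.model_probability:.6f}",
                "" if r.model_selected is None else int(r.model_selected),
                "" if r.both_selected is None else int(r.both_selected),
            ]
            w.writerow(row)
    return path


def write_summary_json(summary: dict, path: Path) -> Path:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
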