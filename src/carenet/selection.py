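"""Selection of likely caregivers among newly discovered names.

Two complementary rules, applied to every unique "new" name:

* the recurrence rule — the name occurs at least twice near caregiver terms;
* the similarity rule — a logistic model, trained to discriminate known
  contacts from new names on seven binary presence features (name appears in
  encounter notes / permanent comments / problem lists / portal messages;
  name near a spousal / child / any other caregiver term), scores the name
  above the 10th percentile of the known contacts' predicted probabilities.

Parent-term adjacency folds into the "other" predictor: the model uses
exactly three term-category features, while the four-category counts remain
available in reports.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .discovery import CandidateName
from .errors import FittingError
from .name_match import MatchKind, MatchResult

FEATURE_NAMES = (
    "present_in_encounter",
    "present_in_permanent_comment",
    "present_in_problem_list",
    "present_in_portal_message",
    "near_spouse_term",
    "near_child_term",
    "near_other_term",
)


@dataclass(frozen=True)
class FeatureVector:
    """Seven binary predictors plus the known(1)/new(0) label."""

    candidate: CandidateName
    values: tuple[int, ...]
    label: int

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)


def featurize(candidates: list[CandidateName]) -> list[FeatureVector]:
    """One vector per unique name occurring at least once in caregiver text.

    Presence features threshold the counts at > 0; parent-term counts fold
    into ``near_other_term``.  Names never seen in caregiver text (all counts
    zero) are excluded.  Emits a warning when only one label class is present,
    since the similarity model cannot then be fitted.
    """
    vectors: list[FeatureVector] = []
    for c in candidates:
        src = c.per_source_counts
        cat = c.per_category_counts
        if sum(src.values()) == 0 and sum(cat.values()) == 0:
            continue
        values = (
            int(src.get("encounter", 0) > 0),
            int(src.get("permanent_comment", 0) > 0),
            int(src.get("problem_list", 0) > 0),
            int(src.get("portal_message", 0) > 0),
            int(cat.get("spouse", 0) > 0),
            int(cat.get("child", 0) > 0),
            int(cat.get("other", 0) + cat.get("parent", 0) > 0),
        )
        vectors.append(FeatureVector(c, values, label=0 if c.is_new else 1))
    labels = {v.label for v in vectors}
    if vectors and labels != {0, 1}:
        warnings.warn(
            "featurize: only one label class present; the similarity model "
            "cannot be fitted on this input",
            stacklevel=2,
        )
    return vectors


def design_matrix(vectors: list[FeatureVector]) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([v.values for v in vectors], dtype=float)
    y = np.array([v.label for v in vectors], dtype=float)
    return X, y


class ContactSimilarityModel:
    """Maximum-likelihood logistic regression fitted by IRLS.

    Newton/IRLS from a zero initial vector; convergence when the largest
    absolute coefficient change drops below ``tol`` (default 1e-8) or after
    ``max_iter`` (default 100) iterations.  If separation is detected (the
    unpenalized fit diverges), the model is refitted with a small L2 penalty
    (``ridge``, default 1e-4, not applied to the intercept) and flagged via
    ``separation_flag_``.

    Fitted attributes: ``intercept_``, ``coef_`` (7-vector), ``n_iter_``,
    ``converged_``, ``separation_flag_``.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100, ridge: float = 1e-4):
        self.tol = tol
        self.max_iter = max_iter
        self.ridge = ridge

    # -- fitting -----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray) -> "ContactSimilarityModel":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise FittingError("X and y have incompatible shapes")
        classes = np.unique(y)
        if not np.array_equal(classes, [0.0, 1.0]):
            raise FittingError(
                f"need both labels 0 and 1 to fit; got classes {classes.tolist()}"
            )
        beta, n_iter, converged, diverged = self._irls(X, y, penalty=0.0)
        separated = diverged or (not converged and np.max(np.abs(beta)) > 20)
        if separated:
            beta, n_iter, converged, _ = self._irls(X, y, penalty=self.ridge)
        self.separation_flag_ = bool(separated)
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:].copy()
        self.n_iter_ = n_iter
        self.converged_ = bool(converged)
        return self

    def _irls(
        self, X: np.ndarray, y: np.ndarray, penalty: float
    ) -> tuple[np.ndarray, int, bool, bool]:
        n, p = X.shape
        Xd = np.hstack([np.ones((n, 1)), X])
        beta = np.zeros(p + 1)
        pen = np.full(p + 1, penalty)
        pen[0] = 0.0  # intercept unpenalized
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            eta = np.clip(Xd @ beta, -30, 30)
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
            H = Xd.T @ (Xd * w[:, None]) + np.diag(pen)
            g = Xd.T @ (y - mu) - pen * beta
            try:
                delta = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(H, g, rcond=None)[0]
            beta = beta + delta
            if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 1e6:
                return beta, it, False, True
            if np.max(np.abs(delta)) < self.tol:
                converged = True
                break
        return beta, it, converged, False

    # -- inference ---------------------------------------------------------
    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        eta = np.clip(self.decision_function(X), -30, 30)
        return 1.0 / (1.0 + np.exp(-eta))

    def log_likelihood(self, X: np.ndarray, y: np.ndarray) -> float:
        eta = self.decision_function(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=float)
        # log-lik = sum y*eta - log(1+exp(eta)), computed stably
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank (ordinal) percentile of ``values``.

    With n sorted values, the p-th percentile is the ceil(p/100 * n)-th
    smallest (at least the 1st).
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("cannot take a percentile of an empty set")
    k = max(1, math.ceil(percentile / 100.0 * v.size))
    return float(v[k - 1])


def select_recurrent(
    candidates: list[CandidateName], min_count: int = 2
) -> list[CandidateName]:
    """Names occurring at least ``min_count`` times near caregiver terms."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return [c for c in candidates if c.total_near_term_count >= min_count]


@dataclass(frozen=True)
class SelectionResult:
    candidate: CandidateName
    recurrent_selected: bool
    model_probability: float
    model_selected: bool

    @property
    def both_selected(self) -> bool:
        return self.recurrent_selected and self.model_selected


def select_by_model(
    model: ContactSimilarityModel,
    vectors: list[FeatureVector],
    percentile: float = 10,
) -> tuple[list[tuple[FeatureVector, float, bool]], float]:
    """Score new names against the known-contact probability percentile.

    The threshold is the nearest-rank ``percentile`` of the known contacts'
    predicted probabilities; a new name is selected iff its probability is
    strictly above the threshold.  Returns ``([(vector, probability,
    selected), ...], threshold)`` over the new-name vectors.
    """
    known = [v for v in vectors if v.label == 1]
    new = [v for v in vectors if v.label == 0]
    if not known:
        raise FittingError("no known contacts scored; percentile threshold undefined")
    pk = model.predict_proba(np.array([v.values for v in known], dtype=float))
    threshold = nearest_rank_percentile(pk, percentile)
    out = []
    if new:
        pn = model.predict_proba(np.array([v.values for v in new], dtype=float))
        out = [(v, float(p), bool(p > threshold)) for v, p in zip(new, pn)]
    return out, threshold


def contact_candidates(
    contacts, matches: list[MatchResult]
) -> list[CandidateName]:
    """Known contacts as candidate rows, with counts from window matches.

    Each ``first_name``-kind match result counts one occurrence for its
    window's source and term category (full-name results refine, not add).
    Contacts never matched in caregiver text get all-zero counts and are
    later excluded by :func:`featurize`.
    """
    by_contact: dict[str, CandidateName] = {}
    for c in contacts:
        by_contact[c.contact_id] = CandidateName(
            patient_id=c.patient_id,
            first_name=c.first_name,
            last_name=c.last_name,
            is_new=False,
        )
    for m in matches:
        if m.match_kind != MatchKind.first_name:
            continue
        cand = by_contact.get(m.contact_id)
        if cand is None:
            continue
        cand.per_source_counts[m.source] = cand.per_source_counts.get(m.source, 0) + 1
        cand.per_category_counts[m.term_category] = (
            cand.per_category_counts.get(m.term_category, 0) + 1
        )
    return list(by_contact.values())


def run_selection(
    new_candidates: list[CandidateName],
    known_candidates: list[CandidateName],
    min_count: int = 2,
    percentile: float = 10,
) -> tuple[dict[tuple[str, str, str], SelectionResult], ContactSimilarityModel | None]:
    """Apply both selection rules; returns results keyed by candidate key.

    If the similarity model cannot be fitted (a label class is absent in the
    caregiver text), model probabilities are NaN and no name is
    model-selected; the recurrence rule still applies.
    """
    recurrent = {c.key() for c in select_recurrent(new_candidates, min_count)}
    vectors = featurize(known_candidates + new_candidates)
    labels = {v.label for v in vectors}
    model: ContactSimilarityModel | None = None
    scored: dict[tuple[str, str, str], tuple[float, bool]] = {}
    if labels == {0, 1}:
        X, y = design_matrix(vectors)
        model = ContactSimilarityModel().fit(X, y)
        ranked, _thr = select_by_model(model, vectors, percentile)
        for v, p, sel in ranked:
            scored[v.candidate.key()] = (p, sel)
    results: dict[tuple[str, str, str], SelectionResult] = {}
    for c in new_candidates:
        p, sel = scored.get(c.key(), (float("nan"), False))
        results[c.key()] = SelectionResult(
            candidate=c,
            recurrent_selected=c.key() in recurrent,
            model_probability=p,
            model_selected=sel,
        )
    return results, model
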