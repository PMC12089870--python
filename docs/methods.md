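# Methods

`carenet` implements a framework for systematically identifying caregivers of
people living with dementia (PLWD) from an EHR extract, by merging structured
"known contact" fields with unstructured clinical text. This note documents
the model, its parameters, the numerical choices, what the synthetic corpus
does and does not emulate, and the known limitations.

## Problem and pipeline

People listed in structured EHR fields (emergency contact, health care agent,
legal guardian, portal proxy, general contact, transportation flowsheet) are
*known contacts* — likely but not certainly caregivers. Much caregiving
information lives instead in free text: encounter, appointment and hospital
notes, problem lists, HIPAA permanent comments, and patient-portal messages.
The pipeline runs six stages:

1. **Caregiver text.** A record is *caregiver text* if it contains at least
   one lexicon term. Records longer than 2^15 characters are excluded
   outright (not truncated) before extraction.
2. **Windows.** Around each term hit, the 5 word-tokens before and after form
   the context window. "Word" is defined by the package tokenizer (maximal
   runs of letters/digits/apostrophes/hyphens); punctuation never counts.
   Windows are shorter at record boundaries, never padded.
3. **Contact matching.** Every window token is compared against the first and
   last names of the patient's known contacts under an operation-cost
   spelling distance (below); first-name and full-name (first + last within
   one intervening token, either order) matches are flagged.
4. **New-name discovery.** A pluggable recognizer proposes person-name spans
   in caregiver text; spans matching a known contact, the patient, or a
   provider seen within the 3 years before the analysis date are excluded;
   spans of common English words, place names, or medication lookalikes are
   scrubbed; survivors are consolidated per patient into unique *new names*
   with per-source and per-term-category counts taken from the windows they
   appear in.
5. **Selection.** New names are selected by recurrence (≥ 2 near-term
   occurrences) and by a logistic known-contact-similarity model with a
   10th-percentile probability threshold.
6. **Merge and summary.** One caregiver-level row per unique
   (patient, canonical name), with structured flags, per-source text counts,
   associated terms, and selection results; plus cohort summary tables under
   both denominator conventions (percent of cohort, percent of names).

## The spelling distance

The matcher's contract is a verbal acceptance rule: accept one letter
replacement, one letter addition (or deletion), or two disjoint pairs of
adjacent letters swapped; reject anything heavier. The distance is the
minimal total cost of a left-to-right edit script (restricted-Damerau model:
each original letter is consumed once; a swapped pair is consumed together)
under a configurable cost table:

| operation | default cost |
|---|---|
| match | 0 |
| adjacent transposition | 50 |
| append at end | 35 |
| truncate at end | 50 |
| delete (mid-word) | 100 |
| insert (mid-word) | 100 |
| replace | 100 |

with acceptance cutoff 100. End-of-word operations are cheaper than the same
operation mid-word, in the tradition of spelling-oriented distances. Under
the defaults: one replacement = 100 (accept), one insertion = 100 (accept;
35 if appended at the end), one deletion = 100 (accept; 50 if truncated),
two disjoint adjacent transpositions = 100 (accept), replacement +
transposition = 150 (reject), two substitutions = 185–200 (reject). Strings
are lower-cased and stripped of non-alphabetic characters before comparison;
the distance is asymmetric whenever the cost table is (append ≠ truncate).

*Model choice.* The script model — not free string rewriting — is deliberate.
Under free rewriting, an adjacent swap at cost 50 can compose with other
operations (e.g. rotating "abc" into "bca" for 100), the minimum is no longer
computable by an alignment dynamic program, and the verbal acceptance classes
above stop being characteristic. In the script model the DP is provably the
minimum, which the test suite verifies against exhaustive edit-script
enumeration over every string pair of length ≤ 5 on a 3-letter alphabet.

Single deletions are accepted by the defaults although the verbal rule names
only "replacement or addition"; the cost table is configurable if a stricter
reading is wanted.

## The lexicon

The bundled default lexicon (39 surfaces, user-overridable via CSV) covers
spouse, child, parent, and other informal-care relationships, including
abbreviations such as "dtr" and the phrases "in law", "son in law",
"daughter in law". Formal paid-care terms (nurse, aide) are excluded, as are
the kinship acronyms DIL/BIL/SIL, which collide with medical abbreviations
(e.g. dilation). "in law" is categorized under child by default. Term
matching is exact per token and case-insensitive — no fuzzy matching on
terms, precisely to avoid acronym collisions — with hyphenated tokens also
matched after splitting ("mother-in-law" hits both "mother" and "in law").
Relationship direction is not disambiguated: "daughter" and "mother" written
about the same dyad cannot be told apart from single mentions, so both stay
in their surface categories and the model folds parent into "other".

## The recognizer

The default backend is deterministic: a token is a strong name candidate if
it is capitalized and gazetteer-listed (bundled common given names and
surnames), or capitalized mid-sentence and outside every stop vocabulary;
capitalized stop-vocabulary words and titles (Dr, Mrs, RN, …) are weak
candidates that can join but not form a span; caregiver-term surfaces,
medication names, and multi-letter all-caps tokens (MRI, CHF) never enter
spans. Spans are maximal candidate runs (≤ 4 tokens, not crossing sentence
breaks) containing at least one strong token; confidence is 1.0 with a
gazetteer token, 0.6 otherwise. Any trained recognizer can be registered
under the same contract (`register_backend`) and selected by configuration;
the pipeline's accuracy then depends on that model, not on these rules.

## The similarity model

Seven binary predictors per unique name occurring at least once in caregiver
text: presence in encounter notes, permanent comments, problem lists, and
portal messages, and presence near a spousal, child, or any other caregiver
term (parent adjacency folds into "other"). Label: known contact (1) vs new
name (0). The fit is maximum-likelihood logistic regression by IRLS from a
zero start, converged when the largest coefficient change is < 1e-8 (max 100
iterations). If the fit diverges (separation — common at small n with binary
predictors), it is refitted with an L2 penalty of 1e-4 on the non-intercept
coefficients and flagged. The selection threshold is the nearest-rank
(ordinal) 10th percentile of the known contacts' predicted probabilities; a
new name is selected iff its probability is *strictly* above it. By
construction, at least 90% of known contacts score at or above the threshold
for any tie-free input (n − ⌈n/10⌉ + 1 ≥ 0.9 n); the strictly-above fraction
can dip to ~82% at unfavorable n (e.g. n = 11), which is why the invariant is
stated at-or-above. No automated variable selection is performed: the seven
predictors are taken as final.

## The synthetic corpus

The generator emulates the documented cohort characteristics: contacts per
patient as a truncated-at-1 rounded normal (mean 2.1, SD 1.1), relationship
mix (child-or-parent 0.542 — split 0.45/0.092 since the package keeps the
codes distinct — spouse 0.156, other 0.171, unknown 0.131), 47.1% of
contacts sharing the patient's surname, ages ≥ 60 (mean ≈ 84), and per-source
caregiver-term prevalence (encounter 26%, portal 34%, problem list 14%,
permanent comments 99%; appointment 20% and hospital 22% are package choices
between the printed problem-list and encounter rates, since no figures are
printed for those sources). Permanent comments duplicate structured contact
entries, as they do in the source system. Contact names planted near terms
are misspelled with configurable per-class rates (replacement, addition,
deletion, single/double transposition, and a "heavy" two-substitution class
the matcher must reject); decoy provider names, place names, and medication
tokens are planted at least a full window away from any term. Each patient
also receives new caregivers (default 2) absent from structured fields, with
occurrence counts drawn from {1: .3, 2: .4, 3: .2, 4: .1}.

Note text is template-based: records are built as token streams, so every
planted term and name has an exact recorded token and character offset,
including negative-control names planted ≥ 6 tokens from every term. Two
generator-level distinguishability conditions make ground truth well-defined:
within one patient's universe, no two people's first names fall within the
fuzzy-acceptance cutoff of each other (a "Jon" and a "John" are one name to
any fuzzy matcher — the nickname ambiguity the framework explicitly does not
resolve), and planted names are sampled outside the cutoff of every template
word (a filler "plan" is one replacement from "Alan"). Everything is driven
by a single seeded generator: identical config and seed reproduce the corpus,
`caregivers.csv`, and `summary.json` byte for byte.

What the generator does **not** emulate: realistic clinical prose, section
structure, copy-paste/template duplication (which inflates real counts),
nicknames, multi-patient notes, and — importantly — scale. The default
corpus has ~18 text strings per patient where the source cohort had ~835, so
per-name occurrence counts, and every summary cell driven by them (percent of
cohort with a name found in a given source, percent with a recurrent new
name), sit well below the full-scale figures. Passing tests therefore show
the machinery is correct on offset-exact ground truth, not that the default
recognizer would reach any particular accuracy on real notes.

## Evaluation

`evaluate` scores (a) recognition at span level (character-overlap matching
against all planted person names — contacts, new caregivers, patients,
providers — over caregiver-text records) and (b) identification at caregiver
level: known contacts with at least one window match vs contacts planted
inside a window, and new-name rows vs planted new caregivers with ≥ 1
near-term occurrence, matched by first/full name under the acceptance rule so
a first-name-only identification of a planted caregiver counts. Precision
with an empty prediction set is reported as 0 with an `undefined` flag. With
zero misspelling and zero decoys the pipeline attains precision = recall =
1.0 at both levels; at default noise the residual errors are exactly the
designed ones (heavily misspelled contacts resurfacing as "new" names).

## Numerical and procedural choices

- Dedup of structured contacts merges same-patient entries whose first and
  last names both pass the acceptance rule; contact-type flags are unioned
  and relationship conflicts resolve child > spouse > parent > other >
  unknown (an artifact decision; the source does not state one).
- Fuzzy consolidation of new names processes names by descending frequency,
  merging lower-frequency variants into the first matching canonical form;
  a first-name-only span merges into a full name with an accepted first name.
- Ties in per-token contact matching break by lower contact id, then input
  order. A token equal to a caregiver-term surface is never matched as a
  name. A full-name pairing tolerates a cost tie on the surname token (two
  same-surname relatives otherwise steal each other's surname token).
- The analysis date (anchor of the 3-year provider window) defaults to the
  latest record timestamp in the corpus.
- Caregiver ids are 12-hex-digit content hashes of
  (patient id, lower-cased canonical name), so partial reruns agree.
- Degenerate inputs: empty text tokenizes to nothing; a cohort with no
  caregiver text yields an empty candidate set and a warning (the similarity
  model needs both labels); an all-zero design matrix reduces to the
  intercept-only model (probability = label prevalence).

## Limitations

The default recognizer is a rule system, not a trained model; its measured
accuracy on template text is an upper bound, not an estimate for clinical
notes. Nicknames and initials are not resolved. Relationship direction is
not inferred. Counts can be inflated by templated/copied text in real data.
Identified names are *potential* caregivers: any clinical use requires human
review.
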