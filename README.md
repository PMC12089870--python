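# carenet

Systematic identification of caregivers of people living with dementia from
the electronic health record, by merging structured "known contact" fields
with unstructured clinical text.

Caregivers — spouses, adult children, relatives, friends — are central to
dementia care but rarely have a dedicated EHR field. People listed in
structured fields (emergency contacts, health care agents, legal guardians,
portal proxies, general contacts, the transportation flowsheet) are *known
contacts*, not necessarily caregivers; meanwhile encounter notes, problem
lists, HIPAA permanent comments, and patient-portal messages mention
caregivers constantly, by name, next to relationship words. `carenet` is a
pipeline for researchers and health-system analysts who want to assemble a
caregiver-level dataset from both sources:

1. select **caregiver text** — records containing a term from a categorized
   caregiver lexicon (spouse / child / parent / other; "daughter", "dtr",
   "carer", …), after excluding records over 2^15 characters;
2. match known-contact names inside the **±5-word windows** around each term
   with an operation-cost spelling distance
   (swap = 50, append = 35, truncate = 50, insert/delete/replace = 100,
   cutoff 100), whose acceptance class is exactly: one letter replacement,
   one addition or deletion, or two disjoint adjacent transpositions;
3. discover **new names** with a pluggable person-name recognizer, excluding
   the patient, known contacts, and providers seen within 3 years, and
   scrubbing common words, place names, and medication lookalikes;
4. select likely caregivers among new names by **recurrence** (≥ 2
   occurrences near terms) and by a **logistic similarity model** —
   P(known | presence in 4 sources, adjacency to spouse/child/other terms) —
   keeping new names scoring strictly above the 10th percentile of the known
   contacts' predicted probabilities;
5. emit `caregivers.csv` (one row per unique patient–name pair, with
   structured flags, per-source counts, associated terms, selection results)
   and `summary.json` (cohort tables under both percent-of-cohort and
   percent-of-names denominators).

A seeded synthetic-EHR generator with offset-exact planted ground truth
(terms, names, misspellings, decoys) supports end-to-end evaluation; real
cohort data never ships with the package.

## Worked example

```python
from carenet import GeneratorConfig, PipelineConfig, generate, evaluate, run_pipeline

corpus, truth = generate(GeneratorConfig(n_patients=50, seed=7))
result = run_pipeline(PipelineConfig(), corpus=corpus, write_outputs=False)

s = result.summary
print("contacts:", s["cohort"]["n_contacts"], "mean/pt:", s["cohort"]["contacts_per_patient_mean"])
print("term rate encounter %:", s["term_hit_rates_pct"]["encounter"])
print("new names:", s["new_names"]["n_names"], "recurrent:", s["new_names"]["n_recurrent"],
      "model:", s["new_names"]["n_model_selected"], "both:", s["new_names"]["n_both_selected"])
m = evaluate(result, truth)
print("span P/R/F1:", m["span"]["precision"], m["span"]["recall"], m["span"]["f1"])
print("contact P/R:", m["contacts"]["precision"], m["contacts"]["recall"])
```

prints

```
contacts: 110 mean/pt: 2.2
term rate encounter %: 23.75
new names: 64 recurrent: 23 model: 35 both: 13
span P/R/F1: 1.0 1.0 1.0
contact P/R: 1.0 0.988095
```

Reading: 50 synthetic patients carry 110 structured contacts (2.2 per
patient); 23.75% of encounter notes contain a caregiver term; discovery
surfaces 64 unique new names, of which 23 recur ≥ 2 times near terms, 35
score above the similarity-model threshold, and 13 pass both rules. The
recognizer finds every planted person-name span with no false positives, and
the window matcher recovers 98.8% of contacts planted near terms — the
misses are names planted with the "heavy" two-substitution misspelling class
that the fuzzy rule is required to reject (they resurface as "new" names
instead, mirroring how a real misspelled contact would).

The same run from the shell:

```bash
carenet simulate --seed 7 --n-patients 50 --out corpus/
carenet run --corpus-dir corpus/ --out results/
```

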