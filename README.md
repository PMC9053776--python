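# noduleval

Evaluation pipeline for multi-vendor lung-nodule detection algorithms on
chest CT.

When a radiology department wants to compare commercial CAD ("computer-aided
detection") tools on its own imaging, the hard part is not running the
algorithms — it is building an objective, repeatable measurement chain
around them: selecting a study cohort from free-text reports, fusing several
radiologists' annotations into a single ground truth, deciding which
algorithm marks correspond to which true lesions, and turning the result
into defensible performance numbers. `noduleval` implements that chain for
the nodule-detection use case, working entirely on coordinates and
measurements (no pixel data), and ships a seeded synthetic-cohort generator
so every stage can be validated against known truth.

It is intended for imaging-informatics and CAD-evaluation teams who receive
algorithm output as structured files (an XML dialect or CSV, schema
included) and need nodule-level detection statistics, stratified by lesion
composition.

## The evaluation protocol

**Cohort triage.** Reports are scanned against an ordered keyword rule list
(first match wins): exclusion families (consolidation, sizeable pleural
effusion, emphysematous change, architectural distortion, prior surgery)
followed by nodule-composition keywords; the included set is sampled
uniformly to the target cohort size.

**Consensus ground truth.** Each study is annotated by three readers.
Annotations from different readers are linked when they satisfy the hit
criterion below; connected components supported by at least 2 of 3 readers
become consensus nodules with centroid center, mean average diameter
((long + short) / 2), and majority-vote attributes. Diffusely calcified
lesions are masked (vendors were told not to report them), and nodules
outside the 4–30 mm eligible window are retained but ignored.

**Hit criterion.** A detection *d* corresponds to a ground-truth nodule *g*
iff

- |Δx| ≤ 10 mm ∧ |Δy| ≤ 10 mm ∧ |Δz| ≤ 10 mm between centers (per-axis by
  default; a Euclidean ‖Δ‖₂ ≤ 10 mm mode is available), and
- their annotation boxes overlap or touch (closed intervals on all axes).

**Matching.** Per study, detections are assigned to eligible nodules by a
maximum-cardinality one-to-one matching on the hit graph (ties broken by
minimal total center distance, then lexicographically). Matched detections
are TP; extra detections of an already-matched nodule are duplicates
(counted as FP by default); detections of masked lesions leave the
accounting; everything else is FP. Unmatched eligible nodules are FN.

**Metrics.** Per vendor, overall and per composition stratum (solid,
ground-glass, part-solid):

- recall = TP / (TP + FN), precision = TP / (TP + FP),
- sensitivity = TP / (TP + FN) and specificity = TN / (TN + FP) with
  study-level true negatives,
- ROC AUC: Mann–Whitney with seeded bootstrap or Hanley–McNeil 95% CI when
  scores exist, single-operating-point AUC = (Se + Sp) / 2 otherwise.

Values are reported raw and rounded (round-half-up, 2 decimals).

## Worked example

```python
from noduleval import EvalConfig, paperlike_cohort
from noduleval.pipeline import evaluate_vendors

cohort = paperlike_cohort(seed=7)          # 100 studies, 3 readers, 3 vendors
annotations = [a for records in cohort.readers.values() for a in records]
eligible, ignored, results, counts, table = evaluate_vendors(
    annotations, cohort.vendors, EvalConfig()
)
print(f"{len(eligible)} eligible consensus nodules, {len(ignored)} masked")
overall = table[table.stratum == "overall"]
print(overall[["vendor", "tp", "fp", "fn", "recall", "precision"]].to_string(index=False))
```

prints

```
236 eligible consensus nodules, 10 masked
vendor  tp  fp  fn  recall  precision
    V1 183  23  53    0.78       0.89
    V2 183 284  53    0.78       0.39
    V3  68 114 168    0.29       0.37
```

The cohort realizes ~243 expected nodules across 100 studies (236 eligible
here, plus 10 calcified granulomas that are masked, not counted). The three
built-in vendor archetypes — conservative/accurate, sensitive/noisy, and
one nearly blind to ground-glass lesions — produce the wide performance
spread such evaluations are designed to expose: V1 pairs high recall with
high precision, V2 buys the same recall with ~12× the false positives, and
V3 misses two-thirds of the lesions.

The same pipeline is available from the shell:

```bash
noduleval simulate --seed 7 --outdir cohort/
noduleval evaluate --gt-dir cohort/readers --outdir results/ cohort/vendors/V*/*.xml
noduleval report --metrics results/metrics.json
```

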