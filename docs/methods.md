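# Methods

This note records the package's model of the evaluation task, the
parameters that matter, the design choices made where the protocol left the
design open, and what the synthetic cohorts do and do not establish about
behaviour on real data.

## Coordinate model and geometry

All computation happens in patient-space millimetres. Annotation files may
carry index coordinates (column, row, 1-based slice); these are converted
once at ingest as x = col·px, y = row·py, z = (slice − 1)·sz using the
pixel/slice spacings in the file header, and never consulted again. Matching
needs a metric space; slice numbers alone do not provide one.

Each annotation is summarized by a center and an axis-aligned box. The box
spans the long-axis diameter in x and y and the average diameter
((long + short) / 2) in z: the schema records a bi-directional in-plane
measurement but no through-plane extent, so the z-span assumes a roughly
isotropic lesion. Consensus nodules retain only the average diameter and get
a cube of that side. This box is an evaluation construct, not a segmentation;
no voxel-overlap (Dice/IoU) semantics are implied.

The hit criterion has two clauses: centers within `hit_distance_mm`
(default 10 mm) and box overlap. "Within 1 cm in all three dimensions" is
read per axis — |Δx|, |Δy|, |Δz| each ≤ 10 mm — which is the most literal
reading; a Euclidean mode (`distance_mode="euclidean"`) is provided so users
can probe how sensitive their results are to the interpretation (the
Euclidean acceptance region is strictly contained in the per-axis one). All
thresholds are inclusive: boundary behaviour has to be fixed somewhere, and
closed intervals make "overlap or intersect" include touching faces.

## Report triage

Rule matching is case-insensitive literal substring search after whitespace
and hyphen normalization, scanned in rule order with first match winning.
This mirrors a phrase-highlighting workflow, deliberately not an NLP one:
there is no stemming and no negation detection ("no consolidation" excludes
a report exactly as "dense consolidation" does), which is the right
fidelity for reproducing a keyword filter and the wrong tool for clinical
information extraction. A `re:` prefix switches a rule to regex for users
who need more. The built-in rule list covers the five exclusion families and
three composition keywords with editorial phrase variants; it is expected to
be overridden with site-specific wording. Cohort sampling is uniform without
replacement from the included set, driven by the run seed.

## Consensus

Inter-reader correspondence uses the same hit criterion as vendor matching —
the protocol defines a single proximity notion, and having two would
invite inconsistency. Annotations of one study form a graph with edges only
between different readers' annotations; connected components (transitive
closure) are candidate lesions. Components with fewer than
`min_supporting_readers` (default 2) distinct readers are dropped.

Aggregation choices, each deterministic and order-independent:

- center = member centroid; size = arithmetic mean of member average
  diameters (unbiased; median equals mean in the two-member case);
- composition, lobe and laterality by majority vote; a composition tie is
  resolved by the precedence part_solid > ground_glass > solid — favouring
  the rarer, clinically stricter class — and flagged
  (`composition_tie=True`) so it can be re-adjudicated;
- a spiculation tie resolves to spiculated (the rarer positive call);
- any member's diffuse-calcification flag masks the nodule
  (`ignored_calcified`), not a majority: vendors were instructed not to
  report these lesions, so a possibly-calcified lesion must not be allowed
  to penalize them. Calcification takes precedence over the size check.

The eligible size window (4–30 mm, inclusive) is evaluated with a 1e-9 mm
tolerance: an average diameter reconstructed from long/short axes can miss
an exact bound by a few ulps, and a lesion measured exactly at the boundary
is eligible by definition.

Ignored nodules (calcified or out-of-window) are retained in the ground
truth because they mask detections during matching; they never enter the
statistics.

## Matching

Per study, detections and eligible nodules form a bipartite hit graph. The
assignment is maximum-cardinality one-to-one matching, with ties among
maximum matchings broken by minimal total center distance and then by
(detection id, nodule id) lexicographic order. The protocol implies a fair
per-nodule correspondence but prescribes no algorithm; maximum matching is
the deterministic choice most favourable to the vendor, and a greedy
nearest-first scheme measurably differs on crossing geometries (the test
suite holds a brute-force enumerator as oracle). Implementation:
`scipy.optimize.linear_sum_assignment` on a cost matrix with non-hit cost
1e9 and a 1e-9·rank lexicographic epsilon on hit costs — the epsilon only
discriminates between exactly-equal distances, since real distance
differences dwarf it.

Order of label assignment:

1. detections hitting a masked calcified nodule are labelled
   `ignored_calcified_hit` and removed before the assignment;
2. the assignment labels pairs TP / detected;
3. leftover detections hitting an already-matched nodule are `duplicate`
   (counted as FP under the default `duplicate_policy="fp"`); leftover
   detections hitting a size-ineligible nodule are
   `ignored_out_of_range_hit` and excluded from FP by default — sub-window
   lesions were deliberately unannotated, so counting their detection
   against a vendor would measure the annotation protocol, not the
   algorithm. The switch `count_out_of_range_hits_as_fp` reverses this.

Conservation holds by construction: TP + FN = eligible nodules;
TP + FP + duplicates + ignored = detections.

## Metrics

Recall and precision are nodule-level ratios. TP and FN take the stratum of
the ground-truth nodule; a false positive has no true composition, so FP is
stratified by the vendor's predicted composition when present and otherwise
counted only in the overall row (stratum FP columns are therefore not
additive to the overall FP, which is also true of the reference tables this
package emulates).

True negatives do not exist at nodule level in a detection task. They are
defined at study level: a study contributes one TN to a stratum when it
contains no eligible nodule of that stratum and the vendor reported no
counted detection of that stratum there. This is the only reading under
which a TN column bounded by the study count is consistent, and it is the
basis of the sensitivity/specificity pair; it is config-visible and
reported alongside the raw counts.

AUC with scores is the Mann–Whitney statistic computed from tied ranks
(ties contribute 1/2), verified in the tests against exhaustive
concordant-pair counting and against `sklearn.metrics.roc_auc_score`. The
95% CI is a seeded stratified percentile bootstrap (default 2000
replicates; positives and negatives resampled separately so every replicate
is well-defined), or the Hanley–McNeil parametric interval. The percentile
interval is widened, if necessary, to contain the point estimate. Without
scores only one operating point exists and the trapezoid AUC (Se + Sp)/2 is
reported, with an optional bootstrap over studies.

Reported values are rounded half-up at 2 decimals, with the raw value
always carried alongside: half-up is the convention the reference values
follow where they are internally consistent, and carrying the raw value
makes any rounding discrepancy inspectable rather than silent.

## Synthetic cohorts

The generator emulates the statistical structure of a 100-study
nodule-surveillance cohort:

| parameter | default | basis |
|---|---|---|
| studies | 100 | cohort size of the emulated evaluation |
| nodules/study | Poisson(2.43) | 243 expected nodules per 100 studies |
| composition mix | 127/243, 76/243, 40/243 | solid / ground-glass / part-solid |
| size law | log-normal per composition, clipped to [4, 30] mm | medians 4.77 / 6.05 / 8.85 mm, IQRs 1.80 / 2.78 / 4.51 mm |
| calcified granulomas | Poisson(0.09)/study | ~8 detected granulomas per 100 studies at vendor detection rates 0.4–0.6 |
| lobe distribution | 63/52/16/45/61/6 over RUL/RLL/RML/LUL/LLL/lingula | cohort feature table |
| spiculation | 9/243 | cohort feature table |
| reader jitter | σ = 2 mm | well below the 10 mm hit distance |
| reader miss probability | 0.1 per reader per nodule | plausible single-reader miss rate for small nodules |
| vendor localization | σ = 1 mm | CAD centroid error, smaller than inter-reader variability |
| inter-nodule spacing | ≥ 25 mm | makes matching unambiguous so closure tests are exact |

Notes on these choices:

- σ parameters are the standard deviation of the **3D displacement
  magnitude** (per-axis σ/√3). Under this convention two readers of the
  same 4 mm nodule overlap with probability ≈ 0.96 per pair, and consensus
  clustering recovers the majority-visible nodule count on ≥ 99% of
  studies — which is what a 2 mm "localization variance that does not
  destroy clustering" should mean. A per-axis reading of the same number
  breaks box overlap for ~40% of same-lesion pairs at the 4 mm size floor
  and is therefore not what is modelled.
- The log-normal σ per composition is derived from the median/IQR pair via
  σ_ln = asinh(IQR/2m)/z₀.₇₅, making the generator's medians and spreads
  match the emulated cohort by construction. Clipping to [4, 30] mm puts an
  atom of probability at exactly 4.0 mm (about a quarter of solid
  nodules), which exercises the size-window boundary.
- The calcified stream is an independent Poisson added on top of the 2.43
  annotatable nodules per study, so the expected eligible count stays 243
  exactly.
- The three default vendor profiles use the reference stratified counts as
  exact detection probabilities (e.g. 105/127 for vendor 1 on solid) and
  the reference FP totals as per-study rates (0.23, 2.70, 1.20), plus
  calcified-detection probabilities 0.4/0.5/0.6 matching the 3/4/5
  granulomas the three emulated systems reported.
- Readers copy the true size, composition and attributes (jitter applies to
  position only); vendors copy the true axes. Truth bookkeeping records
  which readers annotated each nodule and every detection's origin, so
  recovery tests compare against exact per-cohort truth rather than
  expectations.

What the generator does **not** emulate: pixel data and image appearance;
reader measurement noise and reader disagreement on composition or
attributes; scanner/protocol covariates; spatially clustered lesions
(beyond the optional `hard_mode` spacing reduction); report text beyond the
keyword templates used in triage tests. Consequently, passing closure and
recovery tests shows the *measurement chain* is correct — clustering,
matching, counting and interval arithmetic do what they claim with known
truth — and says nothing about the detection difficulty of real lesions or
real inter-reader behaviour.

## Problem sizes in the test suite

The suite exercises parameter recovery at 500 studies (≈1200 nodules, one
vendor), consensus recovery over 20 seeds × 100 studies, matching-oracle
equivalence on 1000 random instances up to 6×6, and exhaustive AUC checks
over all ≤12-observation instances on a three-level score grid plus all
≤10-observation label patterns with distinct scores. These sizes give the
binomial/Poisson recovery intervals useful width (99% central intervals)
while keeping the whole suite around ten seconds.

## Known limitations

- The XML element vocabulary is this package's own concrete rendering of a
  schema whose published form enumerates content, not element names;
  interoperability with other dialects is via the CSV mirror or a thin
  adapter.
- Matching operates on centers and boxes only; overlapping or bilobed
  lesions closer than the hit distance can legitimately be merged by
  consensus or cross-matched, which is why the generator's closure tests
  enforce spacing and real evaluations should review flagged clusters.
- Single-operating-point AUC is a coarse summary; with no vendor scores the
  ROC curve is unobservable and the reported value is exactly (Se + Sp)/2,
  not an estimate of a richer quantity.
- Study-level TN depends on the cohort's stratum occupancy and is not
  comparable across cohorts with different prevalence.
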