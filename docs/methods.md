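# Methods

## Problem and data model

The package classifies dyadic social behaviour of group-housed gestating
sows from the output of posture/key-point image analysis. The unit of
analysis is an **event window**: ten annotated images sampled at 0.5 s
intervals around one event — four before (phases B1–B4), the start (S)
and end (E) images, and four after (A1–A4). Non-interaction windows have
the same shape (phases N01–N10). Each image carries, for the two sows of
the observed pair, a posture in {standing, sitting, lying} and the
planar coordinates of nose, neck and tail.

Three *period views* slice a window by frame position: before = frames
1–5, during = frames 5–6, after = frames 6–10. For interaction windows
these coincide with B1–B4+S, S+E, and E+A1–A4. The source defines no
periods for non-interaction windows; the same positional convention is
applied symmetrically so that every window yields the same feature rows.

Sow 1 / sow 2 within a pair is an arbitrary designation (not
initiator/recipient), which is why classification rules can reference
role-specific quantities such as `d_travelled_sow2` even though the
roles carry no semantics.

### Units and calibration

Internal canonical units are meters and seconds; every decision
threshold is in m or m/s. The annotation CSV stores pixel coordinates;
`CalibrationSpec.pixels_per_meter` (user-supplied — no fixed factor is
assumed) is applied at ingest and inverted on write. Timestamps are
authoritative for durations of annotated windows, since annotated frames
are 0.5 s apart rather than consecutive video frames (the native video
rate, 12 fps, is retained in `CalibrationSpec` for raw-footage uses).

## Features

Per period view:

- **AvgD** — arithmetic mean of the per-image Euclidean distance for
  each of five key-point pairs (nose1–nose2, nose1–neck2, nose2–neck1,
  nose1–tail2, nose2–tail1).
- **D_evolution** — last-image distance minus first-image distance;
  the only signed feature (negative ⇔ convergence).
- **Speed** — unsigned rate of change of a pairwise distance. The
  underlying "distance travelled" of a point pair is ambiguous; the
  default (`endpoint`) mode reuses the defined quantity
  |D_evolution|/duration, and a `cumulative` mode
  (Σ|Δd between consecutive images|/duration) is available behind
  configuration. Cumulative ≥ endpoint always holds and is pinned by a
  test. Speeds are reported unsigned because every published speed
  threshold is positive and compared with ">".
- **D_travelled_sowK** — straight-line nose displacement of one sow
  between the period's first and last image.
- **Posture proportions** — per-sow occupancy of each posture (sums to
  1), pooled occupancy over the 2n sow-images, plus two pair-level
  summaries bound by the decision rules: `prop_any_standing` (fraction
  of images with at least one standing sow; the presence rules' "%
  standing", glossed in the source as "at least one was active") and
  `prop_both_lying` (fraction with both sows lying; the valence rule's
  "percentage of images showing both paired sows lying").
- **duration** — last minus first timestamp (2.0 s before/after, 0.5 s
  during).

All features are invariant to translation and rotation of the
coordinate frame; distances, evolutions, speeds and displacements scale
linearly with a global rescaling while proportions and durations do not.
Both properties are enforced by property tests.

## Published decision rules

Each (step, period) classifier is a published depth-≤3 decision tree.
They are shipped as an ordered **decision list** in
`data/published_rules.yaml`: each branch is a conjunction of
`feature <op> threshold` conditions with an outcome label, evaluated
first-match, with a default label for the remainder. This routing is
equivalent to the tree form, makes totality hold by construction, and
keeps thresholds as audited data rather than code.

Boundary convention: comparisons are exactly as printed (strict where
the text is strict); a value exactly equal to a strict threshold fails
the condition and falls through. Every threshold's boundary behaviour is
pinned by a dedicated test.

Three printed ambiguities had to be resolved:

1. *Presence/before, third branch* — "D_travelled_nose2_tail1 below
   −0.3 m" names a per-pair travelled distance that the feature calculus
   never defines (D_travelled is per sow). With its negative threshold it
   can only be the signed nose2–tail1 distance evolution, and it is bound
   to `d_evolution_nose2_tail1 < −0.3`.
2. *Presence/after, residual branch* — the printed sub-branches ("when
   D_evolution_nose1_nose2 was below 0.13 m … higher than 0.14 m") are
   internally contradictory and unreachable as printed. They are not
   implemented; the classifier keeps only the two consistent interaction
   branches and the default.
3. *Orientation/during* — the printed nose-tail condition ("below
   1.7 m") overlaps the nose-neck band (0.75–1.7 m); it is read as
   "above 1.7 m", the only reading that partitions the feature space.
   In *orientation/after*, the overlapping close-range clauses are
   ordered with the low nose2–tail1 clause first (mirroring the tree
   structure), and the one region the text never assigns (far apart,
   little nose-nose divergence, growing nose2–tail1 distance) falls to
   nose_tail, symmetric with the close-range subtree.

## Retraining (CART)

The retraining pipeline mirrors the original analysis: a PCA on the
standardized explanatory variables (reporting only — eigendecomposition
of the correlation matrix, loadings as variable–component correlations),
removal of collinear variables, a stratified 80/20 split, and a
depth-limited classification tree.

- **Collinearity screening** operationalizes the original
  loading-inspection step as a greedy pass in priority order (the
  variables the published trees split on first): a candidate is dropped
  when |Pearson r| ≥ 0.8 (default) with an already-kept variable. On
  generated data this reproduces the original exclusions (the
  D_evolution neck variants and AvgD neck variants fall to their
  nose-nose counterparts).
- **Split**: per class, round(0.8·n) rows to training, seeded and
  reproducible; both sides non-empty per class.
- **Tree learner**: greedy binary recursive partitioning maximizing the
  Gini impurity decrease; candidate thresholds at midpoints between
  consecutive sorted unique values; `value ≤ threshold` routes left;
  ties between equal-quality splits go to the first-listed feature and
  the smallest threshold; stopping on max depth (default 3), node
  purity, or a minimum leaf size (default 5); leaf label = majority
  class (ties to the lexicographically first). No pruning — the depth
  cap is the only regularizer, with `tune_depth` selecting among depths
  1–5 by held-out accuracy (ties to the smallest depth). The learner is
  hand-written because these conventions are contractual and the model
  file serializes the exact structure; scikit-learn's
  `DecisionTreeClassifier` acts as an independent cross-check in the
  test suite, and an exhaustive enumeration oracle verifies root splits.
- **Model files** are nested YAML (feature, threshold, children, class
  counts) and load back into the same `classify` path as the published
  rules.

## Evaluation

One-vs-rest confusion counts per modality; sensitivity TP/(TP+FN),
specificity TN/(FP+TN), precision TP/(TP+FP), F = harmonic mean of
precision and sensitivity; global accuracy = correct/n (for a single
one-vs-rest table, (TP+TN)/n). The per-period "global F-score" is
reported as the unweighted (macro) mean of per-modality F-scores — the
aggregation most consistent with the reported values lying between the
per-modality ones — with a frequency-weighted variant available.
Metrics with zero denominators are reported as explicit nulls, never
coerced to 0, and are excluded from macro averages. Cohen's kappa uses
the standard (p_o − p_e)/(1 − p_e) with marginal-product chance
agreement; it is undefined (NaN) when both raters are constant and
identical.

## Synthetic generator

The generator replicates the annotation study design — 120 positive and
120 negative interactions plus 120 non-interaction moments, 10 frames at
0.5 s, in a 7.5 m × 8.0 m pen — with surrogate kinematics. No
quantitative movement distributions were published, so all parameters
are truncated normals chosen once so that class-conditional features
straddle the published thresholds; they are package parameters, not
measured values, and all are overridable.

Geometry: bodies are rigid three-point chains (nose–neck 0.6 m,
neck–tail 1.0 m, small heading jitter). An interaction places the
recipient at the origin and the initiator's nose approaching the
orientation's target key point — frontal for nose–nose, perpendicular at
the neck for nose–neck, from behind for nose–tail — from a pre-approach
separation of truncnorm(1.6, 0.3) m (bounds 1.0–2.5) down to a 0.15 m
contact distance at S. The initiator stands throughout (per the
ethogram); the recipient's posture is sampled (0.4/0.2/0.4). Negative
interactions add a lateral lunge of ~0.55 m at E with a ~0.35 m
recipient recoil, then a post-event separation at truncnorm(0.6,
0.12) m/s split 70/30 between recipient flight and initiator retreat.
Positive interactions end with a slow withdrawal (truncnorm(0.05,
0.03) m/s) and a near-stationary recipient (drift ≤ 0.35 m).
Non-interactions draw one of three ethogram configurations: both sows
lying side by side (static, bodies ~0.45 m apart), static proximity at
1.0–3.0 m (never both lying), or distant (3.2–6.2 m) independent slow
wandering (≤ 0.2 m/s). Gaussian coordinate noise (sd 0.01 m) is added
and the scene is randomly rotated and placed inside the pen; points are
clipped to the arena. The sow-1/sow-2 role assignment is randomized per
event, as in the annotation protocol. Orientations are drawn from the
observed 119/68/53 composition.

`effect_scale ∈ [0, 1]` multiplies every class-specific displacement
(approach closing, lunge, recoil, flight, withdrawal); at 0 interactions
become static pairs indistinguishable from non-interactions and
presence detection collapses to chance — the monotone-degradation tests
rely on this.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: key-point detection error structure
(occlusion, identity switches, non-Gaussian outliers), curved or
hesitant approach paths, posture transitions within a 5-s window,
multi-sow scenes, pen furniture, and any correlation between posture and
movement beyond the ethogram constraints. End-to-end accuracies on the
replica dataset (≈0.97 presence-before, ≈0.97 valence-after, nose-tail
F ≈0.98, seeds 0–1) exceed the reported real-data performances (0.88,
0.80, 0.94) precisely because the surrogate kinematics are idealized;
they validate the pipeline's internal consistency, not field
performance. The before-period valence rules sit near chance on
generated data (as they nearly do on real data, 59 %), since the
generator gives positive and negative classes identical pre-contact
approaches.

## Numerical choices and degenerate inputs

- Distances via `math.hypot`; impurity computations in float64 with a
  1e-12 tie tolerance on split quality.
- A node with no impurity-reducing split becomes a leaf (a constant-
  feature or balanced-XOR table yields a single-leaf tree, not an
  error).
- Feature extraction refuses empty or single-frame sequences where the
  operation is undefined (means need ≥1 frame, evolutions/durations ≥2,
  speeds positive duration).
- CSV round-tripping serializes coordinates at six decimals; reads
  validate the two-rows-per-image contract, label vocabulary, shared-
  label consistency within an image, and strict timestamp ordering, each
  with a dedicated error type.
- Problem sizes in the shipped tests and acceptance script (360-event
  replica datasets, 10 000-vector fuzzing, 100 random CART tables, 20
  recovery seeds) complete in well under a minute; they were chosen as
  the smallest sizes at which the checked properties are stable.

## Known limitations

- The published-rule engine classifies per annotated event window; it
  does not scan continuous recordings with a sliding window.
- "Distance travelled" in the speed formula, the %standing binding, the
  Step-1-after residual branch and the during-orientation overlap are
  resolved interpretations (documented above), not printed facts.
- The retrained trees are only as good as the synthetic data they are
  fitted to; no claim is made that retraining on this generator
  transfers to real pens.
- Lying is a single posture class; lateral vs sternal recumbency (which
  affects whether a lying sow can interact) is not modelled.
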