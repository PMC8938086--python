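# Methods

## Adaptive median filter

The filter operates per pixel on the original image only (no in-place
propagation), so its output is independent of scan order. Windows are
square (`m = n`), start at `initial_size = 3`, and grow by 2 per side per
Level-A failure up to `s_max = 7`; both defaults are package choices — the
clinical description names no sizes — and both are arguments everywhere.
All inequalities are strict ("greater than 0"), so a tie (e.g. a constant
window, or a median equal to the window minimum) triggers enlargement.
Borders are handled by edge replication so every pixel sees a full window.

Two consequences of the strict rule are worth knowing:

* A lone impulse on a *perfectly constant* background is never removed:
  every window's median equals the background, hence equals the minimum or
  maximum, Level A never passes, and exhaustion emits the centre value
  `Z_xy` unchanged. Real speckled backgrounds do not hit this degenerate
  case, and a window containing both a salt and a pepper pixel always
  clears Level A.
* The output-closure invariant holds: every output pixel is an element of
  the (padded) input, because the median of an odd-cardinality window is a
  member.

The vectorised implementation computes per-window-size min/median/max maps
with `scipy.ndimage` and resolves the per-pixel window growth by masking;
the test suite checks it pixel-for-pixel against an independent pure-Python
per-pixel implementation on random images.

Rotation by multiples of 90° uses exact array rotation (no interpolation),
so composition identities like "90° twice = 180°" hold bit-exactly;
arbitrary angles interpolate bilinearly and clip to [0, 255].

## Segmentation evaluation

VOE is a symmetric pseudo-metric on binary masks; two empty masks are
defined as identical (VOE 0, with a warning) since the union is empty.
"Highest reliability" among k annotators is operationalised as minimal mean
pairwise VOE, ties broken toward the lowest annotator index; the selected
gold standard is always a member of the input set. Confusion metrics are
pixel-level. Average precision is computed exactly as the trapezoid sum
over an explicit, recall-sorted point list; sweeping thresholds to produce
the list is the caller's job. Precision/recall with zero denominators are
reported as undefined (`None`), never as 0.

## Modality rules and fusion

The three single-modality rules are deterministic thresholds on ordinal
scores, and the multimodal rule is a strict AND on malignancy. The
benign/malignant assignment of *non-characteristic* CEUS
enhancement/washout is ambiguous in the clinical description; this package
groups it with "not observed" (the benign side) by default and exposes
`noncharacteristic_benign=False` for the opposite grouping.

A structural note the simulated cohort makes visible: AND-fusion can only
raise specificity and lower sensitivity relative to its inputs when the
three modalities err independently. The high *published* multimodal
sensitivity therefore cannot emerge from these rules plus independent
per-modality feature noise; reproducing the published diagnostic numbers
is done from the published contingency cells (the reproducible surface),
not from the simulation.

## Diagnostic and agreement statistics

2×2 tables take malignant as the positive class and biopsy pathology as
truth. Sensitivity, specificity and accuracy are reported as percentages
rounded half-up to 2 decimals (matching the printing convention of
clinical tables) with raw fractions alongside; `accuracy × total = TP + TN`
exactly before rounding. Cohen's κ is `(p_o − p_e)/(1 − p_e)` from the
table margins, with bands poor (< 0.45), good ([0.45, 0.70)), satisfactory
(≥ 0.70); degenerate margins (`p_e = 1`) yield undefined. Chi-square is
Pearson's without continuity correction by default (none is mentioned in
the source analyses; a flag enables Yates); Fisher's test is the two-sided
exact hypergeometric p-value. Both delegate to `scipy.stats` behind the
module surface and are cross-checked in tests against a literal
Σ(O−E)²/E loop and a full enumeration of tables with fixed margins.

## Published-table replay

The printed diagnosis blocks and expression counts are shipped as fixtures
and every derivable statistic is recomputed from them. Several printed
values are internally inconsistent and are deliberately *flagged, not
matched*: the Doppler sensitivity (57.69 % printed vs 16/26 = 61.54 % from
its cells), the multimodal sensitivity (88.87 % vs 24/27 = 88.89 %), all
four κ values (0.46/0.49/0.48/0.68 printed vs 0.25/0.18/0.26/0.76 from the
cells), the Doppler "malignant total" (22 printed vs 16 + 4), the p57
lesional row (49 + 34 = 83 specimens against a stated n = 79, printed rate
40.04 %), and both expression χ² statistics (8.23 / 8.13 printed vs 78.0 /
44.7 from the counts). The EZH2 "control n = 79" header is read as the
n = 39 its own cells (35 + 4) and the stated control-group size give.

## Synthetic-data generator

The generator's defaults are the study conditions, fixed once:

* **Cohort**: 100 patients in four arms of 25; P(single lesion) = 0.74,
  multiple-lesion patients draw their count uniformly from {2, 3, 4}
  (mean 3), giving 152 expected lesions; per-lesion malignancy probability
  110/152; malignant grade probabilities 49/40/21 over poorly / moderately /
  highly differentiated; lesion diameters uniform on [0.8, 3.0] cm.
* **Imaging features**: per-grade probabilities of the malignant-typical
  category default to the observed frequencies (e.g. irregular shape
  0.7959 / 0.70 / 0.3333 for poor / moderate / high differentiation). The
  flow-grading percentages (0.9592 / 0.90 / 0.6667) are read as
  P(flow grade 2–3) per grade — the source sentence is garbled and this
  monotone-decreasing reading is the package's choice. Benign-lesion
  probabilities are not reported anywhere; the defaults here are package
  assumptions (a mild complement pattern: mostly regular / clear /
  homogeneous, low flow, soft, no washout) and every entry is
  config-overridable.
* **IHC**: group sizes 79 lesional / 79 perilesional / 39 normal; EZH2
  positivity 60/79, 12/79, 4/39; p57 perilesional 63/79 and normal 37/39
  from the consistent printed counts, lesional 34/79 as the closest
  consistent reading of the defective printed row; per-grade positivity
  (EZH2 0.5526/0.5385/0.5333, p57 0.1683/0.2059/0.8079) drives a separate
  graded-specimen generator over the 38/26/15 case split.
* **Phantoms**: two-level ellipse or radially-perturbed blob; speckle as
  mean-1 multiplicative log-normal noise, long-tail noise as salt-and-pepper
  with equal salt/pepper probability. No physical B-mode acoustics, CEUS
  time-intensity curves, or histology images are simulated.
* **Annotators**: integer boundary shifts plus dilation/erosion scaled by
  the jitter parameter (non-identity enforced when jitter > 0); an outlier
  annotator displaces the lesion by half the image.

All generators draw from per-stream children of one seed
(`numpy.random.SeedSequence.spawn`), so stages can re-run independently and
identical config + seed is bit-identical everywhere.

What passing tests on this synthetic data do **not** show: recovery of the
published per-arm diagnostic numbers from the simulation (see the fusion
note above), realism of speckle statistics, inter-feature correlation
within a lesion (features are sampled independently given grade), or
anything about the excluded trained segmentation network.

## Problem sizes and numerical choices

Oracle-equivalence checks run on random images up to 32×32 (50 images ×
three window configurations), denoising checks on twenty 64×64 phantoms at
impulse densities 0.05–0.2, and parameter-recovery checks on ~10,000
generated lesions and ~20,000 IHC specimens — sizes at which binomial
standard errors make 3-SE bands decisive while the whole suite runs in
seconds. AP equivalence against numerical trapezoid integration is asserted
at 1e-12; percentage rounding is half-up to 2 decimals throughout.

## Known limitations

* The pipeline accepts one findings record per lesion; the two-reader
  adjudication used clinically is a human process outside its scope.
* The trained segmentation network behind the source study's segmentation
  accuracy figures is out of scope (no released weights or images); only
  its evaluation arithmetic is implemented and validated.
* Per-field IHC counting (five ×400 fields, 120 cells each) is metadata
  only; scores are inputs, not measured from images.
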