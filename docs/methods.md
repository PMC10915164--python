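# Methods

## Generative model of a recording

A recording is a renewal process on a single reactive site. With analyte
concentrations C_i (mM) and calibration coefficients k_i
(events·mM⁻¹·ms⁻¹), captures arrive at total rate λ = Σ k_i·C_i per ms;
open intervals are Exponential(1/λ), the captured class is drawn with
probability k_i·C_i/λ, the event sub-state by its weight, and the dwell is
Exponential(τ_i). Because the site holds one molecule at a time, events
never overlap (exclusive occupancy) and event features are independent of
concentration; only the rate carries C. An optional background stream adds
non-clustered noise events: blockage ratio uniform on (−0.9, 0.9),
log-uniform dwell on (5, 500) ms, Gaussian intra-event noise.

Within an event the current is I₀(1 + r) plus intra-event noise; open-pore
samples are I₀ plus Gaussian baseline noise (sd 2 pA). The trace is
optionally low-pass filtered with a zero-phase 4-pole Bessel filter at the
spec corner (default 1 kHz) and sampled at the spec rate (default 25 kHz);
zero-phase filtering was chosen so that event edges are smeared
symmetrically rather than delayed, keeping detected boundaries unbiased.

### Intra-event noise: sinh–arcsinh Gaussian

Intra-event noise is σ_e·(S − E[S]) with
S = sinh((arcsinh(Z) + ε)/δ), Z standard normal. The two shape parameters
give independent, closed-form control over skewness (ε) and tail weight /
kurtosis (δ): ε = 0, δ = 1 is exactly Gaussian; raw moments come from the
Jones–Pewsey Bessel-function formulas and are verified against numerical
quadrature in the test suite. The draw is **centred** (analytic mean
subtracted) so that the mean blocked current is exactly I₀(1 + r) and the
generating blockage ratio r is identifiable from the ratio feature; central
moments, hence the std/skew/kurt signature, are unaffected by centring.

### The default panel

Eleven target classes (CAT, 3-CQA, D-SOR, XYL, L-MA, D-MA, L-TA, CA, ICIT,
D-GLC, D-FRU) plus, on request, four unknowns (sucrose, U1–U3) and the
background pseudo-class. Category rules are enforced as invariants:
α-hydroxy acids strictly positive-going, diphenols/alditols/saccharides
strictly negative-going, exactly one sub-state per class except the
saccharides (≥ 2 sub-states, e.g. D-GLC at r = −0.52/−0.60). Blockage-ratio
means are spaced ≥ 0.06 apart against a ratio jitter sd of 0.004, i.e.
adjacent classes sit ≥ 4 pooled sd apart in the ratio feature alone, with
ε/δ varied so the moment features differ too; the enantiomer pair
L-MA/D-MA (+0.18 vs +0.24) is comfortably resolvable. Mean dwells are
25–50 ms and k values 1.2×10⁻⁴–8×10⁻⁴ events·mM⁻¹·ms⁻¹, so that mixtures
at single-digit-mM concentrations stay below ~20 % occupancy. These
constants are documented fixtures designed for sign structure,
multimodality and separability; they are not fitted to, and do not claim to
reproduce, any measured analyte's numbers.

### The feature-space sampler

`simulate_features` emulates a labeled training deposit without simulating
currents: ratio ~ Normal(r, 0.004); std/skew/kurt are the analytic
sinh–arcsinh values plus Gaussian sampling jitter at the classical
large-sample standard errors (sd·√((κ−1)/4n), √(6/n), √(24/n)) with n the
sample count implied by the dwell at nominal 25 kHz; dwell is
Exponential(τ) conditioned on > 10 ms (memorylessness: 10 + Exp(τ)).
Note these are the moments of the *unfiltered* noise law: feature rows from
this sampler and feature rows extracted from low-pass-filtered traces agree
in ratio and dwell but differ in the moment features (filtering shrinks std
and pulls skew/kurt toward Gaussian). Workflows therefore never mix the two
routes across a train/test boundary: trace-based experiments train on
trace-derived features, exactly as the real workflow trains on measured
sole-analyte recordings.

## Event idealization

`estimate_baseline` is an iterative robust running median: block-decimated
median (numerically a running median for windows ≫ block, O(n)), samples
deviating > 4 scaled-MAD masked, re-estimated until masks stabilize (≤ 10
passes). The masking is seeded from the *global* median level — the open
pore dominates the recording overall — otherwise a window locally
majority-filled by a long blockade inverts the mask and the level tracks
the blockade. The default window is 500 ms: it must comfortably exceed
typical dwells so blockades are masked rather than followed. On very long
traces the robust statistics are computed on strided subsamples (capped at
2×10⁶ points), which changes them only at the 10⁻³ level.

`detect_events` opens an event where |current − level| > 4·noise_sd and
closes it below half that threshold (hysteresis 0.5), reporting both
polarities. Boundaries are then refined to the first/last crossing of half
the event's own median amplitude — the usual single-channel convention.
Without refinement, correlated post-filter baseline noise occasionally
rides above the low hysteresis level just before an edge and glues ~1 ms of
noise onto the event; with it, boundary error against ground truth is
~0.01 ms and recall of clear events (dwell > 12 ms, amplitude > 6 noise sd)
is ≈ 99.3 %. The residual misses are pairs of events separated by a
sub-millisecond gap that any threshold idealizer merges. The dwell filter
keeps events strictly longer than 10 ms ("more than 10 ms" read literally:
an event of exactly 10.00 ms is dropped).

## Feature extraction

Moments are bias-uncorrected central moments over the event interior:
std = √m₂ (denominator n, in pA — not on normalized current),
skew = m₃/m₂^1.5, kurt = m₄/m₂² (Pearson convention, Gaussian = 3); a
zero-variance interior reports skew 0 / kurt 3 with a warning. I₀ local to
each event is the baseline level averaged over a 50 ms pre-event window, to
tolerate slow drift. The interior excludes 2 ms at each boundary: the 1 kHz
filter edge itself settles in ~1 ms, but the detector opens up to ~0.6 ms
*before* the true edge on large events, and kurtosis is sensitive enough
that even a 10⁻² residual of the transition visibly inflates it; 2 ms
leaves the residual below 10⁻³ of the step. The median current is computed
and stored but is not part of the five-feature ML vector.

## Classification

`BaggingClassifier` over unpruned axis-aligned decision trees, 30 bootstrap
learners by default, majority vote with ties resolved toward the
lexicographically first class; no feature scaling (tree splits are
scale-invariant), and saccharide events carry the single analyte label —
the ensemble absorbs the multimodality. Validation is stratified 10-fold
cross-validation with pooled accuracy; stratification matters because the
reference set sizes are imbalanced (100 events for CA vs 1000 for the
saccharides). Training rows are put into a canonical (label, features)
order before bootstrap and fold seeding, so results are invariant to input
row order at fixed seed. `compare_models` runs decision tree, LDA, Gaussian
naive Bayes, RBF-SVM, k-NN, the bagged ensemble and a small MLP on
identical folds (scaling applied inside the pipelines that need it).

## Screening cascade

Features are min–max scaled to the frozen training reference — the DBSCAN
radii (ε = 0.17/min_samples = 18 for fresh juice, 0.1/10 for kiwifruit,
0.3/30 for commercial juice) are dimensionless and only meaningful in a
normalized space; probes outside the reference range are not clipped. Both
DBSCAN passes (denoising and unknown discovery) run on the
(ratio, std) plane, where cluster structure is defined in this assay; the
one-class SVM uses all five features, RBF kernel with variance-scaled
bandwidth, ν = 0.05. Unknown clusters are registered U1, U2, … by
descending size (ties by first row index); unclustered outliers are
discarded. `match_cluster` declares a cluster consistent with a separately
measured reference analyte when ≥ 50 % of its events fall inside a
one-class boundary fitted to the reference.

A structural property of this cascade worth knowing: the ν-tail of each
*known* class (the ~5 % of its events outside the one-class boundary) sits
at the class's own (ratio, std) location, and in samples of ≳ 1500 events
those fringes can exceed min_samples and be registered as small spurious
"unknown" clusters (a few % of events in total). A class's own one-class
model rejects its ν-tail too, so reference matching cannot reabsorb them.
Quantities defined over the real analyte classes (the end-to-end demo's
proportions) are therefore compared after renormalizing over those classes,
with the diverted share reported and bounded separately.

## Quantification

C_i = E_i/(k_i·t) with t the *total* recording time, and k_i the
through-origin least-squares slope k = Σ(C·r)/Σ(C²) of rate r = E/t versus
C (a zero-concentration sample produces no events, so no intercept). Using
total rather than open-pore time biases rates low by the occupancy factor
1/(1 + λτ̄); at < 20 % occupancy this stays under ~10 %, and because the
calibration and the assay share the counting pipeline (including the
dwell-filter attrition e^(−10/τ)), the bias largely cancels in a round
trip. The residual systematic is the *spread* of occupancy across the
calibration range, which the fit averages with C² weights — the round-trip
benchmark uses the panel's lowest-k·τ analyte (XYL) so this tilt stays
near 4 %.

## Reference experiments and problem sizes

The benchmarks module fixes the study conditions shared by the test suite,
the acceptance script and the examples:

* detector recall: 100 × 60 s traces at 25 kHz, three-analyte mixture
  (λ ≈ 0.0026/ms) plus background; ~10⁴ eligible events;
* classifier fixture: reference set sizes (500 × 7 classes, 1000 × 2
  saccharides, 100 CA = 5600 training / 1120 test events; + 500/100 D-MA
  for the 11-class roster);
* novelty ν-check: 2000 training events, 200 per class;
* unknown discovery: 1350 known + 150 U1 events (10 %);
* quantification: XYL at 0.5/1/2/4 mM, 4000 dwell-filtered events per
  point, traces at 2.5 kHz simulated unfiltered in ~2400 s chunks (the
  count is insensitive to the anti-alias filter, and chunking keeps peak
  memory modest);
* concentration invariance: L-TA at 2 and 20 mM, ~2000 events each at
  5 kHz, features extracted at ground-truth boundaries (so the comparison
  isolates the generative law + feature extraction from rare
  detector-merging artifacts, which the recall benchmark covers);
* end-to-end demo: five analytes at equal capture rates (λ_total =
  0.01/ms) + 5 % background, ~1600 analyzed events at 10 kHz; classifier
  and novelty model trained from per-class calibration traces.

Sampling rates below 25 kHz are used where only counts or low-order
statistics are measured; every TraceSpec still satisfies
rate > 2 × filter corner.

## What passing tests do and do not show

The generator reproduces the *structure* the analysis relies on — exclusive
occupancy, rate ∝ concentration, feature/concentration independence, event
polarity by chemical class, saccharide multimodality, non-clustered
background — with class separations chosen to be clean. Passing the suite
therefore demonstrates that the pipeline is correct and well-calibrated
under that structure; it does not certify accuracy figures on real
recordings, where class overlap, baseline drift, open-pore gating and
pore-to-pore variability are larger. Known limitations: no multi-level
sub-state idealization within one event (sub-states surface only through
the moment features); no modelling of boronate-ester kinetics, pH or
voltage dependence; quantification carries the occupancy bias discussed
above and no matrix-effect correction; the ν-tail clustering effect above
is intrinsic to screening at fixed ν and DBSCAN presets.
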