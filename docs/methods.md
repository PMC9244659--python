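# Methods

This note documents the models, the synthetic data, the numerical choices and
the known limitations of the package. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## Input representation

Each encounter becomes a 51 × 64 matrix: row 0 normalized age, rows 1–2
male/female indicators, rows 3–26 the 24 time-varying features (7 vitals, 16
labs, and the computed SIRS score), rows 27–50 the paired availability masks.
Columns are 64 consecutive 20-minute bins whose right edge is the prediction
time, so the model can never see past it. Within a bin the most recent
measurement wins — the snapshot semantics of an EHR flowsheet; the choice is
otherwise arbitrary and is documented here rather than inferred from data.
Histories shorter than 64 bins are zero-padded on the left (mask 0), longer
ones truncated to the most recent 64.

Normalization is deliberately coarse: for each feature the center of the
adult clinical normal range approximates the mean and half the range width
the SD (`src/ardsmtl/data/normal_ranges.yaml`, version 1), so matrix entries
read as z-scores against a healthy reference. Missing cells are zero with
mask 0. Age has no laboratory range; it uses μ=50 y, σ=20 y. SIRS (a 0–4
count of abnormal temperature, heart rate, respiratory rate and white-cell
criteria, strict inequalities, missing components contributing nothing) is
recomputed per bin from forward-filled components; its pseudo-range 0–2
centers the score at 1. Its mask is 1 from the first bin in which any
component has been observed. The PaCO₂ and immature-band alternatives of the
classic SIRS definition are omitted because those inputs are not collected.

**Prediction time ("algotime").** One prediction per encounter, 40 minutes
after the first moment every required feature (age, sex, blood pressures,
heart rate, respiratory rate, SpO₂, temperature, WBC, lymphocytes,
creatinine, neutrophils) has been measured at least once. Training and
validation records missing a required feature default to admission + 8 h;
test records are excluded instead, so held-out evaluation only sees complete
encounters.

## Outcome labels

Thirteen binary targets per encounter: five ARDS variants (diagnosis code,
optionally with a stay-wide SpO₂ nadir below 91% or 96% and/or no heart
failure code prior to the first ARDS code), two sepsis variants (code alone,
or code plus maximum stay-wide SIRS > 2), four hypoxemia variants (below
91%/96%, any time or strictly after the prediction time), in-hospital death,
and COVID-19 (positive in-stay PCR or a COVID code within ±7 days of
admission). Thresholds are strict ("below 91%" means < 91). The SpO₂ nadir
for the ARDS variants is stay-wide; no time restriction relative to the
diagnosis code is applied. An ARDS code entered exactly at the prediction
time counts as *late* (the prediction cannot have preceded it).

Eight implications follow structurally (e.g. a <91% dip implies a <96% dip
with the same code requirement) and are enforced as invariants on 10,000
generated encounters.

## The recurrent attention network

Inputs pass through a learned elementwise normalization `a·(v−μ)/σ + b`
(σ parameterized as `exp(s)` so it stays positive), then a stack of GRU
layers (library default: 4 layers × 128 hidden units) over the 64 timesteps.
A soft attention module scores each deepest-layer hidden state h_i against
the final state h_n as `Kᵀ tanh(W_a PReLU(W_b [h_n, h_i]))`; scores are
softmax-normalized over all 64 steps, padded steps included — padding columns
are all-zero and the network may learn to down-weight them, but they are not
masked out. The attention-weighted sum of hidden states (context vector) is
concatenated with h_n and passed through FC1 (64 units; this activation is
the *penultimate embedding* used for phenotype clustering) with PReLU, then
FC2 to one logit per target, each squashed by a sigmoid. The loss is the
mean of per-element binary cross-entropies — hard parameter sharing across
tasks.

Training uses Adam (lr 1e-3 default, batch 128, ≤15 epochs, patience 3),
early-stopping on the validation AUROC of the primary ARDS target and
restoring the best-epoch weights. All weights initialize uniform
±1/√(fan-in) from a seeded generator; training is a deterministic function
of (data, config).

The network runs on a small in-package reverse-mode automatic
differentiation core over numpy arrays (`autodiff.py`) carrying exactly the
operations the architecture needs; its gradients are pinned down by central
finite-difference tests. On one CPU this backend favors modest widths, so
the package's *experiment scale* (used by the acceptance script and the
flagship test) is 24 hidden units × 2 GRU layers, batch 256, lr 3e-3 on a
5,000-encounter cohort — the full-size architecture remains the default for
library users.

**Target ablation.** The 13-target model is trained first; the two
lowest-AUROC targets on the test set are removed (never the primary ARDS
target) and the model retrained, yielding the 13/11/9/7/5 series.

**Comparator.** One XGBoost classifier per target on the identical tensors,
flattened row-major to 3,264 features with masked cells passed as native
missing values (mask rows retained — sampling intensity itself is signal).
Grid search (depth × learning rate) per target by validation AUROC.

## Evaluation

AUROC by rank statistics (Mann–Whitney with average ranks, so ties count ½);
95% CIs by the percentile bootstrap over patients, B=1,000 by default,
single-class resamples redrawn. Operating points report the smallest
threshold whose sensitivity reaches a target (default 0.65, matching the
sensitivity convention of the reference comparison tables); an unreachable
target degrades to calling everything positive.

## Phenotype clustering

ARDS-coded patients across the whole data set are embedded by FC1, projected
to two principal components for display (component signs fixed by making the
largest-magnitude loading positive), and grouped by k-means with k=3 and 10
seeded restarts. Clusters are relabeled A/B/C by decreasing mortality, ties
broken by size then centroid coordinates, making labels invariant to patient
ordering. A silhouette score is reported as a diagnostic but never used for
selection. Per-cluster incidences recombine exactly to population rates
(conservation is a tested invariant).

## Benefit estimation

Patients positive for the strict ARDS definition are split by whether the
clinical code was entered before (early) or after (late) the prediction
time; mortality is compared with a self-contained two-sided Fisher exact
test: the sum of hypergeometric probabilities, computed in log space from
log-binomial coefficients, of all tables with the observed margins whose
probability is at most the observed table's (relative tolerance 1e-7, the
same convention scipy and R use). A table with any zero margin admits a
single configuration and yields p = 1; only an empty table is undefined.
Group mortality percentages print to 1 decimal, baselines to 2.

## The synthetic cohort

Hospital EHR feeds of this shape are private, so the package ships a
generator whose cohorts have the statistical structure the analysis needs:

* **Latent severity.** One scalar per patient, standard Gaussian clipped to
  ±4. Outcome logits are affine in it (loadings: ARDS code 1.4, sepsis 1.3,
  death 1.5, COVID 0.35); intercepts are root-solved at configuration time
  so the four primary event channels hit their prevalence targets. Event
  probabilities below logit −7 truncate to exactly zero, making the
  minimum-severity limit (no severity-coupled events) structural.
* **Observations.** Per-feature homogeneous sampling over the stay (vitals
  0.06/bin, SpO₂ 0.08, labs 0.006, arterial blood gas 0.004), values =
  normal-range center + severity loading + Gaussian noise of 1.3 range-SDs.
  The noise and rates are set to the high-missingness, high-variance regime
  of real hospital feeds; in a low-noise regime every model saturates at the
  Bayes ceiling and the multitask comparison degenerates. An admission panel
  (triage vitals + basic labs within the first hour) makes the prediction
  time determinable early; the CBC differential arrives with a Gamma delay
  (mean ~12 h), which dominates the algotime distribution, and is absent
  entirely in 3% of stays.
* **Hypoxemia.** Each patient has one desaturation nadir,
  `93.3 − 3.38·z + 1.2·U(−1,1)`, deepened for 80% of ARDS-coded patients by
  a second channel `91.0 − 1.2·max(z,0) + 1.5·U(−1,1)`; at maximum severity
  the nadir is below 91% for every draw. The nadir is always charted. Mild
  dips (nadir ≥ 91%) occur at presentation with probability 0.76, deep dips
  with probability 0.25, otherwise uniformly inside the stay — this
  depth-dependent timing is what reconciles the any-time and
  after-prediction hypoxemia prevalences.
* **Diagnosis timing.** ARDS code delay is a mixture: 20% near-immediate
  (exponential, mean 3 h), 80% Gamma(2, 85 h), overall mean ≈ 139 h, clipped
  to the stay; about a fifth of strict-ARDS patients end up diagnosed before
  the prediction time. Late entry shifts the death logit by +0.45 (recentred
  so population mortality stays on target) — a marker of a deteriorating
  course, not a causal claim.
* **Calibration.** All 13 label prevalences sit within ±2 binomial SDs of
  their targets at n=16,000 over two generator seeds; the conditional
  constants above were fixed by quantile matching and Monte Carlo once and
  are not revisited per run.

What the generator does **not** emulate: medication and oxygen-device data,
radiology, multi-hospital site effects, unit conversions, circadian or
treatment-response dynamics, and correlated multi-feature episodes beyond
the planted SIRS episode in septic patients. Passing tests therefore
demonstrate correctness of the pipeline and the claimed statistical
properties on data with this structure — not clinical performance on real
records.

## Numerical and design choices

* The input matrix has 51 rows (1 age + 2 sex + 24 features + 24 masks); the
  row order is fixed in `features.py`.
* Attention softmax covers all 64 steps, padded included (documented above).
* The head is concat(256) → FC1(64) → PReLU → FC2; the 64-dim FC1 activation
  is the clustering embedding.
* k is fixed at 3 for phenotype clustering.
* Argmax ties in the attention profile resolve to the earliest timestep.
* CSV round-trips use `float_precision="round_trip"`; artifact manifests
  record SHA-256 hashes, and two runs with one config and seed are
  bit-identical.
* PCR results serialize as a JSON column in `patients.csv` to keep the
  three-file cohort contract lossless.

## Known limitations

* The numpy training backend is single-threaded and CPU-bound; full-size
  (128×4) training on large cohorts is slow, and no GPU path exists.
* The one-scalar severity model cannot represent outcome-specific risk
  directions; it is the simplest structure under which multitask sharing
  provably helps, not a claim about ARDS physiology.
* Operating-point selection assumes a fixed-sensitivity convention.
* The benefit comparison is a raw two-group contrast with no causal
  adjustment.
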