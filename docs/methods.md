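# Methods

This note records the models, parameter choices, and numerical conventions
used throughout the package, and what the synthetic-data generator does and
does not emulate.

## Assay format (plates)

A compound occupies one plate row: a 10-step, 3-fold descending dilution
series (top 100 µM, endpoint 100/3⁹ ≈ 5.08 nM) in duplicate (columns 1–10
and 11–20), one positive-control and one negative-control well per row
(columns 21–22), vehicle blanks elsewhere. Sixteen compounds therefore fill
a 384-well plate with 320 test wells and 16 control pairs. The within-row
column placement is a package convention; only the well counts are fixed by
the format. Cell deposition is density × volume (2.5 × 10⁶ cells/mL × 40 µL
→ 100,000 cells/well, rounded to the nearest cell).

## Flow I/O

Event data are 12-parameter matrices: FSC, SSC, CalceinAM, SYTOXRed,
MitoSOXRed, Monobromobimane, JC9_green, JC9_red, PI, PI_W, DCV, DCV_W. The
panel enumeration is configuration, not hard-coded truth: JC-9 occupies two
detectors and DyeCycle Violet and propidium iodide each contribute an
area and a width parameter. Physically the fluorescence channels come from
two dye mixes acquired on sister plates; in memory an `EventMatrix` always
carries the merged 12-parameter panel for one logical well, with the mix
assignment kept as channel metadata. A compact FCS 3.0/3.1 list-mode codec
(float32/float64, both endiannesses) is included because the pipeline must
read instrument-style files; CSV is supported as a plain-text alternative.
Well QC requires at least 10,000 aspirated events by default.

## QF reduction

Each channel of each dosed well is compared to the pooled negative controls
with the quadratic-form distance D(h,g) = √(dᵀAd), d = h − g on
probability-normalised histograms. The bin-similarity kernel is Gaussian,
A_ij = exp(−(i−j)²/2σ²) with σ = 3 bins, which is symmetric, unit-diagonal
and positive-definite, so D is a proper metric; as σ → 0 it degenerates to
the Euclidean distance on bin masses. Histograms use 64 bins on shared
edges computed from the pooled negative controls (1st–99th percentiles,
with ±∞ overflow bins so no event is dropped). Fluorescence intensities are
arcsinh-transformed with cofactor 150 before binning; scatter channels stay
linear.

The per-channel distance-vs-dose curve (replicate-averaged; single-replicate
points flagged) is smoothed by isotonic regression on log10 concentration —
the monotone-response assumption — and reduced to two features: the
max-rate point (midpoint of the grid interval with the largest smoothed
increase; ties break to the lowest interval, so the reduction is
deterministic) and the range (max − min of the smoothed curve). Twelve
channels × two features give the 24-feature phenotype. A control-noise
floor can be estimated by half-split resampling of the negative-control
pool.

## Cell-health classification

The Cell Health Index (CHI) is the positive-class probability of an
elastic-net-regularised logistic regression (scikit-learn saga solver) on
standardised phenotype features, labels "yes"/"no" with balanced class
weights. Hyperparameters are chosen on a grid (C ∈ {0.01, 0.1, 1, 10} ×
l1_ratio ∈ {0.5, 1.0}) by repeated stratified K-fold cross-validation
(default 5 folds × 10 repeats) scored by held-out log-likelihood, with a
one-standard-error parsimony rule: among settings whose mean score is
within one standard error of the best, pick the smallest C (strongest
regularisation), breaking ties toward the larger l1_ratio (sparser model).
The selected setting is refit on all data. Degenerate inputs (single class,
too few examples per fold) raise typed errors rather than fitting silently.

The endpoint fingerprint trains the same estimator eight more times, each
restricted to the feature columns of one biology endpoint (CM ← FSC/SSC,
CMI ← CalceinAM/SYTOXRed, ROS ← MitoSOXRed, GSH ← Monobromobimane, MMP ←
JC9_green/JC9_red, NMI1 ← DCV_W, NMI2 ← PI, CC ← DCV; PI_W feeds only the
full model). A compound's fingerprint is the vector of eight sub-model
probabilities; the top-scoring endpoint names the dominant stress axis.

## Viability analysis

Viability fractions (vehicle-normalised) are fit with the four-parameter
logistic y(c) = bottom + (top − bottom)/(1 + 10^((log10 IC50 − log10 c)·hill))
by least squares with 7 log-spaced IC50 starts × two Hill signs, bounds
log10 IC50 ∈ [range − 3, range + 3], |hill| ≤ 10, asymptotes in [0, 10],
and tight tolerances (1e-13) so noise-free data are recovered to ~1e-6
relative error. The (hill, top, bottom) ↔ (−hill, bottom, top) redundancy
is normalised to top ≥ bottom, so inhibition curves have hill < 0.

Censoring: a fit is reported as "> top-concentration" (e.g. "> 100") when
the fitted IC50 exceeds the top tested concentration **or** the fitted
curve never falls to half the control plateau (y ≤ top/2) inside the tested
range. The half-of-plateau form is deliberate: for full-amplitude curves it
coincides with the asymptote midpoint, while for shallow dips (a compound
whose true IC50 lies far above the range produces only a few-percent dip
that a free 4PL can "explain" with a high bottom asymptote) it still
censors, matching the reporting convention of SAR tables. Table entries are
rendered at two significant figures.

Fold changes and selectivity indices are IC50 ratios. A censored operand
propagates as a one-sided bound ("> 100"/1.2 → "> 83.3"); two censored
operands are indeterminate and raise. Selectivity is toxicity IC50
(control line) over efficacy IC50 (disease line).

## Synthetic data

Per channel, events are two-component mixtures of lognormals: a baseline
component (fixed log-means per channel class, log-SD 0.5) and a stressed
component shifted by `max_shift` in log space. The stressed fraction at
dose c is `max_stressed_fraction × Hill(c; ec50, hill)`, the stressed event
count is a binomial draw, and event order is permuted. All generators are
pure functions of (parameters, seed); a master SeedSequence spawns
independent per-well streams, so any well is reproducible in isolation.

Training libraries draw "yes" compounds with 3–8 affected channels at QF
amplitudes 1.0–2.5 and "no" compounds with ≤ 2 channels at ≤ 0.2 — a
strongly separated two-class world by construction. By default the library
generator uses a flagged analytic shortcut: per-channel QF curves are
synthesised directly (amplitude × Hill + folded-Gaussian noise, SD 0.03)
and passed through the real `reduce_curve`/`phenotype_vector` code;
`pipeline=True` instead simulates events and runs the full histogram
pipeline. Viability plates are quadruplicate 4PL evaluations with
multiplicative Gaussian noise (default CV 5%).

What the generator emulates: dose-monotone distributional shifts, mixture
heterogeneity, replicate noise, censored-regime viability. What it does
not: spectral spillover/compensation, debris and doublets, acquisition
drift, plate-position (edge) effects, channel-correlated event noise, or
non-monotone (hormetic) dose responses.

## Problem sizes and validation studies

The validation studies shipped in the test suite use sizes chosen by this
package: a 300-compound library (150/150) with a 200-compound held-out set
for the classifier study; 50 seeded single-endpoint stressors against one
trained fingerprint for the specificity study; 500 seeded quadruplicate
plates at 5% CV (true IC50s 0.5/5/50 µM) plus 100 censored-truth plates
(true IC50 1 mM, ten-fold above the top concentration) for the 4PL study;
1000 random histogram pairs against an explicit O(b²) double-sum oracle
for the QF distance. `scripts/acceptance.py` re-runs the same studies from
a single seed.

## Limitations

- The classifier's reported performance is on the synthetic generator's
  strongly separated classes; it states pipeline correctness, not expected
  performance on real screens.
- The isotonic reduction assumes monotone dose response; hormetic curves
  are flattened.
- The QF kernel bandwidth (σ = 3 bins), bin count (64), and arcsinh
  cofactor (150) are fixed defaults, not auto-tuned.
- The FCS codec covers list-mode float data as produced by common
  cytometers and this package's writer; it is not a general FCS
  implementation (no integer/log-amplified data, no analysis segments).
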