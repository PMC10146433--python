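# Methods

This note documents the models, algorithms, defaults and design choices in
`herbscreen`, and states precisely what the synthetic studies do and do
not demonstrate.

## The screening problem

A supplement sample is a homogenized mixture of botanical powders. The
screening question is binary per regulated plant: *does this mixture
contain plant P at a mass fraction of roughly 5 % or more?* Training data
are triturations — a reference plant powder mixed into a blank supplement
matrix at known mass ratios — plus the unspiked blanks. Each injection is
measured by UHPLC with diode-array detection, giving an absorbance
surface over wavelength (200–400 nm) and retention time (0–8 min).

The per-plant study design is fixed: 11 blank matrices × 5 spike ratios
(1/20, 1/15, 1/10, 1/5, 1/2, interpreted as plant mass fractions
5 %–50 %) = 55 triturations, plus the 11 blanks and 1 pure reference: 67
records, 56 positive / 11 negative. The 5-class pool combines four plants:
4 × 55 + 11 + 4 = 235 records.

## Pipeline stages

The stage order is fixed and logged: wavelength selection → crop → COW →
unfold → (optional pretreatment) → duplex → cross-validation → fit →
external validation. Screening unknown samples reuses all train-time
state; nothing is refitted.

### Wavelength selection

The correlation map is computed on the reference standard's record,
restricted to the fingerprint window: entry (i, j) is the Pearson
correlation between channel i's and channel j's time traces. Selection is
a deterministic greedy replacement for visual colour-map inspection: seed
with the channel of maximal total absorbance; repeatedly add the channel
whose maximum |r| against the current selection is smallest; stop when
that value reaches the cutoff (0.95) or five channels are chosen; break
ties toward the lower wavelength. Absolute correlation is used because an
anti-correlated channel is as redundant as a correlated one. Flat
(zero-variance) channels are flagged and never selected. The pairwise
(not merely adjacent-channel) cutoff is enforced, which is what makes the
resulting set "orthogonal".

### Fingerprint window

The 1.5–6.6 min window is kept as a closed interval; at 0.05 s sampling
this retains 6121 points, and unfolding five or four channels gives
30,605 or 24,484 columns. Time stamps are minutes; COW requires the grid
to be regular within 1e-9 min because segments are defined in index
units.

### Correlation-optimized warping

The target trace per channel is the sample with the highest mean Pearson
correlation to all others (ties → lowest index). The target axis is cut
into segments of `segment_length` points (default 35); the final segment
absorbs the remainder rather than dropping points. Sample-side boundary
nodes may deviate from their proportional positions, each boundary by at
most `slack` points (default 3) relative to its predecessor, so boundary
b can drift up to ±b·slack cumulatively; the first and last nodes are
pinned. Each candidate sample segment is linearly interpolated onto its
target segment and scored by Pearson correlation (zero-variance segments
score 0); dynamic programming over the boundary states returns the global
optimum of the summed scores. Score ties resolve to the first predecessor
in scan order (smallest deviation). When a segment's source and target
lengths coincide the segment is copied rather than interpolated, so
warping a trace onto itself is bit-exact identity with score equal to the
segment count.

The DP kernel is numba-compiled; a full-scale warp (6121 points, segment
35, slack 3, ≈ 46,000 DP states) takes ~40 ms, so aligning a 67-sample,
5-channel study costs ~15 s. The parameter grid search (segments
10..50 step 5, slack 1..5) maximizes the mean warped-to-target
correlation over all non-target traces, ties toward the smaller segment
then smaller slack; the pipeline default uses the fixed (35, 3) spec and
exposes the search behind a flag (globally, or per channel).

### Duplex splitting

Distances are Euclidean on the unfolded matrix exactly as modelled
(post-warping, unscaled). The farthest remaining pair joins the
calibration set, the next farthest the validation set, alternating until
the validation set holds ⌈0.25 n⌉ members — the only rounding consistent
with both 67 → 17 and 235 → 59 — after which all remaining points join
the calibration set. If the validation set needs a single final point on
its turn, the member of the pair farther from the existing validation
points is taken. Distance ties resolve to the lexicographically smallest
index pair, making the split deterministic and permutation-stable
whenever pairwise distances are distinct.

### PLS-DA

Responses are coded 1 (positive) / 2 (blank) in a single column for
binary models, one 0/1 indicator column per class for multiclass.
Predictors and responses are mean-centered, never scaled (matching the
no-pretreatment default). Latent variables are extracted by NIPALS with
deflation of both blocks; the inner loop converges at 1e-12 relative
change of the score vector with at most 500 iterations per factor
(single-column responses converge in one step). Predicted codes below the
1.5 midpoint map to class 1, the boundary itself to class 2; multiclass
predictions take the argmax with ties toward the lowest class.

Factor count is chosen by seeded, label-stratified 10-fold
cross-validation over 1..30 factors: per class, members are shuffled and
dealt round-robin to folds; a fold whose training complement loses a
class raises an error. Because NIPALS factors are nested, each fold is
fitted once at 30 factors and truncated predictions are accumulated by
the test-deflation recursion, which reproduces the per-k coefficient form
exactly (asserted in the tests). The chosen count is the argmax of pooled
held-out ccr, ties toward fewer factors.

### Pretreatments

SNV (row-wise standardization with the population sd), Savitzky–Golay
derivatives (default window 15, polyorder 2, applied per wavelength block
and never across block boundaries, derivative with respect to the point
index) and autoscaling are available but **off by default** — evaluating
them showed no benefit after warping for this kind of data. Row-wise
(stateless) pretreatments run before the duplex split; autoscaling is
fitted on the calibration rows only and its state is applied unchanged to
validation and screening data, so the listed stage order holds for the
stateless transforms while test statistics can never leak into the
transform.

## The synthetic study generator

### Signal model

Every constituent is a Gaussian chromatographic peak (σ ≈ 0.014–0.036
min) carrying a UV spectrum that is a weighted sum of three Gaussians in
wavelength: a narrow primary band (σ 9–16 nm), a secondary band (σ 15–30
nm, weight 0.2–0.5) and a broad tail (σ 60–90 nm, weight 0.04–0.1). The
broad tails matter: they give every DAD channel correlated signal above
the noise floor, so adjacent channels correlate smoothly — the structure
the 0.95-cutoff selection assumes.

A record is the sum of its constituents' peak surfaces, plus a slow
polynomial baseline that decays toward long wavelengths (end absorbance),
plus i.i.d. Gaussian noise; each injection carries one global
retention-time shift. Absorbance contributions pass through two mild,
monotone saturations:

* **extraction cap** (default 0.2 AU): the recovered amount of a
  constituent grows as c·(1 − e^(−x/c)) in its load — crude-powder
  extracts at fixed solvent volume are solubility-limited, so a 1/2
  trituration does not yield ten times the peaks of a 1/20 one;
* **detector saturation** (default 1.0 AU): the DAD reading flattens as
  strong bands approach the stray-light limit.

Both are monotone (peak locations are preserved) and both can be disabled
(`None`), in which case a simulated record is *exactly* linear in the
mass fractions — the tests assert this invariant in the ideal-instrument
configuration.

The concave concentration response is not a cosmetic detail; it is what
makes the blank class learnable at all. A classifier fitted by
least-squares regression on class codes is linear in the record, hence
affine along a trituration series in the spike fraction r. Under an
exactly linear instrument a blank is precisely the r → 0 point of its own
matrix's trituration line, so the fitted code at the blank is the
extrapolation of a line fitted to a constant code over r ∈ [0.05, 0.5] —
which lands at ≈ 1 (the positive code), never past the 1.5 threshold, for
*any* factor count. With the concave response the trituration series
curves, the r → 0 extrapolation overshoots upward, and held-out blanks
become separable — at the price of needing many latent variables, which
is exactly the regime the cross-validation selects (15–25 factors) and
the regime in which external errors concentrate on blank false
positives.

### Study materials

`build_plant_library(n_plants, n_matrices, seed)` lays profiles out on
retention and spectral lattices with provable separation: peak retention
centers of distinct profiles differ by more than twice the largest peak
width, signature spectral centers by at least 176/n_profiles − 4 nm, and
randomly drawn non-signature spectral centers keep ≥ 10 nm away from
every plant signature band.

* **Plants** (6 specific peaks, 0.3–1.0 AU): reference plant powders are
  peak-rich in the fingerprint window — that is why the window is chosen
  — and contain none of the matrices' formulation compounds.
* **Matrices** (3 specific peaks, 0.3–1.2 AU, plus backbone): formulated
  supplement products genuinely differ from each other, and additionally
  share an 8-peak backbone of ubiquitous formulation/common compounds
  (0.5–1.2 AU, ±15 % product-to-product abundance variation). The
  backbone supplies COW's alignment anchors and the shared background
  that spiking dilutes.
* **Lactose stand-in** (last matrix): a single near-flat peak with
  minimal UV absorbance and no botanical backbone.

`default_study_library()` freezes one such library (4 plants, 11
matrices) as the packaged study materials; simulation seeds then vary
only the measurement realization — noise, baseline coefficients,
retention jitter — the way replicate laboratory campaigns would.

### Instrument defaults and rationale

| parameter | default | rationale |
|---|---|---|
| wavelength grid | 200–400 nm, 1 nm | DAD acquisition range |
| time grid | 0–8 min, 0.05 s | run time and sampling; 6121 window points |
| `rt_jitter_sd` | 0.005 min (0.3 s) | injection-to-injection retention drift of a thermostatted UHPLC |
| `noise_sd` | 0.0005 AU | 0.5 mAU short-term detector noise |
| `baseline_drift_amp` | 0.001 AU | within-sequence baseline reproducibility |
| `saturation_au` | 1.0 AU | DAD linear range / stray-light limit |
| `extraction_cap_au` | 0.2 AU | solubility-limited recovery of major constituents at 10 mg/mL loads |

### What the generator does not emulate

Peak asymmetry and tailing, co-elution and retention-order swaps,
gradient-dependent baseline shapes, pump pulsation, carryover, detector
spectral response and wavelength calibration error, inter-day drift, and
the true UV spectra of real phytochemicals. Consequently, passing tests
demonstrate that the pipeline's algorithms are correct and that the
workflow recovers known class structure under the stated physical
assumptions — not that a particular real plant would be detected at a
particular spike level on a particular instrument.

## Problem sizes used in the test suite

Unit tests run on miniature studies (2 plants, 3 matrices, coarse grids).
Design-count and duplex checks run the full 67- and 235-record designs on
coarse instrument grids (their results are grid-independent). The warping
oracle compares the DP against exhaustive path enumeration on 100 random
instances with ≤ 5 segments and slack ≤ 2. The parameter-recovery and
channel-strategy checks run ten full-scale binary studies (67 records,
five selected channels, 6121 window points) at seeds 1–10, each modelled
on the selected channel set and on 254 nm alone with a shared duplex
split; `scripts/acceptance.py` additionally runs one full-scale
multiclass study (235 records).

## Known limitations

* COW's cumulative slack lets mid-trace boundaries drift far; on traces
  with genuinely different peak sets the optimizer can warp unrelated
  peaks onto each other. The shared backbone keeps this benign in the
  packaged studies, but alignment quality should be inspected (the
  per-channel log records cross-sample correlation before and after) on
  unusual data.
* The 1/2-coded regression with a fixed 1.5 threshold is asymmetric under
  class imbalance (56:11); blanks are the fragile class, and external
  errors are essentially always blank false positives.
* The CSV cube dialect canonicalizes row order; reading a written cube
  reproduces the original sample order only when sample ids sort
  lexicographically (the simulator emits zero-padded ids for this
  reason).
* Duplex assigns the most extreme points to calibration first; with
  heavy-tailed data the validation set can under-represent outliers.
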