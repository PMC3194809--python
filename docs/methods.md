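# Methods

## The problem

A SELDI-TOF mass spectrum is a vector of ion intensities over
mass-to-charge ratio (m/z, in Da). Biomarker studies reduce a cohort of
such spectra to a *peak profile* — a samples × peaks matrix of
quantified intensities — and then test each peak for differential
expression (DE) between disease and control groups. Both steps are
algorithm-dependent: different pre-processing pipelines detect
different peak sets, and the multiplicity burden of a large profile can
erase discoveries that a small profile retains. This package implements
the whole chain on simulated data with known truth so that the
agreement between pipelines, and the statistical mechanisms behind
their disagreement, can be measured rather than argued.

## Synthetic spectra

`simulate_dataset` generates, for each biological sample, `n_replicates`
technical spectra (default 2, mirroring the duplicate-spectrum designs
common in SELDI studies) on a shared uniform m/z grid:

    spectrum = scale · (Σ_p h_sp · N(m; c_p, σ_p) + A·exp(−m/τ)) + ε

* **Peaks** are Gaussians; σ_p = a + b·c_p grows linearly with m/z
  (a = 1 Da, b = 0.002 by default), the conventional first-order model
  of TOF peak broadening. Centres are drawn uniformly with a minimum
  spacing of twice the widest σ so peaks are resolvable; configurations
  that cannot satisfy the spacing are rejected.
* **Heights.** Group-level mean heights are uniform on [20, 100]
  intensity units. Each *sample* draws one multiplicative log-normal
  factor per peak (`biological_cv`, default 0.15, mean-corrected so the
  expectation equals the group mean); both replicates of a sample share
  these heights, which is what duplicate-consensus averaging exploits.
  Without a sample-level variance component the two-group t-test would
  see only technical noise, so this term is load-bearing, not
  decorative.
* **DE structure.** A `de_fraction` of peaks (default 0.2, i.e. 6 of
  30) carries a fold change, applied multiplicatively to the cancer
  group mean. The default fold-change vector is direction-balanced
  (2.0, 0.5, 2.0, 0.5, 2.0, 0.5): all-up designs shift the cancer
  group's total ion current and TIC normalization then smears the
  signal across every null peak as an apparent down-regulation.
  Balanced regulation keeps that artifact small (≈5% residual bias
  here); it is a real property of TIC-style normalization, not a bug,
  and passing a scalar restores the one-sided design.
* **Baseline** is A·exp(−m/τ) (A = 50, τ = 3000 Da), a smooth decaying
  background of the kind matrix/chemical noise produces at low m/z.
* **Technical variation**: one log-normal intensity scale per spectrum
  (sd 0.1 on the log scale, mean-corrected — what normalization should
  remove), one constant m/z jitter per spectrum (sd 1 Da — what FFT
  alignment should remove; a constant shift rather than per-point noise
  so alignment has a recoverable signal), and white Gaussian intensity
  noise (sd 1).

`GroundTruth` records peak centres, DE flags, fold changes and group
means; `evaluate_detection` scores any detected peak list against it by
greedy one-to-one matching inside a relative window (±0.3% by default),
giving sensitivity and an empirical detection FDR.

What the simulator does **not** model: isotope envelopes, multiple
charge states, detector saturation, non-uniform TOF grids,
heteroscedastic (intensity-dependent) noise, or chip/matrix chemistry.
Passing tests therefore demonstrate correctness of the algorithms and
of the statistical mechanisms, not performance claims on real serum
spectra.

`simulate_pvalue_mixture` is the abstract companion for FDR work:
nulls are U(0,1), alternatives are one-sided p-values of N(effect, 1)
draws, optionally confined to one stratum.

## Pre-processing presets

All three presets are *average-spectrum-dependent*: peaks are detected
once on the mean of all spectra and then quantified in each individual
spectrum as the maximum inside the peak's interval. Intervals are
half-open index ranges bounded by the local minima flanking each apex;
plateau ties resolve to the lowest index, and intervals never overlap.

* `specalign_like` — per spectrum: Savitzky–Golay smoothing (window 11,
  order 3), restrained-moving-average baseline, rescale to minimum 0,
  TIC normalization (every spectrum scaled to the mean total ion
  current); then average, FFT-align each spectrum to the average
  (integer grid shifts, |shift| ≤ 10, edges padded), re-average, and
  pick local maxima with a height-ratio SNR (default threshold 1.5).
* `mswpro_like` — detection by continuous-wavelet-transform ridge lines
  (Mexican hat, 12 dyadically spaced scales 1–64, ridge gap tolerance
  2, minimum ridge length 6, via `scipy.signal.find_peaks_cwt`) on the
  lightly smoothed, baseline-free average spectrum at SNR 3;
  quantification per spectrum after linear-interpolation baseline
  subtraction (anchors at the minima of 20 equal segments) and
  median-AUC normalization (trapezoidal areas equalized to the median).
* `cromwell_like` — average first; denoise by the undecimated discrete
  wavelet transform (db8, hard threshold at 3 noise sigmas); subtract
  the monotone-minimum baseline (left-to-right running minimum); pick
  local maxima at SNR 5; per spectrum the same denoise/baseline steps,
  average-TIC normalization, interval-maximum quantification.

**Noise/SNR conventions.** The noise scale is 1.4826 × the median
absolute deviation (MAD) of the finest-level UDWT detail coefficients
of the detection signal (`cromwell_like`, CWT), or of the per-spectrum
residual left by Savitzky–Golay smoothing, averaged over spectra (the
`specalign_like` "height ratio"). A peak's SNR is its
baseline-subtracted apex over that scale. Two numerical guards: the
noise scale has an absolute floor of 1e−12, and a dynamic-range floor
of 1e−4 × the signal maximum so that on effectively noise-free input
the numerical ripple left by baseline subtraction cannot pass any
threshold. Because each preset estimates noise on a different signal
(raw per-spectrum residual vs average-spectrum wavelet detail), equal
SNR thresholds do not mean equal intensity cutoffs — the SpecAlign-like
preset is by far the most conservative, and the Cromwell-like preset
detects supersets of its peaks at low thresholds, reproducing the
orderings such comparisons show on real data.

**Restrained moving average.** Implemented as the iterated
signal-restrained moving average: baseline ← min(moving_average(baseline),
signal), four iterations, window 2% of the grid. The more obvious
min-filter-then-smooth construction undershoots flat background by
roughly two noise sigmas, and the resulting positively biased residual
crests just above a 1.5 height-ratio threshold as spurious peaks; the
iterated form is bias-free on flat background, still satisfies
baseline ≤ signal everywhere, and equals the constant on a constant
spectrum.

## Replicate consensus and matching

Duplicate spectra are pre-processed together (they enter the average)
but quantified separately; `consensus_by_sample` averages the replicate
rows of each sample into one consensus row. `restrict_mz_range` keeps
peaks inside a closed m/z interval (analyses conventionally drop the
low-mass matrix-noise region and the high-mass detection-limit region).

`match_peaks` matches two sorted peak lists one-to-one, greedily in
order of increasing relative distance, inside a window of ±shift·mz
anchored on the first list (shift 0.003 by default). At sub-0.3%
windows greedy and optimal assignment coincide on realistic lists and
the shared count k is symmetric in the argument order; at much wider
windows neither property is guaranteed, which the tests document.

## DE testing and stratified FDR control

Per peak: equal-variance two-sample Student's t-test, fold change
FC = mean(cancer)/mean(normal) (∞ when the normal mean is 0; direction
"none" when FC = 1, and such peaks can never count as shared DE peaks).
A `--log2` switch tests log2(intensity + 1) instead of raw intensities;
fold changes are always reported on the raw scale. Zero-variance peaks
get p = 1 when the means agree and the smallest positive p otherwise,
with a logged warning.

Simple selection is BH at level q (default 0.10). Stratified selection
first partitions peaks by 1-D k-means on |log2 FC| — the magnitude
makes strong up- and down-regulation land in the same "high" stratum;
infinite FC maps above the largest finite value — with 25 seeded
restarts per k, k ∈ {2,…,10}, chosen by maximal mean silhouette (ties
to the smaller k; degenerate FC vectors fall back to one stratum), then
runs BH inside each stratum at the same q. Disjoint per-stratum
discovery sets keep the FDR of the union at or below q, while a small
high-FC stratum escapes the q·i/m cutoffs of the full profile — the
mechanism that lets a large profile recover discoveries that
profile-wide BH misses entirely.

## PO/nPO consistency scores

For peak lists of lengths l1 ≤ l2 sharing k peaks, PO = k/l1 (coverage
of the shorter list) and nPO = (PO − E(PO))/(1 − E(PO)): the observed
excess over chance relative to the maximum possible excess, with the
maximum potential PO taken as 1. E(PO) is the mean PO of `n_perm`
(default 1,000) random list pairs of the same lengths drawn without
replacement from the two m/z universes — the full detection grids for
peak-level comparisons, the profiles' detected peak lists (carrying
each peak's observed direction) for DE-level comparisons. The p-value
is the plain proportion of null scores not less than the observed one;
its resolution floor is 1/n_perm and no +1 smoothing is applied. When
the shared count takes few distinct values the tie mass makes this
p-value super-uniform (conservative) under the null — E[p] =
(1 + P(tie))/2 — so the calibration guarantee is validity
(P(p ≤ t) ≤ t), not exact uniformity; the test suite checks exactly
that. In the identical-universe, exact-matching limit E(k) is
hypergeometric, E(PO) = l2/N, which anchors the permutation machinery
to a closed form.

## Experiments

* **SNR sweep** (`run_snr_sweep`): each preset over a grid of
  thresholds against every reference preset at its default, reporting
  peak counts, DE counts and peak-/DE-level consistency. Default grids
  span each preset's informative range on the default simulation (the
  high end prunes true peaks).
* **Subsampling power** (`run_subsample_power`): at each sample size,
  100 subsets drawn with the cohort's cancer:normal proportion fixed;
  mean DE count per preset and mean direction-aware PO between preset
  pairs. A subset where either profile finds no DE peak scores PO = 0 —
  zero reproduced discoveries — rather than being dropped, which would
  condition on success and inflate small-sample scores.
* **Stratified comparison** (`run_stratified_comparison`): one DE
  table selected under both modes, scored against ground truth
  (empirical FDR and power over the truly DE peaks, identified by
  matching profile peaks to true centres).

### Constructed scenarios

Two analyses need conditions placed deliberately in the regime where
their mechanism operates; both are fixed constructions, not tuned fits.

* **Discovery reversal.** A profile of m = 4000 tests whose 16
  alternatives (noncentrality 1.4 — what a small cohort yields for a
  modest fold change) all sit in one small stratum. Profile-wide BH at
  q = 0.10 needs p ≲ q/m ≈ 2.5e−5 for a first discovery and recovers no
  true alternative in most replicates, while BH inside the 16-test
  stratum recovers some; the reversal appears in ≈85–90% of replicates.
  The reversal is counted on *true* alternatives: profile-wide BH still
  makes a purely false discovery in ≈ q·π0 ≈ 9% of replicates (a
  property of BH itself, Simes' identity), so a total-discovery count
  would cap the attainable frequency near 0.77 regardless of
  construction.
* **Power-limited subsampling.** The sample-size analysis uses modest
  fold changes (1.5 and 1/1.5) and serum-level biological variability
  (CV 0.35), because with the default effect sizes the t-tests are
  already near-saturated at n = 12 and the size trend vanishes. Under
  the power-limited scenario the mean DE count rises from ≈0.4 at
  n = 12 to 6 (all true DE peaks) at n = 45 and mean PO^DE from ≈0.3
  to 1.0.

## Problem sizes and determinism

The default simulation is 30 cancer + 15 normal samples in duplicate
(90 spectra) on a 1–10 kDa grid at 1 Da steps (9001 points) with 30
peaks — chosen so every experiment, and the whole test suite, runs in
minutes on one CPU while keeping ≥10 samples per group for stable
t-tests. Every stochastic component takes an explicit seed
(`numpy.random.default_rng`); identical seeds give bit-identical
spectra, profiles and reports, and all artifacts round-trip through
their plain-text formats (CSV/TSV + JSON sidecars,
`float_precision="round_trip"` on the way in).

## Known limitations

* The presets are procedural re-implementations of three published
  pipelines' *structure*, not bit-compatible ports of their binaries;
  SNR thresholds are comparable within a preset, not across presets.
* All spectra must share one m/z grid; no resampling is performed, and
  mismatched grids are an error by design.
* TIC/median-AUC normalization couples peaks; with strongly one-sided
  DE structure this induces compensatory apparent fold changes in null
  peaks, visible as an elevated empirical DE FDR on raw intensities.
* The stratified procedure inherits k-means/silhouette behaviour: with
  no fold-change structure it falls back to a single stratum rather
  than inventing strata.
* Greedy matching is the contract even where optimal assignment would
  differ (wide windows, dense lists).
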