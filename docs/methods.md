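# Methods

## Scope

`eegmse` implements a complete resting-state EEG complexity analysis:
multiscale sample entropy over the 19-electrode 10-20 montage, scale-bin
averaging, a Welch PSD control analysis, and mixed-design
repeated-measures ANCOVA group statistics with Greenhouse–Geisser
correction and Benjamini–Hochberg FDR. A synthetic cohort generator
provides the two-group study structure (high vs low cognitive function in
older adults) that the statistics are designed for.

## Multiscale entropy

**Coarse-graining.** Scale-τ series are means of non-overlapping windows
of τ consecutive samples; the trailing remainder is dropped, so a
4000-sample epoch yields exactly 100 points at scale 40.

**Sample entropy.** SampEn(m, r) = −ln(A/B) where B counts template pairs
(i < j) of length m matching within r, and A counts pairs whose
(m+1)-point extensions also match. Both counts run over the N−m templates
that admit an extension (Richman–Moorman convention); matching is strict
(`< r`) under the Chebyshev norm, and self-matches are excluded. The
pair-count normalisation cancels in the ratio. When either count is zero
the value is *undefined* and propagates as a masked (NaN) entry, never an
exception. Defaults m = 2, r = 0.2.

**Normalisation.** Each coarse-grained series is z-scored with the
population SD before matching (`r_mode="per_scale"`), so r is in SD units
of that scale's series. Under this convention i.i.d. Gaussian noise has
the scale-free analytic value −ln(erf(r/2)) ≈ 2.185 at r = 0.2, making
flatness of the white-noise MSE curve a built-in estimator check. The
original convention — r fixed relative to the scale-1 SD — is available
as `r_mode="global"`; the classic ordering "1/f² above white noise at
coarse scales" holds only under that convention, and the corresponding
test uses it. The z-score is applied after coarse-graining at every
scale (including τ = 1).

**Implementation.** An O(n²) pair scan accelerated by sorting on the
first template coordinate (only pairs within r on that coordinate are
examined), compiled with numba. A brute-force quadratic reference lives
in the test suite and must agree to 1e-10; the kernel's pair conventions
were fixed so the two match bit for bit.

**Epoching and averaging.** SampEn is computed per epoch and averaged
across epochs, ignoring undefined entries; a cell is missing only if it
is undefined in every epoch. The epoch-averaged 40-scale profile is
reduced to 8 bins of 5 scales by unweighted means over defined entries.
At the default 200 Hz analysis rate bin k spans (5k−4)·5 … 5k·5 ms,
ending at 180–200 ms for bin 8.

**Sampling-rate convention.** Recordings are acquired at 500 Hz but the
scale-to-time mapping of 5 ms per scale step presumes 200 Hz; the
pipeline therefore downsamples to 200 Hz by default (`target_fs`), and a
flag allows native-rate analysis. Epoch length defaults to 20 s (4000
samples at 200 Hz — scale-40 series of 100 points, short but serviceable
for m = 2, with ~12 epochs averaged per subject to control variance).

## Preprocessing

Zero-phase (forward-backward) order-4 Butterworth band-pass at 1–60 Hz;
polyphase resampling; segmentation into non-overlapping fixed-length
epochs; amplitude-threshold epoch rejection at ±100 µV (the common
clinical convention) standing in for manual artifact exclusion. Subjects
losing all epochs are flagged unusable, not silently dropped.

## Welch PSD control

Modified periodograms over 2.0 s Hann windows with 50% overlap (the
overlap is unstated in the protocol being emulated; 50% is Welch's
standard recommendation and is configurable), averaged across all
windows of all kept epochs, in dB re 1 µV²/Hz. The native 0.5 Hz grid is
decimated to the 2–60 Hz / 1.0 Hz output grid (59 points) by taking every
second bin — the simplest reading of a "1.0 Hz frequency bin" — with
band-averaging available as an alternative.

## Group statistics

**Model.** Univariate mixed-design GLM: between-subject factor group,
within-subject factors electrode (19) and scale bin (8), covariates age
(grand-mean centred) and sex (centred binary indicator). For each
group-involving effect the subject × cell matrix is projected onto
orthonormal within-subject contrasts and a multivariate regression on
the between design X = [1, group, age, sex] is fitted; the averaged
univariate F is tr(H)/d ÷ tr(E)/(d·dfe) with dfe = n − 4, and partial
η² = tr(H)/(tr(H)+tr(E)). Sums of squares are Type III with sum-to-zero
group coding (identical to Type II here, as there are no between-factor
interactions). Greenhouse–Geisser epsilon is Box's estimate from the
error covariance of the contrast scores and shrinks both F degrees of
freedom. The implementation is validated against R `car::Anova`
(Type III, repeated-measures with covariates) on frozen deterministic
datasets, and the between-subject stratum is cross-checked at run time
against a statsmodels OLS ANOVA of subject cell-means.

**Post-hoc grids.** Student's pooled two-sample t per cell (Welch behind
a flag), positive t meaning the high group's mean is larger, without
covariate adjustment by default (a covariate-adjusted variant is a
follow-up option, off by default, since the omnibus ANCOVA and the
descriptive post-hoc map serve different purposes). BH step-up FDR at
q < 0.05 over the whole grid (152 MSE cells; 1121 PSD cells); the
critical p is the largest ranked p below its step-up bound. Subjects
with any missing cell are deleted listwise with a logged count.

## Synthetic cohort generator

**What it emulates.** 22 high / 21 low cognitive-function subjects; ages
drawn N(70, 4.3) vs N(74.1, 5.2) years (clipped to 65–85), male/female
6/16 vs 7/14, cognitive totals N(168.3, 10.0) vs N(142.5, 8.3); 19
channels at 500 Hz; eyes-closed recordings of at least 3 min; 9–15 clean
epochs of 20 s per subject (mean ≈ 12).

**Signal model.** Per channel, a complex Fourier spectrum
Z(f) = √(S(f)/2)·(g₁+ig₂) with S(f) combining a 1/f^β background
(β = 1.5), a Gaussian alpha bump at 10 Hz and a white floor
(white_frac = 0.1), restricted to 1–60 Hz; the inverse FFT is scaled to a
target RMS of 8 µV. Between-subject realism comes from jitters on β
(SD 0.3), alpha amplitude (lognormal σ 0.4), white fraction (SD 0.08)
and overall gain (SD 2 dB).

**The group effect.** Injected through *phase structure only*: for
effect channels of the low group, the 1–5 Hz Fourier phases are pulled
(circular mixing, strength λ) toward the phases of a jittered periodic
pulse train (period 3 s, width 0.2 s). The slow dynamics become
quasi-periodic and bursty — more regular, hence lower slow-scale SampEn —
while |Z(f)| is untouched, so both groups' periodogram amplitudes are
drawn from the identical distribution and pointwise PSD comparisons are
null by construction. The alternative of giving the groups different
spectral slopes was rejected precisely because it would make the PSD
control analysis sensitive to the group difference, contradicting the
phenomenon being emulated (a complexity effect invisible to power
spectra).

The λ dose-response is threshold-like, so it was measured once on this
generative model through the default analysis chain and frozen as a
lookup table; `effect_size` (in nats of slow-scale, bins 3–8, SampEn
difference at the effect electrodes, default 0.1) is mapped to λ by
inverting that table. The mechanism saturates near 0.17 nats. Effect
electrodes default to the 13 frontal/parietal/temporal sites where the
target phenomenon is reported. Covariates (age, sex) are generated with
realistic group imbalance but do not causally influence the signals, so
the null generator stays exactly exchangeable.

**What the generator does not emulate.** No biophysical forward
modelling, no eye-blink/EMG artifacts beyond optional amplitude spikes,
no volume-conduction correlation between channels (channels are
independent), no causal acquisition-filter dynamics. Passing tests
demonstrate that the pipeline recovers a slow-scale complexity effect of
the designed size under these idealised conditions — not that clinical
effect sizes would be recovered from real recordings.

## Numerical and design choices

- Population (divide-by-N) SD in all z-scoring; fixed for reproducibility.
- Strict `< r` matching, as in the SampEn definition used here; with
  continuous-valued data the choice is immaterial.
- Median-split ties are assigned to the low group with a warning
  (deterministic groups); an all-tied input degenerates to a single low
  group with a warning rather than an error.
- Undefined SampEn cells are masked; statistics drop affected subjects
  listwise with a logged count.
- EDF export uses 16-bit quantisation with per-channel physical ranges
  and 1 s records; reading tolerates shuffled channel order, drops
  non-montage channels with a warning, and fails loudly (naming the
  channels) when montage sites are missing. Non-µV unit strings warn and
  pass through.
- The 3-min minimum recording duration is a convention, enforced as a
  warning rather than an error so that reduced-size simulation studies
  remain expressible.

## Problem sizes used in validation

Replicate-based checks run the full pipeline at reduced sizes chosen as
a deliberate compute/coverage trade-off: null calibration uses 400
cohorts of 43 subjects with 2–3 epochs of 4 s at 128 Hz and an 8-scale
grid (the 19 × 8 analysis grid is preserved); effect recovery uses 50
cohorts with 2–3 epochs of 8 s at 200 Hz and the full 40-scale grid; the
acceptance script uses 3–4 epochs of 8 s. Estimator noise is larger at
these sizes than at the 12 × 20 s default, which works against the
checks, not for them.

## Known limitations

- The regularity mechanism's dose-response calibration is specific to
  the default spectral parameters; changing `base_mix` rescales the
  realised effect.
- SampEn at coarse scales on short epochs is biased slightly upward
  (small-count conditioning); both groups are affected equally.
- The ANCOVA assumes two groups exactly and complete within-subject
  grids after listwise deletion.
- Only EDF and the delimited-matrix format are supported on disk.
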