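# Methods

This note documents the statistical model, the fixed analysis settings, the
numerical choices where the underlying protocol leaves freedom, what the
synthetic-data generator does and does not emulate, and known limitations.

## Analysis unit and inclusion rules

The unit of analysis is the **call segment**: one acoustic unit of a
vocalization, pre-cut into its own mono WAV file. Some call types
(threat grunts, copulation grunts, hoot series) are uttered as sequences of
repeated segments; segments within a sequence share `sequence_id`, and all
segments of independent sequences enter the analysis. Three inclusion rules
run before anything else (`audio.filter_call_records`):

1. records whose `quality_ok` flag is false are dropped (recording quality
   is judged upstream and arrives as metadata);
2. for repeated-segment call types, a sequence is kept only if it starts at
   least `min_gap_s` (default 3600 s) after the start of the previously
   *retained* sequence of the same caller and call type — consecutive
   sequences closer than the gap are discarded, and the gap clock restarts
   at each retained sequence. Applying the rule per (caller, call type)
   rather than per caller is a package choice, configurable by editing the
   `repeated_types` argument;
3. every (caller, call type) cell with fewer than `min_calls` (default 4)
   surviving segments is removed entirely.

The filter is idempotent and logged, so dataset attrition is auditable.

## Spectrogram grid

All features are defined on one fixed short-time grid: analysis frames of
256 samples, zero-padded to a 1024-point FFT (bin spacing rate/1024), with
93% overlap *of the 256-sample frame*, giving a hop of round(256·0.07) = 18
samples and frame count ⌊(N−256)/18⌋+1. The zero-padding interpolates the
spectrum fourfold; it adds no resolution. Audio is first downsampled
(polyphase, anti-aliased) into a per-call-type analysis band of 22 050,
11 025 or 4 000 Hz. The band assignment follows each call type's frequency
range (wideband for screams and hoot series, narrow for low-pitched grunts)
and is configurable (`rate_map`), since only the three rates themselves are
protocol constants. The window defaults to Hamming and is configurable;
window choice mildly affects the tonality/noise and dominant-band features
(sidelobe level sets how much energy leaks across bins), which is why it is
surfaced in `RunConfig`.

## The 20 acoustic parameters

Frame-level primitives (frames with zero energy are skipped everywhere):

* **Energy-quartile frequencies** (`dfa1`, `dfa2`): smallest bin-centre
  frequency at which the cumulative squared magnitude reaches 25% / 50% of
  the frame total.
* **Dominant frequency bands**: maximal runs of contiguous bins whose
  magnitude is within `band_threshold_db` (default −24 dB) of the frame
  maximum; each band is summarised at its peak bin. This threshold is the
  single most consequential free parameter of the extraction — it defines
  `df1*`, `diffmean`, `diffreq`, `ampratio1`, `ranmean`, and the `fp1*`
  candidates — and is deliberately a config entry, not a constant.
* **First peak** (`fp1`): the lowest-frequency local spectral maximum at or
  above the band threshold; plateau ties break toward lower frequency, and
  if no local maximum clears the threshold the global peak is used.
* **Peak frequency** (`pf`): the single highest-energy bin.
* **Tonality class**: by spectral flatness (Wiener entropy, geometric over
  arithmetic mean of the power spectrum): tonal ≤ `tonal_cut`, noisy ≥
  `noisy_cut`, else neither. Defaults are 0.10 / 0.45. The noisy cut sits
  where it does because the flatness of a genuinely white frame does not
  approach 1: periodogram bins are approximately exponential, so flatness
  concentrates near e^(−γ) ≈ 0.56 (measured 0.57 ± 0.04 on this grid), while
  a frame of tone plus equal-power noise measures ≈ 0.31 and a pure tone
  ≈ 10⁻⁴. Note that *band-limited* noise occupying a minority of the
  analysis band has low full-spectrum flatness and will classify tonal or
  neither; the tonal/noisy percentages are therefore statements about
  spectral concentration relative to the whole analysis band, not about
  perceptual noisiness.

Segment-level aggregation: means/extrema over valid frames; the "location"
parameters `dfa1maloc`/`dfa2maloc` are the relative temporal position
(0 = first frame, 1 = last; 0.5 for a single frame) of the frame with the
maximum quartile frequency; `diffmean` is the *minimum* over frames of the
spacing between the first two bands, `ampratio1` the mean band1/band2
amplitude ratio over frames with ≥ 2 bands. When no frame has two bands,
`diffmean`/`ampratio1` are missing, and rows with missing values are deleted
listwise within the affected call type before discriminant analysis (DFA
needs complete vectors). Every threshold is relative to the frame maximum,
so all 20 features are exactly invariant to rescaling the waveform — a
property the tests verify. These definitions are documented surrogates for
the classical spectrogram-measurement toolchain; exact third-party
definitions of the band threshold, tonality criterion and location units
are not recoverable, so ours are stated in full and kept configurable.

## Variability and PIC

CV = 100·SD/mean with sample SD (n−1) throughout (the denominator is a
package choice). CV_inter pools all calls of a type; CV_intra is the
*unweighted* mean of per-caller CVs (callers contribute equally regardless
of n); PIC = CV_inter/CV_intra per parameter, and the overall PIC of a call
type is the ratio of the two 20-parameter CV means. A zero-mean parameter
leaves its CV undefined (missing, never silently zero). A composite
"average of per-caller SDs totalled with the SD of caller means" appears in
some descriptions of SD_intra but is internally inconsistent with the
CV_intra formula above; only the CV formula is implemented. Friedman tests
(mid-rank tie correction, χ² approximation — adequate at 20 blocks, and the
convention of SPSS-style software) compare CV or PIC profiles across call
types with parameters as blocks; a fully tied matrix returns χ² = 0, p = 1.

## Discriminant analysis

Forward-stepwise selection minimises Wilks' Λ = det(W)/det(T); a candidate
enters when its partial F = (Λ_p/Λ_{p+1} − 1)(n−g−p)/(g−1) ≥ `f_to_enter`
(default 3.84) and included parameters leave when their F-to-remove drops
below `f_to_remove` (default 2.71) — the common stepwise-DFA defaults.
Candidates that make the within scatter singular are skipped. Canonical
functions come from the generalized eigenproblem Bv = λWv, scaled to unit
pooled within-group variance; Λ = Π 1/(1+λᵢ), χ² = −(n−1−(p+g)/2)·ln Λ with
df = p(g−1) (Bartlett). Loadings are pooled within-group correlations
between every input parameter and the function scores.

Classification is linear DA with pooled covariance and **equal priors**
(chance = 100/g); ties break toward the lexicographically smallest caller
ID, making runs deterministic. Leave-one-out (U-method) refits per held-out
call, implemented by exact rank-one downdates of the within scatter
(Sherman–Morrison); the tests verify exact agreement with a literal
refit-per-sample loop. A fold whose removal leaves the held-out caller with
fewer than two calls is skipped.

## Permuted DFA

The pDFA attaches p-values to the observed rates. The parameter set is
fixed before the loop (no re-selection inside permutations). For unbalanced
designs the observed rates are averaged over `n_selections` (default 100)
random balanced subsets, drawing the minimum per-caller n from every
caller; each null iteration (default 1000) permutes caller labels and uses
one balanced subset. When segments are nested in sequences, labels are
permuted at sequence-block level so repeated segments of one vocalization
travel together — the tests confirm that a caller-confounded sequence
effect then does *not* masquerade as individuality. Block permutation of
unequal-size blocks can unbalance per-caller counts; arrangements leaving
any caller below the subset size are rejection-sampled (≤ 50 tries) before
relaxing the subset to the available minimum. P = (b+1)/(m+1) for both the
fitting rate (P₁) and the cross-validated rate (P₂), so p-values are never
zero and are floored at 1/(m+1).

## Mixed models

Parameters loading > `loading_cutoff` (default 0.45, absolute value, any
function) on the discriminant functions — always including the selected
set — are tested one at a time: a linear mixed model with caller identity
as fixed effect and sequence as random intercept, ML-fitted, against the
intercept-only null via likelihood ratio (χ², df = g−1), Hochberg's step-up
correction across the tested set. Degenerate fits (constant parameter)
yield missing p-values; non-convergent random-intercept fits fall back to
a fixed-effects LRT with a warning. The cross-call-type comparison arcsine-
square-root transforms per-caller leave-one-out proportions and fits call
type as fixed factor, caller as random intercept and centred log n-calls as
covariate; the call-type factor is assessed by a Wald F. The original
protocol's "number of calls as random factor" is under-specified, so this
structure is the package's own, stated here rather than asserted as anyone
else's.

## Synthetic data

`synth_feature_table` draws caller parameter means as
population mean + effect_size · within-SD · unit offset, where the unit
offsets are standard-normal draws per signature parameter, centred across
callers and normalised to unit RMS — so `effect_size` is exactly the
planted between-caller spread in within-SD units, and `effect_size = 0`
makes callers exchangeable (the null for calibrating the pDFA). Calls are
independent normals with diagonal within-caller covariance around
caller-plus-sequence means (sequence random intercept 0.5 within-SD by
default); population means and SDs imply CVs of roughly 25–40%, the range
typical of graded great-ape repertoires. Rows are post-processed into
feasible feature vectors (min ≤ mean ≤ max triples re-sorted, bounded
parameters clipped) — clipping slightly truncates planted effects on
bounded parameters near their limits. Defaults are 3 callers × 20 calls
per call type, with unequal designs (e.g. 24/18/10) available to exercise
the balanced-subset path.

`synth_waveform` renders three structural templates — pulsed grunts
(amplitude-modulated low harmonics), harmonic series (caller-shifted f0
with spectral tilt, 3% within-caller f0 jitter), band-limited noise with
caller-shifted edges — plus a white noise floor at configurable SNR
(default 30 dB). What the generator does **not** emulate: correlated
within-caller covariance (a diagonal default, correlated structure being
unavailable information), formant structure, frequency modulation,
reverberation, varying recording distance, or overlapping background
vocalizations. Passing tests therefore demonstrate that the *chain* is
correct and calibrated, not that real recordings of any species would
yield a particular accuracy.

## Problem sizes and determinism

The test-suite and acceptance-script simulations run at 3 callers × 20
calls, 100 null replicates, and 200 permutations per pDFA — sizes chosen so
the permutation floor (1/201) sits well below α = 0.05 while the whole
calibration stays desk-scale; the protocol-default 100 selections × 1000
permutations remain the pipeline defaults. Every random draw flows from an
explicit seed (per-call-type seeds derive from the run seed); identical
config + seed reproduces byte-identical CSV/JSON reports.

## Known limitations

* The chain analyses pre-cut segments; call detection/segmentation and
  noise reduction are out of scope, as are pitch tracking, LPC formants and
  frequency-modulation measures.
* The χ² approximations (Bartlett, Friedman, LRT) are asymptotic; at very
  small n the pDFA's permutation p-values are the trustworthy ones.
* With n_min = 2 per caller, leave-one-out skips every fold and P₂ is
  undefined; cross-validated results at < 10 calls per caller are unstable
  and should be read alongside P₂.
* Stepwise selection with many parameters and few calls overfits; the
  resubstitution/leave-one-out gap and P₁ vs P₂ make this visible rather
  than preventing it.
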