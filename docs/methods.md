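# Methods

## Model and estimators

### Wavelet phase decomposition

Each channel/trial is decomposed with a complex Morlet continuous wavelet
transform, computed in the frequency domain: the signal spectrum is
multiplied by a one-sided Gaussian centred at f₀ with width
σ_f = f₀ / cycles (the Fourier transform of a Morlet wavelet whose
temporal envelope has s.d. σ_t = cycles / (2π f₀)), then inverse
transformed. The gain is unity at the centre frequency, so a pure
sinusoid of amplitude A yields coefficients of modulus A. This
formulation imposes no minimum epoch length (a time-domain convolution
kernel for θ at 7 cycles is longer than a 1 s epoch) and is exactly
linear. Zero-padding to beyond ten low-frequency envelope widths prevents
circular wrap-around; samples within one e-folding time (√2 σ_t) of the
epoch edges are flagged by `WaveletCoefficients.edge_valid()` and can be
excluded downstream.

Defaults: 1 Hz frequency spacing within the band of interest,
`cycles = 7`. Both are conventional for event-locked rhythm analysis and
are exposed as parameters. Band edges are closed on both sides, so the
shared edges 5, 8 and 14 Hz belong to both neighbouring bands.

### PLI and wPLI

Given per-trial cross-spectra S = W_c · conj(W_c′):

- PLI = |E_n{sgn Im S}| — sign consistency of the lag, magnitude-blind;
- wPLI = |E_n{Im S}| / E_n{|Im S|} — imaginary-part-weighted, which
  nulls contributions from near-zero-lag trials. When every trial's
  imaginary part is exactly zero (perfect zero-lag degeneracy) the
  estimator is defined as 0.

wPLI is deliberately computed from the **unnormalised** cross-spectrum:
on a unit-normalised cross-spectrum with the literal magnitude weighting
(`wpli(..., weight="magnitude")` on `cross_spectrum(..., normalize=True)`)
the weights are constant and wPLI collapses exactly onto PLI, erasing the
distinction between the two metrics. Both variants exist so the collapse
is a testable property rather than a footnote.

### Trial-count matching across conditions

PLI and wPLI are positively biased at finite trial counts, and the bias
shrinks roughly as n^(-1/2). With rare targets (20% of trials) the two
condition ensembles differ fourfold in size, so a naive per-condition
comparison is biased *by construction* — on pure noise the target
estimate systematically exceeds the non-target one, and every
label-based test would reject. `subject_connectivity` therefore
subsamples the larger condition to the size of the smaller one by
default (seeded, reproducible). This is the standard remedy in
trial-ensemble phase-synchrony work; the cost is discarding some
non-target trials. Type-I simulations (noise-only data, 20 seeds)
confirm the matched comparison is clean.

The per-condition split happens **before** the ensemble statistic: each
condition's synchrony is estimated from its own trials, which is the only
reading that yields genuinely label-specific synchrony.

### Windowing

Window schemes are ordered, contiguous, half-open intervals `[start, end)`
covering the analysis extent, so every sample belongs to exactly one
window. Fixed schemes divide the extent into ⌊length/τ⌋ windows with any
remainder absorbed into the final window (never dropped); variable
schemes are delimited by externally supplied change points; the
whole-extent scheme is the stationary baseline (τ = T). Windowing applies
to the post-stimulus extent [0, 0.8] s by default — the prestimulus
interval is the baseline, not part of the analysis — with the extent
configurable. The per-window representative value is the within-window
mean, which makes refinement exactly consistent: window means weighted by
sample counts reconstruct the global mean to machine precision.

### Link selection

*pUTh* (unsupervised): per window, keep links whose across-subject mean
connectivity is ≥ q × the maximum mean over links. q defaults to 0.7
(sensible sweep range 0.4–0.9); raising q never adds links.

*pSTh* (supervised): per (window, link), a two-sided Mann–Whitney U test
between the M target and M non-target subject values; per (subject,
link), the same test between the N_τ-long target and non-target window
series. The exact null enumeration is used when the combined sample size
is ≤ 16 with no ties, otherwise the normal approximation with midrank tie
correction and continuity correction. Benjamini–Hochberg FDR runs across
the V links within each (band, window) family by default (switchable to a
global family); a p-value equal to its step-up threshold is rejected.

The across-window test treats windows as exchangeable units although
neighbouring windows are serially correlated (the wavelet envelope alone
correlates them); the FDR correction mitigates but does not remove this,
and it is the main caveat on the per-subject masks.

Combination: κ = (OR over per-window masks) AND (OR over per-subject
masks). The conjunction keeps only links supported both by a
window-localised group effect and by at least one subject's window
dynamics; it is what suppresses most isolated false positives in the
recovery simulations.

### Decoding and segmentation

The variable-window boundaries come from a time-resolved decoding curve:
a sliding window (default 100 ms, 20 ms step) over the epoch, and inside
each window a stratified k-fold cross-validation (default 10-fold) where
CSP filters are fitted on training folds only, log-variance features feed
an LDA with Ledoit–Wolf shrinkage, and the held-out fold is scored. CSP
solves the generalised eigenproblem S₁w = μ(S₁+S₂)w of the
trace-normalised class covariances; the top-k and bottom-k eigenvectors
(k = 3 per class by default) are scaled so the filtered variance under
the composite covariance is 1.

The score is **balanced accuracy** (mean of per-class accuracies) by
default: with 20% targets, plain accuracy has a chance level of ~0.8 set
by the majority class, whereas balanced accuracy sits at 0.5 at any class
ratio, making "above chance" well-defined; `scoring="accuracy"` restores
the plain fraction correct.

Change points are found by exact dynamic programming over piecewise-linear
segment fits (per-segment residual sums of squares from prefix sums, so
the DP is exact and checkable against exhaustive search), with the
segment count chosen by BIC
(n·log(RSS/n) + (3k−1)·log n) up to a maximum. The curve is smoothed with
a 50 ms moving average first (configurable, 0 disables). A
smoothed-derivative-extrema detector is available behind
`method="derivative"` as the less principled but more literal
"where the derivative changes" alternative.

## Synthetic data: what it emulates and what it does not

The generator mirrors the multi-subject oddball recording geometry:
M = 17 subjects, C = 34 channels, N = 375 trials at target probability
0.2 (first two trials forced non-target), 1 kHz sampling, epochs
[−200, +800] ms — all configurable, and tests use reduced M/C/fs for
speed.

Couplings are narrow-band Gaussian noise (band-pass-filtered white noise,
±1 Hz around the centre), one independent realisation per trial, tapered
to the coupling window by a Tukey envelope, with the second channel's
copy rotated in phase through the analytic signal. Trial-to-trial phase
variability is therefore intrinsic — a pure sinusoid would make PLI/wPLI
degenerate — while the inter-channel lag is held fixed. `snr` is the
amplitude ratio of the oscillation (RMS inside its window) to the
unit-variance sensor noise; a per-subject log-normal multiplier
(sd `subject_jitter`, default 0.2) emulates between-subject amplitude
variability. Noise is white by default, with AR(1) and 1/f (pink)
alternatives. The zero-lag control injects the *identical* signal into
both channels (and/or applies an instantaneous mixing matrix), which is
the sensor-level signature of volume conduction.

Not emulated: realistic head geometry or lead fields (mixing is an
arbitrary linear operator), ERP waveform shape, artifacts (blinks,
muscle), electrode noise correlations, or non-stationary background
rhythms. Passing tests therefore demonstrate that the *estimators and
selection rules* behave correctly under controlled phase-lagged coupling
and realistic trial statistics — not that any particular real dataset
would yield a particular graph.

## Numerical choices and degenerate inputs

- Filters (1 Hz high-pass, ±1 Hz notches at 60/120 Hz, 120 Hz low-pass)
  are 4th-order Butterworth run forward-backward, preserving phase.
- wPLI denominators of zero return 0; single-trial ensembles warn.
- Rank-deficient CSP covariances raise an error that names the shrinkage
  remedy; `reg` shrinks toward the scaled identity.
- Zero-variance decoding features warn and are floored at log(1e-30).
- Noiseless segmentation (RSS = 0) is handled by flooring RSS in the BIC
  at 1e-12·n, so the smallest adequate segment count wins.
- Window boundaries tolerate 1e-9 s of floating-point slack; sample
  membership is half-open with the final window including its endpoint.
- All pipeline randomness derives from one root seed via
  `numpy.random.SeedSequence` spawns (simulation, trial matching,
  classifier folds, consistency permutations), making end-to-end runs
  byte-identical under a fixed config.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run at desk scale, chosen so
the full suite completes in a few minutes on one CPU: planted-link
recovery at M = 10 subjects, C = 10 channels (45 links), N = 80 trials,
snr = 2, 10 seeds; type-I control at M = 8, C = 8, N = 48 over 20 seeds;
zero-lag diagnostics at snr = 5 with 200 surrogates over 20 seeds;
decoding at M = 2, C = 6, N = 80, snr = 4. At these sizes the supervised
pipeline attains sensitivity 1.0 on planted links with a false-positive
fraction well inside the α = 0.05 binomial band, and the noise-only
selected fraction is ≈ 0.

## Known limitations

- The across-window Mann–Whitney ignores serial correlation (above).
- With very few subjects (M ≤ 4) the across-subject test cannot reach
  p < 0.05 after FDR at realistic link counts; group analyses need
  M ≳ 6 to have any power and M ≥ 10 for reliable recovery.
- wPLI's trial-count bias is handled by matching, not by an analytic
  debiasing; unmatched comparisons remain available but are not
  label-comparable.
- The amplitude rule (pUTh) keys on group-mean connectivity and is
  condition-blind by design; it selects strong links, not discriminative
  ones.
- No artifact rejection, re-referencing or resampling is performed;
  readers preserve whatever reference the file carries.
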