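# Methods

## Problem and scope

`phaselag` estimates resting-state EEG phase synchronization between
scalp electrodes in a way that is robust to volume conduction, tests it
against per-subject empirical nulls, contrasts it between a case group
(mild traumatic brain injury) and controls, and correlates the
null-normalized synchrony with white-matter microstructure (fractional
anisotropy, FA) of a designated tract.  The package covers the full
chain from raw multichannel recordings to the final statistical report,
plus a synthetic cohort generator that makes every stage testable
without clinical data.

## Synchronization estimators

For channels 1 and 2, let X₁(f), X₂(f) be discrete Fourier transforms
of one 1-s epoch (rectangular window, so integer-Hz bins).  The
cross-spectrum is S(f) = X₁(f)·X₂*(f) = r₁r₂·e^{iΔθ}; its imaginary
part r₁r₂·sin Δθ is non-zero only for lagged (non-instantaneous)
coupling.  Volume conduction is quasi-instantaneous at scalp scale, so
statistics built solely on Im S are insensitive to it.  Across epochs j
= 1..N:

* **WPLI** = |⟨Im S⟩| / ⟨|Im S|⟩ — phase-lead/lag asymmetry weighted by
  the magnitude of Im S (lags near the real axis, which flip sign under
  small noise, contribute little);
* **PLI** = |⟨sign Im S⟩| — the unweighted sign asymmetry;
* **debiased WPLI-square** = Σ_{j≠k} Im S_j Im S_k / Σ_{j≠k} |Im S_j Im S_k| —
  an asymptotically unbiased estimator of WPLI², evaluated in the O(N)
  algebraic form ((ΣI)² − ΣI²)/((Σ|I|)² − ΣI²).

The debiased square is the primary measure throughout; it can be
negative in finite samples and is deliberately **not clipped** at 0 —
clipping would re-introduce bias and break the surrogate z-scoring,
which presumes a signed statistic.  When every Im S_j is exactly zero
(identical or purely zero-lag channels) all three measures return 0 by
convention: pure instantaneous coupling is precisely what they are
designed to ignore.

Band summaries are arithmetic means over inclusive integer bins —
theta 4–7, alpha 8–13, beta 15–23, low-gamma 25–40 Hz — and the
"global" statistic is the mean over all unordered EEG channel pairs.
Epochs enter the FFT untapered and undetrended: at 1-s epochs the bins
are exactly 1 Hz apart and the synthetic carrier sits on a bin, so no
leakage correction is needed; this is also the simplest defensible
reading for real data.

## Preprocessing

Fixed order, each stage deterministic:

1. **EOG regression** — each EEG channel is replaced by its
   least-squares residual after regressing on all EOG channels plus an
   intercept over the full continuous recording.  Residuals are exactly
   orthogonal to the ocular regressors; zero-variance EOG channels are
   dropped with a warning.  Trial-averaged refinements of the classic
   regression approach are unnecessary for resting data (no events).
2. **Band-limiting** — zero-phase (forward–backward) Butterworth
   cascade: 4th-order high-pass at 0.5 Hz plus 13th-order low-pass at
   50 Hz.  Phase metrics demand zero-phase filtering.  The low-pass
   order is chosen so that the *two-pass* response still attenuates
   60 Hz mains to ≤ 1% amplitude (measured −41 dB at fs 2048) while the
   2–40 Hz passband stays within 5%; a 4th-order low-pass would leave
   60 Hz at ~34% after two passes, which is unusable next to a 50 Hz
   edge.
3. **Resampling** — polyphase anti-aliased downsampling to 256 Hz
   (refuses to upsample).  Redundant given the 50 Hz low-pass, but kept
   for robustness under configuration changes.
4. **Epoching** — consecutive non-overlapping 1-s windows from sample
   0; a trailing partial window is dropped (150 s → 150 pseudotrials).
   A single epoch is permitted here; the N ≥ 2 requirement of the
   pairwise estimator is enforced at estimation time, where it belongs.
5. **Artifact rejection** — a trial is rejected iff any EEG-channel
   sample exceeds the threshold (default 75 µV) in absolute value.
   Read as instantaneous amplitude, not peak-to-peak, and EOG channels
   do not count; both are configuration knobs.  If every trial is
   rejected the subject is named in the error.

## Surrogate nulls

Per subject, each channel's retained samples (concatenated across
retained epochs) are independently permuted and re-segmented — the
marginal amplitude distribution is preserved exactly (a permutation),
while all temporal and cross-channel structure is destroyed.
Sample-level (not epoch-level) permutation is required for the null to
destroy within-epoch phase structure.  B surrogates (default 1,000) of
the target statistic give an empirical null; the observed statistic is
summarized as an add-one permutation p-value, (1 + #{null ≥ obs})/(1 + B)
(one-sided "greater" by default, two-sided by flag), and a z-score
(obs − null mean)/null SD with the sample SD (B − 1 denominator).
Replicate b draws its generator from the b-th child of
SeedSequence(master), so nulls are reproducible and order-independent.
Shuffling operates on post-rejection epochs, so observed statistic and
null use identical data.

## Group statistics

* Synchrony contrasts use the Wilcoxon rank-sum test: exact null
  enumeration when the pooled sample is ≤ 12 and tie-free, otherwise
  the normal approximation with tie and continuity corrections
  (cross-validated against full enumeration in the tests).
* The band→pair procedure is hierarchical: across-pairs band means are
  tested per band (uncorrected); only bands significant at α descend to
  per-pair tests, reported uncorrected by default (a Holm flag exists).
  This mirrors standard screening practice for a small montage.
* Demographics: pooled-variance two-sample t (df = n₁ + n₂ − 2),
  oriented (control mean − case mean)/SE so that higher case scores give
  negative t.  Fisher's exact test for 2×2 categorical tables reports
  both the standard two-sided sum and the hypergeometric point
  probability of the observed table — published tables are ambiguous
  about which convention they print, so both are surfaced.
* FA screening: pooled t per (ROI, side) with Holm–Bonferroni across
  all rows (28 in the default tract vocabulary); ROIs missing for more
  than half the cohort are dropped with a warning.
* Correlation: Pearson r with significance from t = r·√((n−2)/(1−r²))
  on df = n − 2 by default.  A Fisher-z variant (atanh r·√(n−3) against
  the normal) is available by flag; the t-form is the default because
  it reproduces published significance levels for the r/n combinations
  in the reference tables (e.g. r = 0.68, n = 12 → t = 2.93, p ≈ 0.015).
  Missing values are dropped pairwise per variable.

## Synthetic cohort model

Each subject has a coupling strength κ_i ~ Normal(group mean, κ_sd)
clipped at 0 (clipping, not redraw-truncation, keeps a κ-mean-0 group
centered at 0).  Each 1-s block b of the recording draws a common
carrier phase φ_b ~ U(0, 2π); channel c carries
A·cos(2πf₀t + φ_b + δ_c + η_{b,c}) with η_{b,c} ~ von Mises(0, κ_i).
Defaults: A = 10 µV, f₀ = 32 Hz (inside the low-gamma band), per-channel
offsets δ spanning 0–π/2, κ-means 4 (control) vs 0 (case), κ_sd 0.5.
Additional components: a broadband Gaussian process added identically to
every EEG channel (zero-lag "volume conduction", gain 2 µV), a < 4 Hz
smoothed ocular process leaked with fixed per-channel factors
(0.03–0.12) and emitted noiselessly as the two EOG channels (so the
regression correction is exactly solvable), and white sensor noise
(5 µV).  An optional artifact flag adds Hann-tapered 250 µV 5 Hz bursts
to a chosen fraction of blocks; tapering confines the excursion to its
block so the injected rate is recovered exactly by the rejection stage.

FA: the designated ROI (right inferior cerebellar peduncle by default)
follows baseline + slope·(κ_i − κ̄) + Normal(0, σ_FA) with defaults
baseline 0.285, slope 0.005 per κ unit and σ_FA 0.004 — calibrated so a
κ contrast of 4 reproduces the ~0.02 FA group difference and row SDs of
the published reference table, from which all other ROIs take their
baselines (plus the same noise, slope 0).

**Population oracles.**  For phase difference Δθ = δ + η with a single
von Mises(0, κ) jitter, `expected_wpli` returns
|sin δ|·(I₁(κ)/I₀(κ)) / E|sin Δθ| with the denominator by adaptive
quadrature (absolute tolerance 1e−8; the |sin| kinks are passed as
break points).  Because the generator jitters *both* channels, a pair's
phase difference is δ + η₁ − η₂; `expected_pair_wpli` handles this case
via the Fourier series of the difference density (coefficients
(I_n(κ)/I₀(κ))², summed to machine precision on a 2¹⁵-point periodic
grid).  The single-jitter form is the natural estimator-level oracle
(draw Δθ directly); the pair form is the recovery oracle for the full
generator.  Both reduce correctly at the edges: κ = 0 or δ = 0 give 0;
κ → ∞ with sin δ ≠ 0 gives 1.

A documented fast path, `simulate_epochs`, emits epoched data directly
at the analysis rate.  It implements the identical phase model (blocks
and epochs are both 1-s and sample-aligned; the carrier sits on an
integer bin), skipping only the continuous-time plumbing, and is used
for estimator-level Monte-Carlo studies; a test verifies its agreement
with the full recording path.

**What the generator does not emulate:** realistic 1/f background
spectra, a biophysical forward model or electrode geometry, heartbeat
and muscle artifact, non-stationary drowsiness effects.  Passing tests
therefore certify the *estimators and inference machinery* under a
controlled coupling model, not clinical performance on real EEG.

## Reference tables

`phaselag.reference_data` embeds the printed group summaries of a
published military mTBI case–control study (demographics/questionnaires
for 15 cases vs 22 controls; per-ROI FA for 12 vs 17).  They serve as
worked-example inputs — recomputing pooled t-statistics from printed
means/SDs, the Holm adjustment of the smallest ROI p-value (0.0015 →
0.042 across 28 tests), the Fisher point-probability convention — and
as the ROI vocabulary and FA baselines of the generator.  The package
never asserts these numbers as outputs of its own pipeline.

## Problem sizes and numerical choices

Monte-Carlo studies in the test suite and acceptance script use scaled
designs chosen to estimate each property with adequate precision:
200 subjects for unbiasedness/calibration checks (3-SE bands),
100–200 cohort replicates for power and α-level (binomial SE ≈ 2%),
10–20 replicates for the structure–function sign-recovery (each
replicate runs the full pipeline on a 14-subject cohort at 256 Hz with
B = 100 surrogates), and N = 20,000 epochs for the convergence bound.
Cohort-level studies use 2- or 5-channel montages; the estimators are
per-pair, so pair count affects only averaging, not correctness.

Determinism: all generator and surrogate randomness flows from
`numpy.random.SeedSequence` spawning, so cohorts and nulls are
bit-reproducible given (config, seed), and rerunning the pipeline with
the same seed yields byte-identical statistics reports.

Degenerate inputs: 0/0 synchrony ratios return 0; zero-SD nulls raise
(naming the statistic) rather than z-scoring against nothing; constant
FA raises in the correlation; an all-rejected subject raises with the
subject id.

## Known limitations

* The EDF writer targets the plain 16-bit EDF profile (no annotations,
  one fixed record duration); it exists because no pre-installed
  library exports EDF, and round trips are verified against the `mne`
  reader to one quantization step.
* The rejection criterion is a single absolute-amplitude threshold; no
  ICA, channel interpolation or re-referencing is provided.
* Surrogates are sample-permutation only (no phase-randomization or
  block permutation variants).
* The hierarchical contrast controls error rate informally (screening
  then uncorrected pair tests); it reproduces a published workflow
  rather than a formal gatekeeping procedure.
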