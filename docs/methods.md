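# Methods

`nvcpipe` estimates resting-state neurovascular coupling (NC) from
simultaneous EEG and continuous-wave fNIRS, tests group differences, and
classifies subjects from the coupling metrics. This note documents the
model, the numerical choices, and what the synthetic benchmark does and
does not establish.

## Signal model and processing chain

**EEG.** Recordings (128 channels, 250 Hz) are cleaned with an automatic
channel QC (reject above ±500 µV or flat), a zero-lag 2nd-order
Butterworth band-pass (1–80 Hz) with a 50 Hz notch, and optionally an
automatic ICA screen (components flagged by |excess kurtosis| > 5 or
|correlation| > 0.7 with a frontal 1–4 Hz reference; flagged components
zeroed). Each cleaned channel is decomposed into theta (3.5–8.2 Hz),
alpha (7.4–13 Hz) and beta (13–30 Hz) bands — the theta/alpha overlap is
kept as defined — and the band power envelope is the magnitude of the
analytic (Hilbert-transformed) band signal.

**fNIRS.** Dual-wavelength (690/830 nm) intensities from 16 long (35 mm)
and 4 short (15 mm) channels at 10.42 Hz become optical densities
OD(t) = −ln(I(t)/I_m), I_m the rest-period mean. Motion artifacts are
corrected by kurtosis-based wavelet filtering (below), the densities are
band-passed 0.01–0.4 Hz (zero-lag 4th-order Butterworth), channels with
implausible post-filter variance are QC-flagged, and the modified
Beer–Lambert law converts the two wavelengths to ΔHbO/ΔHbR (µM):

    [ΔHbO; ΔHbR] = (1/ρ) · M⁻¹ · [OD₈₃₀; OD₆₉₀],
    M[λ, c] = ε_c(λ) · DPF(λ, age)

with ρ the interoptode distance, ε molar extinction coefficients
(shipped as a versioned plain-text table; standard compiled hemoglobin
values) and DPF the general age- and wavelength-dependent differential
pathlength polynomial (shipped as JSON, validity 650–900 nm and 18–100
years).

**Coupling estimation.** Per band, channel envelopes are z-scored and a
temporal PCA extracts the first principal component (sign fixed to
positive mean loading) — a volume-conduction-robust global band
envelope; its explained-variance fraction is retained. Each global
envelope is convolved with a canonical double-gamma HRF (gamma shapes
6 and 16, undershoot ratio 6, 32 s support, peak-normalized; peak ≈ 5 s),
block-averaged to 1 Hz, and z-scored. The GLM per long channel regresses
the z-scored 1 Hz hemoglobin series on the three band predictors, the
four z-scored short-channel series of the *matching* chromophore
(standard scalp-nuisance practice), and an intercept. Operations are
ordered convolve → resample → z-score so the coefficients are
standardized betas; the first 30 s after convolution are discarded. The
six subject metrics are the band betas averaged over (QC-surviving) long
channels for HbO and HbR. Unimodal controls: mean squared band envelope
(EEG) and the per-channel hemoglobin SD averaged over long channels
(fNIRS).

**Statistics and classification.** One-sample t-tests per group (is a
coupling nonzero?) and pooled-variance two-sample t-tests (patients vs
controls, df = n₁+n₂−2), two-tailed, no multiplicity correction across
the six metrics — the multivariate analysis is the guard against that.
Classification uses leave-one-out OLS regression of the 0/1 label on the
features; out-of-fold predictions are scored by ROC. AUC is the
rank-based Mann–Whitney statistic (ties half-weighted); its significance
is z = (AUC−0.5)/SE₀ with SE₀ the Hanley–McNeil standard error evaluated
at the null AUC (= √(3/(n₁n₂))), one-sided p. Reported loadings are the
fold-mean coefficients; their z-scores divide by the SD of full-sample
refits over 10,000 subject bootstrap resamples (single-class resamples
redrawn). Sweeps rerun metric extraction and classification on centered
time windows (15–300 s, step 15) or seeded random channel subsets
(4–128, step 4); the full window / full channel set reproduce the full
analysis exactly (identical code path).

## Kurtosis-based wavelet motion correction

Each OD series is decomposed (sym8, depth such that the coarsest detail
band sits near 0.1 Hz). A detail level whose coefficient kurtosis
(Pearson; Gaussian = 3) exceeds 3.3 has coefficients beyond 3 robust
SDs (1.4826·MAD) zeroed, iterating until the level kurtosis falls below
threshold. Two numerical details matter:

- *Finite-sample guard.* Sample kurtosis of an n-coefficient level has
  SE ≈ √(24/n) under Gaussianity; coarse levels of a 300 s record at
  10.42 Hz have only ~50–300 coefficients, so a fixed 3.3 threshold
  trips on perfectly clean data. The threshold is floored at
  3 + 4·√(24/n). Measured artifact levels sit at kurtosis 40–750, far
  above either bound, so sensitivity is unaffected while clean Gaussian
  input passes through essentially unchanged (<2% RMS).
- The corrector assumes each detail level contains a noise bulk against
  which outliers are defined. Very short records (≲1 min) push the
  decomposition into boundary-dominated levels where this fails; the
  intended regime is the full ~5 min recording.

## Zero-phase filtering and envelope rate

Forward–backward Butterworth filtering has transfer function |H(f)|²
with exactly zero phase. The EEG path applies that gain directly in the
frequency domain (periodic edge handling; ends trimmed downstream),
which is numerically equivalent inside the record and roughly an order
of magnitude faster on high-density arrays; `method="filtfilt"` is
available and tested to agree. Because the analytic signal of a
band-passed series is one-sided and band-limited, its exact samples on a
decimated grid come from a truncated spectrum: the pipeline evaluates
envelopes at fs/3 ≈ 83.3 Hz (≥ 2.5× the highest band edge; alias gain
< 3%). The public single-band API returns full-rate envelopes; the
pipeline rate is configurable (`envelope_decim`). The six coupling
metrics move by ≲0.01 between the two rates.

Resampling to 1 Hz uses non-overlapping block averaging on a time-bin
grid, which is anti-aliasing by construction and handles the non-integer
10.42 Hz ratio. Envelope and hemoglobin edges (5 s, capped at 5% of the
window for short sweeps) are trimmed before z-scoring; the convolution
transient trim is 30 s, capped at 20% of the window.

## Synthetic cohort: what it emulates

Each subject is generated forward from raw signals so every pipeline
stage is exercised:

1. Band-limited Gaussian latents (the three bands) at 250 Hz.
2. EEG = smooth all-positive random spatial lobes (8–12 µV) mixing the
   latents across a sunflower-disc montage + 5 µV white sensor noise —
   a caricature of volume conduction, not a head model.
3. Hemoglobin drive: each latent's Hilbert envelope, HRF-convolved and
   variance-normalized, enters long-channel HbO/HbR with the group's
   signed coupling weights (controls default to theta–HbO = alpha–HbR
   = 0.4; patients to 0, i.e. un-coupling). A systemic scalp signal
   (0.08–0.12 Hz vasomotion + 0.2–0.3 Hz respiration, HbR at 0.4× the
   HbO waveform) leaks into long channels (gain 0.3) and fully occupies
   short channels. Couplings are signed and free because the
   physiological sign convention (e.g. for alpha–HbR) is itself an
   empirical question.
4. Channels are normalized to a fixed 0.5 µM SD — coupling alters the
   correlation structure, not the fluctuation power, so unimodal power
   metrics do not separate the groups (matching the phenomenon the
   cohort emulates).
5. Forward Beer–Lambert (the same ε/DPF tables the pipeline inverts)
   gives OD; optional motion artifacts are exponentially decaying steps
   of random sign (5–10× the channel OD SD) in OD space; 0.002 white OD
   noise models the photon/electronics floor; I = I_m·exp(−OD) with
   channel-specific positive I_m.

Ages are N(73, 7.5) truncated at 50. All randomness derives from spawned
seed sequences; cohorts are bit-reproducible.

**What passing tests show — and don't.** Recovery tests demonstrate that
the chain estimates the planted couplings monotonically (R² > 0.5
against truth), that short-channel regression removes scalp
contamination, that the planted group difference is found by exactly the
right two metrics, and that LOO-CV separates the groups. They do not
show that real aging/atrophied-head EEG-fNIRS behaves this way: there is
no head geometry, no inter-subject coupling heterogeneity (group
couplings are fixed, so group t-statistics on synthetic data are far
larger than any real cohort would give), no physiological drift or
heartbeat, and EEG noise is white. The synthetic benchmark validates the
estimator, not the biology.

## Problem sizes used in the checks

Unit and property tests run scaled-down subjects (typically 16–32 EEG
channels, 60–120 s) — the estimator is size-agnostic and these keep the
suite fast. The acceptance recovery test runs the full design: 20
replicate cohorts of 17 patient-like + 18 control-like subjects, 300 s,
128 channels (the two planted metrics must give the two smallest
p-values in ≥80% of replicates and median LOO-CV AUC must exceed 0.85).
`scripts/acceptance.py` re-runs the same analysis on 5 full-size cohorts
plus the worked examples, oracle comparisons, Beer–Lambert round trip,
10,000-draw t-test calibration and the sweep identity checks.

## Known limitations

- ICA cleaning defaults off in the cohort pipeline (synthetic data are
  artifact-free unless injection is requested); it is intended for real
  recordings and is exercised by its own tests.
- The independent-samples AUC-difference test assumes uncorrelated
  AUCs and must not be used to compare classifiers scored on the same
  subjects; no paired AUC comparison is provided.
- EDF files are read but not written (no EDF writer dependency); the
  interchange bundle and SNIRF cover synthetic-data export.
- LOO out-of-fold scores are pessimistically biased under the null
  (anti-learning), so permutation nulls of the *refit* analysis center
  slightly below AUC 0.5; significance against 0.5 uses the closed-form
  null SE instead.
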