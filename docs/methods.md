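# Methods

This note records the model, the conventions and the genuinely open design
choices behind `ecghc`, in the spirit of a package reference manual.  It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Ordinal quantifiers

**Symbolization.** A series `x₁ … x_K` embedded at dimension `D ≥ 2` and
delay `τ ≥ 1` yields `K − (D−1)τ` windows `(x_k, x_{k+τ}, …, x_{k+(D−1)τ})`.
Each window is replaced by its rank word (the rank of each sample within
the window, earliest sample ranked lowest on ties) and the word is indexed
by its position in the *reverse-lexicographic* ordering of the permutations
of `(1..D)`: the fully descending window is type 1, the fully ascending
window is type `D!`.  For `D = 3` the order is `(321), (312), (231), (213),
(132), (123)`, so `(1,2,5) → 6`, `(2,5,4) → 5`, `(5,4,3) → 1`.  This
enumeration extends deterministically to every `D` and is frozen by the
acceptance script.

**Ties.** Rank ties are broken by temporal order (the standard Bandt–Pompe
convention), which makes a constant segment read as "ascending".  An
optional `tie_jitter` argument adds sub-resolution uniform noise before
ranking for data with heavy quantization; it is off by default so that
identical inputs give identical outputs.

**Normalization.** Pattern probabilities are counts divided by the *actual*
number of extracted windows, `K − (D−1)τ`, which sums to one for every
delay.  (Some presentations write the denominator for the special case
`τ = 1`; using the actual window count is the only choice consistent with
arbitrary delays.)  A warning — not an error — is raised when a series
yields fewer than 5·`D!` windows, where the PDF estimate becomes coarse;
per-beat windows at the defaults (506 windows over 24 patterns) sit above
this line by design.

**Quantifiers.** Entropy uses the natural logarithm throughout, `H = S/ln L`
with `L = D!`.  The Jensen–Shannon divergence is computed in its entropy
form `J[p,q] = S[(p+q)/2] − S[p]/2 − S[q]/2`; its square root is a metric,
which the tests verify on random triples.  The disequilibrium constant
`Q₀` is evaluated exactly as `1 / J[δ, Pₑ]` for a degenerate `δ`; that the
degenerate distribution maximizes `J[·, Pₑ]` over the simplex is confirmed
in the tests by direct numerical maximization at `L = 6` rather than
assumed.

**Envelope.** For fixed `L`, both complexity extremes at given entropy are
attained on one-parameter families with `m = 0 … L−2` components exactly
zero and one free component among the remaining `s = L − m`.  Entropy is
monotone in the free parameter on each side of the within-branch uniform
point, so `Cmin(H)`/`Cmax(H)` are evaluated *exactly* by bisection per
branch and min/max over branches; the exported grid is a rendering of these
exact functions, and containment checks never interpolate.  Containment of
10,000 Dirichlet-sampled distributions and agreement with a dense
brute-force family scan at `L = 6` are tested.

## Preprocessing and beat processing

Pipeline order: notch → baseline → Kors → modulus.  All voltages are in
microvolts end-to-end.

- **Notch.** "2nd-order Butterworth at the mains frequency" is implemented
  as a band-stop with −3 dB edges ±1 Hz around the line frequency
  (default 60 Hz, configurable for 50 Hz mains), applied forward–backward
  for zero phase.
- **Baseline.** One knot per beat at the midpoint of the 20 ms pre-Q
  segment (an isoelectric PR-region point); the baseline estimate at a knot
  is the median voltage in a 20 ms window, interpolated with a not-a-knot
  cubic spline and held constant beyond the outermost knots.  The
  not-a-knot end condition is used because the natural condition leaves a
  visibly larger residual near the record edges for smooth respiratory
  wander.
- **Kors transform.** The published 3×8 regression matrix (rows X, Y, Z
  over leads I, II, V1–V6) is embedded as a named constant and exposed in
  the packaged YAML for audit; tests exercise linearity rather than
  clinical values.
- **R detection.** The built-in detector (band-pass 5–25 Hz, squared
  derivative, 120 ms integration, adaptive threshold, 250 ms refractory,
  peak refinement) is a deliberately simple stand-in for full wavelet
  delineation.  Exact fiducials can be supplied via the JSON sidecar and
  bypass it entirely; the synthetic generator emits them as ground truth.
- **Q onset.** First sample, walking back from the steepest point of the
  QRS upstroke, where the band-passed slope falls below 5% of that peak
  slope, capped at 80 ms before R.  Overridable by sidecar fiducials.
- **Windows.** `round(0.512·fs)` samples per beat; 512 samples cannot be
  exactly centred, so the convention is 256 samples before the R sample and
  256 at-and-after (half-open).  Beats within 256 ms of a record edge are
  dropped and logged.
- **Template acceptance.** Median (not mean) template across beats, robust
  to ectopic outliers.  Acceptance uses the *maximum* normalized
  cross-correlation over lags within ±50 ms — the max-lag reading of the
  75% criterion, chosen because it subsumes the subsequent jitter
  correction — and jitter correction shifts the accepted beat by the best
  integer lag (no sub-sample interpolation).  Normalized correlation makes
  acceptance scale-invariant.
- **RMS gate.** Per-beat RMS of the ≥40 Hz residual in the 20 ms pre-Q
  segment, measured on lead II (the detection lead): the modulus of a
  3-vector of independent per-lead noises carries only ~2/3 of the
  per-lead RMS, so a modulus-side measurement would under-read a
  lead-level 20 μV criterion.  The *record* is excluded when the median
  per-beat RMS exceeds the limit; per-beat values are kept for diagnostics.

## Trajectories and statistics

Quantifiers (not PDFs) are averaged per window — 30 s during occlusion,
15 s during recovery, 30 s for the control record — matching the averaging
of the reference protocol; pooling PDFs per window before quantifying is
available as a config alternative (`pooled_pdf_windows`) for sensitivity
analysis, off by default.  Windows tile each phase from its start; a
trailing partial window is kept only when the phase covers at least half of
it.  Empty windows stay empty (NaN), never interpolated.  `δH`/`δC` use the
first and last non-empty windows of a phase.

The control JSD series is split into as many equal-duration sections as the
patient has occlusion windows (4 min of occlusion at 30 s windows → 8
sections), and each occlusion window is compared with its matched control
section across patients: D'Agostino–Pearson normality screening on both
samples, then an unpaired two-tailed Student's t-test if both pass at
`α = 0.05`, otherwise a two-sided Mann–Whitney U test.  Samples below the
minimum size of the normality test (n = 8) go to the non-parametric branch.
Unpaired tests are the default (group sizes can differ after QC); no
multiple-testing correction is applied, matching the per-section reporting
convention, with Benjamini–Hochberg available behind a config flag.
Recovery windows default to 15 s for both trajectories and any
recovery-side sectioning.

## k-noise landmarks

`f^(−k)` noises are synthesized spectrally: a complex Gaussian spectrum
shaped by `f^(−k/2)` with the DC bin zeroed, inverse-transformed and
standardized.  This gives exact spectral control (the tests verify log–log
periodogram slopes of `−k ± 0.1` at `n = 2^16`).  Landmarks are the mean
`(H, C)` over seeded realizations, computed by default with the analysis
embedding `D = 4`, `τ = 2` so that they live in the same plane as the ECG
trajectories; entropy decreases strictly in `k` over `[0, 3]`, and white
noise sits at the `(1, 0)` corner.

## Synthetic cohort generator

The generator emulates the *study design*, not ischaemia physiology: its
beat is a sum of Gaussian-shaped P/QRS/T components of a 3-D cardiac
dipole, mapped to the 8 standard leads through the pseudoinverse of the
Kors matrix (so the analysis-side transform recovers the dipole exactly),
with additive baseline wander (0.25 Hz), mains interference (60 Hz) and
broadband noise per lead.  Defaults follow the reference protocol: 24
patients (9 LAD-like / 15 RCA-like), 1 kHz sampling, a 300 s control
record, occlusion duration drawn around 4 min 6 s ± 90 s and recovery
around 3.7 min, heart rate 70 bpm with 2% RR jitter, 7 μV broadband noise
(safely under the 20 μV gate).

The two occlusion profiles are *qualitative* caricatures calibrated once
(the tuned values live in `data/default_config.yaml`, not in code):

- **LAD-like:** the ST-T dome amplitude ramps from its resting value to a
  large single dome, merging the beat into an action-potential-like
  waveform — within-beat structure becomes more deterministic, so entropy
  falls and complexity rises along the occlusion;
- **RCA-like:** after a quiescent first 40% of the occlusion, the T wave
  flattens, beat-to-beat ST variability grows, and the broadband noise
  ramps up (still under the RMS gate) — the modulus becomes
  noise-dominated, so entropy rises and complexity falls;
- **recovery (both):** morphology returns to control while broadband noise
  ramps up moderately, emulating the increasingly stochastic reperfusion
  signal — entropy rises and complexity falls in both groups.

What passing tests show: the full pipeline recovers the *directional*
`δH`/`δC` signatures (LAD occlusion ↓H ↑C; RCA occlusion ↑H ↓C; recovery
↑H ↓C for both), keeps control beats in a narrow `H×C` box, recalls ≥95%
of ground-truth R waves at default SNR, and excludes noise-injected
records.  What they do not show: agreement of absolute `H`, `C`, `δ`
magnitudes with clinical recordings — the generator's control region and
effect sizes are properties of its calibration, not of real ischaemic ECG.
Analysing real recordings requires the CSV + sidecar ingest path.

## Numerical and reproducibility choices

- Degenerate inputs: constant beats symbolize as fully "ascending" under
  the tie rule (H = 0); zero-signal records return an empty detection with
  a warning rather than crashing; empty windows and missing references
  propagate NaN, never fabricated values.
- All randomness flows from a single seed through `numpy` `SeedSequence`
  spawning (one child stream per patient, shared child streams across `k`
  values for landmark comparability).  Identical inputs and seed give
  byte-identical CSV outputs, which the tests assert.
- The run-configuration hash covers every analysis parameter and is
  written into each report manifest; it changes iff a parameter changes.
- Problem sizes in the test suite are chosen desk-scale: landmark
  calibration at `n = 2^16` with 10–20 seeds, envelope validation with
  10,000 random distributions, and one full 24-patient synthetic run at
  the default durations; all other tests use minutes-long records or
  shorter.

## Known limitations

- The built-in R detector is an energy detector; it is validated against
  the generator's ground truth, not against clinical delineation
  benchmarks.  For real data, supply fiducials via the sidecar.
- WFDB-format ingest is not included; records are consumed via the plain
  CSV dialect described in `ecghc.io`.
- The statistics module implements the per-section testing convention of
  the reference protocol; it does not model within-patient correlation
  across sections.
- Only two qualitative morphology profiles are generated; pathology beyond
  the LAD-like/RCA-like caricatures (ectopy, conduction block, atrial
  fibrillation) is out of scope.
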