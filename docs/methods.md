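# Methods

This note documents the models, numerical choices, and known limitations of
the package. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Stimulus synthesis

### Oval cutout

All four stimulus classes share one soft cutout: a binary ellipse blurred
with a Gaussian (`blur_sigma`, default `size/20` pixels), used as an alpha
map. Composites are `alpha * content + (1 - alpha) * background`, where the
background is the source face image (uniform gray for synthetic faces).

### Blanks

The blank's fill color is the **alpha²-weighted** mean RGB of the face's
oval region, not the plain alpha-weighted mean. Because the fill is blended
through the same alpha map, this is the unique constant for which the
*composite* blank has exactly the face's alpha-weighted oval mean color —
the matched-mean invariant of a stimulus quadruple. For a uniform face both
definitions coincide.

### Block masks

The oval's bounding box is tiled with `block_px` × `block_px` squares
(default 10 px), anchored at the box's top-left corner. Complete blocks are
permuted uniformly at random; partial edge blocks stay in place, which
avoids tearing the blurred rim. The permuted image is then re-cut with the
same alpha map, so only blocks fully inside the oval survive verbatim.

### Spectrum-matched scrambles

The control requirement is that the scramble's Fourier **amplitude**
spectrum, computed on the alpha-windowed oval region (per RGB channel, over
the oval bounding box), match the face's, while the **phase** content is
randomized. Writing the windowed spectrum as `M + D` — `M` the deterministic
window-times-mean-color term, `D` the content deviation — the target
amplitude is `A = |M + D|` per bin, and the construction is closed-form per
frequency bin:

* where the deviation dominates (`|D| ≥ |M|`), any total phase is
  attainable: draw θ uniformly and set `X = −M + A·e^{iθ}` (exact
  amplitude, fully random phase);
* where the window term dominates (`|M| > |D|`), the amplitude constraint
  admits exactly two solutions — the face's own deviation or its mirror
  about the window phase — and the mirror sign is drawn at random. This is
  a genuine information-theoretic limit: the low-frequency structure shared
  with the window cannot be randomized without breaking the spectrum match.

The spatial image is recovered by adding the deviation field to the mean
color, clipping to [0, 255], and refining with a few alternating-projection
sweeps (impose `A` in frequency; clip, restore mean color, re-composite in
space) until the relative L2 amplitude distance of the rounded 8-bit
composite is ≤ `spectral_tolerance` (default 1 %). A final DC shift makes
the composite's oval mean color match the face's exactly up to rounding.
Convergence on 256 × 256 images typically takes < 15 sweeps (< 0.3 s);
non-convergence within `n_iterations` returns the best iterate flagged
`converged=False` with its achieved distance.

Conjugate symmetry of all random fields is guaranteed by deriving phases
and signs from the FFT of real white noise; self-conjugate bins (DC,
Nyquist) keep the face's real-valued coefficients, which in particular
preserves the mean color.

### Procedural faces

`synth_face` replaces photographic face databases: a skin-tone head
ellipse, two darker eye disks, a mouth bar, and multi-scale Gaussian
shading. The shading amplitudes deliberately put most deviation energy at
mid/fine spatial scales (σ = 2 and 0.8 px), as in photographs; this is what
lets the scramble decorrelate from the face (see above — only
window-dominated low-frequency bins are forced to copy face structure).
Deterministic per seed.

## Trial design

3 stimulus types × 80 exemplars × 2 ISIs × 2 repetitions = 960 trials.
Orders are drawn by rejection sampling: reshuffle until no condition cell
(stimulus type × ISI) repeats more than `max_run = 3` times consecutively
(acceptance probability ≈ e^(−960/6³) ≈ 1 %, so a valid order appears
within a few hundred attempts; the limit is 10 000). Four independent
versions are generated and assigned to participants cyclically. No
constraints are placed on exemplar spacing or repetition distance.

## Synthetic behavior (PAS)

Equal-variance SDT on one latent visibility axis: trial strength
~ Normal(μ(stimulus, ISI), 1); the PAS rating is 1 + the number of the
participant's ordered criteria c₁ < c₂ < c₃ below the sample.

Defaults (latent SD units): μ(face, 0) = 0.45, μ(scramble, 0) = 0.30,
μ(blank, 0) = 0, μ(face, 200) = 4.7, μ(scramble, 200) = 2.1,
μ(blank, 200) = 2.0; criteria mean (1.40, 2.85, 3.60), between-participant
criterion shift SD 0.35, per-criterion jitter SD 0.08, face/scramble
sensitivity offset SD 0.45. These were chosen once so that the
dichotomized group measures reproduce the paradigm's signature: a small
positive d′ with a strongly conservative criterion under immediate masking
(yes = anything beyond the mask), high d′ with a slightly liberal criterion
at ISI 200 (yes = face features), and enough labelable trials per awareness
cell. At-scale simulation places group d′(ISI 0) near 0.45 and c(ISI 200)
slightly negative, matching the direction and order of magnitude of the
published group statistics.

d′ is computed with faces as signal and blanks as noise (160 trials each at
full scale, matching the 0.5/160 rate correction); scramble-vs-blank d′ is
available by argument. The published analysis does not state the signal
class; faces are the natural reading.

Extreme-bias participants for exclusion tests are injected by shifting all
three criteria by ±4.0. Note a structural cap: z-standardization with the
sample SD bounds any single outlier at |z| ≤ (n−1)/√n, and the 0.5/n rate
correction bounds the attainable criterion itself, so reliable flagging
needs n ≥ ~12 participants and the full 160-trials-per-cell design.

## Synthetic EEG

Epochs span −200 to +800 ms at 512 Hz, 16 channels (the six analysis
channels P9/P7/PO7/P10/P8/PO8, eight additional scalp sites, HEOG/VEOG).

Signal model per trial: `a_P1·T_P1 + a_N170·T_N170 + mask response + noise`.
Templates are temporal Gaussians (P1: 90 ± 10 ms; N170: 150 ± 15 ms) times
a spatial pattern that is +1 on the analysis channels and balances to zero
mean across scalp channels — so average-referencing leaves planted
amplitudes untouched — normalized so unit amplitude produces a windowed
mean of exactly 1 µV in the component's own window. The mask-evoked
response (its own P1/N1 pair) onsets at 17 ms + ISI; its analytically
computed contribution to each analysis window is subtracted from the target
amplitudes, so the per-condition calibration table *is* the
pipeline-recovered windowed mean in the noiseless limit (verified to
< 0.01 µV in tests).

Amplitude calibration (µV, windowed means) follows the published group
condition means: P1 marginals near 2.4/2.35/1.8 for faces/scrambles/blanks
with the blank deficit concentrated in the conscious condition, N170
marginals near −2.6/−0.26/−0.25 with a large conscious face effect (−4.5 vs
−1.0) and an attenuated nonconscious one (−0.65 vs +0.5). Between-
participant structure: a shared multiplicative gain (SD 0.25) on condition
effects plus additive per-component offsets (SD 2.0) that cancel in
within-participant contrasts; single-trial amplitude jitter SD 1 µV.

Noise is 1/f-shaped Gaussian noise (exponent 1, 6 µV RMS) plus white noise
(3 µV RMS), independent across channels. Artifacts are injected per trial:
blinks (5 %; 150–350 µV Gaussian bump on VEOG with frontal propagation
0.3/0.15/0.07), gross amplitude excursions (2 %; 200–400 µV burst on one
scalp channel), and flat trials (0.5 %; all channels zeroed, caught by the
low-signal criterion). Ground truth (planted amplitudes, artifact labels,
participant parameters) is returned beside every dataset.

**Reduced scale.** The default cohort runs the full 80-exemplar design at
one repetition (480 trials/participant, 80 per condition cell) with 16
channels; `scale="full"` gives the complete 960-trial design. The
participant-exclusion threshold scales accordingly: the pipeline default is
40 surviving trials per awareness × stimulus cell (matching 160 recorded
trials per cell), and the reduced-scale configuration uses 20 (matching
80). What the generator does *not* emulate: spatially correlated noise,
volume-conducted component topographies, latency jitter across trials and
participants, and any dependence of single-trial EEG amplitude on the PAS
rating within a condition. Passing recovery tests therefore validate the
analysis code, not claims about real EEG.

## Preprocessing choices

* Stage order: average reference → band-pass → EOG regression → artifact
  rejection → bad-channel interpolation → baseline → labeling → averaging.
* The band-pass is a first-order high-pass at 0.01 Hz cascaded with a
  fourth-order low-pass at 40 Hz (6 and 24 dB/octave), applied zero-phase
  (forward–backward), so the effective roll-offs double. Applied per epoch;
  at 0.01 Hz the high-pass is near-identity on 1-s epochs and matters only
  for long continuous recordings.
* Proprietary automatic eye-artifact correction is replaced by multivariate
  least-squares EOG regression on concatenated epochs — reproducible and
  testable by construction.
* "Low signal < 0.01 µV" is operationalized as within-epoch peak-to-peak
  per scalp channel; gradient as the maximum absolute sample-to-sample
  difference; all criteria per channel over the whole epoch, any violation
  rejecting the trial.
* Bad channels are a configuration input (the reference analysis used
  visual inspection); interpolation is spherical-spline (Perrin, order
  m = 4) via mne on the standard 10-05 montage.
* Window boundaries are inclusive on the sample grid (t_k = −200 + k/0.512
  ms); fixed thresholds replace per-participant semi-automatic adjustment,
  for reproducibility.

## Statistics

* The 3 × 2 within-subject ANOVA is computed by pingouin with uncorrected
  degrees of freedom — (2, 2(n−1)), (1, n−1), (2, 2(n−1)) — as is
  conventional for this design; a brute-force sums-of-squares oracle in the
  tests guards the decomposition. Degenerate 0/0 tables (no effect and no
  error variance) report F = 0, p = 1. η²ₚ = F·df₁/(F·df₁+df₂).
* JZS Bayes factors integrate the noncentral-t likelihood over a
  Cauchy(0, √2/2) effect-size prior (the common analysis-software default),
  adaptively after the substitution δ = r·tan(φ) that maps the real line to
  a finite interval, with the integrand peak passed as a quadrature
  breakpoint; relative tolerance 1e−10, quadrature error reported in
  percent of the BF. One-sided tests truncate (and renormalize) the prior
  to the hypothesized half-line. An independent 200 001-point Simpson
  oracle and pingouin's two-sided implementation cross-check it in tests to
  3 significant figures.
* FDR is Benjamini–Hochberg at q = 0.05, applied over the six F-tests (two
  components × three effects) and, in the behavioral stage, over the four
  one-sample tests (d′ and c at each ISI).
* The sequential rule stops at n ≥ 40 with BF₁₀ > 3 or < 1/3 on the
  monitored contrast (nonconscious N170, face vs scramble); bounds are
  strict inequalities.

## Known limitations

* The scramble construction matches amplitude per FFT bin of the windowed
  region; algorithms that match, e.g., rotationally averaged power spectra
  would admit more phase freedom. At window-dominated bins residual
  face–scramble correlation is unavoidable (measured mean |r| ≈ 0.06 per
  channel on the synthetic faces' oval content).
* EOG regression removes brain activity correlated with the EOG channels;
  bias is negligible here because simulated blink propagation is linear,
  but real data would motivate ICA or dedicated correction.
* No sphericity correction is applied by default (uncorrected dfs are
  reported); Greenhouse–Geisser values are available from pingouin's table
  if needed.
* EDF/BDF reading for real recordings goes through mne; EDF export of
  synthetic epochs is not provided (the internal npy + JSON container is
  the interchange format).
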