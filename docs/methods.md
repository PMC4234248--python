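# Methods

This note documents the models and procedures implemented in `fcqual`, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Problem setting

Nonlinear frequency compression (NFC) in hearing aids moves high-frequency
speech cues (frication, high formants) into the residual audible range of a
listener with high-frequency hearing loss. The processing trades audibility
against sound quality, so fitting decisions benefit from an *objective*
quality predictor: a model that scores a processed signal against its
unprocessed reference and correlates with subjective MUSHRA ratings.
`fcqual` implements such predictors — the internal-representation measures
PSM and qc with a hearing-impairment extension, plus four classical
LPC-domain distances — together with the NFC processor, the MUSHRA anchor
degradations, a synthetic study generator, and the correlation harness that
evaluates predictors against rating tables.

## Signal conventions

* Working rate: **32 kHz**. The wideband peripheral filterbank extends to
  15.3 kHz, so the working Nyquist must exceed that; 32 kHz gives headroom
  while keeping the filterbank and short-time processing cheap. All inputs
  are resampled on load (polyphase, long Kaiser-windowed FIR; round-trip
  out-of-band leakage below −40 dB).
* Calibration: full-scale RMS ≡ **100 dB SPL** (configurable). Stimuli are
  presented to the models at **65 dB SPL**, a typical conversational
  playback level; pinning the reference level makes all scores invariant to
  a common rescaling of both inputs.
* Alignment: the test signal is shifted by the cross-correlation-maximizing
  lag (search bounded to ±0.5 s, ties toward smaller |lag|), RMS-matched to
  the reference, and both are truncated to the common length.

## NFC processor and anchors

The frequency map is identity below the cutoff `F_c` and a power law above
it:

    F_out = F_c^(1−p) · F_in^p,   p = 1/CR,

i.e. linear compression by CR on a log-frequency axis. An alternative
piecewise-linear map is available behind a flag for sensitivity checks. The
signal-domain processor remaps STFT bins (frame 1024, hop 256, Hann):
each bin's complex value is relocated to the mapped frequency and split
linearly between the two nearest target bins, with a phase-vocoder rotation
so relocated components advance at the target frequency across frames.
A zero-delay linear-phase lowpass at `map(F_nyquist)` removes residual
overlap-add splatter, honoring the contract that nothing lies above the
mapped Nyquist (every third-octave band above it sits > 40 dB below the
total energy). The five standard study settings are
cr2-fc4k, cr2-fc3k, cr6-fc3k, cr10-fc3k and cr2-fc2k.

Anchors: a 10th-order Butterworth lowpass at 2 kHz (−3 dB at cutoff), and
hard clipping at 25 % of the *observed* stimulus peak (not nominal full
scale), so the output peak equals exactly 0.25 × input peak.

## Auditory model (PEMO front-end)

Per channel of a 4th-order gammatone filterbank (1 filter/ERB; wideband
bank 235 Hz–15.3 kHz for PSM, telephone-band 235 Hz–4 kHz for qc):

1. half-wave rectification + first-order 1 kHz lowpass (envelope);
2. optional hearing-impairment stage (below);
3. five cascaded adaptation loops (time constants 5/50/129/253/500 ms)
   with a soft overshoot limit of 10 — stationary inputs are compressed
   approximately logarithmically, onsets overshoot; output scaled to model
   units (0 at the absolute-threshold floor, 100 for a stationary
   full-scale input). The divisive floor is 1e−5 of full scale (0 dB SPL
   under the calibration convention);
4. modulation analysis: first-order 8 Hz lowpass (`lp`, 2-D output) or a
   modulation filterbank (`fb`, 3-D output: 2.5 Hz lowpass + constant-Q
   (Q = 2) bands at 5, 10, 16.7, 27.8, 46.3, 77.2 and 128.6 Hz).

Envelopes are decimated 8× (to 4 kHz) after the instantaneous HI stage and
before adaptation; this resolves the 5 ms shortest loop time constant and
the 129 Hz top modulation band while keeping desk-scale benchmarks fast.

### Hearing-impairment stage

The audiogram is interpolated to channel center frequencies (linear in
log-frequency vs. dB HL, flat extrapolation). The total loss per channel is
split as

    OHCL = min(ohc_fraction · HL, ohcl_cap),  IHCL = HL − OHCL,

with defaults `ohc_fraction = 0.8`, `ohcl_cap = 55 dB` (the conventional
attribution of the larger share of a sensorineural loss to outer hair
cells, capped at the level beyond which losses must be inner-hair-cell
driven). Per sample, the envelope is attenuated by IHCL and then expanded.
The expansion is defined in the dB domain:

    L_out = L − OHCL · ((L_conv − L)/L_conv)²  for L < L_conv = 100 dB,

identity at and above `L_conv`. This curve is the inverse of a compressive
healthy-cochlea input/output function: slope 1 + 2·OHCL·(L_conv−L)/L_conv²
≥ 1, decreasing toward 1 with level, output reduced by exactly OHCL at
L = 0 dB (threshold shift), and identity when OHCL = 0. The exact
parameterization of the original expansion stage is unpublished; this form
satisfies every documented property of it and is fully configurable.
Channels with zero loss pass through bit-for-bit, so a zero audiogram
reproduces the normal-hearing model exactly, and in the HI variants the same
audiogram-configured model processes both test and reference.

## Quality measures

**PSM** is the Pearson correlation of the two internal representations over
all cells jointly (time × channel × modulation band flattened). A global
correlation (rather than per-channel averaging) is used, consistent with
the contrast between the overall measure and its frame-wise sibling.
**qc** is the same computation on the telephone-band model, with two
options applied first:

* **+W** band-importance weighting: each channel is multiplied by a
  monotone ramp over ERB-rate (0.5 → 1.5) emphasizing higher telephone-band
  channels. The originally published weighting table is not reproduced
  here; the ramp is a synthetic stand-in with the documented emphasis
  direction.
* **+B** asymmetric assimilation: wherever the test representation falls
  below the reference, the difference is halved; positive deviations are
  kept. "Missing" signal components are perceptually less disturbing than
  "added" ones.

Degenerate rule: two constant-and-equal representations score 1; constant
but unequal is an error, not NaN. Scores are clipped to [−1, 1] against
floating-point drift.

## LPC distances

Narrowband analysis: both signals resampled to 8 kHz (analysis band
0–4 kHz; an 8 kHz-bandwidth mode is available behind a flag), 32 ms Hamming
frames, 16 ms hop, order 10, autocorrelation method (Levinson–Durbin).
Frames below −60 dBFS in either signal are excluded jointly; frame
distances are aggregated by the mean over the lowest 95 % of frames
(trimmed, configurable) to bound outlier frames.

* **ISD**: mean over the (whole-circle) frequency grid of
  `P_r/P_t − log(P_r/P_t) − 1` between the all-pole spectra; asymmetric.
* **LLR**: `log[(a_t R_r a_tᵀ)/(a_r R_r a_rᵀ)]` with the reference
  autocorrelation matrix; asymmetric.
* **LAR**: RMS difference of log-area ratios from the reflection
  coefficients; symmetric.
* **WSSD**: critical-band (Bark) log-magnitude spectra; adjacent-band slope
  differences weighted by Klatt peak-proximity weights (global-peak and
  local-peak proximity, K = 20 / K_loc = 1, local peak found by walking up
  the flank the band sits on); weighted mean over bands, mean over frames;
  symmetric and invariant to a common gain.

## Evaluation harness

Ratings tables hold per-subject 0–100 MUSHRA scores keyed by (subject,
group, condition, talker); duplicates and out-of-range values are rejected
at load. Aggregation averages over subjects per (condition, talker) and
optionally over talkers per condition. Agreement between predictions and
mean ratings is quantified by Pearson's r on raw values and Spearman's rs
(average ranks on ties), with no regression mapping of predictions. The
hidden reference and both anchors are included by default
(`exclude_anchors` reproduces sensitivity analyses). "Per-talker"
correlations pool all (condition, talker) points into one correlation —
consistent with scatter-plot point counts — rather than averaging
per-talker coefficients; missing cells are dropped pairwise and logged,
never imputed.

## Synthetic study generator

The generator emulates the study design, not natural speech: two male-like
(f0 115/125 Hz) and two female-like (f0 195/215 Hz) talker presets produce
source-filter vowels (impulse train through formant resonators, formants
spanning ~600–3900 Hz across presets) interleaved with 3.5–9 kHz frication
bursts under a 4 Hz raised-cosine syllable envelope, at 1 s duration for
benchmarks. Each reference is processed into the 8-condition MUSHRA set.
Simulated ratings map true quality scores affinely onto [5, 95] and add
i.i.d. Gaussian subject noise (sd 5 on the 0–100 scale, 12 subjects by
default), clipped to [0, 100]; all randomness flows from one seed.

What this does *not* capture: natural prosody and coarticulation, talker
idiosyncrasy, hearing-aid amplification chains, room acoustics, and real
subjects' criterion shifts. Passing tests therefore demonstrate internal
consistency, correct contracts, and the documented qualitative orderings
(quality falls with compressor strength; the telephone-band measure is less
sensitive to missing energy above 4 kHz) — not field validity on recorded
hearing-aid speech.

## Numerical choices and degenerate inputs

* Gammatone filters: `scipy.signal.gammatone` 4th-order IIR; stable across
  235 Hz–15.3 kHz at 32 kHz.
* Resampling: polyphase with a 60·max(up,down)+1-tap Kaiser (β = 9) FIR.
* Adaptation loops: states initialized and floored at the steady state for
  threshold input, so silence maps to 0 without transients.
* Identity scoring: Pearson of a representation with itself is 1 to within
  ~1e−15; tests assert 1.0 at 1e−9.
* Silent signals are rejected (`DegenerateInputError`) wherever a level,
  peak, or correlation is required.

## Problem sizes

Desk-scale defaults: 1 s stimuli, 4 talkers × 8 conditions, 33-channel
wideband / 21-channel telephone-band filterbanks, 4 kHz envelope rate. The
full benchmark (16 PEMO-variant measures + 4 LPC distances, 32 stimulus
pairs) completes in roughly one to two minutes on one CPU; these sizes are
the package's chosen defaults for its bundled synthetic study.

## Known limitations

* The band-importance table and the expansion-stage parameters of the
  original models are unpublished; both are replaced by documented,
  configurable stand-ins (see above).
* The NFC processor is a magnitude-remapping STFT realization of the
  frequency map, not a reimplementation of any commercial hearing-aid
  signal path (which typically includes amplification, compression and
  output limiting; all out of scope here, processing is unity-gain).
* No middle-ear transfer function beyond the band limits, no binaural
  processing, no loudness model.
* The temporal quality variant (frame-wise correlation with nonlinear
  mapping) is deliberately not implemented; only the overall measures are.
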