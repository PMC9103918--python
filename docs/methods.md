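# Methods

This note documents the signal model, the numerical choices and the known
limitations of the package, in the spirit of a model-documentation page.

## Signal path

Mono audio at 48 kHz is peak-normalized to 0.95 so results do not depend on
the capture device's absolute recording level; the normalization gain is
folded back into the SPL calibration offset so level readings still refer
to the original input (plus the user's calibration constant). Analysis runs
on 256-sample frames advanced by 128 samples, windowed by a square-root
periodic Hann. The same window is applied at synthesis, which makes the
overlap-add an exact identity (Hann at 50% overlap sums to one), verified
to below 1e−6 RMS.

Per frame the chain computes an SPL reading and a speech-presence
probability, updates the {WDRC, NR} flag pair, and buffers the implied
filter index. Every `decision_rate_frames` (default 200, ≈ 0.53 s) a
majority vote over the buffer — ties broken toward the lowest index, i.e.
the least aggressive processing — fixes the active filter for the next
window. Until the first vote the neutral Filter 3 (moderate, NR off) is
active. Filter switches are bridged by a 10 ms linear crossfade computed
from a shared FIR input history, so switching introduces no state
transient and no extra delay.

Noise reduction runs in the STFT domain on the analysis frames; the WDRC
FIR runs on the reconstructed stream with its group delay (order/2 = 64
samples) compensated at the output. Algorithmic latency is therefore
2·frame/fs + (order/2)/fs = 10.67 + 1.33 = 12.0 ms. A hard limiter clamps
the output to ±1 (the soft-speech prescription applies up to 25 dB of gain
to an already peak-normalized signal, so clipping is expected and counted,
not silently ignored).

## SPL meter

Exponential time weighting of the squared signal with the conventional
"fast" time constant τ = 125 ms; the frame reading is 10·log10 of the
frame-averaged weighted mean square, clamped at a −120 dB floor, plus the
calibration offset. Weighting is flat (Z); this keeps the relation between
digital level and reading analytic (a full-scale sine settles at −3.01 dB)
and mirrors the calibrate-against-a-physical-meter workflow: absolute
accuracy lives entirely in the user's calibration constant.

## VAD

A Gaussian statistical likelihood-ratio detector over the 512-point
zero-padded spectrum: per bin, a-posteriori SNR γ = |X|²/N and
decision-directed a-priori SNR ξ (smoothing α = 0.98) give
log L = γξ/(1+ξ) − log(1+ξ), averaged over bins. The decision-directed
estimator is biased slightly positive under noise-only input
(E[log L] ≈ (1−α)·E[(γ−1)²·1{γ>1}] ≈ +0.015 nats), so mapping the raw
statistic through L/(1+L) would sit marginally above 0.5 for pure noise.
The probability is therefore a logistic map of the averaged log-likelihood
with midpoint 0.25 nats and scale 0.15 nats: noise-only frames score ≈
0.17 (measured false-positive rate at the 0.5 threshold: 0/1000 matched
noise frames), while speech frames at +20 dB SNR score ≈ 1.0. The
decision-directed memory also acts as an implicit hangover: ξ decays over
tens of frames after speech stops, which keeps short inter-syllable gaps
classified as speech — desirable, because the NR flag should respond to
genuine noise-only stretches, not to 75 ms pauses.

The noise PSD initializes as the average periodogram of the first
`noise_init_frames` (default 75 frames ≈ 0.2 s — the capture protocol this
package emulates always starts with a noise-only lead-in) and then adapts
by exponential smoothing (rate 0.95) only on frames scored below the VAD
threshold, freezing during speech to avoid leaking speech into the model.
At very low SNR (≈ 5 dB) modulation minima can still dip under the
threshold and slowly drag the noise model upward; at the ≥ 10 dB SNRs the
synthetic suite uses, frame-level VAD accuracy against ground-truth labels
is 100%.

## WDRC

The static curve is the standard feed-forward soft-knee law (quadratic
interpolation over the knee). Level dynamics are a one-pole smoother whose
coefficient is exp(−hop/attack) when the detected level rises and
exp(−hop/release) when it falls; simulating the recursion and
interpolating the 63% crossing recovers the nominal constants (0.0101 s /
1.000 s at the 2.67 ms hop).

The three compressor responses are frozen into filters at one
representative input level per category: −50 (soft), −35 (moderate), −20
(loud) dBFS — the centers of the three SPL categories after a nominal
calibration that places conversational speech around −35 dBFS. These are
configurable; the static gains at those operating points are what the FIRs
realize.

## Filter design

Each filter is a type-I (even order 128, symmetric, constant group delay)
FIR fitted by weighted least squares to a smooth target: the five band
gains anchored at the geometric band centers, interpolated by a monotone
piecewise-cubic (PCHIP) in log-frequency and held constant outside the
outermost centers. Frequency sampling against a piecewise-constant target
was rejected: with only 129 taps the corner discontinuities at band edges
ripple by more than the 0.5 dB band-center tolerance, while the smooth
least-squares fit lands within 0.3 dB at every center for all six
prescriptions. The fit grid is log-spaced so low bands carry weight
commensurate with their octave width. Requests above 60 dB band gain are
rejected as unrealizable.

## Noise reduction

Per-bin Wiener gains g = ξ/(1+ξ) with the same decision-directed ξ
(α = 0.98) and a gain floor of 0.1 (−20 dB) against musical noise. The
noise PSD object is shared with the VAD so detector and suppressor agree
on the noise model; the engine updates it once per frame (via the VAD
rule). On matched stationary noise the suppressor removes ≈ 20 dB; on
scenes it lowers the noise-segment level by well over the 3 dB margin
while moving the speech-segment level by < 1 dB at SNR 15.

## Synthetic scenes

`gen_scene` reproduces the field-capture protocol: noise alone for a few
seconds (so the noise model can initialize), then a talker over the
continuing noise. Noise kinds: white, pink (−3 dB/octave), fan-like
(low-passed rumble + 120/240 Hz hum), and babble-like (eight summed
surrogates). The speech surrogate is a harmonic complex (f0 = 120 Hz
drifting ±10%, partials to 4 kHz with 1/k roll-off and three formant
boosts at 500/1500/2500 Hz) gated at 4 Hz with duty cycle 0.7. The gating
floor is −8 dB (modulation depth 0.6) rather than silence: natural
inter-syllable gaps carry residual energy, and hard-zero 75 ms gaps —
shorter than the meter's 125 ms time constant — would make the NR flag
latch onto decayed speech readings in a way real recordings do not
exhibit. Scene SPL targets are defined against the package's own meter
(flat weighting, fast), making `set_spl` self-consistent rather than
physically absolute; the default scene calibration (100 dB) puts a
full-scale sine at ≈ 97 dB.

What the surrogate does *not* model: phonetic content, room reverberation,
nonstationary noise onsets, Lombard effects. Passing the synthetic suite
therefore demonstrates that the selection logic, metering and suppression
behave per the design rules — not speech intelligibility outcomes.

One structural consequence of the selection rules worth noting: Filter 2
(soft speech with NR on) is unreachable on any scene where the noise alone
reaches the 55 dB NR threshold, because speech frames then read the
speech+noise mix, which is necessarily ≥ 55 dB (moderate). The behavioral
suite covers the five reachable filters.

## Numerical conventions and degenerate inputs

- Boundary SPLs of exactly 55 / 75 dB classify as moderate (closed
  interval, deterministic).
- A VAD probability exactly at threshold counts as speech (conservative
  for intelligibility).
- All-zero frames: the meter reads its −120 dB floor; the VAD returns
  p = 0 without touching the noise model.
- Knee width 0 is the hard-knee limit of the static curve.
- Silent input to `normalize` passes through with factor 1 and a warning.
- Inputs shorter than two frames, or at the wrong sample rate, are
  rejected with instructive errors (the CLI offers `--resample`).

## Problem sizes

The test suite runs everything at desk scale: scenes of 5–8 s (≈ 1900–3000
frames), 20 scenes in the behavioral suite, 10,000 random buffers for the
majority-vote oracle, 1000 frames for the VAD false-positive rate. These
sizes were chosen to give stable statistics for the asserted margins.
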