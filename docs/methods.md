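# Methods

This note documents the models, conventions and numerical choices behind
`eggdenoise`, in the order the pipeline runs.

## Level conventions

All samples are dimensionless ratios of digital full scale (±1.0); levels
are dBFS.  Deterministic tones are specified and measured by **peak**
amplitude (a sine with peak 10^(L/20) is "at L dBFS"); stochastic noise is
specified by its standard deviation (rms).  This makes both analytically
checkable: a sine generated at −33 dBFS has `level_dbfs(x, "peak") = −33`
exactly, and Gaussian noise at −50 dBFS converges to
`level_dbfs(x, "rms") = −50` as duration grows.

## High-pass and low-pass FIR design

The high-pass template is: cutoff 100 Hz, stopband at and below 20 Hz with
≥ 60 dB attenuation, linear phase, ~1024 taps at 44.1 kHz.  An even-length
symmetric FIR (type II) is structurally zero at Nyquist and cannot be a
high-pass, so an even requested length is rounded down to the next odd
count (1023).  The design is equiripple (Parks–McClellan) with the
stopband error weighted ~67× the passband, landing at ≈ 62 dB stopband
attenuation and ≈ ±0.45 dB passband ripple.  The coefficients are exactly
symmetric, so the group delay is (n−1)/2 samples at every frequency;
`apply_fir` removes that delay by default, which is free offline.

The low-pass (default cutoff 10 kHz, stopband from 12 kHz) uses a
Kaiser-windowed design instead: the much wider transition band makes the
Remez exchange numerically fragile at ~1000 taps, while a Kaiser window
meets the 60 dB template with a large margin.  Both designs are verified
against their template on a dense grid at design time and raise a
`FilterDesignError` naming the achieved attenuation if it cannot be met.

Notches are audio peaking-EQ biquads (one second-order section each) with
negative gain, parameterized as (frequency, gain dB, Q).  They are not
linear-phase; the phase ripple is confined to roughly one bandwidth
(f0/Q) around the center frequency, where the EGG carries negligible
energy.

## Spectral gate

Frames of 2048 samples at 50% overlap are windowed with a half-sine
(sin(πn/N)) analysis window, transformed with an rfft, processed, inverse
transformed, windowed again with the half-sine synthesis window and
overlap-added.  The analysis-synthesis window product is a Hann window,
which satisfies constant overlap-add at 50% hop, so the chain is an
identity to float rounding when no gating is applied.  The track is
reflect-padded by one frame at each end so edge frames see signal-level
content; the first/last `n_fft` output samples are still edge-transient,
like the transient of any filter.

Per-bin processing is a static downward expander in the dB domain:
`out = T + 4·(in − T)` for levels below the threshold T, identity above
it, phases untouched.  No attack/release smoothing is applied.

**Calibration.**  Per-bin dBFS is *peak-sine-referenced*: a full-scale
sine centered on a bin reads ≈ 0 dBFS (raw magnitude divided by half the
window sum, ≈ N/π).  The alternative linear `thresh` parameter — the
single-number convention of phase-vocoder compander units — maps through
`20·log10(thresh/N)`, taken as definitional.  The
peak-sine reference was chosen because it reproduces the documented
operating points: a −33 dBFS sine survives a −35 dBFS threshold with
≈ 1.6 dB margin, while power- or N-normalized conventions would place the
same sine ~10 dB below its nominal level and the gate would destroy it.

Note that the "per-bin noise floor sits 10·log10(N) ≈ 33 dB below the
broadband level" arithmetic refers to a rectangular-window FFT normalized
by N (E|X_k|²/N² = σ²/N); that convention is used where that quantity is
computed and is distinct from the gate's windowed calibration.

## Cycle segmentation (stand-in)

Production EGG systems use proprietary phase-tracking segmentation; this
package uses a deterministic stand-in adequate for validation:
autocorrelation f_o track (4096-sample window, hop 1024, normalized
correlation ≥ 0.5 for voicing, parabolic peak refinement clamped to ±1
lag), regions split at > 20% f_o jumps, zero-phase 2nd-order Butterworth
band-pass at 0.6–1.5× the region's median f_o, period boundaries at
linearly interpolated positive-going zero crossings.  The period T is the
non-integer crossing distance; the sample span is the enclosing integer
range; A_pp and δ_max are measured on the original conditioned samples.

Two guards matter in practice: a span yields cycles only if the
band-limited fundamental amplitude exceeds the voicing floor (default
−60 dBFS), which keeps silence and dither from producing cycles; and a
six-period margin at each region boundary is discarded because the
band-pass filter's edge ringing biases the outermost crossing times (the
2nd-order band-pass rings for several cycles even under zero-phase
filtering).  On a 1-second 220 Hz sinusoid this yields ~207 cycles, each
with f_o within 0.5% and Q_Δ within 0.001 of its closed-form value.

On the closed form: a *sampled* sinusoid has Q_Δ = 1/cos(π/T) only at the
worst sampling phase (sample pair straddling the steepest point, peak on a
sample), which is exact when T ≡ 2 (mod 4); elsewhere the sampled value is
lower by O((π/2T)²).  Tests assert exact agreement at T = 50 and
agreement to those analytic bounds at T = 200 and 1000.

## Per-cycle metrics

* `Q_Δ = 2·δ_max/(A_pp·sin(2π/T))` with the interpolated T.  Undefined
  (NaN) for a flat cycle rather than an error, since silence is expected
  input.
* `Q_ci` = mean of (x − x_min)/A_pp over the cycle: the area under the
  amplitude- and time-normalized pulse; 0.5 for a sine.
* `HRF_egg = 20·log10(Σ_{i=2..10} H_i / H_1)` dB, where H_k comes from a
  direct Fourier transform over exactly one period,
  `H_k = (2/T)·|Σ x[n]·e^{−i2πkn/T}|`.  The upper harmonic defaults to 10
  but is configurable, since the original definition of the harmonic
  richness factor is open-ended.
* Contact classification is a strict `>` against Q_Δ = 2 or
  HRF = −10 dB.

Histograms of Q_Δ default to 40 log-spaced bins over [0.5, 20], matching
the usual voice-map color span from 1 (sine) to 20 (very rapid
contacting).  The bimodality rule of thumb — de-noising was effective if
one local mode lies in [0.8, 1.5] and another above 4 — is implemented on
local maxima of the histogram.  Voice maps bin cycles into cells one
semitone wide (relative to a reference f_o, default 110 Hz) and one dB
high, with per-cell running means; SPL calibration is out of scope, so
the level axis uses the acoustic channel when present and EGG rms dBFS
otherwise.

## Synthetic signals

The generator covers the four noise families seen in EGG hardware: white
Gaussian system noise (rms-referenced), mains hum (harmonic stack at
50 Hz by default, switchable to 60 Hz, peak-referenced, optional per-
harmonic rolloff), static side tones (pure tones, peak-referenced) and
near-DC drift (low-passed Gaussian, corner 5 Hz by default).  All draws
flow from a single master seed through `numpy.random.SeedSequence.spawn`,
so identical seeds give bit-identical tracks.

**Contacting-pulse model.**  The contacting EGG waveform is modeled as a
sinusoidal baseline carrying a band-limited contact impulse: equal-
amplitude cosine harmonics 2..K (a Dirichlet-kernel pulse), K = 8 by
default, with `contact_speed` scaling the impulse amplitude
(b = 0.5·(contact_speed − 1); contact_speed = 1 is a pure sine).  Two
considerations drove this choice over, e.g., a raised-cosine contact
bump.  First, real contacting cycles are harmonically rich (HRF_egg up to
≈ +5 dB), which a fast-decaying bump spectrum is not.  Second, the peak
derivative that defines Q_Δ is carried by the harmonics k·H_k; with a
raised-cosine bump those harmonics decay so fast that at the validation
operating point (peak −13 dBFS, threshold −35 dBFS) they straddle the gate
threshold and the gate itself erases the quantity under study.  The
equal-amplitude comb places every contact harmonic ≈ 20 dB below the
waveform peak — comfortably above the thresholds used — so gating leaves
the pulse intact, which is the documented behavior of the method on real
contacting signals.  The defaults give a sampled Q_Δ ≈ 5.80 at
220 Hz / 44.1 kHz.  The generator never assumes this value: it measures
its own waveform's per-period Q_Δ directly from the samples and reports
the median over ~100 sampling phases as ground truth, which is what a
per-cycle analysis of the same waveform estimates.

**Validation experiment.**  Ten seconds alternating 1-s blocks of sine at
−33 dBFS and contacting pulse at −13 dBFS (f_o 220 Hz, five repeats), plus
Gaussian dither at −95 dBFS so logs never see exact zeros.  Optional
white noise is added, the signal is conditioned (high-pass, then the gate
when a threshold is given), segmented, and the per-cycle Q_Δ is
histogrammed.  Mode locations are refined beyond bin resolution as the
median of the values in the modal bin and its neighbors.  One physical
subtlety: at −95 dBFS the dither's sample differentials add ~5% to the
−33 dBFS sine's δ_max, so even the no-noise low mode sits at ≈ 1.05
rather than exactly 1 — an inherent property of the peak-derivative
statistic, and a miniature of the very noise sensitivity the gate exists
to repair.

## Problem sizes and limitations

Validation runs use 1–10 s of 44.1 kHz audio and 2048-point FFTs; every
experiment configuration completes in well under a minute on one core.

What passing these tests does *not* show about real data: the generator's
noise is stationary and the contact pulse is strictly periodic, so the
experiments exercise neither wandering side tones, automatic gain
control, amplitude/f_o jitter, nor hum whose harmonics interleave with
the signal's — the method is documented to handle none of the first three
(a static threshold and static notches assume stationarity).  The
segmentation stand-in is validated on clean synthetic signals; its
robustness on pathological voice is untested.  SPL calibration and any
clinical interpretation are out of scope.
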