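# eggdenoise

Offline de-noising of electroglottographic (EGG) signals and per-cycle
vocal-fold contact metrics.

## The problem

The EGG signal tracks vocal-fold contact area across the larynx.  When the
vocal folds oscillate *without* contacting (soft or breathy phonation), the
EGG is tiny and nearly sinusoidal; the onset of contacting changes the
waveform shape abruptly but is not audible.  A convenient shape-based
detector is the cycle-normalized peak of the EGG derivative,

    Q_Δ = 2·δ_max / (A_pp · sin(2π/T))

where δ_max is the largest sample-to-sample differential in a glottal
cycle, A_pp its peak-to-peak amplitude and T the period in sample
intervals.  A sinusoid gives Q_Δ = 1; contacting drives it up abruptly,
with Q_Δ > 2 a practical contacting criterion.  The derivative, however,
is extremely noise-sensitive: hardware noise makes Q_Δ float above 1 even
when no contact occurs, obscuring the transition.

`eggdenoise` implements the pragmatic remedy chain used in EGG practice:

1. **Steep linear-phase FIR high-pass** (~1024 taps, cutoff 100 Hz,
   ≥ 60 dB down at and below 20 Hz) removing near-DC drift;
2. **Parametric notch filters** (peaking-EQ biquads with negative gain)
   against static high-frequency side tones;
3. **Spectral threshold-and-expand gating**: 2048-point half-sine-windowed
   STFT; bins whose level falls below a threshold are expanded downwards
   at 4:1 in dB, phases untouched, harmonics above threshold unchanged;
4. an optional **steep FIR low-pass** at 10 kHz.

On the conditioned signal it segments glottal cycles, computes per-cycle
Q_Δ, the contact quotient Q_ci (area under the amplitude/time-normalized
cycle; 0.5 for a sine), and the harmonic richness factor
HRF_egg = 20·log10(Σ_{i=2..10} H_i / H_1) dB from a direct Fourier
transform over exactly one period, and aggregates cycles into Q_Δ
histograms and semitone × dB voice maps.  A synthetic generator produces
EGG waveforms (sine and contacting pulse with a known, self-measured Q_Δ)
and the four standard noise families (drift, white noise, mains hum,
side tones), so the whole chain is validated without any recordings.

## Worked example

The built-in validation experiment alternates 1-second blocks of a
sinusoidal EGG at −33 dBFS (no contact, Q_Δ = 1) and a contacting pulse at
−13 dBFS (Q_Δ ≈ 5.8), five times, at f_o = 220 Hz.  With white noise added
at −60 dBFS and the spectral gate at −45 dBFS:

```sh
$ eggdenoise experiment --noise -60 --gate -45 --seed 1
{
  "version": "0.1.0",
  "seed": 1,
  "noise_level_dbfs": -60.0,
  "gate_threshold_dbfs": -45.0,
  "n_cycles": 2177,
  "bimodal": true,
  "low_mode": 1.0095371510864504,
  "high_mode": 5.702527025627088,
  "qdelta_true": 5.795603160486658
}
```

The per-cycle Q_Δ histogram is bimodal: the low mode sits at ≈ 1.01
(non-contacting cycles recovered despite the noise) and the high mode at
≈ 5.70, within 2% of the generator's ground truth 5.80.  Running the same
experiment with `--noise -60` but no `--gate` displaces the low mode to
≈ 1.4 — the noise masquerades as weak contacting, which is exactly the
failure the gate repairs.

Other subcommands: `eggdenoise denoise in.wav out.wav --denoise <thresh>`
conditions a recording, `eggdenoise metrics in.wav --csv cycles.csv`
exports per-cycle metrics with a bimodality verdict, and
`eggdenoise synth` writes synthetic test signals.

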