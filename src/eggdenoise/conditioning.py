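"""Time-domain filter stages for EGG conditioning.

The chain runs in a fixed order: steep linear-phase FIR high-pass (removes
near-DC drift), optional parametric notch filters against static side tones,
an optional steep FIR low-pass (removes very-high-frequency artifacts), and
then the spectral gate (see :mod:`eggdenoise.spectral_gate`).

High- and low-pass filters are equiripple linear-phase FIRs; their exact
design method is a free choice as long as the response template holds
(high-pass: ≤ −60 dB at and below 20 Hz, passband from 100 Hz).  Notches are
the standard audio peaking-EQ biquad with negative gain — a single
second-order section per notch.  Unlike the FIR stages, a biquad is not
linear-phase: its phase ripple is confined to roughly one bandwidth
(f0/Q) around the center frequency and is negligible elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .signal_io import SignalTrack

__all__ = [
    "FirSpec",
    "NotchSpec",
    "FilterDesignError",
    "design_highpass_fir",
    "design_lowpass_fir",
    "apply_fir",
    "make_notch",
    "apply_notch",
    "apply_chain",
]


class FilterDesignError(ValueError):
    """The requested filter template cannot be met."""


@dataclass(frozen=True)
class FirSpec:
    """Template for a steep linear-phase FIR filter.

    ``min_stop_atten_db`` is a positive attenuation requirement: the designed
    magnitude must be at or below ``-min_stop_atten_db`` throughout the
    stopband.
    """

    n_taps: int = 1024
    cutoff_hz: float = 100.0
    kind: str = "highpass"
    stopband_edge_hz: float = 20.0
    min_stop_atten_db: float = 60.0


#: Default low-pass template: pass to 10 kHz, ≥60 dB down from 12 kHz.
LOWPASS_DEFAULT = FirSpec(
    n_taps=1024, cutoff_hz=10000.0, kind="lowpass",
    stopband_edge_hz=12000.0, min_stop_atten_db=60.0,
)


@dataclass(frozen=True)
class NotchSpec:
    """One parametric notch: center frequency, (negative) gain, quality factor."""

    freq_hz: float
    gain_db: float = -30.0
    q: float = 30.0

    def __post_init__(self) -> None:
        if not self.freq_hz > 0:
            raise ValueError("notch frequency must be positive")
        if not self.q > 0:
            raise ValueError("notch Q must be positive")


def _design_fir(spec: FirSpec, rate: float) -> np.ndarray:
    nyq = rate / 2.0
    if spec.kind == "highpass":
        if not spec.stopband_edge_hz < spec.cutoff_hz < nyq:
            raise FilterDesignError(
                "highpass needs stopband_edge < cutoff < Nyquist"
            )
        n_taps = spec.n_taps
        # A type-II (even-length symmetric) FIR is forced to zero at Nyquist
        # and cannot be a high-pass; use the next lower odd length.
        if n_taps % 2 == 0:
            n_taps -= 1
        bands = [0.0, spec.stopband_edge_hz, spec.cutoff_hz, nyq]
        # stopband weighted ~67x the passband: drives the equiripple
        # trade-off to ≈0.45 dB pass ripple and ≈62 dB stop attenuation
        coeffs = signal.remez(n_taps, bands, [0.0, 1.0],
                              weight=[10 ** (spec.min_stop_atten_db / 20.0) / 15.0, 1.0],
                              fs=rate)
    elif spec.kind == "lowpass":
        if not spec.cutoff_hz < spec.stopband_edge_hz < nyq:
            raise FilterDesignError(
                "lowpass needs cutoff < stopband_edge < Nyquist"
            )
        # windowed design: the wide transition band makes remez's exchange
        # grid ill-conditioned at ~1000 taps, while a Kaiser window meets
        # a 60 dB template in a fraction of the length
        beta = signal.kaiser_beta(spec.min_stop_atten_db + 10.0)
        coeffs = signal.firwin(
            spec.n_taps,
            0.5 * (spec.cutoff_hz + spec.stopband_edge_hz),
            window=("kaiser", beta), fs=rate)
    else:
        raise ValueError(f"unknown FIR kind {spec.kind!r}")
    # Verify the template on a dense grid before handing the filter out.
    freqs, resp = signal.freqz(coeffs, worN=1 << 16, fs=rate)
    mag_db = 20.0 * np.log10(np.abs(resp) + 1e-300)
    stop = (
        freqs <= spec.stopband_edge_hz
        if spec.kind == "highpass"
        else freqs >= spec.stopband_edge_hz
    )
    achieved = float(mag_db[stop].max())
    if achieved > -spec.min_stop_atten_db:
        raise FilterDesignError(
            f"{spec.kind} design reaches only {achieved:.1f} dB in the "
            f"stopband; {-spec.min_stop_atten_db:.1f} dB required "
            f"(try more taps than {spec.n_taps})"
        )
    return coeffs


def design_highpass_fir(spec: FirSpec | None = None, rate: float = 44100.0) -> np.ndarray:
    """Equiripple linear-phase FIR high-pass meeting ``spec``.

    Defaults reproduce the standard EGG conditioning template: ~1024 taps,
    cutoff 100 Hz, ≥ 60 dB attenuation at and below 20 Hz.  Coefficients are
    exactly symmetric, so the group delay is ``(len(coeffs) - 1) / 2``
    samples at every frequency.
    """
    spec = spec or FirSpec()
    if spec.kind != "highpass":
        raise ValueError("design_highpass_fir requires kind='highpass'")
    return _design_fir(spec, rate)


def design_lowpass_fir(spec: FirSpec | None = None, rate: float = 44100.0) -> np.ndarray:
    """Equiripple linear-phase FIR low-pass (default: 10 kHz cutoff)."""
    spec = spec or LOWPASS_DEFAULT
    if spec.kind != "lowpass":
        raise ValueError("design_lowpass_fir requires kind='lowpass'")
    return _design_fir(spec, rate)


def apply_fir(track: SignalTrack, coeffs: np.ndarray,
              compensate_delay: bool = True) -> SignalTrack:
    """Convolve a track with FIR coefficients.

    Zero-padded convolution, output trimmed to the input length.  With
    ``compensate_delay`` (default, for offline use) the output is advanced
    by the filter's group delay ``(n_taps - 1) // 2`` samples so that
    filtered and unfiltered tracks stay time-aligned.
    """
    coeffs = np.asarray(coeffs, dtype=np.float64)
    if coeffs.size == 0:
        raise ValueError("empty coefficient sequence")
    full = signal.fftconvolve(track.samples, coeffs, mode="full")
    delay = (coeffs.size - 1) // 2 if compensate_delay else 0
    out = full[delay : delay + len(track)]
    return track.with_samples(out)


def make_notch(spec: NotchSpec, rate: float = 44100.0) -> tuple[np.ndarray, np.ndarray]:
    """Peaking-EQ biquad (one second-order section) realizing a notch.

    Audio-EQ-cookbook peaking filter with gain ``spec.gain_db`` (negative
    for a notch) and bandwidth set by ``spec.q``.  The response equals the
    requested gain at the center frequency and returns to 0 dB at DC and
    Nyquist.  Returns ``(b, a)`` coefficient arrays of length 3.
    """
    if spec.freq_hz >= rate / 2.0:
        raise FilterDesignError(
            f"notch at {spec.freq_hz} Hz is at or above Nyquist ({rate / 2} Hz)"
        )
    A = 10.0 ** (spec.gain_db / 40.0)
    w0 = 2.0 * np.pi * spec.freq_hz / rate
    alpha = np.sin(w0) / (2.0 * spec.q)
    b = np.array([1 + alpha * A, -2 * np.cos(w0), 1 - alpha * A])
    a = np.array([1 + alpha / A, -2 * np.cos(w0), 1 - alpha / A])
    return b / a[0], a / a[0]


def apply_notch(track: SignalTrack, spec: NotchSpec) -> SignalTrack:
    b, a = make_notch(spec, track.rate)
    return track.with_samples(signal.lfilter(b, a, track.samples))


def apply_chain(track: SignalTrack, config) -> SignalTrack:
    """Run the fixed-order conditioning chain on a track.

    Order: high-pass → notches (in series) → optional low-pass → optional
    spectral gate.  Each stage is individually bypassable through the
    config; a stage failure is re-raised with the stage name attached.
    ``config`` is an :class:`eggdenoise.cli.PipelineConfig` or any object
    with the same attributes.
    """
    from . import spectral_gate as sg  # local import to avoid a cycle

    out = track
    try:
        if getattr(config, "highpass_enabled", True):
            spec = FirSpec(
                n_taps=getattr(config, "highpass_n_taps", 1024),
                cutoff_hz=getattr(config, "highpass_cutoff_hz", 100.0),
                stopband_edge_hz=getattr(config, "highpass_stopband_edge_hz", 20.0),
            )
            out = apply_fir(out, design_highpass_fir(spec, out.rate))
    except Exception as exc:
        raise RuntimeError(f"highpass stage failed: {exc}") from exc
    try:
        for nspec in getattr(config, "notches", []) or []:
            out = apply_notch(out, nspec)
    except Exception as exc:
        raise RuntimeError(f"notch stage failed: {exc}") from exc
    try:
        if getattr(config, "lowpass_enabled", False):
            spec = FirSpec(
                n_taps=getattr(config, "lowpass_n_taps", 1024),
                cutoff_hz=getattr(config, "lowpass_cutoff_hz", 10000.0),
                kind="lowpass",
                stopband_edge_hz=getattr(config, "lowpass_stopband_edge_hz", 12000.0),
            )
            out = apply_fir(out, design_lowpass_fir(spec, out.rate))
    except Exception as exc:
        raise RuntimeError(f"lowpass stage failed: {exc}") from exc
    try:
        gate_cfg = getattr(config, "gate", None)
        if gate_cfg is not None and gate_cfg.enabled:
            out = sg.gate(out, gate_cfg)
    except Exception as exc:
        raise RuntimeError(f"spectral gate stage failed: {exc}") from exc
    return out
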