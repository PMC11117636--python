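"""Glottal-cycle segmentation and per-cycle harmonic analysis.

Segmentation strategy
---------------------
EGG analysis systems typically track the phase of the fundamental to find
period boundaries.  Here a deterministic, testable stand-in is used:

1.  A coarse f_o track is estimated by normalized autocorrelation over a
    sliding window (4096 samples, hop 1024 by default).
2.  Voiced frames (autocorrelation peak above 0.5, rms above the floor) are
    grouped into regions; a region is split where f_o jumps by more than
    20% between adjacent frames, so stepwise pitch changes start new runs.
3.  Within each region the signal is band-limited around the region's
    median f_o (2nd-order zero-phase Butterworth, 0.6–1.5×), and period
    boundaries are placed at positive-going zero crossings of that
    fundamental, refined to sub-sample precision by linear interpolation.
4.  A cycle is kept only if its period lies in the requested f_o range and
    the local fundamental amplitude exceeds the voicing floor (default
    −60 dBFS), which prevents "cycles" in silence.

The period ``T`` is the (non-integer) distance between interpolated
crossings; the sample span is the enclosing integer range.  Peak-to-peak
amplitude and the maximum positive sample differential are measured on the
original (conditioned) samples within the span.

Per-cycle spectra come from a direct Fourier transform over exactly one
period: ``H_k = (2/T)·|Σ_n x[n]·exp(−i2πkn/T)|``, which needs no window and
no peak picking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .signal_io import SignalTrack

__all__ = ["Cycle", "HarmonicSpectrum", "segment_cycles", "cycle_dft"]


@dataclass(frozen=True)
class Cycle:
    """One detected glottal period.

    ``start``/``end`` delimit the half-open sample span; ``T`` is the
    interpolated period length in sample intervals (generally non-integer).
    """

    start: int
    end: int
    T: float
    a_pp: float
    delta_max: float

    def __post_init__(self) -> None:
        if self.T < 4:
            raise ValueError("cycle period must be at least 4 samples")
        if self.a_pp < 0 or self.delta_max < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass(frozen=True)
class HarmonicSpectrum:
    """Harmonic amplitudes H_1..H_n (linear) and phases for one cycle."""

    amplitudes: np.ndarray
    phases: np.ndarray


def _autocorr_f0(frame: np.ndarray, rate: float, fo_min: float,
                 fo_max: float) -> float | None:
    """Coarse f_o by normalized autocorrelation; None if unvoiced."""
    frame = frame - frame.mean()
    power = float(np.dot(frame, frame))
    if power <= 0:
        return None
    n = frame.size
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(frame, nfft)
    ac = np.fft.irfft(spec * np.conj(spec))[:n]
    lag_min = max(2, int(np.floor(rate / fo_max)))
    lag_max = min(n - 1, int(np.ceil(rate / fo_min)))
    if lag_min >= lag_max:
        return None
    seg = ac[lag_min : lag_max + 1]
    best = int(np.argmax(seg))
    if seg[best] / ac[0] < 0.5:
        return None
    lag = lag_min + best
    # parabolic refinement of the autocorrelation peak; the shift is
    # clamped to one sample since a flat peak makes the fit ill-conditioned
    if 1 <= lag < n - 1:
        y0, y1, y2 = ac[lag - 1], ac[lag], ac[lag + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            lag = lag + float(np.clip(0.5 * (y0 - y2) / denom, -1.0, 1.0))
    f0 = rate / lag
    if not (fo_min * 0.9 <= f0 <= fo_max * 1.1):
        return None
    return f0


def segment_cycles(track: SignalTrack,
                   fo_range: tuple[float, float] = (60.0, 1000.0),
                   voicing_floor_dbfs: float = -60.0,
                   frame: int = 4096, hop: int = 1024) -> list[Cycle]:
    """Segment a conditioned (DC-free) EGG track into glottal cycles."""
    fo_min, fo_max = fo_range
    if not (30.0 <= fo_min < fo_max <= 2000.0):
        raise ValueError("fo_range must lie within [30, 2000] Hz")
    x = track.samples
    rate = track.rate
    if x.size < frame:
        return []
    floor_amp = 10.0 ** (voicing_floor_dbfs / 20.0)

    # 1) coarse f_o track
    starts = np.arange(0, x.size - frame + 1, hop)
    f0s = np.full(starts.size, np.nan)
    for i, s in enumerate(starts):
        f0 = _autocorr_f0(x[s : s + frame], rate, fo_min, fo_max)
        if f0 is not None:
            f0s[i] = f0

    # 2) voiced regions, split at >20% f_o jumps
    regions: list[tuple[int, int, float]] = []  # (sample_start, sample_end, f0_med)
    i = 0
    while i < starts.size:
        if np.isnan(f0s[i]):
            i += 1
            continue
        j = i
        while (j + 1 < starts.size and not np.isnan(f0s[j + 1])
               and abs(f0s[j + 1] - f0s[j]) <= 0.2 * f0s[j]):
            j += 1
        s0 = int(starts[i])
        s1 = int(starts[j]) + frame
        regions.append((s0, min(s1, x.size), float(np.nanmedian(f0s[i : j + 1]))))
        i = j + 1

    cycles: list[Cycle] = []
    for s0, s1, f0 in regions:
        region_cycles: list[Cycle] = []
        seg = x[s0:s1]
        lo = max(0.6 * f0, 0.9 * fo_min)
        hi = min(1.5 * f0, 1.1 * fo_max, 0.45 * rate)
        sos = signal.butter(2, [lo, hi], btype="bandpass", fs=rate, output="sos")
        fund = signal.sosfiltfilt(sos, seg)
        # 3) interpolated positive-going zero crossings of the fundamental
        neg = fund[:-1] <= 0
        pos = fund[1:] > 0
        zc = np.nonzero(neg & pos)[0]
        if zc.size < 2:
            continue
        frac = -fund[zc] / (fund[zc + 1] - fund[zc])
        times = zc + frac  # fractional sample of each crossing, region-local
        for t0, t1 in zip(times[:-1], times[1:]):
            T = t1 - t0
            if not (rate / fo_max <= T <= rate / fo_min) or T < 4:
                continue
            a = int(np.ceil(t0))
            b = int(np.ceil(t1))
            if b - a < 4:
                continue
            # 4) voicing gate on the band-limited fundamental amplitude
            famp = 0.5 * (fund[a:b].max() - fund[a:b].min())
            if famp <= floor_amp:
                continue
            cyc = x[s0 + a : s0 + b]
            a_pp = float(cyc.max() - cyc.min())
            d = np.diff(cyc)
            delta_max = float(d.max()) if d.size else 0.0
            region_cycles.append(Cycle(start=s0 + a, end=s0 + b, T=float(T),
                                       a_pp=a_pp, delta_max=max(delta_max, 0.0)))
        # crossings near the region ends sit in the band-pass filter's edge
        # transient and carry biased periods; trim a six-period margin
        # (the 2nd-order band-pass rings for several cycles)
        margin = 6.0 * rate / f0
        region_cycles = [c for c in region_cycles
                         if c.start - s0 >= margin and s1 - c.end >= margin]
        cycles.extend(region_cycles)
    return cycles


def cycle_dft(track: SignalTrack, cycle: Cycle,
              n_harmonics: int = 10) -> HarmonicSpectrum:
    """Direct Fourier transform over exactly one period.

    ``H_k = (2/T)·|Σ_n x[n]·exp(−i2πkn/T)|`` for k = 1..n_harmonics, with
    the matching phases.  The cycle must be long enough that all requested
    harmonics lie below the per-cycle Nyquist (``T ≥ 2·n_harmonics``).
    """
    if cycle.T < 2 * n_harmonics:
        raise ValueError(
            f"period T={cycle.T:.1f} too short for {n_harmonics} harmonics "
            f"(need T ≥ {2 * n_harmonics})"
        )
    if cycle.start < 0 or cycle.end > len(track):
        raise ValueError("cycle span outside the track")
    xs = track.samples[cycle.start : cycle.end]
    n = np.arange(xs.size)
    k = np.arange(1, n_harmonics + 1)
    basis = np.exp(-2j * np.pi * np.outer(k, n) / cycle.T)
    coeffs = basis @ xs * (2.0 / cycle.T)
    return HarmonicSpectrum(amplitudes=np.abs(coeffs), phases=np.angle(coeffs))
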