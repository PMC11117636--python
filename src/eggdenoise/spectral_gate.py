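"""Spectral threshold-and-expand de-noiser (spectral gating).

The signal is taken to the frequency domain in short half-sine-windowed
frames (default 2048 points, 50% overlap).  In every frame, each bin whose
magnitude falls below the threshold is attenuated downwards with a 4:1 ratio
in dB relative to the threshold (downward dynamics expansion); bins at or
above the threshold, and all phases, are left untouched.  The frames are
then inverse-transformed and overlap-added with a matching half-sine
synthesis window — the analysis/synthesis product is a Hann window, which
satisfies constant overlap-add at 50% hop, so a gate with a zero threshold
is an identity up to float rounding.

Level conventions
-----------------
Per-bin levels are peak-sine-referenced dBFS: a full-scale sine centered on
a bin reads approximately 0 dBFS.  Concretely, a raw rfft magnitude ``M`` of
a half-sine-windowed frame maps to ``20·log10(M / C)`` with calibration
``C = (Σ window) / 2``.  The alternative linear ``thresh`` parameter (the
single-number convention of phase-vocoder compander units) maps to a
per-bin threshold of ``20·log10(thresh / n_fft)`` dBFS; both configuration
routes agree through that formula.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .signal_io import SignalTrack

__all__ = [
    "GateConfig",
    "compander_curve",
    "stft_frames",
    "overlap_add",
    "gate_frames",
    "gate",
    "EnergyRemovalWarning",
]


class EnergyRemovalWarning(UserWarning):
    """The gate removed nearly all of the signal's energy."""


def half_sine_window(n_fft: int) -> np.ndarray:
    """The half-sine (cosine) window sin(π·n/N), n = 0..N−1."""
    return np.sin(np.pi * np.arange(n_fft) / n_fft)


def bin_calibration(n_fft: int) -> float:
    """Raw rfft magnitude of a full-scale sine at a bin center.

    Equals half the window sum, ≈ n_fft/π for the half-sine window.
    """
    return float(half_sine_window(n_fft).sum() / 2.0)


@dataclass
class GateConfig:
    """Configuration of the spectral gate.

    The threshold can be given either as the linear ``thresh`` parameter
    (per-bin level ``20·log10(thresh/n_fft)`` dBFS) or directly as
    ``threshold_dbfs``; exactly one of the two should be set.  ``thresh = 0``
    (or ``threshold_dbfs = None``) disables thresholding.
    """

    n_fft: int = 2048
    thresh: float | None = None
    threshold_dbfs: float | None = None
    ratio: float = 4.0
    hop: int | None = None
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.n_fft < 2 or (self.n_fft & (self.n_fft - 1)):
            raise ValueError("n_fft must be a power of two ≥ 2")
        if self.ratio < 1.0:
            raise ValueError("expansion ratio must be ≥ 1")
        if self.thresh is not None and self.thresh < 0:
            raise ValueError("thresh must be ≥ 0")
        if self.hop is None:
            self.hop = self.n_fft // 2
        if self.thresh is not None and self.threshold_dbfs is not None:
            # both given: they must agree through the defining formula
            implied = 20.0 * np.log10(self.thresh / self.n_fft)
            if abs(implied - self.threshold_dbfs) > 1e-6:
                raise ValueError(
                    "thresh and threshold_dbfs disagree: "
                    f"20*log10(thresh/N) = {implied:.3f} dBFS"
                )

    @property
    def effective_threshold_dbfs(self) -> float | None:
        """Per-bin threshold in dBFS, or None when gating is disabled."""
        if self.threshold_dbfs is not None:
            return self.threshold_dbfs
        if self.thresh is not None and self.thresh > 0:
            return float(20.0 * np.log10(self.thresh / self.n_fft))
        return None


def compander_curve(level_db: float | np.ndarray, threshold_db: float,
                    ratio: float) -> float | np.ndarray:
    """Static downward-expansion curve in dB.

    Levels at or above the threshold pass unchanged; below it, the shortfall
    is multiplied by ``ratio``:  out = T + ratio·(in − T).  The threshold is
    a fixed point and ratio = 1 is the identity.
    """
    if ratio < 1.0:
        raise ValueError("expansion ratio must be ≥ 1")
    level_db = np.asarray(level_db, dtype=np.float64)
    out = np.where(
        level_db >= threshold_db,
        level_db,
        threshold_db + ratio * (level_db - threshold_db),
    )
    return float(out) if out.ndim == 0 else out


def stft_frames(track: SignalTrack, config: GateConfig) -> tuple[np.ndarray, int]:
    """Half-sine-windowed STFT of a track.

    The input is reflect-padded by one frame on each side so that every
    sample receives full analysis-synthesis weight and the edge frames see
    signal-level content (zero padding would pull their bin levels below
    any threshold and gate the track ends).  Returns ``(frames, pad)``
    where ``frames`` has shape (n_frames, n_fft//2 + 1) and ``pad`` is the
    number of padding samples prepended (needed to undo the padding after
    :func:`overlap_add`).
    """
    n, hop = config.n_fft, config.hop
    if len(track) < n:
        raise ValueError(f"track shorter than one frame ({len(track)} < {n})")
    w = half_sine_window(n)
    x = np.pad(track.samples, (n, n), mode="reflect")
    starts = np.arange(0, x.size - n + 1, hop)
    idx = starts[:, None] + np.arange(n)[None, :]
    return np.fft.rfft(x[idx] * w[None, :], axis=1), n


def overlap_add(frames: np.ndarray, config: GateConfig, length: int,
                pad: int) -> np.ndarray:
    """Inverse the STFT of :func:`stft_frames` with half-sine synthesis."""
    n, hop = config.n_fft, config.hop
    w = half_sine_window(n)
    segs = np.fft.irfft(frames, n=n, axis=1) * w[None, :]
    total = pad + length + pad
    y = np.zeros(total + n)
    norm = np.zeros(total + n)
    for i in range(frames.shape[0]):
        s = i * hop
        y[s : s + n] += segs[i]
        norm[s : s + n] += w * w
    mid = slice(pad, pad + length)
    return y[mid] / norm[mid]


def gate_frames(frames: np.ndarray, config: GateConfig) -> np.ndarray:
    """Per-bin threshold-and-expand on complex STFT frames.

    Magnitudes follow :func:`compander_curve` exactly (in the dB domain);
    phases are untouched.  Exposed separately so the frame processor can be
    checked bin-by-bin against the static curve.
    """
    thr_dbfs = config.effective_threshold_dbfs
    if thr_dbfs is None:
        return frames
    t_raw = bin_calibration(config.n_fft) * 10.0 ** (thr_dbfs / 20.0)
    mag = np.abs(frames)
    below = (mag < t_raw) & (mag > 0)
    gains = np.ones_like(mag)
    # out_dB = T + ratio·(in − T)  ⇔  M' = M·(M/T)^(ratio−1) for M < T
    gains[below] = (mag[below] / t_raw) ** (config.ratio - 1.0)
    return frames * gains


def gate(track: SignalTrack, config: GateConfig) -> SignalTrack:
    """Apply thresholded 4:1 downward spectral expansion to a track.

    Output has the input's length with no net delay (offline processing).
    A warning is emitted when more than 99% of the total energy is removed,
    which usually means the threshold is far too high.
    """
    thr_dbfs = config.effective_threshold_dbfs
    if thr_dbfs is None or not config.enabled:
        return track.with_samples(track.samples.copy())
    frames, pad = stft_frames(track, config)
    out = overlap_add(gate_frames(frames, config), config, len(track), pad)
    e_in = float(np.sum(track.samples**2))
    e_out = float(np.sum(out**2))
    if e_in > 0 and e_out < 0.01 * e_in:
        warnings.warn(
            f"spectral gate removed {100 * (1 - e_out / e_in):.1f}% of the "
            "signal energy; the threshold may be set too high",
            EnergyRemovalWarning,
            stacklevel=2,
        )
    return track.with_samples(out)
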