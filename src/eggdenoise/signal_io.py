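"""PCM audio I/O and level conventions for EGG processing.

Amplitudes are carried internally as floating-point ratios of digital full
scale (±1.0), regardless of the bit depth of the file they came from.
Levels are expressed in dBFS: decibels relative to full scale.  Deterministic
tones are specified and measured by their *peak* amplitude (a sine with peak
10^(L/20) is "at L dBFS"); stochastic noise is specified by its standard
deviation, i.e. rms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.io import wavfile

__all__ = [
    "SignalTrack",
    "ClippingWarning",
    "read_wav",
    "write_wav",
    "level_dbfs",
]

#: Sampling rate (Hz) assumed throughout unless a file header says otherwise.
DEFAULT_RATE = 44100


class ClippingWarning(UserWarning):
    """Samples beyond ±1.0 full scale were clipped on write."""


@dataclass
class SignalTrack:
    """A sampled waveform with its rate and channel role.

    Parameters
    ----------
    samples
        Amplitude ratios, full scale = ±1.0 (dimensionless).
    rate
        Sampling rate in Hz; must be positive.
    label
        Free-text channel role, conventionally ``"egg"`` or ``"audio"``.
    """

    samples: np.ndarray
    rate: float = DEFAULT_RATE
    label: str = "egg"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("SignalTrack samples must be one-dimensional")
        if not self.rate > 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise ValueError("SignalTrack samples must all be finite")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Track duration in seconds."""
        return self.samples.size / self.rate

    def with_samples(self, samples: np.ndarray) -> "SignalTrack":
        """A copy of this track carrying new samples (same rate/label)."""
        return replace(self, samples=np.asarray(samples, dtype=np.float64))


def read_wav(path, channel_map: dict[int, str] | None = None) -> list[SignalTrack]:
    """Read a 1- or 2-channel PCM WAV file into :class:`SignalTrack` objects.

    Integer PCM is rescaled so that the most negative code maps to −1.0;
    float files are passed through.  ``channel_map`` assigns a role label to
    each channel index, e.g. ``{0: "audio", 1: "egg"}``; unmapped channels
    get ``"ch<i>"``.

    Raises
    ------
    ValueError
        If the file is not readable PCM WAV or has more than 2 channels.
    """
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:  # noqa: BLE001 - normalize library errors
        raise ValueError(f"cannot read {path!r} as PCM WAV: {exc}") from exc
    if data.ndim == 1:
        data = data[:, None]
    n_channels = data.shape[1]
    if n_channels > 2:
        raise ValueError(
            f"unsupported channel layout: {n_channels} channels (max 2)"
        )
    if data.dtype == np.int16:
        scaled = data.astype(np.float64) / 32768.0
    elif data.dtype == np.int32:
        scaled = data.astype(np.float64) / 2147483648.0
    elif data.dtype == np.uint8:
        scaled = (data.astype(np.float64) - 128.0) / 128.0
    elif np.issubdtype(data.dtype, np.floating):
        scaled = data.astype(np.float64)
    else:
        raise ValueError(f"unsupported WAV sample format {data.dtype}")
    channel_map = channel_map or {}
    tracks = []
    for i in range(n_channels):
        label = channel_map.get(i, f"ch{i}")
        tracks.append(SignalTrack(scaled[:, i], rate=float(rate), label=label))
    return tracks


def write_wav(path, tracks: list[SignalTrack], bit_depth: int | str = 16) -> None:
    """Write tracks as an interleaved RIFF/WAV file.

    ``bit_depth`` is 16, 24 or ``"32-float"`` (alias 32).  Values beyond
    ±1.0 are clipped with a :class:`ClippingWarning` reporting the count;
    they are never wrapped.

    Raises
    ------
    ValueError
        On an empty track list or mismatched rates/lengths.
    """
    if not tracks:
        raise ValueError("write_wav requires at least one track")
    rate = tracks[0].rate
    length = len(tracks[0])
    for t in tracks[1:]:
        if t.rate != rate or len(t) != length:
            raise ValueError("all tracks must share rate and length")
    data = np.stack([t.samples for t in tracks], axis=1)
    n_clipped = int(np.sum(np.abs(data) > 1.0))
    if n_clipped:
        warnings.warn(
            f"{n_clipped} sample(s) beyond full scale were clipped",
            ClippingWarning,
            stacklevel=2,
        )
        data = np.clip(data, -1.0, 1.0)
    if data.shape[1] == 1:
        data = data[:, 0]
    if bit_depth == 16:
        # scale by 2^15 (matching the read convention) and clip the one
        # unrepresentable code at +full scale
        pcm = np.clip(np.round(data * 32768.0), -32768, 32767).astype(np.int16)
        wavfile.write(path, int(rate), pcm)
    elif bit_depth == 24:
        _write_wav24(path, int(rate), data)
    elif bit_depth in (32, "32-float", "32f"):
        wavfile.write(path, int(rate), data.astype(np.float32))
    else:
        raise ValueError(f"unsupported bit depth {bit_depth!r}")


def _write_wav24(path, rate: int, data: np.ndarray) -> None:
    # scipy.io.wavfile reads but does not write 24-bit PCM; pack the three
    # low bytes of a little-endian int32 by hand.
    import wave

    if data.ndim == 1:
        data = data[:, None]
    pcm = np.clip(np.round(data * 8388608.0), -8388608, 8388607).astype(np.int32)
    raw = pcm.astype("<i4").tobytes()
    frames = b"".join(
        raw[i : i + 3] for i in range(0, len(raw), 4)
    )
    with wave.open(str(path), "wb") as fh:
        fh.setnchannels(data.shape[1])
        fh.setsampwidth(3)
        fh.setframerate(rate)
        fh.writeframes(frames)


def level_dbfs(track: SignalTrack, mode: str = "rms") -> float:
    """Signal level in dBFS.

    ``mode="peak"`` returns ``20·log10(max |x|)``; ``mode="rms"`` returns
    ``20·log10(rms(x))``.  An all-zero track yields ``-inf`` rather than
    raising.
    """
    if len(track) == 0:
        raise ValueError("level of an empty track is undefined")
    x = track.samples
    if mode == "peak":
        v = np.max(np.abs(x))
    elif mode == "rms":
        v = np.sqrt(np.mean(x * x))
    else:
        raise ValueError(f"mode must be 'peak' or 'rms', got {mode!r}")
    if v == 0.0:
        return -np.inf
    return float(20.0 * np.log10(v))
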