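"""Per-cycle vocal-fold contact metrics and their aggregation.

Three shape metrics are computed per glottal cycle:

* ``Q_Δ`` — the cycle-normalized peak of the EGG derivative,
  ``2·δ_max / (A_pp · sin(2π/T))`` with ``δ_max`` the largest positive
  sample-to-sample differential, ``A_pp`` the peak-to-peak amplitude and
  ``T`` the period in sample intervals.  A sampled sinusoid gives exactly
  ``1/cos(π/T)`` → 1 as T grows; vocal-fold contacting drives it up
  abruptly, and ``Q_Δ > 2`` is a practical contacting criterion.
* ``Q_ci`` — the contact quotient: the area under the cycle after both
  amplitude and time are normalized to [0, 1]; 0.5 for a sine wave.
* ``HRF_egg`` — the harmonic richness factor
  ``20·log10(Σ_{i=2..10} H_i / H_1)`` in dB; contacting onset corresponds
  to roughly −10 dB and above.

Cycles are aggregated into Q_Δ histograms (bimodality indicates that
de-noising separated non-contacting ≈1 cycles from contacting ones) and
into voice maps on a grid of 1 semitone × 1 dB cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cycles import Cycle, HarmonicSpectrum
from .signal_io import SignalTrack

__all__ = [
    "CycleMetrics",
    "VoiceMapGrid",
    "compute_qdelta",
    "compute_qci",
    "compute_hrf",
    "classify_contacting",
    "qdelta_histogram",
    "check_bimodal",
    "build_voice_map",
    "metrics_for_cycles",
]

QDELTA_CONTACT_THRESHOLD = 2.0
HRF_CONTACT_THRESHOLD_DB = -10.0

#: Default Q_Δ histogram bin edges: 40 log-spaced bins over [0.5, 20],
#: matching the usual green-(1)-to-red-(20) voice-map color span.
DEFAULT_QDELTA_EDGES = np.logspace(np.log10(0.5), np.log10(20.0), 41)


@dataclass
class CycleMetrics:
    """Per-cycle metric bundle; NaN marks an undefined metric."""

    fo_hz: float
    q_delta: float
    q_ci: float
    hrf_db: float = np.nan
    contacting: bool = False


def compute_qdelta(cycle: Cycle) -> float:
    """Cycle-normalized peak dEGG, ``2·δ_max/(A_pp·sin(2π/T))``.

    Returns NaN (undefined) for a flat cycle (``A_pp = 0``) rather than
    raising — silence is an expected input, not an error.
    """
    if cycle.a_pp == 0:
        return np.nan
    return float(2.0 * cycle.delta_max / (cycle.a_pp * np.sin(2.0 * np.pi / cycle.T)))


def compute_qci(track_or_samples, cycle: Cycle | None = None) -> float:
    """Contact quotient: area under the amplitude/time-normalized cycle.

    Accepts either a :class:`SignalTrack` plus a :class:`Cycle` (the span
    is extracted) or a bare sample array for one cycle.  NaN when the cycle
    is flat.
    """
    if cycle is not None:
        xs = np.asarray(track_or_samples.samples[cycle.start : cycle.end], float)
    else:
        xs = np.asarray(track_or_samples, dtype=np.float64)
    if xs.size == 0:
        return np.nan
    a_pp = xs.max() - xs.min()
    if a_pp == 0:
        return np.nan
    return float(np.mean((xs - xs.min()) / a_pp))


def compute_hrf(spectrum: HarmonicSpectrum, upper_harmonic: int = 10) -> float:
    """Harmonic richness factor in dB, ``20·log10(Σ_{i=2..m} H_i / H_1)``.

    ``upper_harmonic`` defaults to 10; the original definition is
    open-ended, so the limit is configurable.  −inf when harmonics 2..m
    vanish; NaN (undefined) when H_1 = 0.
    """
    amps = spectrum.amplitudes
    if amps.size == 0 or amps[0] == 0:
        return np.nan
    upper = min(upper_harmonic, amps.size)
    s = float(np.sum(amps[1:upper]))
    if s == 0:
        return -np.inf
    return float(20.0 * np.log10(s / amps[0]))


def classify_contacting(metrics: CycleMetrics, criterion: str = "qdelta",
                        qdelta_threshold: float = QDELTA_CONTACT_THRESHOLD,
                        hrf_threshold_db: float = HRF_CONTACT_THRESHOLD_DB) -> bool | None:
    """Strict-greater-than contact classification on the chosen metric.

    Returns None when the requested metric is undefined for this cycle.
    """
    if criterion == "qdelta":
        v, thr = metrics.q_delta, qdelta_threshold
    elif criterion == "hrf":
        v, thr = metrics.hrf_db, hrf_threshold_db
    else:
        raise ValueError(f"criterion must be 'qdelta' or 'hrf', got {criterion!r}")
    if v is None or np.isnan(v):
        return None
    return bool(v > thr)


def qdelta_histogram(values, edges: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of Q_Δ values (raw cycles or voice-map cell means).

    ``values`` may be a sequence of floats or of :class:`CycleMetrics`.
    NaNs are dropped.  Returns ``(counts, edges)``; empty input yields an
    all-zero histogram.
    """
    edges = DEFAULT_QDELTA_EDGES if edges is None else np.asarray(edges, float)
    vals = np.asarray(
        [v.q_delta if isinstance(v, CycleMetrics) else v for v in values],
        dtype=np.float64,
    )
    vals = vals[~np.isnan(vals)] if vals.size else vals
    counts, _ = np.histogram(vals, bins=edges)
    return counts, edges


def check_bimodal(counts: np.ndarray, edges: np.ndarray,
                  low_range: tuple[float, float] = (0.8, 1.5),
                  high_min: float = 4.0) -> dict:
    """Bimodality verdict on a Q_Δ histogram.

    De-noising is judged effective when the histogram has one local mode
    near 1 (non-contacting, sinusoidal cycles) and another above about 4
    (contacting).  Mode locations are geometric bin centers.  Returns a
    dict with ``bimodal``, ``low_mode`` and ``high_mode`` (None if absent).
    """
    counts = np.asarray(counts, float)
    if counts.sum() == 0:
        return {"bimodal": False, "low_mode": None, "high_mode": None}
    centers = np.sqrt(edges[:-1] * edges[1:])
    padded = np.concatenate([[-1.0], counts, [-1.0]])
    is_peak = (padded[1:-1] >= padded[:-2]) & (padded[1:-1] > padded[2:]) & (counts > 0)
    peak_idx = np.nonzero(is_peak)[0]
    low_mode = high_mode = None
    low_best = high_best = 0
    for i in peak_idx:
        c = centers[i]
        if low_range[0] <= c <= low_range[1] and counts[i] > low_best:
            low_best, low_mode = counts[i], float(c)
        if c > high_min and counts[i] > high_best:
            high_best, high_mode = counts[i], float(c)
    return {
        "bimodal": low_mode is not None and high_mode is not None,
        "low_mode": low_mode,
        "high_mode": high_mode,
    }


@dataclass
class VoiceMapGrid:
    """Sparse voice map on a 1-semitone × 1-dB grid.

    Cell index = (semitone bin of f_o relative to ``ref_fo``, integer dB
    bin of level).  Each contributing cycle falls in exactly one cell.
    """

    ref_fo: float
    cells: dict = field(default_factory=dict)
    n_skipped: int = 0

    def cell(self, semitone_bin: int, db_bin: int) -> dict | None:
        return self.cells.get((semitone_bin, db_bin))


def build_voice_map(metrics_list: list[CycleMetrics], levels_db,
                    ref_fo: float = 110.0) -> VoiceMapGrid:
    """Bin cycles into a voice map and average their metrics per cell.

    ``levels_db`` holds one level per cycle (acoustic channel when present,
    otherwise EGG rms in dBFS).  Cycles with undefined f_o or level are
    skipped and counted in ``n_skipped``.
    """
    levels_db = np.asarray(levels_db, dtype=np.float64)
    if levels_db.size != len(metrics_list):
        raise ValueError("metrics and levels must be aligned")
    grid = VoiceMapGrid(ref_fo=ref_fo)
    for m, lev in zip(metrics_list, levels_db):
        if not np.isfinite(m.fo_hz) or m.fo_hz <= 0 or not np.isfinite(lev):
            grid.n_skipped += 1
            continue
        key = (int(np.floor(12.0 * np.log2(m.fo_hz / ref_fo))), int(np.floor(lev)))
        cell = grid.cells.setdefault(
            key, {"count": 0, "q_delta": 0.0, "q_ci": 0.0, "hrf_db": 0.0}
        )
        cell["count"] += 1
        n = cell["count"]
        for name, v in (("q_delta", m.q_delta), ("q_ci", m.q_ci),
                        ("hrf_db", m.hrf_db)):
            if np.isfinite(v):
                cell[name] += (v - cell[name]) / n  # running mean
    return grid


def metrics_for_cycles(track: SignalTrack, cycles: list[Cycle],
                       n_harmonics: int = 10,
                       criterion: str = "qdelta") -> list[CycleMetrics]:
    """Convenience: full per-cycle metric bundle for a segmented track."""
    from .cycles import cycle_dft

    out = []
    for c in cycles:
        qd = compute_qdelta(c)
        qc = compute_qci(track, c)
        hrf = np.nan
        if c.T >= 2 * n_harmonics:
            hrf = compute_hrf(cycle_dft(track, c, n_harmonics))
        m = CycleMetrics(fo_hz=track.rate / c.T, q_delta=qd, q_ci=qc, hrf_db=hrf)
        m.contacting = bool(classify_contacting(m, criterion=criterion))
        out.append(m)
    return out
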