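import numpy as np
import pytest

from eggdenoise import (Cycle, CycleMetrics, HarmonicSpectrum, SignalTrack,
                        build_voice_map, check_bimodal, classify_contacting,
                        compute_hrf, compute_qci, compute_qdelta,
                        qdelta_histogram)

RATE = 44100.0


def sine_cycle(T, amp=1.0, offset=0.0, phase=0.0):
    x = amp * np.sin(2 * np.pi * np.arange(int(np.ceil(T))) / T + phase) + offset
    d = np.diff(x)
    return x, Cycle(start=0, end=len(x), T=float(T), a_pp=float(np.ptp(x)),
                    delta_max=float(max(d.max(), 0.0)))


def qdelta_bruteforce(x, T):
    """Literal loop over all sample differentials applying the definition."""
    delta_max = 0.0
    for i in range(len(x) - 1):
        delta_max = max(delta_max, x[i + 1] - x[i])
    a_pp = max(x) - min(x)
    return 2 * delta_max / (a_pp * np.sin(2 * np.pi / T))


class TestQdelta:
    def test_sine_at_220hz_is_one(self):
        # many sampling phases; T = 200.4545 samples
        T = RATE / 220.0
        vals = [compute_qdelta(sine_cycle(T, phase=p)[1])
                for p in np.linspace(0, 2 * np.pi, 20)]
        assert np.allclose(vals, 1.0, atol=1e-3)

    @pytest.mark.parametrize("T,rel", [(50, 1e-12), (200, 2e-4), (1000, 1e-5)])
    def test_closed_form_inverse_cosine(self, T, rel):
        # worst-phase sampled sinusoid: Q_Δ = 1/cos(π/T).  With the sample
        # grid straddling the steepest point, the identity is exact when
        # the peak also falls on a sample (T ≡ 2 mod 4, e.g. T = 50) and
        # holds to ~cos(π/2T) otherwise.
        x = np.sin(2 * np.pi * (np.arange(T) + 0.5) / T)
        d = np.diff(np.sin(2 * np.pi * (np.arange(T + 1) + 0.5) / T))
        c = Cycle(start=0, end=T, T=float(T), a_pp=float(np.ptp(x)),
                  delta_max=float(d.max()))
        assert compute_qdelta(c) == pytest.approx(1 / np.cos(np.pi / T), rel=rel)

    def test_flat_cycle_undefined(self):
        c = Cycle(start=0, end=100, T=100.0, a_pp=0.0, delta_max=0.0)
        assert np.isnan(compute_qdelta(c))

    def test_matches_bruteforce_on_asymmetric_pulse(self):
        from eggdenoise import EggPulseSpec, gen_egg
        track, _ = gen_egg(EggPulseSpec(fo_hz=210.0), 0.05, RATE)
        T = RATE / 210.0
        x = track.samples[: int(T)]
        d = np.diff(track.samples[: int(T) + 1])
        c = Cycle(start=0, end=int(T), T=T, a_pp=float(np.ptp(x)),
                  delta_max=float(d.max()))
        assert compute_qdelta(c) == pytest.approx(
            qdelta_bruteforce(track.samples[: int(T) + 1], T), rel=1e-12)

    def test_invariant_under_scale_and_offset(self):
        x, c = sine_cycle(200.0)
        q0 = compute_qdelta(c)
        x2 = 3.5 * x + 0.2
        d = np.diff(x2)
        c2 = Cycle(start=0, end=len(x2), T=200.0, a_pp=float(np.ptp(x2)),
                   delta_max=float(d.max()))
        assert compute_qdelta(c2) == pytest.approx(q0, rel=1e-12)

    def test_noise_biases_upward_monotone(self):
        rng = np.random.default_rng(123)
        T = 200
        base = np.sin(2 * np.pi * np.arange(T) / T)
        means = []
        for sigma in (0.0, 0.01, 0.03, 0.1):
            qs = []
            for _ in range(200):
                x = base + rng.normal(0, sigma, T)
                d = np.diff(x)
                c = Cycle(start=0, end=T, T=float(T), a_pp=float(np.ptp(x)),
                          delta_max=float(max(d.max(), 0)))
                qs.append(compute_qdelta(c))
            means.append(np.mean(qs))
        assert all(a < b for a, b in zip(means[:-1], means[1:]))
        assert means[0] == pytest.approx(1.0, abs=1e-3)


class TestQci:
    def test_sine_is_half(self):
        x, _ = sine_cycle(RATE / 220.0)
        assert compute_qci(x) == pytest.approx(0.5, abs=0.005)

    def test_symmetric_triangle_is_half(self):
        x = np.concatenate([np.linspace(0, 1, 51), np.linspace(1, 0, 51)[1:]])
        assert compute_qci(x) == pytest.approx(0.5, abs=0.01)

    def test_rectangular_pulse_duty_030(self):
        T = 1000
        x = np.zeros(T)
        x[:300] = 1.0
        assert compute_qci(x) == pytest.approx(0.30, abs=1e-12)

    def test_time_reversal_invariant(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0, 1, 157)
        assert compute_qci(x) == pytest.approx(compute_qci(x[::-1]), rel=1e-12)

    def test_always_in_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            x = rng.normal(0, 1, rng.integers(5, 300))
            v = compute_qci(x)
            assert 0.0 <= v <= 1.0

    def test_flat_cycle_undefined(self):
        assert np.isnan(compute_qci(np.ones(50)))

    def test_track_and_cycle_form(self):
        x, c = sine_cycle(200.0)
        track = SignalTrack(x, rate=RATE)
        assert compute_qci(track, c) == pytest.approx(compute_qci(x))


class TestHrf:
    def mk(self, amps):
        a = np.asarray(amps, float)
        return HarmonicSpectrum(amplitudes=a, phases=np.zeros_like(a))

    def test_pure_sine_minus_infinity(self):
        assert compute_hrf(self.mk([1.0] + [0.0] * 9)) == -np.inf

    def test_unity_ratio_zero_db(self):
        amps = [1.0] + [1.0 / 9] * 9
        assert compute_hrf(self.mk(amps)) == pytest.approx(0.0, abs=1e-9)

    def test_harmonic_series(self):
        amps = [1.0 / i for i in range(1, 11)]
        expected = 20 * np.log10(sum(1.0 / i for i in range(2, 11)))
        assert compute_hrf(self.mk(amps)) == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(5.7, abs=0.1)

    def test_zero_fundamental_undefined(self):
        assert np.isnan(compute_hrf(self.mk([0.0, 1.0, 0.5])))


class TestClassify:
    @pytest.mark.parametrize("qd,expected", [(1.0, False), (5.8, True),
                                             (2.0, False), (2.0001, True)])
    def test_qdelta_strict_threshold(self, qd, expected):
        m = CycleMetrics(fo_hz=220.0, q_delta=qd, q_ci=0.5)
        assert classify_contacting(m, "qdelta") is expected

    def test_hrf_criterion(self):
        m = CycleMetrics(fo_hz=220.0, q_delta=1.0, q_ci=0.5, hrf_db=-5.0)
        assert classify_contacting(m, "hrf") is True
        m.hrf_db = -10.0
        assert classify_contacting(m, "hrf") is False

    def test_undefined_metric_propagates(self):
        m = CycleMetrics(fo_hz=220.0, q_delta=np.nan, q_ci=0.5)
        assert classify_contacting(m, "qdelta") is None


class TestHistogramAndBimodality:
    def test_single_value_single_bin(self):
        counts, edges = qdelta_histogram([1.0] * 50)
        assert counts.sum() == 50
        assert np.count_nonzero(counts) == 1

    def test_total_count_preserved_and_nans_dropped(self):
        counts, _ = qdelta_histogram([1.0, 2.0, 5.0, np.nan, 8.0])
        assert counts.sum() == 4

    def test_empty_histogram(self):
        counts, edges = qdelta_histogram([])
        assert counts.sum() == 0
        assert check_bimodal(counts, edges)["bimodal"] is False

    def test_modes_at_1_and_58_bimodal(self):
        counts, edges = qdelta_histogram([1.0] * 100 + [5.8] * 80)
        v = check_bimodal(counts, edges)
        assert v["bimodal"] is True
        assert v["low_mode"] == pytest.approx(1.0, abs=0.15)
        assert v["high_mode"] == pytest.approx(5.8, rel=0.1)

    def test_single_mode_not_bimodal(self):
        counts, edges = qdelta_histogram([3.0] * 100)
        assert check_bimodal(counts, edges)["bimodal"] is False

    def test_high_mode_must_exceed_four(self):
        counts, edges = qdelta_histogram([1.2] * 100 + [3.5] * 80)
        assert check_bimodal(counts, edges)["bimodal"] is False


class TestVoiceMap:
    def test_single_condition_single_cell(self):
        ms = [CycleMetrics(fo_hz=220.0, q_delta=1.5, q_ci=0.5) for _ in range(25)]
        grid = build_voice_map(ms, [-20.5] * 25, ref_fo=110.0)
        assert len(grid.cells) == 1
        ((st, db),) = grid.cells
        assert st == 12 and db == -21
        assert grid.cells[(st, db)]["count"] == 25

    def test_octave_is_twelve_semitones(self):
        ms = [CycleMetrics(fo_hz=220.0, q_delta=1.0, q_ci=0.5)]
        grid = build_voice_map(ms, [-30.0], ref_fo=110.0)
        assert next(iter(grid.cells))[0] == 12

    def test_two_block_means_match_direct(self):
        rng = np.random.default_rng(9)
        qa = rng.normal(1.0, 0.01, 40)
        qb = rng.normal(5.8, 0.05, 40)
        ms = [CycleMetrics(fo_hz=220.0, q_delta=q, q_ci=0.5) for q in qa]
        ms += [CycleMetrics(fo_hz=220.0, q_delta=q, q_ci=0.5) for q in qb]
        levels = [-33.0] * 40 + [-13.0] * 40
        grid = build_voice_map(ms, levels, ref_fo=110.0)
        assert grid.cells[(12, -33)]["q_delta"] == pytest.approx(qa.mean(), rel=1e-9)
        assert grid.cells[(12, -13)]["q_delta"] == pytest.approx(qb.mean(), rel=1e-9)

    def test_undefined_skipped_with_counter(self):
        ms = [CycleMetrics(fo_hz=np.nan, q_delta=1.0, q_ci=0.5),
              CycleMetrics(fo_hz=220.0, q_delta=1.0, q_ci=0.5)]
        grid = build_voice_map(ms, [-20.0, -20.0])
        assert grid.n_skipped == 1
        assert sum(c["count"] for c in grid.cells.values()) == 1
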