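"""Envelope segmentation, bout assembly/filtering, and syllable rate."""

import numpy as np
import pytest

from songdev.segmentation import (EnvelopeTrace, SegmentationParams,
                                  assemble_bouts, filter_bouts,
                                  segment_envelope, segment_to_records,
                                  syllable_rate)
from songdev.simulate import render_envelope, simulate_ontogeny

from conftest import small_config

P = SegmentationParams(amplitude_threshold=0.5)


def _trace(values, sp=1.0):
    return EnvelopeTrace(sample_period_ms=sp, values=np.asarray(values, float))


def brute_force_runs(values, threshold, sp):
    """Sample-by-sample run scan: the segmentation oracle."""
    out, start = [], None
    for k, v in enumerate(values):
        if v > threshold and start is None:
            start = k
        elif v <= threshold and start is not None:
            out.append((start * sp, k * sp))
            start = None
    if start is not None:
        out.append((start * sp, len(values) * sp))
    return out


def brute_force_bouts(intervals, max_gap):
    """Pairwise-gap grouping oracle."""
    bouts = []
    for iv in intervals:
        if bouts and iv[0] - bouts[-1][-1][1] <= max_gap:
            bouts[-1].append(iv)
        else:
            bouts.append([iv])
    return bouts


class TestSegmentEnvelope:
    def test_all_zero_trace_yields_nothing(self):
        assert segment_envelope(_trace([0.0] * 50), P) == []

    def test_single_pulse_duration(self):
        v = [0.0] * 10 + [1.0] * 60 + [0.0] * 10
        (on, off), = segment_envelope(_trace(v), P)
        assert off - on == 60.0 and on == 10.0

    @pytest.mark.parametrize("seed", range(5))
    def test_random_traces_match_run_length_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = (rng.random(400) > 0.6).astype(float)
        got = segment_envelope(_trace(v, sp=0.5), P)
        assert got == brute_force_runs(v, 0.5, 0.5)

    def test_threshold_is_strict(self):
        v = [0.0, 0.5, 0.5, 0.0]  # exactly at threshold: below
        assert segment_envelope(_trace(v), P) == []

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            SegmentationParams(amplitude_threshold=0.0)


class TestAssembleBouts:
    def test_gap_at_most_100ms_shares_a_bout(self):
        ivs = [(0.0, 50.0), (130.0, 180.0)]  # 80 ms gap
        assert len(assemble_bouts(ivs, P)) == 1

    def test_gap_over_100ms_splits(self):
        ivs = [(0.0, 50.0), (200.0, 250.0)]  # 150 ms gap
        assert len(assemble_bouts(ivs, P)) == 2

    def test_boundary_gap_inclusive(self):
        ivs = [(0.0, 50.0), (150.0, 200.0)]  # exactly 100 ms
        assert len(assemble_bouts(ivs, P)) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_random_trains_match_grouping_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        onsets = np.cumsum(rng.uniform(20, 300, size=40))
        ivs = [(float(o), float(o + 15.0)) for o in onsets]
        assert assemble_bouts(ivs, P) == brute_force_bouts(ivs, P.max_gap_ms)

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            assemble_bouts([(100.0, 150.0), (0.0, 50.0)], P)


class TestFilterBouts:
    def test_short_bout_dropped_entirely(self):
        bouts = [[(0.0, 80.0), (120.0, 180.0)]]  # 180 ms span
        assert len(filter_bouts(bouts, P)) == 0

    def test_exact_750ms_span_retained(self):
        bouts = [[(0.0, 300.0), (400.0, 750.0)]]
        df = filter_bouts(bouts, P)
        assert len(df) == 2
        assert np.isnan(df.iloc[-1]["pause_ms"])  # bout-final: no pause
        assert df.iloc[0]["pause_ms"] == 100.0

    def test_mixed_set_matches_span_oracle(self):
        rng = np.random.default_rng(4)
        bouts = []
        t = 0.0
        for _ in range(30):
            n = int(rng.integers(1, 8))
            ivs = []
            for _ in range(n):
                ivs.append((t, t + float(rng.uniform(30, 200))))
                t = ivs[-1][1] + float(rng.uniform(10, 90))
            bouts.append(ivs)
            t += 500.0
        df = filter_bouts(bouts, P)
        expected = sum(len(b) for b in bouts
                       if b[-1][1] - b[0][0] >= P.min_bout_span_ms)
        assert len(df) == expected


class TestSyllableRate:
    @pytest.mark.parametrize("d,i,sr", [(50, 50, 10.0), (100, 100, 5.0),
                                        (40, 6, 1000 / 46)])
    def test_rate_is_inverse_period(self, d, i, sr):
        assert syllable_rate(d, i) == pytest.approx(sr)

    def test_absent_pause_gives_absent_rate(self):
        assert np.isnan(syllable_rate(50.0, float("nan")))

    def test_identical_pulse_train_rate_is_exactly_1000_over_period(self):
        v = np.zeros(2000)
        for k in range(0, 2000 - 40, 100):  # period 100 ms, duration 40
            v[k:k + 40] = 1.0
        df = segment_to_records(_trace(v), P)
        rates = df["syllable_rate_hz"].dropna()
        assert (rates == 10.0).all()


class TestMonotonicity:
    def _random_trace(self, seed):
        rng = np.random.default_rng(seed)
        v = np.zeros(8000)
        t = 0
        while t < 7500:
            dur = int(rng.uniform(20, 150))
            v[t:t + dur] = 1.0
            t += dur + int(rng.uniform(10, 250))
        return _trace(v)

    def test_retained_count_monotone_in_parameters(self):
        trace = self._random_trace(9)
        counts_span = []
        for span in (200.0, 750.0, 1500.0, 3000.0):
            p = SegmentationParams(0.5, min_bout_span_ms=span)
            counts_span.append(len(segment_to_records(trace, p)))
        assert counts_span == sorted(counts_span, reverse=True)
        counts_gap = []
        for gap in (20.0, 60.0, 100.0, 200.0):
            p = SegmentationParams(0.5, max_gap_ms=gap)
            counts_gap.append(len(segment_to_records(trace, p)))
        assert counts_gap == sorted(counts_gap)


class TestEnvelopeRoundTrip:
    def test_rendered_day_recovers_timings_within_one_sample(self):
        ds, _ = simulate_ontogeny(small_config(seed=2, t1_days=10,
                                               silent_days=5, t2_days=8,
                                               bouts_per_day=2.0))
        day = ds.singing_days()[-1]
        rec = ds.records[ds.records["experiment_day"] == day]
        trace = render_envelope(rec, sample_period_ms=0.5)
        got = segment_envelope(trace, SegmentationParams(0.5))
        assert len(got) == len(rec)
        onsets = np.sort(rec["onset_ms"].to_numpy())
        np.testing.assert_allclose(np.array([g[0] for g in got]), onsets,
                                   atol=trace.sample_period_ms)
        durs = rec.sort_values("onset_ms")["duration_ms"].to_numpy()
        np.testing.assert_allclose(np.array([g[1] - g[0] for g in got]),
                                   durs, atol=2 * trace.sample_period_ms)
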