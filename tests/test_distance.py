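"""Median normalization and 8-D Euclidean syllable distances."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from songdev.datamodel import FEATURES, OntogenyDataset
from songdev.distance import (COORDINATES, distance_summaries,
                              euclidean_distance, median_normalize)

from conftest import make_calendar, make_records

COLS = [FEATURES[c] for c in COORDINATES]


def _cohort_frame(values_by_col):
    n = len(next(iter(values_by_col.values())))
    base = {c: np.ones(n) for c in COLS}
    base.update(values_by_col)
    return pd.DataFrame(base)


class TestMedianNormalize:
    def test_values_divided_by_global_median(self):
        df = _cohort_frame({"fm": np.array([2.0, 4.0, 6.0])})
        med, (out,) = median_normalize(df)
        assert med["fm"] == 4.0
        np.testing.assert_allclose(out["fm"], [0.5, 1.0, 1.5])

    def test_identical_cohort_normalizes_to_ones(self):
        df = _cohort_frame({c: np.full(5, 3.0) for c in COLS})
        _, (out,) = median_normalize(df)
        np.testing.assert_allclose(out[COLS], 1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_medians_match_sort_based_oracle(self, seed):
        rng = np.random.default_rng(seed)
        df = _cohort_frame({c: rng.uniform(1, 9, size=21) for c in COLS})
        med, _ = median_normalize(df)
        for c in COLS:
            s = np.sort(df[c].to_numpy())
            assert med[c] == s[len(s) // 2]

    def test_zero_median_names_the_feature(self):
        df = _cohort_frame({"fm": np.zeros(3)})
        with pytest.raises(ValueError, match="fm"):
            median_normalize(df)


class TestEuclideanDistance:
    def test_identical_vectors_are_at_distance_zero(self):
        v = np.ones(8)
        assert euclidean_distance(v, v) == 0.0

    def test_unit_difference_in_one_coordinate(self):
        a = np.ones(8)
        b = a.copy()
        b[3] += 1.0
        assert euclidean_distance(a, b) == 1.0

    def test_all_ones_vs_all_twos_is_sqrt_8(self):
        assert euclidean_distance(np.ones(8), np.full(8, 2.0)) \
            == pytest.approx(np.sqrt(8))

    def test_incomplete_vector_rejected(self):
        a = np.ones(8)
        b = a.copy()
        b[0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            euclidean_distance(a, b)

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(-50, 50), min_size=8, max_size=8),
           st.lists(st.floats(-50, 50), min_size=8, max_size=8),
           st.lists(st.floats(-50, 50), min_size=8, max_size=8))
    def test_metric_axioms(self, a, b, c):
        a, b, c = np.array(a), np.array(b), np.array(c)
        dab = euclidean_distance(a, b)
        assert dab >= 0.0
        assert dab == euclidean_distance(b, a)
        assert dab <= euclidean_distance(a, c) + euclidean_distance(c, b) \
            + 1e-9


def _typed_dataset(tokens_t1, tokens_t2):
    """tokens_*: dict type -> list of 8-coordinate vectors."""
    rows = []
    frames = []
    for phase, day0, tokens in (("T1_PLUS", 10, tokens_t1),
                                ("T2_PLUS", 40, tokens_t2)):
        recs = []
        for styp, vecs in tokens.items():
            for k, v in enumerate(vecs):
                day = day0 + (k % 7)
                sr, d, i, fm, am, bw, mf, e = v
                recs.append(dict(
                    bird_id="b1", phase=phase, experiment_day=day,
                    phase_day=np.nan, bout_id=f"{phase}_{day}_{styp}{k}",
                    bout_position=0, syllable_type=styp,
                    onset_ms=float(k), duration_ms=d, pause_ms=i,
                    syllable_rate_hz=sr, fm=fm, am=am, bandwidth_hz=bw,
                    mean_frequency_hz=mf, wiener_entropy=e))
        frames.append(pd.DataFrame(recs))
    rec = pd.concat(frames, ignore_index=True)
    cal = make_calendar(t1=(0, 20, 10), tm=(21, 35), t2=(36, 50, 40))
    return OntogenyDataset(bird_id="b1", calendar=cal, records=rec)


def _vec(x):
    return [x] * 8


class TestDistanceSummaries:
    def test_degenerate_cohort_separates_categories(self):
        ds = _typed_dataset({"a": [_vec(1.0)] * 3, "b": [_vec(4.0)] * 3},
                            {"a": [_vec(1.0)] * 3, "b": [_vec(4.0)] * 3})
        med = pd.Series(1.0, index=COLS)
        sums = distance_summaries(ds, med, n_per_type=3, seed=0)
        assert sums["T1xT1"].mean_distance == 0.0
        assert sums["T1xT2"].mean_distance == 0.0
        assert sums["T1xT2_ext"].mean_distance > 0.0

    def test_tiny_cohort_matches_exhaustive_pairwise_oracle(self):
        rng = np.random.default_rng(2)
        toks = {s: [list(rng.uniform(0.5, 2.0, 8)) for _ in range(3)]
                for s in ("a", "b")}
        toks2 = {s: [list(rng.uniform(0.5, 2.0, 8)) for _ in range(3)]
                 for s in ("a", "b")}
        ds = _typed_dataset(toks, toks2)
        med = pd.Series(1.0, index=COLS)
        sums = distance_summaries(ds, med, n_per_type=3, seed=0)

        def dist(u, v):
            return np.sqrt(np.sum((np.array(u) - np.array(v)) ** 2))

        within = [dist(u, v) for s in toks
                  for u, v in itertools.combinations(toks[s], 2)]
        per_type_within = [np.mean([dist(u, v) for u, v in
                                    itertools.combinations(toks[s], 2)])
                           for s in toks]
        cross = [np.mean([dist(u, v) for u in toks[s] for v in toks2[s]])
                 for s in toks]
        ext = [np.mean([dist(u, v) for u in toks[s]
                        for o in toks2 if o != s for v in toks2[o]])
               for s in toks]
        assert sums["T1xT1"].mean_distance == pytest.approx(
            np.mean(per_type_within))
        assert sums["T1xT2"].mean_distance == pytest.approx(np.mean(cross))
        assert sums["T1xT2_ext"].mean_distance == pytest.approx(np.mean(ext))

    def test_sampling_is_stable_across_seeds(self):
        rng = np.random.default_rng(3)
        toks = {s: [list(rng.normal(loc, 0.1, 8)) for _ in range(40)]
                for s, loc in (("a", 1.0), ("b", 2.0))}
        toks2 = {s: [list(rng.normal(loc, 0.1, 8)) for _ in range(40)]
                 for s, loc in (("a", 1.0), ("b", 2.0))}
        ds = _typed_dataset(toks, toks2)
        med = pd.Series(1.0, index=COLS)
        s1 = distance_summaries(ds, med, n_per_type=20, seed=1)
        s2 = distance_summaries(ds, med, n_per_type=20, seed=99)
        for cat in ("T1xT1", "T1xT2", "T1xT2_ext"):
            sem = s1[cat].sem if np.isfinite(s1[cat].sem) else 0.05
            assert abs(s1[cat].mean_distance - s2[cat].mean_distance) \
                < max(3 * sem, 0.15)


class TestRescalingInvariance:
    def test_feature_rescaling_cancels_in_normalized_distances(self):
        rng = np.random.default_rng(4)
        base = {c: rng.uniform(1, 5, size=9) for c in COLS}
        df1 = pd.DataFrame(base)
        df2 = df1.copy()
        df2["bandwidth_hz"] = df2["bandwidth_hz"] * 137.0
        med1, (n1,) = median_normalize(df1)
        med2, (n2,) = median_normalize(df2)
        d1 = euclidean_distance(n1[COLS].iloc[0], n1[COLS].iloc[5])
        d2 = euclidean_distance(n2[COLS].iloc[0], n2[COLS].iloc[5])
        assert d1 == pytest.approx(d2, rel=1e-12)
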