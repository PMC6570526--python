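"""Amplitude-threshold segmentation of envelope traces into syllables.

Vocalizations are segmented by thresholding an amplitude envelope: maximal
runs of strictly supra-threshold samples become syllables.  Syllables
separated by gaps of at most ``max_gap`` ms share a song bout, and only
bouts spanning at least ``min_bout_span`` ms are analyzed (this removes
isolated calls and cage noise).  The syllable rate of syllable *a* is
``SR_a = 1/(d_a + i_a)`` where *d* is its duration and *i* the pause to
the next syllable in the same bout; bout-final syllables have no pause and
therefore no rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EnvelopeTrace",
    "SegmentationParams",
    "segment_envelope",
    "assemble_bouts",
    "filter_bouts",
    "syllable_rate",
    "read_envelope_csv",
    "read_wav_envelope",
    "segment_to_records",
]


@dataclass(frozen=True)
class EnvelopeTrace:
    """A sampled non-negative amplitude envelope."""

    sample_period_ms: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.sample_period_ms <= 0:
            raise ValueError("sample_period_ms must be > 0")
        if self.values.size < 2:
            raise ValueError("an envelope needs at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("envelope values must be finite")
        if (self.values < 0).any():
            raise ValueError("envelope values must be non-negative")


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholding and bout-assembly parameters.

    ``amplitude_threshold`` has the envelope's units and is recording-setup
    specific (no universal default exists; it is chosen once per bird).
    """

    amplitude_threshold: float
    max_gap_ms: float = 100.0
    min_bout_span_ms: float = 750.0

    def __post_init__(self):
        if self.amplitude_threshold <= 0:
            raise ValueError("amplitude_threshold must be > 0")
        if self.max_gap_ms <= 0 or self.min_bout_span_ms <= 0:
            raise ValueError("max_gap_ms and min_bout_span_ms must be > 0")


def segment_envelope(
    trace: EnvelopeTrace, params: SegmentationParams
) -> list[tuple[float, float]]:
    """Maximal strictly-supra-threshold runs as (onset_ms, offset_ms).

    Onset is the time of the first supra-threshold sample; offset is the
    time just after the last one.  Intervals are sorted, non-overlapping.
    """
    above = trace.values > params.amplitude_threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    sp = trace.sample_period_ms
    return [(float(s * sp), float(e * sp)) for s, e in zip(starts, ends)]


def assemble_bouts(
    intervals: list[tuple[float, float]], params: SegmentationParams
) -> list[list[tuple[float, float]]]:
    """Group sorted syllable intervals into bouts by the max-gap rule.

    Consecutive intervals whose gap (next onset minus previous offset) is
    at most ``max_gap_ms`` share a bout; a larger gap starts a new bout.
    """
    if not intervals:
        return []
    arr = np.asarray(intervals, dtype=float)
    if (np.diff(arr[:, 0]) < 0).any():
        raise ValueError("intervals must be sorted by onset")
    bouts: list[list[tuple[float, float]]] = [[intervals[0]]]
    for prev, cur in zip(intervals, intervals[1:]):
        if cur[0] - prev[1] <= params.max_gap_ms:
            bouts[-1].append(cur)
        else:
            bouts.append([cur])
    return bouts


def filter_bouts(
    bouts: list[list[tuple[float, float]]],
    params: SegmentationParams,
    bout_id_prefix: str = "b",
) -> pd.DataFrame:
    """Keep bouts spanning >= ``min_bout_span_ms``; emit timing records.

    Returns a DataFrame with columns bout_id, bout_position, onset_ms,
    duration_ms, pause_ms, syllable_rate_hz.  The pause (and hence the
    rate) of each bout's last syllable is absent (NaN).
    """
    rows = []
    kept = 0
    for bout in bouts:
        span = bout[-1][1] - bout[0][0]
        if span < params.min_bout_span_ms:
            continue
        bid = f"{bout_id_prefix}{kept:05d}"
        kept += 1
        for pos, (on, off) in enumerate(bout):
            d = off - on
            if pos + 1 < len(bout):
                i = bout[pos + 1][0] - off
                sr = syllable_rate(d, i)
            else:
                i = np.nan
                sr = np.nan
            rows.append((bid, pos, on, d, i, sr))
    return pd.DataFrame(
        rows,
        columns=["bout_id", "bout_position", "onset_ms", "duration_ms",
                 "pause_ms", "syllable_rate_hz"],
    )


def syllable_rate(d_ms: float, i_ms: float) -> float:
    """SR = 1000/(d+i) Hz for durations in ms; NaN when the pause is absent."""
    if d_ms <= 0:
        raise ValueError("duration must be > 0")
    if i_ms is None or np.isnan(i_ms):
        return float("nan")
    if i_ms < 0:
        raise ValueError("pause must be >= 0")
    return 1000.0 / (d_ms + i_ms)


def segment_to_records(
    trace: EnvelopeTrace, params: SegmentationParams, bout_id_prefix: str = "b"
) -> pd.DataFrame:
    """Envelope -> retained syllable timing records (segment, group, filter)."""
    intervals = segment_envelope(trace, params)
    bouts = assemble_bouts(intervals, params)
    return filter_bouts(bouts, params, bout_id_prefix=bout_id_prefix)


# ---------------------------------------------------------------------------
# envelope ingestion

def read_envelope_csv(path) -> EnvelopeTrace:
    """Read a 2-column (time_ms, amplitude) CSV with uniform sampling."""
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(float)
    dt = np.diff(t)
    if dt.size == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("envelope CSV must be uniformly sampled in time_ms")
    return EnvelopeTrace(sample_period_ms=float(dt[0]),
                         values=df.iloc[:, 1].to_numpy(float))


def read_wav_envelope(path, window_ms: float = 2.0) -> EnvelopeTrace:
    """Mono WAV -> rectified moving-RMS envelope (window default 2 ms)."""
    from scipy.io import wavfile

    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("only mono WAV input is supported")
    x = data.astype(float)
    if data.dtype.kind == "i":
        x /= float(np.iinfo(data.dtype).max)
    win = max(1, int(round(window_ms * rate / 1000.0)))
    kernel = np.ones(win) / win
    rms = np.sqrt(np.convolve(x * x, kernel, mode="same"))
    return EnvelopeTrace(sample_period_ms=1000.0 / rate, values=rms)
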