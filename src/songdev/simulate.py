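"""Seeded generator of synthetic song ontogenies with known ground truth.

The generator emulates the statistical structure the analysis assumes,
for a small repertoire of 6 syllable types falling into three syllable-
rate classes (fast ~21.7 Hz, medium ~11.9 Hz, slow ~4.9 Hz):

* a three-phase design — first treatment (song develops over ~200 days),
  withdrawal (~75 silent days), second treatment (~35 days) — with a
  3-day first-song latency after each implant;
* per-feature logistic drift of the type means from an undifferentiated
  subsong value toward the crystallized target; during the second
  treatment both the inflection day and the slope scale are divided by a
  ``savings_factor``, so re-acquisition is a time-compressed copy of
  acquisition;
* feature-selective deterioration: at the second implant the pause,
  frequency-modulation and amplitude-modulation means (and hence the
  derived syllable rate) are reset partway back toward their subsong
  values, while duration, bandwidth, mean frequency and entropy resume
  at their targets;
* first-order Markov phrase sequencing with no self-transitions, per-type
  phrase lengths, and Poisson bout production.

Per-syllable values are the day's type mean plus a shared day-level
offset (recording/motivation drift common to all syllables of a day)
plus independent Gaussian noise.  Everything is deterministic for a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    OntogenyDataset,
    Phase,
    PhaseCalendar,
    PhaseWindow,
    TABLE_COLUMNS,
)
from .segmentation import EnvelopeTrace

__all__ = [
    "FeatureDrift",
    "GeneratorConfig",
    "GeneratorTruth",
    "default_config",
    "simulate_ontogeny",
    "simulate_cohort",
    "render_envelope",
    "simulate_spine_segments",
]

_TYPES = ("a", "b", "c", "d", "e", "f")


@dataclass(frozen=True)
class FeatureDrift:
    """Logistic drift of one feature's per-type means (first treatment).

    The mean for a type starts at ``start`` (undifferentiated subsong,
    shared by all types), and approaches the type's ``target`` as
    ``start + (target-start) * sigmoid((t - inflection_day)/scale_days)``
    with ``t`` in days since implantation.  ``deteriorates`` marks
    features reset partway toward ``start`` at the second implant.
    """

    start: float
    targets: tuple[float, ...]
    sd: float
    day_sd: float
    inflection_day: float
    scale_days: float
    deteriorates: bool


def _default_drifts() -> dict[str, FeatureDrift]:
    # periods d+i per class: 46.08 ms (21.7 Hz), 84.03 (11.9), 204.08 (4.9)
    return {
        "d": FeatureDrift(55.0, (25.0, 28.0, 40.0, 42.0, 60.0, 65.0),
                          sd=2.5, day_sd=0.3, inflection_day=95.0,
                          scale_days=14.0, deteriorates=False),
        "i": FeatureDrift(42.0, (21.08, 18.08, 44.03, 42.03, 144.08, 139.08),
                          sd=3.5, day_sd=0.5, inflection_day=45.0,
                          scale_days=9.0, deteriorates=True),
        "FM": FeatureDrift(20.0, (55.0, 25.0, 70.0, 35.0, 15.0, 45.0),
                           sd=5.0, day_sd=0.6, inflection_day=75.0,
                           scale_days=12.0, deteriorates=True),
        "AM": FeatureDrift(8.0, (25.0, 12.0, 30.0, 18.0, 9.0, 22.0),
                           sd=3.5, day_sd=0.4, inflection_day=70.0,
                           scale_days=12.0, deteriorates=True),
        "BW": FeatureDrift(2500.0, (1200.0, 2800.0, 900.0, 2000.0, 3200.0,
                                    1500.0),
                           sd=220.0, day_sd=30.0, inflection_day=70.0,
                           scale_days=11.0, deteriorates=False),
        "MF": FeatureDrift(3000.0, (2500.0, 3400.0, 2100.0, 3800.0, 2900.0,
                                    3300.0),
                           sd=160.0, day_sd=20.0, inflection_day=65.0,
                           scale_days=11.0, deteriorates=False),
        "E": FeatureDrift(-0.8, (-2.5, -1.4, -3.1, -1.9, -1.1, -2.8),
                          sd=0.22, day_sd=0.03, inflection_day=70.0,
                          scale_days=12.0, deteriorates=False),
    }


def _default_matrix(n: int) -> np.ndarray:
    # sparse cyclic syntax: mostly advance one type, sometimes skip one
    m = np.zeros((n, n))
    for t in range(n):
        m[t, (t + 1) % n] = 0.75
        m[t, (t + 2) % n] = 0.25
    return m


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of a simulated ontogeny.

    Defaults mirror the study conditions the analysis is built for: a
    6-type repertoire in three rate classes, ~200/75/35-day phases, 3-day
    first-song latency, a savings factor of 7, and daily output of ~800
    syllables (~2x10^5 per bird over the whole ontogeny).
    """

    seed: int = 0
    types: tuple[str, ...] = _TYPES
    drifts: dict[str, FeatureDrift] = field(default_factory=_default_drifts)
    savings_factor: float = 7.0
    reset_fraction: float = 0.6
    t1_days: int = 200
    silent_days: int = 75
    t2_days: int = 35
    first_song_latency: int = 3
    transition_matrix: np.ndarray = None  # type: ignore[assignment]
    phrase_length_means: tuple[float, ...] = (8.0, 8.0, 5.0, 5.0, 3.0, 3.0)
    phrases_per_bout_mean: float = 5.0
    bouts_per_day: float = 30.0
    bout_gap_ms: float = 500.0

    def __post_init__(self):
        if self.transition_matrix is None:
            object.__setattr__(self, "transition_matrix",
                               _default_matrix(len(self.types)))
        m = np.asarray(self.transition_matrix, dtype=float)
        n = len(self.types)
        if m.shape != (n, n):
            raise ValueError("transition matrix shape must match repertoire")
        if not np.allclose(m.sum(axis=1), 1.0):
            raise ValueError("transition matrix rows must sum to 1")
        if np.diag(m).any():
            raise ValueError("self-transitions are not allowed")
        if self.savings_factor < 1:
            raise ValueError("savings_factor must be >= 1")
        if not 0 <= self.reset_fraction <= 1:
            raise ValueError("reset_fraction must be in [0, 1]")
        for name, dr in self.drifts.items():
            if dr.scale_days <= 0 or dr.sd < 0:
                raise ValueError(f"invalid drift for feature {name}")
            if len(dr.targets) != n:
                raise ValueError(f"{name}: one target per type is required")
        object.__setattr__(self, "transition_matrix", m)


def default_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """The study-condition default configuration, with keyword overrides."""
    return GeneratorConfig(seed=seed, **overrides)


@dataclass(frozen=True)
class GeneratorTruth:
    """Ground truth of a simulated ontogeny, for parameter-recovery tests."""

    savings_factor: float
    reset_fraction: float
    deteriorating: tuple[str, ...]
    persisting: tuple[str, ...]
    sr_class_rates: tuple[float, float, float]  # fast, medium, slow, Hz
    transition_matrix: np.ndarray
    drift_t1: dict[str, tuple[float, float]]  # feature -> (inflection, scale)
    drift_t2: dict[str, tuple[float, float]]


def _truth(config: GeneratorConfig) -> GeneratorTruth:
    det = tuple(f for f, d in config.drifts.items() if d.deteriorates)
    per = tuple(f for f, d in config.drifts.items() if not d.deteriorates)
    periods = np.array(config.drifts["d"].targets) + np.array(
        config.drifts["i"].targets)
    rates = 1000.0 / periods
    classes = tuple(
        float(np.mean(rates[k:k + 2])) for k in (0, 2, 4)
    )
    k = config.savings_factor
    t1 = {f: (d.inflection_day, d.scale_days)
          for f, d in config.drifts.items()}
    t2 = {f: (d.inflection_day / k, d.scale_days / k)
          for f, d in config.drifts.items()}
    return GeneratorTruth(
        savings_factor=k,
        reset_fraction=config.reset_fraction,
        deteriorating=det + ("SR",),  # SR is derived from d and i
        persisting=per,
        sr_class_rates=classes,
        transition_matrix=config.transition_matrix.copy(),
        drift_t1=t1,
        drift_t2=t2,
    )


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _phase_means(
    config: GeneratorConfig, feature: str, phase: Phase, t: float
) -> np.ndarray:
    """Per-type mean of ``feature`` at ``t`` days since the phase implant."""
    dr = config.drifts[feature]
    targets = np.asarray(dr.targets)
    if phase is Phase.T1_PLUS:
        lo = np.full_like(targets, dr.start)
        c, s = dr.inflection_day, dr.scale_days
    else:  # T2_PLUS
        if dr.deteriorates:
            lo = targets + config.reset_fraction * (dr.start - targets)
        else:
            lo = targets
        k = config.savings_factor
        c, s = dr.inflection_day / k, dr.scale_days / k
    return lo + (targets - lo) * _sigmoid((t - c) / s)


def simulate_ontogeny(
    config: GeneratorConfig, bird_id: str = "bird01"
) -> tuple[OntogenyDataset, GeneratorTruth]:
    """Generate one bird's full three-phase ontogeny.

    Returns the dataset (records sorted by day and onset, with phase and
    implant-relative day bookkeeping filled in) and the generator truth.
    """
    rng = np.random.default_rng(config.seed)
    n_types = len(config.types)
    cum = np.cumsum(config.transition_matrix, axis=1)
    plm = np.asarray(config.phrase_length_means)

    t1_start = 0
    t1_end = config.t1_days - 1
    tm_start = config.t1_days
    tm_end = tm_start + config.silent_days - 1
    t2_start = tm_end + 1
    t2_end = t2_start + config.t2_days - 1
    lat = config.first_song_latency

    calendar = PhaseCalendar(
        bird_id=bird_id,
        windows={
            Phase.T1_PLUS: PhaseWindow(t1_start, t1_end,
                                       first_song_day=t1_start + lat),
            Phase.T1_MINUS: PhaseWindow(tm_start, tm_end),
            Phase.T2_PLUS: PhaseWindow(t2_start, t2_end,
                                       first_song_day=t2_start + lat),
        },
    )

    sing = [(d, Phase.T1_PLUS, d - t1_start)
            for d in range(t1_start + lat, t1_end + 1)]
    sing += [(d, Phase.T2_PLUS, d - t2_start)
             for d in range(t2_start + lat, t2_end + 1)]

    frames = []
    feat_names = list(config.drifts)
    for day, phase, t in sing:
        nb = int(rng.poisson(config.bouts_per_day))
        if nb == 0:
            continue
        n_phrases = 3 + rng.poisson(max(config.phrases_per_bout_mean - 3.0,
                                        0.0), size=nb)
        total_phr = int(n_phrases.sum())
        u = rng.random(total_phr)
        phr_types = np.empty(total_phr, dtype=np.int64)
        pos = 0
        for b in range(nb):
            state = int(rng.integers(n_types))
            for _ in range(int(n_phrases[b])):
                phr_types[pos] = state
                state = int(np.searchsorted(cum[state], u[pos]))
                pos += 1
        lengths = 1 + rng.poisson(np.maximum(plm[phr_types] - 1.0, 0.0))
        types_idx = np.repeat(phr_types, lengths)
        bout_of_phr = np.repeat(np.arange(nb), n_phrases)
        bout_idx = np.repeat(bout_of_phr, lengths)
        n_syll = types_idx.size

        vals = {}
        for f in feat_names:
            dr = config.drifts[f]
            mean = _phase_means(config, f, phase, float(t))[types_idx]
            day_off = rng.normal(0.0, dr.day_sd)
            vals[f] = rng.normal(mean + day_off, dr.sd)
        d_ms = np.clip(vals["d"], 5.0, None)
        i_ms = np.clip(vals["i"], 1.0, None)
        bw = np.clip(vals["BW"], 0.0, None)
        mf = np.clip(vals["MF"], 100.0, None)
        ent = np.clip(vals["E"], None, -0.01)

        # positions, bout-final pauses, onsets
        is_last = np.r_[bout_idx[1:] != bout_idx[:-1], True]
        new_bout = np.r_[True, bout_idx[1:] != bout_idx[:-1]]
        bout_pos = np.arange(n_syll) - np.maximum.accumulate(
            np.where(new_bout, np.arange(n_syll), 0))
        i_full = i_ms.copy()
        i_ms = np.where(is_last, np.nan, i_ms)
        sr = np.where(is_last, np.nan, 1000.0 / (d_ms + i_full))
        step = d_ms + np.where(is_last, config.bout_gap_ms, i_full)
        onset = np.r_[0.0, np.cumsum(step)[:-1]]

        frames.append(pd.DataFrame({
            "bird_id": bird_id,
            "phase": phase.value,
            "experiment_day": np.int64(day),
            "phase_day": float(day - (calendar.window(phase).first_song_day)),
            "bout_id": pd.array(
                [f"{day:03d}_{b:04d}" for b in bout_idx], dtype=object),
            "bout_position": bout_pos.astype(np.int64),
            "syllable_type": pd.array(
                [config.types[ti] for ti in types_idx], dtype=object),
            "onset_ms": onset,
            "duration_ms": d_ms,
            "pause_ms": i_ms,
            "syllable_rate_hz": sr,
            "fm": vals["FM"],
            "am": vals["AM"],
            "bandwidth_hz": bw,
            "mean_frequency_hz": mf,
            "wiener_entropy": ent,
        }))
    records = pd.concat(frames, ignore_index=True)
    records = records.reindex(columns=list(TABLE_COLUMNS))
    dataset = OntogenyDataset(bird_id=bird_id, calendar=calendar,
                              records=records)
    # fill treatment_day bookkeeping
    from .datamodel import assign_phase_days

    return assign_phase_days(dataset), _truth(config)


def simulate_cohort(
    n_birds: int = 6, seed: int = 0, **config_overrides
) -> tuple[list[OntogenyDataset], GeneratorTruth]:
    """Simulate an independent cohort (bird k uses a child seed of ``seed``)."""
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in
                   ss.spawn(n_birds)]
    datasets = []
    truth = None
    for k, cs in enumerate(child_seeds):
        cfg = default_config(seed=cs, **config_overrides)
        ds, truth = simulate_ontogeny(cfg, bird_id=f"bird{k + 1:02d}")
        datasets.append(ds)
    return datasets, truth


def render_envelope(
    records: pd.DataFrame,
    sample_period_ms: float = 1.0,
    amplitude: float = 1.0,
    noise_floor: float = 0.001,
    tail_ms: float = 200.0,
) -> EnvelopeTrace:
    """Render syllable timings as rectangular pulses over a low floor.

    ``records`` needs ``onset_ms`` and ``duration_ms`` columns (one day's
    bouts).  Overlapping syllables are rejected.
    """
    on = records["onset_ms"].to_numpy(float)
    off = on + records["duration_ms"].to_numpy(float)
    if on.size == 0:  # silent day: flat floor
        n = max(int(np.ceil(tail_ms / sample_period_ms)), 2)
        return EnvelopeTrace(sample_period_ms=sample_period_ms,
                             values=np.full(n, noise_floor))
    order = np.argsort(on)
    on, off = on[order], off[order]
    if (on[1:] < off[:-1]).any():
        raise ValueError("overlapping syllables cannot be rendered")
    n = int(np.ceil((off[-1] + tail_ms) / sample_period_ms)) + 1
    values = np.full(n, noise_floor)
    lo = np.ceil(on / sample_period_ms).astype(int)
    hi = np.ceil(off / sample_period_ms).astype(int)
    for a, b in zip(lo, hi):
        values[a:b] = amplitude
    return EnvelopeTrace(sample_period_ms=sample_period_ms, values=values)


# ---------------------------------------------------------------------------
# synthetic dendrite-segment tables (morphometry fixture)

#: group -> (mean spine density um^-1, lognormal sigma) in HVC.  Sigmas
#: are solved so that, after Poisson spine-counting noise on ~30 um
#: segments, the dense-dendrite (>0.8 um^-1) rate per ROI lands near
#: 0.64 (controls), 0.28 (treated) and 0.33 (withdrawn) at 1.5
#: dendrites per ROI.
_HVC_DENSITY = {"C": (0.95, 0.78), "T1_PLUS": (0.64, 0.20),
                "T1_MINUS": (0.69, 0.05)}
_RA_DENSITY = (0.80, 0.35)


def simulate_spine_segments(
    seed: int = 0,
    birds_per_group: dict[str, int] | None = None,
    rois: dict[str, int] | None = None,
    dendrites_per_roi: float = 1.5,
) -> pd.DataFrame:
    """Synthetic dendrite-segment table (synthetic stand-in for traced data).

    Per bird and region, ``rois`` regions of interest each contain a
    Poisson number of spinous dendrite segments whose spine densities are
    lognormal with group-specific parameters; HVC groups differ (a
    singing-related pruning shifts treated groups toward sparse spines)
    while RA groups do not.  Columns: bird_id, group, region, roi_id,
    length_um, spine_count.
    """
    rng = np.random.default_rng(seed)
    birds_per_group = birds_per_group or {"C": 6, "T1_PLUS": 8, "T1_MINUS": 6}
    rois = rois or {"HVC": 15, "RA": 10}
    rows = []
    for group, n_birds in birds_per_group.items():
        for b in range(n_birds):
            bird = f"{group}_{b + 1:02d}"
            bird_factor = rng.lognormal(0.0, 0.08)
            for region, n_rois in rois.items():
                mean, sigma = (_HVC_DENSITY[group] if region == "HVC"
                               else _RA_DENSITY)
                mu = np.log(mean * bird_factor) - sigma ** 2 / 2.0
                for r in range(n_rois):
                    roi = f"{bird}_{region}_{r + 1:02d}"
                    for _ in range(int(rng.poisson(dendrites_per_roi))):
                        dens = rng.lognormal(mu, sigma)
                        length = float(np.clip(rng.normal(30.0, 8.0), 10.0,
                                               None))
                        count = int(rng.poisson(dens * length))
                        rows.append((bird, group, region, roi, length, count))
    return pd.DataFrame(rows, columns=["bird_id", "group", "region", "roi_id",
                                       "length_um", "spine_count"])
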