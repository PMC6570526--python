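"""Shared fixtures: scaled-down simulated ontogenies for fast unit tests."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from songdev.datamodel import Phase, PhaseCalendar, PhaseWindow
from songdev.simulate import (GeneratorConfig, _default_drifts,
                              default_config, simulate_ontogeny)


def small_config(seed: int = 0, savings_factor: float = 5.0,
                 **kw) -> GeneratorConfig:
    """A short ontogeny (~20k syllables) with proportionally faster drift."""
    drifts = {f: replace(dr, inflection_day=dr.inflection_day * 0.35,
                         scale_days=dr.scale_days * 0.35)
              for f, dr in _default_drifts().items()}
    kw.setdefault("t1_days", 80)
    kw.setdefault("silent_days", 10)
    kw.setdefault("t2_days", 25)
    kw.setdefault("bouts_per_day", 8.0)
    return default_config(seed=seed, savings_factor=savings_factor,
                          drifts=drifts, **kw)


@pytest.fixture(scope="session")
def small_bird():
    """One scaled-down simulated ontogeny plus its generator truth."""
    return simulate_ontogeny(small_config(seed=7))


@pytest.fixture(scope="session")
def small_records(small_bird):
    return small_bird[0].records


def make_calendar(bird="b1", t1=(0, 199, 3), tm=(200, 274), t2=(275, 309, 278)):
    """Convenience three-phase calendar."""
    return PhaseCalendar(bird_id=bird, windows={
        Phase.T1_PLUS: PhaseWindow(t1[0], t1[1], first_song_day=t1[2]),
        Phase.T1_MINUS: PhaseWindow(tm[0], tm[1]),
        Phase.T2_PLUS: PhaseWindow(t2[0], t2[1], first_song_day=t2[2]),
    })


def make_records(rows, bird="b1"):
    """Minimal record frame from (phase, day, bout, pos, type, d, i) tuples."""
    recs = []
    for phase, day, bout, pos, styp, d, i in rows:
        sr = 1000.0 / (d + i) if np.isfinite(i) else np.nan
        recs.append(dict(bird_id=bird, phase=phase, experiment_day=day,
                         phase_day=np.nan, bout_id=bout, bout_position=pos,
                         syllable_type=styp, onset_ms=float(pos) * 100.0,
                         duration_ms=d, pause_ms=i, syllable_rate_hz=sr,
                         fm=1.0, am=1.0, bandwidth_hz=1000.0,
                         mean_frequency_hz=3000.0, wiener_entropy=-1.0))
    return pd.DataFrame(recs)
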