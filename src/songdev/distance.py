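"""Median-normalized Euclidean distance between syllables.

Every syllable is a point in an 8-dimensional acoustic space with
coordinates (SR, d, i, FM, AM, BW, MF, E).  To give the features equal
weight, each coordinate is divided by its global median over all
syllables of the whole cohort.  The Euclidean distance between two
normalized syllables then measures their dissimilarity; three summaries
characterize how well syllable identities are conserved across the two
treatments:

* ``T1xT1`` — distances among same-type syllables within the first
  treatment's stable song (baseline within-type variation);
* ``T1xT2`` — distances between same-type syllables across the two
  treatments (conservation of the type);
* ``T1xT2_ext`` — distances between first-treatment syllables and
  *other*-type second-treatment syllables (between-type separation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .datamodel import FEATURES, OntogenyDataset, Phase, UNTYPED

__all__ = [
    "COORDINATES",
    "DistanceSummary",
    "median_normalize",
    "euclidean_distance",
    "stable_window_records",
    "transitional_types",
    "distance_summaries",
    "cohort_distance_table",
]

#: coordinate order of the 8-D syllable feature space
COORDINATES = ("SR", "d", "i", "FM", "AM", "BW", "MF", "E")
_COORD_COLUMNS = [FEATURES[c] for c in COORDINATES]


@dataclass(frozen=True)
class DistanceSummary:
    """Mean pairwise distance for one comparison category."""

    category: str  # T1xT1 | T1xT2 | T1xT2_ext
    mean_distance: float
    sem: float
    n_pairs: int
    seed: int


def median_normalize(
    cohort: list[pd.DataFrame] | pd.DataFrame,
) -> tuple[pd.Series, list[pd.DataFrame]]:
    """Divide each coordinate by its global cohort median.

    ``cohort`` is one frame or a list of per-bird frames of syllable
    records; the medians are taken over *all* syllables of all birds
    (rows missing any coordinate are ignored for the medians and dropped
    from the normalized output, since a distance over a partial vector is
    meaningless).  Returns (medians, normalized frames).
    """
    frames = [cohort] if isinstance(cohort, pd.DataFrame) else list(cohort)
    pooled = pd.concat([f[_COORD_COLUMNS] for f in frames], ignore_index=True)
    pooled = pooled.dropna()
    if len(pooled) == 0:
        raise ValueError("no syllable has all 8 coordinates")
    medians = pooled.median()
    zero = medians.index[medians == 0]
    if len(zero):
        raise ValueError(f"zero global median for feature(s): {list(zero)}")
    out = []
    for f in frames:
        g = f.dropna(subset=_COORD_COLUMNS).copy()
        g[_COORD_COLUMNS] = g[_COORD_COLUMNS] / medians
        out.append(g)
    return medians, out


def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Plain Euclidean distance over the 8 normalized coordinates."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coordinate vectors must have equal shape")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("coordinates must be finite (incomplete syllables "
                         "are excluded upstream)")
    return float(np.sqrt(((b - a) ** 2).sum()))


def stable_window_records(
    dataset: OntogenyDataset, phase: Phase, window: int = 7
) -> pd.DataFrame:
    """Syllables from the last ``window`` singing days of a treatment."""
    days = dataset.singing_days(phase)
    if days.size == 0:
        return dataset.records.iloc[0:0]
    keep = days[-window:]
    rec = dataset.records
    return rec[(rec["phase"] == Phase(phase).value)
               & rec["experiment_day"].isin(keep)]


def transitional_types(records: pd.DataFrame) -> set[str]:
    """Types behaving as single transitional syllables between phrases.

    A type is transitional when its modal phrase length is 1 and its
    tokens occur between two distinct phrases (i.e. mid-bout, flanked by
    other types).  Such types are excluded from the distance analysis.
    """
    out = set()
    rec = records.sort_values(["bout_id", "bout_position"])
    for styp, grp in rec.groupby("syllable_type"):
        if styp == UNTYPED:
            continue
        # phrase lengths: run lengths of this type within each bout
        lengths = []
        flanked = []
        for _, bout in rec.groupby("bout_id", sort=False):
            types = bout["syllable_type"].to_numpy()
            n = len(types)
            k = 0
            while k < n:
                if types[k] != styp:
                    k += 1
                    continue
                j = k
                while j + 1 < n and types[j + 1] == styp:
                    j += 1
                lengths.append(j - k + 1)
                flanked.append(k > 0 and j < n - 1)
                k = j + 1
        if not lengths:
            continue
        vals, counts = np.unique(lengths, return_counts=True)
        if vals[np.argmax(counts)] == 1 and any(flanked):
            out.add(str(styp))
    return out


def _sample(df: pd.DataFrame, n: int, rng: np.random.Generator) -> np.ndarray:
    mat = df[_COORD_COLUMNS].to_numpy(float)
    if len(mat) > n:
        mat = mat[rng.choice(len(mat), size=n, replace=False)]
    return mat


def distance_summaries(
    dataset: OntogenyDataset,
    medians: pd.Series,
    n_per_type: int = 100,
    seed: int = 0,
    window: int = 7,
    exclude_types: set[str] | None = None,
) -> dict[str, DistanceSummary]:
    """Per-bird mean distances for T1xT1, T1xT2 and T1xT2_ext.

    For every syllable type, ``n_per_type`` syllables are sampled (without
    replacement, seeded) from the stable windows of each treatment.
    ``T1xT1`` averages all distinct pairs within the first-treatment
    sample, ``T1xT2`` all cross pairs of the same type, and ``T1xT2_ext``
    all pairs of the first-treatment sample with samples of every *other*
    type from the second treatment.  Types with fewer tokens contribute
    what they have; transitional types are excluded automatically unless
    an explicit ``exclude_types`` set is given.
    """
    rng = np.random.default_rng(seed)
    t1 = stable_window_records(dataset, Phase.T1_PLUS, window)
    t2 = stable_window_records(dataset, Phase.T2_PLUS, window)
    excl = (transitional_types(dataset.records)
            if exclude_types is None else set(exclude_types))

    t1 = t1.dropna(subset=_COORD_COLUMNS).copy()
    t2 = t2.dropna(subset=_COORD_COLUMNS).copy()
    t1[_COORD_COLUMNS] = t1[_COORD_COLUMNS] / medians
    t2[_COORD_COLUMNS] = t2[_COORD_COLUMNS] / medians

    types = sorted(
        (set(t1["syllable_type"]) & set(t2["syllable_type"])) - excl - {UNTYPED}
    )
    if not types:
        raise ValueError("no typed syllables shared by both stable windows")
    samples1 = {}
    samples2 = {}
    for styp in types:
        samples1[styp] = _sample(t1[t1["syllable_type"] == styp], n_per_type,
                                 rng)
        samples2[styp] = _sample(t2[t2["syllable_type"] == styp], n_per_type,
                                 rng)

    within, cross, ext = [], [], []
    n_within = n_cross = n_ext = 0
    for styp in types:
        s1, s2 = samples1[styp], samples2[styp]
        if len(s1) >= 2:
            d11 = cdist(s1, s1)
            iu = np.triu_indices(len(s1), k=1)
            within.append(d11[iu].mean())
            n_within += iu[0].size
        d12 = cdist(s1, s2)
        cross.append(d12.mean())
        n_cross += d12.size
        others = [samples2[o] for o in types if o != styp]
        if others:
            d1x = cdist(s1, np.vstack(others))
            ext.append(d1x.mean())
            n_ext += d1x.size

    def _summ(cat, vals, n_pairs):
        vals = np.asarray(vals, dtype=float)
        if vals.size == 0:
            return DistanceSummary(cat, float("nan"), float("nan"), 0, seed)
        sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) \
            if vals.size > 1 else float("nan")
        return DistanceSummary(cat, float(vals.mean()), sem, int(n_pairs), seed)

    return {
        "T1xT1": _summ("T1xT1", within, n_within),
        "T1xT2": _summ("T1xT2", cross, n_cross),
        "T1xT2_ext": _summ("T1xT2_ext", ext, n_ext),
    }


def cohort_distance_table(
    datasets: list[OntogenyDataset],
    n_per_type: int = 100,
    seed: int = 0,
    window: int = 7,
) -> pd.DataFrame:
    """Per-bird distance summaries on shared cohort medians, as tidy rows."""
    medians, _ = median_normalize([d.records for d in datasets])
    rows = []
    for k, ds in enumerate(datasets):
        sums = distance_summaries(ds, medians, n_per_type=n_per_type,
                                  seed=seed + k, window=window)
        for cat, s in sums.items():
            rows.append((ds.bird_id, cat, s.mean_distance, s.sem, s.n_pairs,
                         s.seed))
    return pd.DataFrame(
        rows, columns=["bird", "category", "mean_distance", "sem", "n_pairs",
                       "seed"])
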