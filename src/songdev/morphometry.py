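"""Dendritic spine-density summaries from dendrite-segment tables.

Input rows are traced spinous dendrite segments (bird, experimental
group, brain region, region-of-interest id, traced length in µm, visible
spine count).  Spine density is spines per µm of dendrite.  Two
summaries are produced: group mean densities (bird means first — the
animal is the unit of analysis — with a segment-pooled variant), and a
binned distribution of dendrites-per-ROI by density class (0.2 µm⁻¹
bins, final bin open above 1.8).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "BIN_EDGES",
    "spine_density",
    "add_densities",
    "group_mean_density",
    "density_distribution",
    "dense_dendrites_per_roi",
]

#: left-closed/right-open density bin edges; the final bin is open above
BIN_EDGES = np.arange(0.0, 2.0, 0.2)  # 0, 0.2, ..., 1.8

REQUIRED = ("bird_id", "group", "region", "roi_id", "length_um",
            "spine_count")


def spine_density(length_um: float, spine_count: int) -> float:
    """Visible spines per µm of traced dendrite."""
    if length_um <= 0:
        raise ValueError("traced length must be > 0")
    if spine_count < 0:
        raise ValueError("spine count must be >= 0")
    return spine_count / length_um


def _check(segments: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED if c not in segments.columns]
    if missing:
        raise ValueError(f"segment table misses column(s): {missing}")
    if (segments["length_um"] <= 0).any():
        raise ValueError("non-positive traced length")
    if (segments["spine_count"] < 0).any():
        raise ValueError("negative spine count")
    return segments


def add_densities(segments: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with a ``density`` column (spines/µm per segment)."""
    segments = _check(segments).copy()
    segments["density"] = segments["spine_count"] / segments["length_um"]
    return segments


def group_mean_density(
    segments: pd.DataFrame, region: str | None = None, unit: str = "bird"
) -> pd.DataFrame:
    """Mean spine density per group.

    ``unit="bird"`` (default) averages segments within each bird first and
    then birds within the group, so every animal carries equal weight;
    ``unit="segment"`` pools all segments of a group directly.  Returns
    columns group, mean_density, sem, n.
    """
    df = add_densities(segments)
    if region is not None:
        df = df[df["region"] == region]
    if unit == "bird":
        per_bird = df.groupby(["group", "bird_id"])["density"].mean()
        g = per_bird.groupby("group")
    elif unit == "segment":
        g = df.groupby("group")["density"]
    else:
        raise ValueError("unit must be 'bird' or 'segment'")
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "mean_density", "count": "n"})


def density_distribution(
    segments: pd.DataFrame, n_rois: int
) -> pd.DataFrame:
    """Dendrites-per-ROI and probabilities by spine-density bin.

    Segments are binned into density classes [0,0.2), [0.2,0.4), ...,
    [1.6,1.8) with a final open bin for densities >= 1.8.  Each bin's
    dendrites-per-ROI is its segment count divided by ``n_rois``;
    probabilities normalize the bins to sum 1.
    """
    if n_rois <= 0:
        raise ValueError("n_rois must be > 0")
    df = add_densities(segments)
    idx = np.minimum(
        np.floor(df["density"].to_numpy() / 0.2).astype(int),
        len(BIN_EDGES) - 1,
    )
    counts = np.bincount(idx, minlength=len(BIN_EDGES)).astype(float)
    per_roi = counts / n_rois
    total = counts.sum()
    probs = counts / total if total > 0 else counts
    labels = [f"[{lo:.1f},{lo + 0.2:.1f})" for lo in BIN_EDGES[:-1]]
    labels.append(f">={BIN_EDGES[-1]:.1f}")
    return pd.DataFrame({
        "bin_low": BIN_EDGES,
        "bin_label": labels,
        "n_segments": counts.astype(int),
        "dendrites_per_roi": per_roi,
        "probability": probs,
    })


def dense_dendrites_per_roi(
    segments: pd.DataFrame, n_rois: int, threshold: float = 0.8
) -> float:
    """Dendrites-per-ROI with density above ``threshold`` (bin aggregate)."""
    dist = density_distribution(segments, n_rois)
    return float(
        dist.loc[dist["bin_low"] >= threshold, "dendrites_per_roi"].sum())
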