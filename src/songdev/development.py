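"""Similarity-trajectory analysis of song development.

The core quantification of vocal skill acquisition works on *distribution
patterns*: for each acoustic feature, syllable values are binned into a
daily histogram, and each day's histogram is correlated (Pearson CC)
against a reference pattern averaged over the 7 last singing days of the
first treatment — crystallized song.  The resulting CC-versus-day
trajectory is summarized by a four-parameter logistic

    F(x) = a + b / (1 + exp((c - x) / d))

where ``a`` is the baseline similarity, ``b`` the developmental rise,
``c`` the inflection day and ``d`` the slope scale in days.  From the fit
two statistics are derived:

* the **stabilization day** — the first (integer) day on which the fitted
  day-to-day increase ``F(x+1) - F(x)`` drops below ``epsilon``
  (0.001/day), reported relative to implantation;
* **d_max** — the maximum day-to-day increase of the fitted curve, an
  acquisition-speed measure.

Feature **deterioration** across the silent gap is the mean CC over the
last 7 singing days of the first treatment minus the mean CC over the
first 2 singing days of the second; **recovery** is the symmetric gain
within the second treatment.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .datamodel import FEATURES, OntogenyDataset, Phase, PhaseCalendar

__all__ = [
    "DEFAULT_BIN_WIDTHS",
    "DailyHistogram",
    "SimilarityTrajectory",
    "DevelopmentFit",
    "ModeTrack",
    "CrossTreatmentCC",
    "FeatureReport",
    "logistic",
    "daily_histograms",
    "reference_pattern",
    "pearson_cc",
    "cc_trajectory",
    "fit_development_curve",
    "stabilization_day",
    "dmax",
    "modal_rate_trajectories",
    "deterioration",
    "recovery",
    "cross_treatment_similarity",
    "feature_development_report",
]

#: per-feature histogram bin widths, in the feature's units.  1 Hz / 1 ms
#: match the discreteness of rate/duration histograms; bandwidth and mean
#: frequency use 50 Hz (1 Hz would be pathologically sparse); Wiener
#: entropy uses 0.1 on its log scale.
DEFAULT_BIN_WIDTHS: dict[str, float] = {
    "SR": 1.0, "d": 1.0, "i": 1.0, "FM": 1.0,
    "AM": 1.0, "BW": 50.0, "MF": 50.0, "E": 0.1,
}


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (symmetric for E<0)."""
    return np.copysign(np.floor(np.abs(x) + 0.5), x)


@dataclass(frozen=True)
class DailyHistogram:
    """Integer-binned distribution of one feature on one day.

    ``support`` is the inclusive (lo, hi) bin-index range shared by every
    day of a bird x feature trajectory, so all daily count vectors are
    directly comparable.  ``day=None`` marks an averaged reference pattern.
    """

    feature: str
    day: int | None
    bin_width: float
    support: tuple[int, int]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self):
        lo, hi = self.support
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (hi - lo + 1,):
            raise ValueError("counts length does not match support")
        object.__setattr__(self, "counts", counts)

    @property
    def empty(self) -> bool:
        return not np.any(self.counts > 0)

    @property
    def frequencies(self) -> np.ndarray:
        total = self.counts.sum()
        return self.counts / total if total > 0 else self.counts.copy()

    @property
    def bin_values(self) -> np.ndarray:
        """Feature value at each bin center."""
        lo, hi = self.support
        return np.arange(lo, hi + 1) * self.bin_width


@dataclass(frozen=True)
class SimilarityTrajectory:
    """Per-day CC of daily histograms against a reference pattern."""

    feature: str
    days: np.ndarray
    cc: np.ndarray
    reference_days: tuple[int, ...]

    def __post_init__(self):
        days = np.asarray(self.days, dtype=int)
        cc = np.asarray(self.cc, dtype=float)
        if days.shape != cc.shape:
            raise ValueError("days and cc must align")
        if (np.diff(days) <= 0).any():
            raise ValueError("days must be strictly increasing")
        ok = np.isfinite(cc)
        if ok.any() and ((cc[ok] < -1 - 1e-9) | (cc[ok] > 1 + 1e-9)).any():
            raise ValueError("CC outside [-1, 1]")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "cc", cc)

    def window_mean(self, days: np.ndarray) -> float:
        mask = np.isin(self.days, days)
        vals = self.cc[mask]
        vals = vals[np.isfinite(vals)]
        return float(vals.mean()) if vals.size else float("nan")


@dataclass(frozen=True)
class DevelopmentFit:
    """Logistic fit of a similarity trajectory (x in implant-relative days)."""

    a: float
    b: float
    c: float
    d_scale: float
    rss: float
    has_developmental_increase: bool
    converged: bool
    n_points: int
    day_range: tuple[float, float]

    def __call__(self, x):
        return logistic(x, self.a, self.b, self.c, self.d_scale)


@dataclass(frozen=True)
class ModeTrack:
    """A persistent histogram mode followed across days."""

    days: np.ndarray
    rates: np.ndarray
    fit: DevelopmentFit | None
    crystallized_rate: float


@dataclass(frozen=True)
class CrossTreatmentCC:
    """Similarity of stable distribution patterns across the two treatments.

    ``cc_t1xt2`` correlates the 7-day averaged stable patterns of the two
    treatments; ``cc_t1xt1`` is the within-treatment baseline (mean CC of
    the 6 consecutive-day pairs inside the first treatment's stable week).
    ``cc_t1xt2_daywise`` is the variant averaging all 49 daywise CCs.
    """

    feature: str
    cc_t1xt2: float
    cc_t1xt1: float
    cc_t1xt2_daywise: float


def logistic(x, a, b, c, d):
    z = np.clip((c - np.asarray(x, dtype=float)) / d, -500.0, 500.0)
    return a + b / (1.0 + np.exp(z))


# ---------------------------------------------------------------------------
# histograms and CC

def _feature_column(feature: str) -> str:
    return FEATURES.get(feature, feature)


def daily_histograms(
    records: pd.DataFrame,
    feature: str,
    bin_width: float | None = None,
    support: tuple[int, int] | None = None,
    days: np.ndarray | None = None,
    day_column: str = "experiment_day",
) -> dict[int, DailyHistogram]:
    """One integer-binned histogram per day over a shared support.

    Values are scaled by ``1/bin_width`` and rounded to the nearest integer
    (halves away from zero).  The support defaults to the global observed
    bin range of ``records`` so every day shares one bin vector.  ``days``
    may request specific days; days without records yield all-zero
    histograms (flagged via :attr:`DailyHistogram.empty`).
    """
    col = _feature_column(feature)
    if bin_width is None:
        bin_width = DEFAULT_BIN_WIDTHS.get(feature, 1.0)
    sub = records[[day_column, col]].dropna()
    vals = sub[col].to_numpy(float)
    bins = _round_half_away(vals / bin_width).astype(np.int64)
    rec_days = sub[day_column].to_numpy()
    rec_days = np.asarray(rec_days, dtype=np.int64)
    if support is None:
        if bins.size == 0:
            raise ValueError(f"no values for feature {feature!r}")
        support = (int(bins.min()), int(bins.max()))
    lo, hi = support
    nbins = hi - lo + 1
    inside = (bins >= lo) & (bins <= hi)
    bins, rec_days = bins[inside], rec_days[inside]
    if days is None:
        days = np.unique(rec_days)
    days = np.asarray(days, dtype=np.int64)
    day_index = {int(d): k for k, d in enumerate(days)}
    table = np.zeros((len(days), nbins))
    keep = np.isin(rec_days, days)
    rows = np.fromiter((day_index[int(d)] for d in rec_days[keep]),
                       dtype=np.int64, count=int(keep.sum()))
    np.add.at(table, (rows, bins[keep] - lo), 1.0)
    return {
        int(d): DailyHistogram(feature=feature, day=int(d), bin_width=bin_width,
                               support=support, counts=table[k])
        for k, d in enumerate(days)
    }


def reference_pattern(
    histograms: list[DailyHistogram], expected_days: int = 7
) -> DailyHistogram:
    """Average the daily *frequencies* of a stable window into a reference.

    Frequencies (not raw counts) are averaged so days with high song output
    do not dominate; the mean is renormalized to sum 1.  Exactly
    ``expected_days`` histograms are required — with fewer singing days
    available, pass a shorter window explicitly via ``expected_days``.
    """
    if len(histograms) != expected_days:
        raise ValueError(
            f"reference window needs exactly {expected_days} day-histograms, "
            f"got {len(histograms)}; configure a shorter window "
            "(expected_days) if fewer stable singing days are available"
        )
    first = histograms[0]
    for h in histograms[1:]:
        if h.feature != first.feature or h.support != first.support:
            raise ValueError("reference histograms must share feature and support")
    freq = np.mean([h.frequencies for h in histograms], axis=0)
    total = freq.sum()
    if total > 0:
        freq = freq / total
    return DailyHistogram(feature=first.feature, day=None,
                          bin_width=first.bin_width, support=first.support,
                          counts=freq)


def pearson_cc(h1: DailyHistogram, h2: DailyHistogram) -> float:
    """Pearson correlation of two histograms over their shared bin vector.

    1 is an absolute copy of the pattern, -1 its absolute inverse.  The CC
    is invariant to positive affine rescaling, so counts and frequencies
    give identical values.  A zero-variance vector makes the CC undefined
    (NaN), never 0.
    """
    if h1.support != h2.support:
        raise ValueError("histograms must share a support")
    x = h1.counts
    y = h2.counts
    xc = x - x.mean()
    yc = y - y.mean()
    nx = np.sqrt((xc * xc).sum())
    ny = np.sqrt((yc * yc).sum())
    if nx == 0.0 or ny == 0.0:
        return float("nan")
    return float(np.clip((xc * yc).sum() / (nx * ny), -1.0, 1.0))


def cc_trajectory(
    histograms: dict[int, DailyHistogram],
    reference: DailyHistogram,
    reference_days: tuple[int, ...] = (),
    leave_one_out: bool = True,
) -> SimilarityTrajectory:
    """CC of every (non-empty) daily histogram against the reference.

    Days whose CC is undefined (zero variance) are omitted from the
    trajectory rather than reported as 0.  A day that itself belongs to
    the reference window shares its sampling noise with the averaged
    reference, which would bias its CC (and hence deterioration of
    perfectly stable features) upward; with ``leave_one_out`` (default)
    such days are correlated against a reference averaged over the other
    window days instead.
    """
    ref_set = set(int(d) for d in reference_days)
    days, ccs = [], []
    for day in sorted(histograms):
        h = histograms[day]
        if h.empty:
            continue
        if leave_one_out and day in ref_set and len(ref_set) > 1:
            others = [histograms[d] for d in sorted(ref_set) if d != day]
            ref = reference_pattern(others, expected_days=len(others))
        else:
            ref = reference
        cc = pearson_cc(h, ref)
        if math.isnan(cc):
            continue
        days.append(day)
        ccs.append(cc)
    return SimilarityTrajectory(
        feature=reference.feature, days=np.array(days, dtype=int),
        cc=np.array(ccs), reference_days=tuple(int(d) for d in reference_days),
    )


# ---------------------------------------------------------------------------
# logistic fitting and derived statistics

def fit_development_curve(
    days: np.ndarray,
    cc: np.ndarray,
    b_threshold: float = 0.05,
    rss_improvement: float = 0.2,
    d_scale_starts: tuple[float, ...] = (5.0, 15.0, 40.0),
) -> DevelopmentFit:
    """Multi-start least-squares fit of the 4-parameter logistic.

    A trajectory counts as showing a developmental increase when the
    fitted rise ``b`` exceeds ``b_threshold`` *and* the logistic reduces
    the residual sum of squares by at least ``rss_improvement`` relative
    to the best constant model; flat or decreasing trajectories are fitted
    but flagged.  Raises on fewer than 8 points.
    """
    x = np.asarray(days, dtype=float)
    y = np.asarray(cc, dtype=float)
    ok = np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 8:
        raise ValueError(f"logistic fit needs >= 8 points, got {x.size}")

    rng_y = float(y.max() - y.min())
    # day of steepest observed rise (midpoint of the steepest segment)
    dx = np.diff(x)
    slopes = np.diff(y) / np.where(dx > 0, dx, 1.0)
    c_rise = float(0.5 * (x[np.argmax(slopes)] + x[np.argmax(slopes) + 1]))
    c_fall = float(0.5 * (x[np.argmin(slopes)] + x[np.argmin(slopes) + 1]))

    def resid(p):
        return logistic(x, *p) - y

    lower = np.array([-np.inf, -np.inf, -np.inf, 0.1])
    upper = np.array([np.inf, np.inf, np.inf, np.inf])
    best = None
    for d0 in d_scale_starts:
        for a0, b0, c0 in ((y.min(), max(rng_y, 0.01), c_rise),
                           (y.max(), -max(rng_y, 0.01), c_fall)):
            p0 = np.array([a0, b0, c0, d0])
            try:
                sol = least_squares(resid, p0, bounds=(lower, upper),
                                    xtol=1e-13, ftol=1e-13, gtol=1e-13,
                                    max_nfev=2000)
            except Exception:  # pragma: no cover - optimizer pathologies
                continue
            rss = float(2.0 * sol.cost)
            if best is None or rss < best[0]:
                best = (rss, sol)
    if best is None:
        return DevelopmentFit(a=float("nan"), b=float("nan"), c=float("nan"),
                              d_scale=float("nan"), rss=float("inf"),
                              has_developmental_increase=False, converged=False,
                              n_points=int(x.size),
                              day_range=(float(x.min()), float(x.max())))
    rss, sol = best
    a, b, c, d_scale = (float(v) for v in sol.x)
    rss_const = float(((y - y.mean()) ** 2).sum())
    has_increase = (
        b > b_threshold
        and rss_const > 0
        and rss <= (1.0 - rss_improvement) * rss_const
    )
    return DevelopmentFit(a=a, b=b, c=c, d_scale=d_scale, rss=rss,
                          has_developmental_increase=bool(has_increase),
                          converged=bool(sol.success), n_points=int(x.size),
                          day_range=(float(x.min()), float(x.max())))


def _daily_increase(fit: DevelopmentFit, x: np.ndarray) -> np.ndarray:
    return fit(x + 1.0) - fit(x)


def stabilization_day(
    fit: DevelopmentFit, epsilon: float = 0.001, max_day: int = 100_000
) -> float:
    """Smallest integer day x >= c with F(x+1) - F(x) < epsilon.

    The day axis of the fit is implant-relative, so the result is the
    duration from implantation to feature stabilization.  Undefined (NaN)
    when the fit shows no rise (b <= 0).
    """
    if not np.isfinite(fit.b) or fit.b <= 0:
        return float("nan")
    x0 = max(int(math.ceil(fit.c)), 0)
    # analytic warm start: F'(x)=eps at p(1-p)=eps*d/b (p the sigmoid value)
    q = epsilon * fit.d_scale / fit.b
    if q < 0.25:
        p = 0.5 * (1.0 + math.sqrt(1.0 - 4.0 * q))
        x0 = max(x0, int(fit.c + fit.d_scale * math.log(p / (1.0 - p))) - 3)
    x = x0
    while x <= max_day:
        if _daily_increase(fit, np.array([x], dtype=float))[0] < epsilon:
            return float(x)
        x += 1
    return float("nan")


def dmax(
    fit: DevelopmentFit, day_range: tuple[float, float] | None = None
) -> float:
    """Maximum day-to-day increase F(x+1) - F(x) over integer days.

    Undefined for trajectories without a developmental increase (flat or
    decreasing similarity carries no acquisition speed).
    """
    if not fit.has_developmental_increase:
        return float("nan")
    lo, hi = day_range if day_range is not None else fit.day_range
    days = np.arange(math.floor(lo), math.ceil(hi) + 1, dtype=float)
    if days.size == 0:
        return float("nan")
    return float(_daily_increase(fit, days).max())


# ---------------------------------------------------------------------------
# modal syllable-rate tracking

def _day_peaks(
    hist: DailyHistogram, smooth: int, prominence_frac: float
) -> list[float]:
    counts = hist.counts
    if counts.sum() == 0:
        return []
    # triangular weights: a flat boxcar would turn a single-bin spike
    # (a very precise rate class) into a 3-bin plateau with no strict
    # local maximum
    if smooth == 3:
        kernel = np.array([0.25, 0.5, 0.25])
    else:
        kernel = np.ones(smooth) / smooth
    s = np.convolve(counts, kernel, mode="same")
    sp = np.r_[0.0, s, 0.0]  # support edges can carry modes
    peaks = []
    floor = prominence_frac * s.max()
    for k in range(s.size):
        if sp[k + 1] > sp[k] and sp[k + 1] > sp[k + 2] and sp[k + 1] >= floor:
            denom = sp[k] - 2.0 * sp[k + 1] + sp[k + 2]
            delta = 0.5 * (sp[k] - sp[k + 2]) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
            peaks.append((hist.support[0] + k + delta) * hist.bin_width)
    return peaks


def modal_rate_trajectories(
    histograms: dict[int, DailyHistogram],
    smooth: int = 3,
    prominence_frac: float = 0.05,
    max_jump: float = 3.0,
    max_tracks: int = 3,
    min_days: int = 10,
) -> list[ModeTrack]:
    """Follow syllable-rate histogram modes across days and fit each track.

    Each day's smoothed histogram (moving average over ``smooth`` bins)
    contributes its strict local maxima with height at least
    ``prominence_frac`` of the day's tallest bin; peak positions are
    refined by parabolic interpolation.  Peaks are linked across days by
    nearest-rate continuity (jumps larger than ``max_jump`` Hz/day start a
    new track); the ``max_tracks`` longest tracks are kept, each
    summarized by a logistic fit whose asymptote ``a+b`` is the
    crystallized rate (falling back to the mean of the last 7 tracked
    days when the fit is unusable).  Tracks are returned fastest-first.
    """
    days_with_song = [d for d in sorted(histograms) if not histograms[d].empty]
    if len(days_with_song) < min_days:
        raise ValueError(
            f"mode tracking needs >= {min_days} days of song, "
            f"got {len(days_with_song)}"
        )
    tracks: list[dict] = []
    for day in days_with_song:
        peaks = _day_peaks(histograms[day], smooth, prominence_frac)
        if not peaks:
            continue
        # greedy nearest-rate matching, one peak per track per day
        pairs = sorted(
            (abs(p - t["rates"][-1]), pi, ti)
            for pi, p in enumerate(peaks)
            for ti, t in enumerate(tracks)
        )
        used_p: set[int] = set()
        used_t: set[int] = set()
        for dist, pi, ti in pairs:
            if dist > max_jump or pi in used_p or ti in used_t:
                continue
            tracks[ti]["days"].append(day)
            tracks[ti]["rates"].append(peaks[pi])
            used_p.add(pi)
            used_t.add(ti)
        for pi, p in enumerate(peaks):
            if pi not in used_p:
                tracks.append({"days": [day], "rates": [p]})
    tracks.sort(key=lambda t: len(t["days"]), reverse=True)
    if len(tracks) > max_tracks:
        warnings.warn(
            f"{len(tracks)} mode tracks found; keeping the {max_tracks} longest",
            stacklevel=2,
        )
        tracks = tracks[:max_tracks]

    out = []
    for t in tracks:
        days = np.array(t["days"], dtype=int)
        rates = np.array(t["rates"])
        fit = None
        crystallized = float(np.mean(rates[-7:]))
        if days.size >= 8:
            try:
                fit = fit_development_curve(days, rates)
            except ValueError:
                fit = None
            if fit is not None and fit.converged:
                asym = fit.a + fit.b
                if rates.min() - 5.0 <= asym <= rates.max() + 5.0:
                    crystallized = float(asym)
        out.append(ModeTrack(days=days, rates=rates, fit=fit,
                             crystallized_rate=crystallized))
    out.sort(key=lambda m: m.crystallized_rate, reverse=True)
    return out


# ---------------------------------------------------------------------------
# deterioration, recovery, cross-treatment similarity

def _phase_days(
    traj: SimilarityTrajectory, calendar: PhaseCalendar, phase: Phase
) -> np.ndarray:
    w = calendar.window(phase)
    return traj.days[(traj.days >= w.start_day) & (traj.days <= w.end_day)]


def deterioration(
    traj: SimilarityTrajectory,
    calendar: PhaseCalendar,
    stable_window: int = 7,
    early_window: int = 2,
) -> float:
    """CC loss across the silent gap.

    Mean CC over the last ``stable_window`` singing days of the first
    treatment minus mean CC over the first ``early_window`` singing days
    of the second.  NaN when either window has no song.
    """
    t1 = _phase_days(traj, calendar, Phase.T1_PLUS)
    t2 = _phase_days(traj, calendar, Phase.T2_PLUS)
    if t1.size < stable_window or t2.size < early_window:
        return float("nan")
    return traj.window_mean(t1[-stable_window:]) - traj.window_mean(
        t2[:early_window])


def recovery(
    traj: SimilarityTrajectory,
    calendar: PhaseCalendar,
    stable_window: int = 7,
    early_window: int = 2,
) -> float:
    """CC regained within the second treatment (last 7 minus first 2 days)."""
    t2 = _phase_days(traj, calendar, Phase.T2_PLUS)
    if t2.size < max(stable_window, early_window):
        return float("nan")
    return traj.window_mean(t2[-stable_window:]) - traj.window_mean(
        t2[:early_window])


def cross_treatment_similarity(
    dataset: OntogenyDataset,
    feature: str,
    bin_width: float | None = None,
    window: int = 7,
) -> CrossTreatmentCC:
    """Similarity of stable patterns between the two treatments.

    The 7-day averaged stable patterns (last ``window`` singing days of
    each treatment) are correlated with each other (``cc_t1xt2``); the
    within-treatment baseline ``cc_t1xt1`` is the mean CC between
    consecutive-day histograms inside the first treatment's stable window.
    """
    hists = daily_histograms(dataset.records, feature, bin_width)
    t1_days = [d for d in dataset.singing_days(Phase.T1_PLUS) if d in hists]
    t2_days = [d for d in dataset.singing_days(Phase.T2_PLUS) if d in hists]
    if len(t1_days) < window or len(t2_days) < window:
        return CrossTreatmentCC(feature, float("nan"), float("nan"),
                                float("nan"))
    w1 = t1_days[-window:]
    w2 = t2_days[-window:]
    ref1 = reference_pattern([hists[d] for d in w1], expected_days=window)
    ref2 = reference_pattern([hists[d] for d in w2], expected_days=window)
    consecutive = [pearson_cc(hists[a], hists[b]) for a, b in zip(w1, w1[1:])]
    daywise = [pearson_cc(hists[a], hists[b]) for a in w1 for b in w2]
    return CrossTreatmentCC(
        feature=feature,
        cc_t1xt2=pearson_cc(ref1, ref2),
        cc_t1xt1=float(np.nanmean(consecutive)),
        cc_t1xt2_daywise=float(np.nanmean(daywise)),
    )


# ---------------------------------------------------------------------------
# per-bird, per-feature orchestration

@dataclass(frozen=True)
class FeatureReport:
    """Everything the pipeline reports for one bird x feature."""

    bird_id: str
    feature: str
    trajectory: SimilarityTrajectory
    fit_t1: DevelopmentFit | None
    fit_t2: DevelopmentFit | None
    stabilization_day_t1: float
    stabilization_day_t2: float
    dmax_t1: float
    dmax_t2: float
    deterioration: float
    recovery: float
    cross_treatment: CrossTreatmentCC

    def to_dict(self) -> dict:
        f = {}
        for tag, fit in (("t1", self.fit_t1), ("t2", self.fit_t2)):
            if fit is not None:
                f[f"fit_{tag}"] = {
                    "a": fit.a, "b": fit.b, "c": fit.c,
                    "d_scale": fit.d_scale, "rss": fit.rss,
                    "has_developmental_increase":
                        fit.has_developmental_increase,
                    "converged": fit.converged, "n_points": fit.n_points,
                }
            else:
                f[f"fit_{tag}"] = None
        return {
            "bird_id": self.bird_id,
            "feature": self.feature,
            **f,
            "stabilization_day_t1": self.stabilization_day_t1,
            "stabilization_day_t2": self.stabilization_day_t2,
            "dmax_t1": self.dmax_t1,
            "dmax_t2": self.dmax_t2,
            "deterioration": self.deterioration,
            "recovery": self.recovery,
            "cc_t1xt2": self.cross_treatment.cc_t1xt2,
            "cc_t1xt1": self.cross_treatment.cc_t1xt1,
            "cc_t1xt2_daywise": self.cross_treatment.cc_t1xt2_daywise,
        }


def _phase_fit(
    traj: SimilarityTrajectory,
    calendar: PhaseCalendar,
    phase: Phase,
    epsilon: float,
) -> tuple[DevelopmentFit | None, float, float]:
    """Fit one treatment's CC segment on its implant-relative day axis."""
    w = calendar.window(phase)
    mask = (traj.days >= w.start_day) & (traj.days <= w.end_day)
    x = traj.days[mask] - w.implant_day
    y = traj.cc[mask]
    if x.size < 8:
        return None, float("nan"), float("nan")
    fit = fit_development_curve(x, y)
    stab = stabilization_day(fit, epsilon=epsilon) \
        if fit.has_developmental_increase else float("nan")
    return fit, stab, dmax(fit)


def feature_development_report(
    dataset: OntogenyDataset,
    feature: str,
    bin_width: float | None = None,
    epsilon: float = 0.001,
    reference_window: int = 7,
    early_window: int = 2,
) -> FeatureReport:
    """Run the full similarity analysis of one feature for one bird.

    Builds daily histograms on the shared support, averages the last
    ``reference_window`` singing days of the first treatment into the
    reference pattern, computes the CC trajectory over all phases, fits
    each treatment's segment on its implant-relative day axis, and derives
    stabilization days, d_max, deterioration/recovery and cross-treatment
    similarity.
    """
    hists = daily_histograms(dataset.records, feature, bin_width)
    t1_days = [d for d in dataset.singing_days(Phase.T1_PLUS) if d in hists]
    if len(t1_days) < reference_window:
        raise ValueError(
            f"only {len(t1_days)} singing days in the first treatment; "
            f"need {reference_window} for the reference pattern"
        )
    ref_days = t1_days[-reference_window:]
    ref = reference_pattern([hists[d] for d in ref_days],
                            expected_days=reference_window)
    traj = cc_trajectory(hists, ref, reference_days=tuple(ref_days))
    fit1, stab1, dmax1 = _phase_fit(traj, dataset.calendar, Phase.T1_PLUS,
                                    epsilon)
    fit2, stab2, dmax2 = _phase_fit(traj, dataset.calendar, Phase.T2_PLUS,
                                    epsilon)
    return FeatureReport(
        bird_id=dataset.bird_id,
        feature=feature,
        trajectory=traj,
        fit_t1=fit1,
        fit_t2=fit2,
        stabilization_day_t1=stab1,
        stabilization_day_t2=stab2,
        dmax_t1=dmax1,
        dmax_t2=dmax2,
        deterioration=deterioration(traj, dataset.calendar,
                                    stable_window=reference_window,
                                    early_window=early_window),
        recovery=recovery(traj, dataset.calendar,
                          stable_window=reference_window,
                          early_window=early_window),
        cross_treatment=cross_treatment_similarity(dataset, feature, bin_width,
                                                   window=reference_window),
    )
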