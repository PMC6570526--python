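"""End-to-end orchestration: ingest/simulate -> analyses -> report bundle.

A pipeline run produces, per bird and feature, the similarity trajectory,
logistic fits, stabilization days, d_max, deterioration and recovery; a
cohort syllable-distance table; per-period syntax metrics; optional
spine-density summaries; and the group statistics tying them together.
Everything is deterministic given the seeds in the configuration, whose
hash is embedded in the report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import development as dev
from . import distance as dist
from . import morphometry as morpho
from . import stats as gstats
from . import syntax as syn
from .datamodel import OntogenyDataset, Phase, read_feature_table
from .simulate import simulate_cohort, simulate_spine_segments

__all__ = ["PipelineConfig", "run_pipeline", "report_summary", "explain_defaults"]

log = logging.getLogger("songdev")

#: features whose re-development is a time-compressed copy of development
#: (they deteriorate and then re-run their whole drift); pooling their
#: per-bird T1/T2 stabilization-day ratios estimates the savings factor.
#: SR is excluded: its T1 timing is dominated by the slowly developing
#: syllable duration, which does not deteriorate, so its ratio confounds
#: savings with the duration/pause timing difference.
SAVINGS_FEATURES = ("i", "FM", "AM")

#: smallest cohort-mean CC drop that counts as deterioration: a drop that
#: is statistically detectable but smaller than this is within the
#: day-to-day wobble of stable-song histograms and carries no behavioral
#: meaning
MIN_DETERIORATION = 0.05


def classify_deterioration(
    det_by_feature: dict[str, list[float]], alpha: float = 0.05,
    min_effect: float = MIN_DETERIORATION,
) -> dict[str, bool]:
    """Classify features as deteriorating from per-bird deterioration values.

    A feature deteriorates when its cohort deterioration significantly
    exceeds zero (two-sided one-sample t at ``alpha``) *and* the mean drop
    is at least ``min_effect`` CC units.
    """
    out = {}
    for feature, vals in det_by_feature.items():
        x = np.asarray([v for v in vals if np.isfinite(v)], dtype=float)
        if x.size < 2:
            out[feature] = False
            continue
        res = gstats.one_sample_t(x, label=f"deterioration[{feature}]")
        out[feature] = (not res.degenerate and res.p_value < alpha
                        and x.mean() > min_effect)
    return out


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    input_paths: list[str] = field(default_factory=list)
    simulate: bool = True
    n_birds: int = 6
    savings_factor: float = 7.0
    seed: int = 0
    bin_widths: dict[str, float] = field(
        default_factory=lambda: dict(dev.DEFAULT_BIN_WIDTHS))
    reference_window: int = 7
    early_window: int = 2
    epsilon: float = 0.001
    n_per_type: int = 100
    features: tuple[str, ...] = tuple(dev.DEFAULT_BIN_WIDTHS)
    spine_table: str | None = None
    simulate_spines: bool = False
    out_dir: str | None = None
    #: extra GeneratorConfig keyword overrides (e.g. shorter phases)
    generator_overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.reference_window <= 0 or self.early_window <= 0:
            raise ValueError("windows must be positive")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not np.isfinite(v) else v
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    return obj


def _mean_sem(values) -> dict:
    x = np.asarray([v for v in values if v is not None and np.isfinite(v)],
                   dtype=float)
    if x.size == 0:
        return {"mean": None, "sem": None, "n": 0}
    sem = float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else None
    return {"mean": float(x.mean()), "sem": sem, "n": int(x.size)}


def _load_datasets(config: PipelineConfig) -> list[OntogenyDataset]:
    if config.simulate:
        log.info("simulating cohort: %d birds, savings factor %.1f, seed %d",
                 config.n_birds, config.savings_factor, config.seed)
        datasets, _ = simulate_cohort(n_birds=config.n_birds,
                                      seed=config.seed,
                                      savings_factor=config.savings_factor,
                                      **config.generator_overrides)
        return datasets
    if not config.input_paths:
        raise ValueError("either simulate=True or input_paths are required")
    return [read_feature_table(p) for p in config.input_paths]


def _feature_block(
    datasets, config: PipelineConfig
) -> tuple[dict, pd.DataFrame]:
    out: dict = {}
    traj_rows = []
    for feature in config.features:
        bw = config.bin_widths.get(feature)
        per_bird = {}
        for ds in datasets:
            log.debug("development analysis: bird %s feature %s",
                      ds.bird_id, feature)
            rep = dev.feature_development_report(
                ds, feature, bin_width=bw, epsilon=config.epsilon,
                reference_window=config.reference_window,
                early_window=config.early_window)
            per_bird[ds.bird_id] = rep.to_dict()
            for day, cc in zip(rep.trajectory.days, rep.trajectory.cc):
                traj_rows.append((ds.bird_id, feature, int(day), float(cc)))
        cohort = {
            key: _mean_sem(r[key] for r in per_bird.values())
            for key in ("stabilization_day_t1", "stabilization_day_t2",
                        "dmax_t1", "dmax_t2", "deterioration", "recovery",
                        "cc_t1xt2", "cc_t1xt1")
        }
        ratios = [
            r["stabilization_day_t1"] / r["stabilization_day_t2"]
            for r in per_bird.values()
            if np.isfinite(r["stabilization_day_t1"])
            and np.isfinite(r["stabilization_day_t2"])
            and r["stabilization_day_t2"] > 0
        ]
        cohort["stabilization_ratio"] = _mean_sem(ratios)
        stats_block = {}
        pairs = [(r["stabilization_day_t1"], r["stabilization_day_t2"])
                 for r in per_bird.values()
                 if np.isfinite(r["stabilization_day_t1"])
                 and np.isfinite(r["stabilization_day_t2"])]
        # group statistics only when >= 3 birds show the developmental rise
        if len(pairs) >= 3:
            a, b = zip(*pairs)
            stats_block["stabilization_paired_t"] = gstats.paired_t(
                a, b, labels=("T1", "T2")).to_dict()
        det = [r["deterioration"] for r in per_bird.values()
               if np.isfinite(r["deterioration"])]
        rec = [r["recovery"] for r in per_bird.values()
               if np.isfinite(r["recovery"])]
        if len(det) >= 2:
            stats_block["deterioration_t"] = gstats.one_sample_t(
                det, label=f"deterioration[{feature}]").to_dict()
        if len(rec) >= 2:
            stats_block["recovery_t"] = gstats.one_sample_t(
                rec, label=f"recovery[{feature}]").to_dict()
        cc_pairs = [(r["cc_t1xt1"], r["cc_t1xt2"]) for r in per_bird.values()
                    if np.isfinite(r["cc_t1xt1"])
                    and np.isfinite(r["cc_t1xt2"])]
        if len(cc_pairs) >= 2:
            a, b = zip(*cc_pairs)
            stats_block["cross_treatment_paired_t"] = gstats.paired_t(
                a, b, labels=("T1xT1", "T1xT2")).to_dict()
        out[feature] = {"per_bird": per_bird, "cohort": cohort,
                        "stats": stats_block}
    trajectories = pd.DataFrame(traj_rows,
                                columns=["bird", "feature", "day", "cc"])
    return out, trajectories


def _syntax_block(datasets, config: PipelineConfig) -> dict:
    per_bird = {}
    for ds in datasets:
        entry = {}
        for phase in (Phase.T1_PLUS, Phase.T2_PLUS):
            rec = dist.stable_window_records(ds, phase,
                                             config.reference_window)
            if len(rec) == 0:
                continue
            k = ds.records["syllable_type"].nunique()
            entry[phase.value] = syn.syntax_summary(rec, repertoire_size=k)
        per_bird[ds.bird_id] = entry
    cohort = {}
    stats_block = {}
    for metric in ("pct_used", "linearity", "consistency", "entropy_bits",
                   "n_transitions"):
        for phase in ("T1_PLUS", "T2_PLUS"):
            vals = [e[phase][metric] for e in per_bird.values()
                    if phase in e and np.isfinite(e[phase][metric])]
            cohort[f"{metric}_{phase}"] = _mean_sem(vals)
        pairs = [(e["T1_PLUS"][metric], e["T2_PLUS"][metric])
                 for e in per_bird.values()
                 if "T1_PLUS" in e and "T2_PLUS" in e]
        if len(pairs) >= 2 and metric != "n_transitions":
            a, b = zip(*pairs)
            res = gstats.paired_t(a, b, labels=("T1", "T2"))
            stats_block[metric] = res.to_dict()
    return {"per_bird": per_bird, "cohort": cohort, "stats": stats_block}


def _distance_block(datasets, config: PipelineConfig) -> dict:
    table = dist.cohort_distance_table(
        datasets, n_per_type=config.n_per_type, seed=config.seed,
        window=config.reference_window)
    cohort = {}
    groups = {}
    for cat, grp in table.groupby("category"):
        cohort[cat] = _mean_sem(grp["mean_distance"])
        groups[cat] = grp["mean_distance"].to_numpy()
    stats_block = [r.to_dict() for r in gstats.anova_tukey_dunnett(groups)] \
        if all(len(v) >= 2 for v in groups.values()) else []
    return {"per_bird_rows": table.to_dict("records"), "cohort": cohort,
            "stats": stats_block}


def _morphometry_block(config: PipelineConfig) -> dict | None:
    if config.spine_table:
        segments = pd.read_csv(config.spine_table)
    elif config.simulate_spines:
        segments = simulate_spine_segments(seed=config.seed)
    else:
        return None
    out: dict = {}
    rois = {"HVC": 15, "RA": 10}
    for region in segments["region"].unique():
        reg = segments[segments["region"] == region]
        summary = morpho.group_mean_density(reg, unit="bird")
        pooled = morpho.group_mean_density(reg, unit="segment")
        per_bird = reg.groupby(["group", "bird_id"]).apply(
            lambda g: (g["spine_count"] / g["length_um"]).mean(),
            include_groups=False)
        groups = {g: per_bird[g].to_numpy() for g in
                  per_bird.index.get_level_values(0).unique()}
        stats_block = [
            r.to_dict() for r in gstats.anova_tukey_dunnett(
                groups, control="C" if "C" in groups else None)
        ] if all(len(v) >= 2 for v in groups.values()) else []
        n_rois_per_bird = rois.get(region, 10)
        dists = {}
        dense = {}
        for group, grp in reg.groupby("group"):
            n_birds = grp["bird_id"].nunique()
            dist_df = morpho.density_distribution(
                grp, n_rois=n_rois_per_bird * n_birds)
            dists[group] = dist_df.to_dict("records")
            dense[group] = morpho.dense_dendrites_per_roi(
                grp, n_rois=n_rois_per_bird * n_birds)
        out[region] = {
            "group_means_bird": summary.to_dict("records"),
            "group_means_segment": pooled.to_dict("records"),
            "distribution": dists,
            "dense_dendrites_per_roi": dense,
            "stats": stats_block,
        }
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return (and optionally write) the report bundle."""
    if not log.handlers:
        logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                            format="%(asctime)s %(levelname)s %(message)s")
    datasets = _load_datasets(config)
    report = {
        "config": _jsonable(asdict(config)),
        "config_hash": config.hash(),
        "birds": [ds.bird_id for ds in datasets],
    }
    stage = "development"
    trajectories = None
    try:
        report["features"], trajectories = _feature_block(datasets, config)
        stage = "distance"
        report["distance"] = _distance_block(datasets, config)
        stage = "syntax"
        report["syntax"] = _syntax_block(datasets, config)
        stage = "morphometry"
        m = _morphometry_block(config)
        if m is not None:
            report["morphometry"] = m
    except Exception as exc:
        log.error("pipeline failed in stage %s: %s", stage, exc)
        if config.out_dir:
            _write_outputs(report, trajectories, config, partial=True)
        raise
    savings = {
        f: report["features"][f]["cohort"]["stabilization_ratio"]
        for f in SAVINGS_FEATURES if f in report["features"]
    }
    pooled = [
        r["stabilization_day_t1"] / r["stabilization_day_t2"]
        for f in SAVINGS_FEATURES if f in report["features"]
        for r in report["features"][f]["per_bird"].values()
        if r["stabilization_day_t1"] is not None
        and r["stabilization_day_t2"] is not None
        and np.isfinite(r["stabilization_day_t1"])
        and np.isfinite(r["stabilization_day_t2"])
        and r["stabilization_day_t2"] > 0
    ]
    savings["pooled"] = _mean_sem(pooled)
    report["savings"] = savings
    if config.out_dir:
        _write_outputs(report, trajectories, config)
    return _jsonable(report)


def _write_outputs(report, trajectories, config: PipelineConfig,
                   partial: bool = False) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    name = "report_partial.json" if partial else "report.json"
    (out / name).write_text(json.dumps(_jsonable(report), indent=2,
                                       sort_keys=True))
    if partial:
        return
    if trajectories is not None:
        trajectories.to_csv(out / "trajectories.csv", index=False)
    if "distance" in report:
        pd.DataFrame(report["distance"]["per_bird_rows"]).to_csv(
            out / "distances.csv", index=False)
    (out / "summary.txt").write_text(report_summary(report))
    log.info("report bundle written to %s", out)


def report_summary(report: dict) -> str:
    """Human-readable per-bird x feature table plus cohort mean ± SEM rows."""
    cols = ("stab_t1", "stab_t2", "dmax_t1", "dmax_t2", "deterior", "recovery")
    lines = [
        f"{'bird':<10}{'feature':<9}" + "".join(f"{c:>10}" for c in cols)]

    def _fmt(v):
        if v is None or (isinstance(v, float) and not np.isfinite(v)):
            return f"{'--':>10}"
        return f"{v:>10.4g}"

    feats = report.get("features", {})
    for feature, block in feats.items():
        for bird, r in block["per_bird"].items():
            vals = (r["stabilization_day_t1"], r["stabilization_day_t2"],
                    r["dmax_t1"], r["dmax_t2"], r["deterioration"],
                    r["recovery"])
            lines.append(f"{bird:<10}{feature:<9}"
                         + "".join(_fmt(v) for v in vals))
        c = block["cohort"]

        def _pm(key):
            m = c[key]["mean"]
            s = c[key]["sem"]
            if m is None:
                return f"{'--':>10}"
            if s is None:
                return f"{m:>10.4g}"
            return f"{m:.3g}±{s:.2g}".rjust(10)

        lines.append(f"{'cohort':<10}{feature:<9}"
                     + _pm("stabilization_day_t1") + _pm("stabilization_day_t2")
                     + _pm("dmax_t1") + _pm("dmax_t2")
                     + _pm("deterioration") + _pm("recovery"))
    return "\n".join(lines) + "\n"


_DEFAULTS_EXPLAINED = """\
songdev pipeline defaults
-------------------------
reference window   7 singing days   stable-song reference pattern = the mean
                                    daily histogram over the last week of
                                    singing in a treatment
early window       2 singing days   "just re-started singing" window used by
                                    deterioration/recovery
epsilon            0.001 CC/day     a feature counts as stabilized on the
                                    first day the fitted similarity curve
                                    gains less than this
bin widths         SR 1 Hz; d,i 1 ms; FM,AM 1 unit; BW,MF 50 Hz; E 0.1
                                    integer binning of daily feature
                                    histograms; coarser bins for wide-range
                                    spectral features keep histograms dense
n_per_type         100 syllables    sample size per syllable type and
                                    treatment for Euclidean-distance
                                    summaries (without replacement, seeded)
consistency cutoff 5%               a phrase transition is "common" when it
                                    carries at least 5% of all transitions
bout rules         gap <= 100 ms, span >= 750 ms
                                    sounds closer than the gap share a bout;
                                    only bouts at least this long count as
                                    song
fit acceptance     b > 0.05 and >=20% RSS reduction vs constant
                                    a trajectory shows a developmental
                                    increase only when the logistic rise is
                                    material and the fit beats a flat model
"""


def explain_defaults() -> str:
    """The design defaults in effect, with the reasoning behind each."""
    return _DEFAULTS_EXPLAINED
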