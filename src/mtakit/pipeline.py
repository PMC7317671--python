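"""End-to-end orchestration: load or simulate a cohort, QC-split it, and
write agreement, progression, sensitivity and conversion-time tables with a
run report. Identical config + seed produces byte-identical outputs."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .agreement import discretize_ratings, independent_spearman, weighted_kappa
from .cohort_model import (
    Cohort,
    CSFCutoffs,
    HEMISPHERES,
    QCViews,
    all_measures,
    measure_value,
    qc_filter,
    read_cohort,
)
from .conversion_time import (
    full_score_time,
    reconciliation_ratio,
    threshold_crossing_time,
)
from .progression import (
    bonferroni_threshold,
    fit_all_slopes,
    group_rate_summary,
    timepoint_summary,
)
from .sensitivity import compute_deltas, crossover_threshold, kde_by_delta_class
from .synthetic_cohort import SimulationConfig, generate_cohort

log = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"  # fixed file precision; full precision kept in memory


class CutoffSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ab42_40: float = 0.10
    ptau: float = 72.0


class KDESettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    bandwidth_rule: Literal["scott", "silverman"] = "scott"
    min_class_size: int = Field(5, ge=2)
    weighted: bool = True


class SimulationSettings(BaseModel):
    """Subset of generator knobs exposed through the config file; anything
    omitted keeps the study-condition default."""

    model_config = ConfigDict(extra="forbid")
    group_sizes: Optional[dict[str, int]] = None
    qc_fail_prob: Optional[float] = Field(None, ge=0.0, le=1.0)
    visit_offsets: Optional[list[float]] = None


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    input_csv: Optional[str] = None  # mutually exclusive with `simulation`
    simulation: Optional[SimulationSettings] = None
    cutoffs: CutoffSettings = Field(default_factory=CutoffSettings)
    kappa_weighting: Literal["linear", "quadratic", "unweighted"] = "linear"
    selection_rule: Literal["baseline", "random_per_subject"] = "baseline"
    kde: KDESettings = Field(default_factory=KDESettings)
    alpha: float = Field(0.05, gt=0.0, lt=1.0)
    m_comparisons: int = Field(66, ge=1)
    outdir: str = "mta_results"
    seed: Optional[int] = None
    log_level: str = "INFO"


@dataclass
class ConfigDiagnostics:
    ok: bool
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    config: PipelineConfig | None = None


def validate_config(path: str | Path) -> ConfigDiagnostics:
    """Schema-check a YAML pipeline config; returns pass/fail with messages
    naming the offending fields."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except (OSError, yaml.YAMLError) as exc:
        return ConfigDiagnostics(ok=False, errors=[f"unreadable config: {exc}"])
    try:
        cfg = PipelineConfig.model_validate(raw)
    except ValidationError as exc:
        msgs = [
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors()
        ]
        return ConfigDiagnostics(ok=False, errors=msgs)
    warns = []
    if cfg.seed is None:
        warns.append(
            "no seed given: a random seed will be drawn and recorded in the run report"
        )
    if cfg.input_csv and cfg.simulation:
        return ConfigDiagnostics(
            ok=False, errors=["input_csv and simulation are mutually exclusive"]
        )
    return ConfigDiagnostics(ok=True, warnings=warns, config=cfg)


@dataclass
class RunReport:
    software_version: str
    seed: int
    n_subjects: int
    n_visits_loaded: int
    n_visits_qc_excluded: int
    n_visits_volume_view: int
    n_pairs_formed: dict[str, int] = field(default_factory=dict)
    n_pairs_dropped: dict[str, int] = field(default_factory=dict)
    classes_merged: dict[str, bool] = field(default_factory=dict)
    significance_threshold: float = 0.0
    at_anomaly_subjects: list[str] = field(default_factory=list)
    output_files: list[str] = field(default_factory=list)


def _build_simulation_config(cfg: PipelineConfig, seed: int) -> SimulationConfig:
    from dataclasses import replace

    from .cohort_model import ATGroup

    sim = SimulationConfig(seed=seed)
    s = cfg.simulation
    if s is not None:
        if s.group_sizes:
            groups = {}
            for name, p in sim.groups.items():
                n = s.group_sizes.get(name.value, p.n)
                n_mci = min(p.n_mci, n)
                groups[name] = replace(p, n=n, n_mci=n_mci)
            sim.groups = groups
        if s.qc_fail_prob is not None:
            sim.qc_fail_prob = s.qc_fail_prob
        if s.visit_offsets is not None:
            sim.visit_offsets = tuple(s.visit_offsets)
    sim.cutoffs = CSFCutoffs(cfg.cutoffs.ab42_40, cfg.cutoffs.ptau)
    return sim


def _agreement_table(cohort: Cohort, cfg: PipelineConfig, seed: int) -> pd.DataFrame:
    """Pairwise kappas among raters and Spearman correlations of every
    rating series against volumes and cognition (one visit per subject)."""
    rows = []
    raters = sorted(cohort.rater_registry)
    by_series: dict[tuple[str, str], list[float | None]] = {
        (r, h): [] for r in raters for h in HEMISPHERES
    }
    for v in cohort.visits:
        for key in by_series:
            by_series[key].append(v.ratings.get(key))

    def as_discrete(r: str, h: str) -> np.ndarray:
        vals = np.array(
            [np.nan if x is None else x for x in by_series[(r, h)]], dtype=float
        )
        if cohort.rater_registry[r] == "continuous":
            ok = np.isfinite(vals)
            vals[ok] = discretize_ratings(vals[ok])
        return vals

    for i, ra in enumerate(raters):
        for rb in raters[i + 1 :]:
            for h in HEMISPHERES:
                res = weighted_kappa(
                    as_discrete(ra, h), as_discrete(rb, h), cfg.kappa_weighting
                )
                rows.append(
                    {
                        "measure_a": f"mta:{ra}:{h}",
                        "measure_b": f"mta:{rb}:{h}",
                        "metric": f"kappa_{res.weighting}",
                        "value": res.kappa,
                        "label": res.label,
                        "n": res.n_pairs,
                        "p_value": np.nan,
                    }
                )
    other = [f"hc:{h}" for h in HEMISPHERES] + [f"ilv:{h}" for h in HEMISPHERES]
    other += ["mmse", "adas_dwr"]
    for r in raters:
        for h in HEMISPHERES:
            for meas in other:
                try:
                    res = independent_spearman(
                        cohort, f"mta:{r}:{h}", meas, cfg.selection_rule, seed
                    )
                except ValueError:
                    continue
                rows.append(
                    {
                        "measure_a": f"mta:{r}:{h}",
                        "measure_b": meas,
                        "metric": "spearman_rho",
                        "value": res.rho,
                        "label": "",
                        "n": res.n,
                        "p_value": res.p_value,
                    }
                )
    return pd.DataFrame(rows)


def _group_rates_table(
    slopes: pd.DataFrame, cohort: Cohort, cfg: PipelineConfig
) -> pd.DataFrame:
    groups = {s: p.at_group.value for s, p in cohort.subjects.items()}
    diag = {
        sid: vs[0].diagnosis.value for sid, vs in cohort.by_subject().items() if vs
    }
    rows = []
    for meas in sorted(slopes.measure.unique()):
        is_volume = meas.split(":")[0] in ("hc", "ilv")
        for stratum in ("all", "SCD", "MCI"):
            for percent in ([False, True] if is_volume else [False]):
                try:
                    s = group_rate_summary(
                        slopes, groups, meas, stratum=stratum, diagnosis=diag,
                        alpha=cfg.alpha, m=cfg.m_comparisons, percent=percent,
                    )
                except Exception as exc:  # strata can be empty in tiny runs
                    log.info("group summary skipped for %s/%s: %s", meas, stratum, exc)
                    continue
                for g, st in s.per_group.items():
                    rows.append(
                        {
                            "measure": meas,
                            "scale": "percent" if percent else "native",
                            "stratum": stratum,
                            "at_group": g,
                            "mean": st["mean"],
                            "sd": st["sd"],
                            "n": st["n"],
                            "kw_h": s.kw_h,
                            "p_value": s.p_value,
                            "significant_after_bonferroni": s.significant_after_bonferroni,
                        }
                    )
    return pd.DataFrame(rows)


def _sensitivity_tables(
    volume_cohort: Cohort, cfg: PipelineConfig, report: RunReport
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, dict[str, float | None]]]:
    """Per discrete rater: density grids and crossover thresholds for HC
    (loss) and ILV (growth), on mm³ and percent scales."""
    density_rows = []
    thr_rows = []
    thresholds: dict[str, dict[str, float | None]] = {}
    var_map = {
        ("hc", "mm3"): ("delta_hc", "loss"),
        ("hc", "percent"): ("delta_hc_pct", "loss"),
        ("ilv", "mm3"): ("delta_ilv", "growth"),
        ("ilv", "percent"): ("delta_ilv_pct", "growth"),
    }
    for rater in sorted(volume_cohort.discrete_raters()):
        pairs = compute_deltas(volume_cohort, rater)
        report.n_pairs_formed[rater] = int(len(pairs))
        report.n_pairs_dropped[rater] = int(pairs.attrs["n_dropped_missing_volume"])
        thresholds[rater] = {}
        for (measure, scale), (variable, direction) in var_map.items():
            try:
                dens = kde_by_delta_class(
                    pairs, variable, cfg.kde.bandwidth_rule, cfg.kde.min_class_size
                )
            except ValueError as exc:
                log.info("KDE skipped for %s/%s: %s", rater, variable, exc)
                continue
            report.classes_merged[f"{rater}:{variable}"] = dens.merged
            cross = crossover_threshold(dens, direction, cfg.kde.weighted)
            thr_rows.append(
                {
                    "rater_id": rater,
                    "measure": measure,
                    "scale": scale,
                    "direction": direction,
                    "weighted": cfg.kde.weighted,
                    "threshold": cross.threshold,
                    "no_crossover": cross.no_crossover,
                    "n_pairs": sum(dens.counts.values()),
                    "n_excluded_negative": dens.n_excluded_negative,
                }
            )
            thresholds[rater][f"{measure}:{scale}"] = cross.threshold
            for k, d in dens.densities.items():
                for gx, gy in zip(dens.grid, d):
                    density_rows.append(
                        {
                            "rater_id": rater,
                            "variable": variable,
                            "delta_mta_class": str(k),
                            "x": gx,
                            "density": gy,
                            "prior": dens.priors[k],
                        }
                    )
    return pd.DataFrame(thr_rows), pd.DataFrame(density_rows), thresholds


def _conversion_table(
    slopes: pd.DataFrame,
    cohort: Cohort,
    thresholds: dict[str, dict[str, float | None]],
) -> pd.DataFrame:
    """Per-group conversion times: reciprocal of the mean continuous rating
    rate (left/right averaged), and threshold time from the rater-averaged
    HC crossover over the mean HC loss rate."""
    groups = {s: p.at_group.value for s, p in cohort.subjects.items()}
    auto = cohort.continuous_raters()
    rows = []
    hc_thrs = [
        t.get("hc:mm3")
        for t in thresholds.values()
        if t.get("hc:mm3") is not None
    ]
    mean_thr = float(np.mean(hc_thrs)) if hc_thrs else None
    for g in sorted(set(groups.values())):
        subj = {s for s, gg in groups.items() if gg == g}
        entry = {"at_group": g}
        if auto:
            r = auto[0]
            meas = [f"mta:{r}:{h}" for h in HEMISPHERES]
            sel = slopes[slopes.measure.isin(meas) & slopes.subject_id.isin(subj)]
            if len(sel):
                rate = float(sel.slope.mean())
                entry["avra_rate"] = rate
                entry["full_score_years"] = full_score_time(rate)
        sel = slopes[
            slopes.measure.isin([f"hc:{h}" for h in HEMISPHERES])
            & slopes.subject_id.isin(subj)
        ]
        if len(sel) and mean_thr is not None:
            hc_rate = float(sel.slope.mean())
            entry["hc_rate"] = hc_rate
            entry["hc_threshold"] = mean_thr
            entry["threshold_years"] = threshold_crossing_time(mean_thr, hc_rate)
        ft, tt = entry.get("full_score_years"), entry.get("threshold_years")
        if ft and tt and np.isfinite(ft) and np.isfinite(tt) and ft > 0 and tt > 0:
            entry["reconciliation_ratio"] = reconciliation_ratio(ft, tt)
        rows.append(entry)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage and write the result tables plus a run report
    into ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    seed = config.seed
    if seed is None:
        seed = int(np.random.SeedSequence().entropy % (2**31))
        log.warning("no seed configured; drew %d", seed)

    cutoffs = CSFCutoffs(config.cutoffs.ab42_40, config.cutoffs.ptau)
    if config.input_csv:
        cohort = read_cohort(config.input_csv, cutoffs)
    else:
        sim = _build_simulation_config(config, seed)
        cohort = generate_cohort(sim)
        from .cohort_model import write_cohort

        write_cohort(cohort, outdir / "cohort.csv")

    views: QCViews = qc_filter(cohort)
    report = RunReport(
        software_version=__version__,
        seed=seed,
        n_subjects=cohort.n_subjects,
        n_visits_loaded=cohort.n_visits,
        n_visits_qc_excluded=views.n_visits_excluded,
        n_visits_volume_view=views.volume_view.n_visits,
        significance_threshold=bonferroni_threshold(config.alpha, config.m_comparisons),
        at_anomaly_subjects=[
            s for s, p in cohort.subjects.items() if p.at_group.value == "AnTp"
        ],
    )
    assert report.n_visits_loaded == report.n_visits_volume_view + report.n_visits_qc_excluded

    files: dict[str, pd.DataFrame] = {}
    files["agreement.csv"] = _agreement_table(views.rating_view, config, seed)

    rating_measures = [
        m for m in all_measures(cohort) if m.split(":")[0] in ("mta",)
    ] + ["mmse", "adas_dwr"]
    volume_measures = [f"{v}:{h}" for v in ("hc", "ilv") for h in HEMISPHERES]
    slopes = pd.concat(
        [
            fit_all_slopes(views.rating_view, rating_measures),
            fit_all_slopes(views.volume_view, volume_measures),
        ],
        ignore_index=True,
    )
    files["slopes.csv"] = slopes
    files["group_rates.csv"] = _group_rates_table(slopes, cohort, config)

    tps = []
    for meas in rating_measures:
        t = timepoint_summary(views.rating_view, meas).reset_index()
        t.insert(0, "measure", meas)
        tps.append(t)
    for meas in volume_measures:
        t = timepoint_summary(views.volume_view, meas).reset_index()
        t.insert(0, "measure", meas)
        tps.append(t)
    files["timepoint_summary.csv"] = pd.concat(tps, ignore_index=True)

    thr_tab, dens_tab, thresholds = _sensitivity_tables(
        views.rating_view, config, report
    )
    files["thresholds.csv"] = thr_tab
    files["densities.csv"] = dens_tab
    files["conversion.csv"] = _conversion_table(slopes, cohort, thresholds)

    for name, df in files.items():
        df.to_csv(outdir / name, index=False, float_format=FLOAT_FMT)
        report.output_files.append(name)

    resolved = config.model_copy(update={"seed": seed})
    (outdir / "config_resolved.yaml").write_text(
        yaml.safe_dump(resolved.model_dump(), sort_keys=True)
    )
    report.output_files.append("config_resolved.yaml")
    (outdir / "run_report.json").write_text(json.dumps(asdict(report), indent=2))
    report.output_files.append("run_report.json")
    return report
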