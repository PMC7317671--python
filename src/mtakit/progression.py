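"""Per-subject annual-change estimation and CSF-group comparison.

Each subject's annual change in a measure is the slope of an ordinary
least-squares line fitted to that subject's values against age at scan.
Group comparisons use the Kruskal-Wallis H test (tie-corrected), with a
Bonferroni-corrected significance threshold, and an exact permutation
p-value for very small samples where the chi-square approximation is poor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_model import (
    ATGroup,
    Cohort,
    Diagnosis,
    DomainError,
    all_measures,
    measure_value,
)

log = logging.getLogger(__name__)

EXACT_KW_MAX_N = 10


@dataclass
class SlopeEstimate:
    subject_id: str
    measure: str
    slope: float  # measure units per year
    intercept: float  # measure units at age 0
    n_points: int
    baseline_value: float


def fit_subject_slope(
    ages: Sequence[float], values: Sequence[float],
    subject_id: str = "", measure: str = "",
) -> SlopeEstimate:
    """OLS slope/intercept of ``values`` against ``ages`` for one subject.

    Missing values (None/NaN) are dropped pairwise. Requires >= 2 points
    with non-zero age variance. Closed form:
    slope = sum((x - xbar)(y - ybar)) / sum((x - xbar)^2).
    """
    x = np.asarray([np.nan if a is None else a for a in ages], dtype=float)
    y = np.asarray([np.nan if v is None else v for v in values], dtype=float)
    if x.shape != y.shape:
        raise ValueError("ages and values must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 2:
        raise DomainError(f"need >= 2 points to fit a slope, have {x.size}")
    xc = x - x.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise DomainError("zero age variance: all points at the same age")
    slope = float(xc @ (y - y.mean())) / sxx
    intercept = float(y.mean() - slope * x.mean())
    baseline = float(y[np.argmin(x)])
    return SlopeEstimate(
        subject_id=subject_id,
        measure=measure,
        slope=slope,
        intercept=intercept,
        n_points=int(x.size),
        baseline_value=baseline,
    )


def fit_all_slopes(
    cohort: Cohort, measures: Iterable[str] | None = None
) -> pd.DataFrame:
    """Per-subject OLS slopes for every requested measure.

    Returns a tidy frame with columns subject_id, measure, slope, intercept,
    n_points, baseline_value. Subjects with fewer than two usable visits for
    a measure are omitted (counts logged). Vectorised via group-wise sums.
    """
    measures = list(measures) if measures is not None else all_measures(cohort)
    rows = []
    for v in cohort.visits:
        for meas in measures:
            val = measure_value(v, meas)
            if val is not None:
                rows.append((v.subject_id, meas, v.visit_index, v.age_at_scan, val))
    if not rows:
        return pd.DataFrame(
            columns=["subject_id", "measure", "slope", "intercept", "n_points", "baseline_value"]
        )
    df = pd.DataFrame(rows, columns=["subject_id", "measure", "visit", "x", "y"])
    df["xy"] = df.x * df.y
    df["xx"] = df.x * df.x
    g = df.groupby(["subject_id", "measure"], sort=True)
    agg = g.agg(
        n=("y", "size"), sx=("x", "sum"), sy=("y", "sum"),
        sxy=("xy", "sum"), sxx=("xx", "sum"),
    )
    base = df.sort_values("visit").groupby(["subject_id", "measure"], sort=True)["y"].first()
    agg["baseline_value"] = base
    varx = agg.sxx - agg.sx**2 / agg.n
    usable = (agg.n >= 2) & (varx > 0)
    n_skipped = int((~usable).sum())
    if n_skipped:
        log.info("slope fitting: skipped %d subject-measure series with <2 points", n_skipped)
    agg = agg[usable]
    varx = varx[usable]
    slope = (agg.sxy - agg.sx * agg.sy / agg.n) / varx
    intercept = agg.sy / agg.n - slope * agg.sx / agg.n
    out = pd.DataFrame(
        {
            "slope": slope,
            "intercept": intercept,
            "n_points": agg.n.astype(int),
            "baseline_value": agg.baseline_value,
        }
    ).reset_index()
    return out


def enumerate_discrete_slopes(
    visit_offsets: Sequence[float], patterns: str = "single_step"
) -> tuple[float, ...]:
    """All annual-change values an integer rating can produce.

    A discretised rating that never decreases and rises by at most one
    ("single_step") or two ("monotone_nondecreasing_max2") categories over
    the follow-up can only yield a small set of OLS slopes; this enumerates
    the admissible 0/1(/2)-valued non-decreasing sequences over the visit
    offsets and returns the de-duplicated sorted slope set.
    """
    offs = tuple(visit_offsets)
    if len(offs) < 2:
        raise ValueError("need at least 2 visit offsets")
    max_step = {"single_step": 1, "monotone_nondecreasing_max2": 2}.get(patterns)
    if max_step is None:
        raise ValueError(f"unknown pattern family {patterns!r}")
    slopes: list[float] = []
    for seq in product(range(max_step + 1), repeat=len(offs)):
        if any(b < a for a, b in zip(seq, seq[1:])):
            continue
        if seq[-1] - seq[0] > max_step:
            continue
        est = fit_subject_slope(offs, seq)
        slopes.append(est.slope)
    out: list[float] = []
    for s in sorted(slopes):
        if not out or abs(s - out[-1]) > 1e-12:
            out.append(s)
    return tuple(out)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Corrected per-comparison significance threshold alpha / m."""
    if not (0.0 < alpha < 1.0):
        raise DomainError(f"alpha must lie in (0, 1), got {alpha}")
    if not (isinstance(m, (int, np.integer)) and m >= 1):
        raise DomainError(f"m must be an integer >= 1, got {m}")
    return alpha / m


def _kw_h(groups: Sequence[np.ndarray]) -> float:
    """Tie-corrected Kruskal-Wallis H statistic."""
    allv = np.concatenate(groups)
    n = allv.size
    ranks = stats.rankdata(allv)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start : start + g.size]
        start += g.size
        h += g.size * (r.mean() - (n + 1) / 2) ** 2
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(allv, return_counts=True)
    tie = 1.0 - float(((counts**3 - counts).sum())) / (n**3 - n) if n > 1 else 1.0
    if tie == 0.0:
        return 0.0
    return h / tie


def _exact_kw_pvalue(groups: Sequence[np.ndarray]) -> float:
    """Exact permutation p-value for the Kruskal-Wallis test, enumerating
    every partition of the pooled values into the observed group sizes.
    Feasible only for small total n."""
    h_obs = _kw_h(groups)
    allv = np.concatenate(groups)
    sizes = [g.size for g in groups]
    n = allv.size
    idx = list(range(n))
    count = 0
    total = 0

    def rec(remaining: list[int], k: int, chosen: list[np.ndarray]):
        nonlocal count, total
        if k == len(sizes) - 1:
            parts = chosen + [allv[remaining]]
            total += 1
            if _kw_h(parts) >= h_obs - 1e-12:
                count += 1
            return
        for combo in combinations(remaining, sizes[k]):
            rest = [i for i in remaining if i not in set(combo)]
            rec(rest, k + 1, chosen + [allv[list(combo)]])

    rec(idx, 0, [])
    return count / total


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """H statistic and p-value across >= 2 groups. Uses the chi-square
    approximation (df = k-1), or exact enumeration when total n is at most
    ``EXACT_KW_MAX_N`` (tiny fixtures)."""
    arrs = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(arrs) < 2:
        raise DomainError("need at least two non-empty groups")
    h = _kw_h(arrs)
    n = sum(a.size for a in arrs)
    if n <= EXACT_KW_MAX_N:
        return h, _exact_kw_pvalue(arrs)
    p = float(stats.chi2.sf(h, df=len(arrs) - 1))
    return h, p


@dataclass
class GroupRateSummary:
    measure: str
    stratum: str  # "all", "SCD", "MCI"
    per_group: dict[str, dict[str, float]]  # group -> {mean, sd, n}
    percent_per_year: dict[str, dict[str, float]] | None
    kw_h: float
    p_value: float
    alpha: float
    m: int
    significant_after_bonferroni: bool


def group_rate_summary(
    slopes: pd.DataFrame,
    groups: Mapping[str, str],
    measure: str,
    stratum: str = "all",
    diagnosis: Mapping[str, str] | None = None,
    alpha: float = 0.05,
    m: int = 66,
    percent: bool = False,
) -> GroupRateSummary:
    """Per-CSF-group mean +/- sd of per-subject slopes and the
    Kruskal-Wallis test of equal group medians.

    ``slopes`` is the frame from :func:`fit_all_slopes`; ``groups`` maps
    subject_id to group label; ``diagnosis`` (subject_id -> "SCD"/"MCI") is
    required when ``stratum`` is not "all". With ``percent=True`` slopes are
    expressed per subject as 100 * slope / baseline_value before summarising
    (volume measures).
    """
    df = slopes[slopes.measure == measure].copy()
    if stratum != "all":
        if diagnosis is None:
            raise ValueError("diagnosis map required for a SCD/MCI stratum")
        df = df[df.subject_id.map(diagnosis) == stratum]
    df["group"] = df.subject_id.map(groups)
    df = df[df.group.notna()]
    values = df.slope
    if percent:
        values = 100.0 * df.slope / df.baseline_value
    df = df.assign(value=values)

    per_group: dict[str, dict[str, float]] = {}
    samples = []
    for g, sub in df.groupby("group", sort=True):
        if len(sub) == 0:
            warnings.warn(f"group {g} has no usable subjects; dropped")
            continue
        per_group[str(g)] = {
            "mean": float(sub.value.mean()),
            "sd": float(sub.value.std(ddof=1)) if len(sub) > 1 else 0.0,
            "n": int(len(sub)),
        }
        samples.append(sub.value.to_numpy())
    if len(samples) < 2:
        raise DomainError("need at least two non-empty groups to compare")
    h, p = kruskal_wallis(samples)
    thr = bonferroni_threshold(alpha, m)
    return GroupRateSummary(
        measure=measure,
        stratum=stratum,
        per_group=per_group,
        percent_per_year=None,
        kw_h=float(h),
        p_value=float(p),
        alpha=alpha,
        m=m,
        significant_after_bonferroni=bool(p < thr),
    )


def timepoint_summary(
    cohort: Cohort, measure: str
) -> pd.DataFrame:
    """Mean +/- sd of a measure at each visit, stratified by CSF group and
    baseline clinical status. Returns a frame indexed by
    (at_group, diagnosis, visit_index) with columns n, mean, sd."""
    diag0 = {
        sid: vs[0].diagnosis.value for sid, vs in cohort.by_subject().items() if vs
    }
    rows = []
    for v in cohort.visits:
        val = measure_value(v, measure)
        if val is None:
            continue
        prof = cohort.subjects[v.subject_id]
        rows.append(
            (prof.at_group.value, diag0[v.subject_id], v.visit_index, val)
        )
    df = pd.DataFrame(rows, columns=["at_group", "diagnosis", "visit_index", "value"])
    if df.empty:
        return pd.DataFrame(columns=["n", "mean", "sd"])
    out = (
        df.groupby(["at_group", "diagnosis", "visit_index"])["value"]
        .agg(n="size", mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0)
    )
    return out
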