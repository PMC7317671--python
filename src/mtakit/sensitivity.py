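"""Discrete-rating sensitivity via density-crossover thresholds.

How much volume change does it take before a discretising rater becomes
more likely to assign a *higher* rating at follow-up than to repeat the
baseline rating? Baseline-to-follow-up volume changes are grouped by the
rating change (0, +1, +2), each class gets a Gaussian kernel density, and
the crossover threshold is the volume change at which the prior-weighted
density of the "rated higher" classes first overtakes that of the
"rated the same" class and stays above it out to the grid edge.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_model import Cohort, HEMISPHERES

log = logging.getLogger(__name__)

GRID_SIZE = 512
MIN_CLASS_SIZE = 5
POOLED = "1+"  # label of the pooled >=1 class after an upward merge


def compute_deltas(cohort: Cohort, rater_id: str) -> pd.DataFrame:
    """Baseline-to-follow-up change pairs for one rater.

    One row per (subject, hemisphere, follow-up visit): the rating change
    ``delta_mta``, volume changes in mm³ and in percent of baseline, and the
    elapsed time. Volumes from QC-failed images are treated as missing;
    pairs missing either volume are dropped and counted in
    ``result.attrs["n_dropped_missing_volume"]``. Subjects without a
    baseline visit (index 0) are skipped with a warning.
    """
    rows = []
    n_dropped = 0
    for sid, vs in cohort.by_subject().items():
        if not vs or vs[0].visit_index != 0:
            warnings.warn(f"subject {sid} has no baseline visit; skipped")
            continue
        base = vs[0]
        for fu in vs[1:]:
            for hemi in HEMISPHERES:
                r0 = base.ratings.get((rater_id, hemi))
                r1 = fu.ratings.get((rater_id, hemi))
                if r0 is None or r1 is None:
                    n_dropped += 1
                    continue
                hc0 = base.hc_vol.get(hemi) if base.qc_pass else None
                hc1 = fu.hc_vol.get(hemi) if fu.qc_pass else None
                ilv0 = base.ilv_vol.get(hemi) if base.qc_pass else None
                ilv1 = fu.ilv_vol.get(hemi) if fu.qc_pass else None
                if None in (hc0, hc1, ilv0, ilv1):
                    n_dropped += 1
                    continue
                rows.append(
                    {
                        "subject_id": sid,
                        "hemisphere": hemi,
                        "rater_id": rater_id,
                        "visit_index": fu.visit_index,
                        "delta_t": fu.age_at_scan - base.age_at_scan,
                        "delta_mta": int(round(r1 - r0)),
                        "delta_hc": hc1 - hc0,
                        "delta_hc_pct": 100.0 * (hc1 - hc0) / hc0,
                        "delta_ilv": ilv1 - ilv0,
                        "delta_ilv_pct": 100.0 * (ilv1 - ilv0) / ilv0,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=[
            "subject_id", "hemisphere", "rater_id", "visit_index", "delta_t",
            "delta_mta", "delta_hc", "delta_hc_pct", "delta_ilv", "delta_ilv_pct",
        ],
    )
    df.attrs["n_dropped_missing_volume"] = n_dropped
    return df


@dataclass
class ClassDensities:
    """Per-rating-change-class kernel densities on a shared grid.

    ``densities`` maps class label (0, 1, 2, or ``"1+"`` after a merge) to
    density values on ``grid``; ``priors`` holds each class's empirical
    probability among retained pairs.
    """

    variable: str
    grid: np.ndarray
    densities: dict[object, np.ndarray]
    priors: dict[object, float]
    counts: dict[object, int]
    n_excluded_negative: int = 0
    merged: bool = False


def kde_by_delta_class(
    pairs: pd.DataFrame,
    variable: str = "delta_hc",
    bandwidth_rule: str = "scott",
    min_class_size: int = MIN_CLASS_SIZE,
) -> ClassDensities:
    """Gaussian KDE of a volume-change variable per rating-change class.

    Classes are delta_mta = 0, 1, 2 (changes above +2 pool into 2; negative
    changes are excluded and counted). Any positive class smaller than
    ``min_class_size`` triggers an upward merge of all >=1 pairs into one
    pooled class. Densities share a 512-point grid spanning the pooled data
    +/- 3 maximal bandwidths; bandwidths follow Scott's rule by default.
    """
    if variable not in pairs.columns:
        raise ValueError(f"unknown variable {variable!r}")
    data = pairs[["delta_mta", variable]].dropna()
    neg = data.delta_mta < 0
    n_neg = int(neg.sum())
    if n_neg:
        log.info("excluding %d pairs with decreased rating from KDE", n_neg)
    data = data[~neg]
    cls = np.minimum(data.delta_mta.to_numpy(), 2)
    x = data[variable].to_numpy(dtype=float)

    groups: dict[object, np.ndarray] = {}
    for k in (0, 1, 2):
        xs = x[cls == k]
        if xs.size:
            groups[k] = xs
    if 0 not in groups or groups[0].size < min_class_size:
        raise ValueError(
            f"unchanged-rating class needs >= {min_class_size} pairs"
        )
    merged = False
    positive = {k: v for k, v in groups.items() if k != 0}
    if positive and any(v.size < min_class_size for v in positive.values()):
        pooled = np.concatenate(list(positive.values()))
        if pooled.size < min_class_size:
            raise ValueError(
                f"fewer than {min_class_size} pairs with an increased rating"
            )
        warnings.warn(
            "a rating-increase class fell below the minimum size; "
            "pooling all >=1 pairs"
        )
        groups = {0: groups[0], POOLED: pooled}
        merged = True
    if not any(k != 0 for k in groups):
        raise ValueError("no pairs with an increased rating")

    kdes = {}
    bw_abs = []
    for k, xs in groups.items():
        kde = stats.gaussian_kde(xs, bw_method=bandwidth_rule)
        kdes[k] = kde
        bw_abs.append(kde.factor * xs.std(ddof=1))
    pad = 3.0 * max(bw_abs)
    lo, hi = x.min() - pad, x.max() + pad
    grid = np.linspace(lo, hi, GRID_SIZE)
    total = sum(xs.size for xs in groups.values())
    densities = {k: kdes[k](grid) for k in groups}
    priors = {k: xs.size / total for k, xs in groups.items()}
    counts = {k: int(xs.size) for k, xs in groups.items()}
    return ClassDensities(
        variable=variable,
        grid=grid,
        densities=densities,
        priors=priors,
        counts=counts,
        n_excluded_negative=n_neg,
        merged=merged,
    )


@dataclass
class CrossoverThreshold:
    """The volume change past which a higher rating becomes more likely.

    ``threshold`` is None when the weighted higher-rating density never
    overtakes the unchanged-rating density inside the grid
    (``no_crossover``)."""

    variable: str
    direction: str  # "loss" (HC) or "growth" (ILV)
    weighted: bool
    threshold: float | None
    no_crossover: bool
    grid: np.ndarray = field(repr=False)
    g_same: np.ndarray = field(repr=False)
    g_higher: np.ndarray = field(repr=False)
    rater_id: str | None = None


def crossover_threshold(
    densities: ClassDensities, direction: str, weighted: bool = True
) -> CrossoverThreshold:
    """Scan from the grid centre outward for the point past which the
    higher-rating density exceeds the unchanged-rating density all the way
    to the grid edge.

    With ``weighted=True`` (default) the curves compared are the
    prior-weighted g0 = p0 f0 and g+ = sum_{k>=1} p_k f_k, i.e. the crossing
    of posterior class probability 1/2; with ``weighted=False`` the raw
    f0 versus the normalised >=1 mixture.
    """
    if direction not in ("loss", "growth"):
        raise ValueError(f"direction must be 'loss' or 'growth', got {direction!r}")
    grid = densities.grid
    f0 = densities.densities[0]
    pos_keys = [k for k in densities.densities if k != 0]
    p0 = densities.priors[0]
    p_pos = sum(densities.priors[k] for k in pos_keys)
    mix = sum(densities.priors[k] * densities.densities[k] for k in pos_keys)
    if weighted:
        g0 = p0 * f0
        gp = mix
    else:
        g0 = f0
        gp = mix / p_pos
    diff = gp - g0
    centre = grid.size // 2
    if direction == "loss":
        # walk left from the edge: find the contiguous run of diff > 0
        # starting at the left edge
        run_end = -1
        for i in range(grid.size):
            if diff[i] > 0:
                run_end = i
            else:
                break
        if run_end < 0:
            return CrossoverThreshold(
                densities.variable, direction, weighted, None, True, grid, g0, gp
            )
        i = run_end
        if i + 1 >= grid.size:
            thr = float(grid[-1])
        else:
            thr = _interp_root(grid[i], grid[i + 1], diff[i], diff[i + 1])
    else:
        run_start = grid.size
        for i in range(grid.size - 1, -1, -1):
            if diff[i] > 0:
                run_start = i
            else:
                break
        if run_start >= grid.size:
            return CrossoverThreshold(
                densities.variable, direction, weighted, None, True, grid, g0, gp
            )
        i = run_start
        if i - 1 < 0:
            thr = float(grid[0])
        else:
            thr = _interp_root(grid[i - 1], grid[i], diff[i - 1], diff[i])
    return CrossoverThreshold(
        densities.variable, direction, weighted, thr, False, grid, g0, gp
    )


def _interp_root(x0: float, x1: float, d0: float, d1: float) -> float:
    """Linear interpolation of the sign change of d between x0 and x1."""
    if d0 == d1:
        return float(0.5 * (x0 + x1))
    return float(x0 + (x1 - x0) * (0.0 - d0) / (d1 - d0))
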