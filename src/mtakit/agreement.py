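"""Inter-rater agreement and cross-measure correlation.

Cohen's weighted kappa for ordinal 0-4 ratings, with linear, quadratic or
unweighted disagreement weights, plus Landis-Koch interpretation bands and
Spearman correlations computed on one timepoint per subject so that all
observations are independent.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort_model import Cohort, DomainError, measure_value
from .synthetic_cohort import round_half_away

log = logging.getLogger(__name__)

N_CATEGORIES = 5  # MTA scores 0..4

WEIGHTINGS = ("linear", "quadratic", "unweighted")


def discretize_ratings(values) -> np.ndarray:
    """Round continuous ratings half-away-from-zero and clip to [0, 4], as
    required before a continuous rater enters a kappa computation."""
    arr = np.asarray(values, dtype=float)
    return np.clip(round_half_away(arr), 0, 4).astype(int)


@dataclass
class KappaResult:
    kappa: float
    weighting: str
    n_pairs: int
    confusion: np.ndarray  # 5x5 counts, rows = rater A, cols = rater B
    label: str
    n_dropped: int = 0


def _clean_pairs(ratings_a, ratings_b) -> tuple[np.ndarray, np.ndarray, int]:
    a = np.asarray(ratings_a, dtype=float)
    b = np.asarray(ratings_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rating sequences must be 1-D and of equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("dropped %d rating pairs with missing values", n_dropped)
    a, b = a[ok], b[ok]
    for name, x in (("a", a), ("b", b)):
        if np.any((x < 0) | (x > 4)) or np.any(x != np.round(x)):
            raise DomainError(
                f"ratings_{name} must be integers in 0..4 "
                "(round continuous ratings with discretize_ratings first)"
            )
    return a.astype(int), b.astype(int), n_dropped


def confusion_matrix(ratings_a, ratings_b) -> np.ndarray:
    """5x5 count matrix; rows index rater A's score, columns rater B's."""
    a, b, _ = _clean_pairs(ratings_a, ratings_b)
    conf = np.zeros((N_CATEGORIES, N_CATEGORIES), dtype=int)
    np.add.at(conf, (a, b), 1)
    return conf


def _weight_matrix(weighting: str) -> np.ndarray:
    i, j = np.indices((N_CATEGORIES, N_CATEGORIES))
    d = np.abs(i - j)
    if weighting == "linear":
        return d / (N_CATEGORIES - 1)
    if weighting == "quadratic":
        return (d / (N_CATEGORIES - 1)) ** 2
    if weighting == "unweighted":
        return (d > 0).astype(float)
    raise ValueError(f"weighting must be one of {WEIGHTINGS}, got {weighting!r}")


def weighted_kappa(ratings_a, ratings_b, weighting: str = "linear") -> KappaResult:
    """Cohen's weighted kappa between two ordinal rating sequences.

    kappa_w = 1 - (sum w_ij O_ij) / (sum w_ij E_ij), with O the observed
    proportion matrix, E the outer product of the marginals and w the
    disagreement weights (linear |i-j|/4, quadratic ((i-j)/4)^2, or 0/1).
    Pairs with a missing value on either side are dropped and counted.
    """
    w = _weight_matrix(weighting)
    a, b, n_dropped = _clean_pairs(ratings_a, ratings_b)
    n = a.size
    if n < 2:
        raise ValueError(f"need at least 2 usable rating pairs, have {n}")
    conf = np.zeros((N_CATEGORIES, N_CATEGORIES), dtype=int)
    np.add.at(conf, (a, b), 1)
    observed = conf / n
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0))
    denom = float((w * expected).sum())
    num = float((w * observed).sum())
    if denom == 0.0:
        # both raters constant on the same category: perfect but degenerate
        kappa = 1.0 if num == 0.0 else 0.0
    else:
        kappa = 1.0 - num / denom
    return KappaResult(
        kappa=kappa,
        weighting=weighting,
        n_pairs=n,
        confusion=conf,
        label=landis_koch_label(max(-1.0, min(1.0, kappa))),
        n_dropped=n_dropped,
    )


_LANDIS_KOCH = (
    (0.0, "poor"),
    (0.2, "slight"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
)


def landis_koch_label(kappa: float) -> str:
    """Landis-Koch agreement band; intervals half-open on the right
    ([0.2, 0.4) is *fair*, [0.6, 0.8) *substantial*, [0.8, 1] almost
    perfect; anything below 0 is poor)."""
    if not (-1.0 <= kappa <= 1.0) or not math.isfinite(kappa):
        raise DomainError(f"kappa must lie in [-1, 1], got {kappa!r}")
    label = "almost perfect"
    for upper, name in reversed(_LANDIS_KOCH):
        if kappa < upper:
            label = name
    return label


@dataclass
class CorrelationResult:
    rho: float
    n: int
    p_value: float
    selection_rule: str


def independent_spearman(
    cohort: Cohort,
    x_measure: str,
    y_measure: str,
    selection_rule: str = "baseline",
    seed: int | None = None,
) -> CorrelationResult:
    """Spearman rank correlation on one visit per subject.

    ``selection_rule``: "baseline" takes each subject's first visit (subjects
    missing either measure there are dropped); "random_per_subject" picks,
    per subject, a uniform-random visit among those where both measures are
    present (seeded).
    """
    if selection_rule not in ("baseline", "random_per_subject"):
        raise ValueError(f"unknown selection rule {selection_rule!r}")
    rng = np.random.default_rng(seed)
    xs: list[float] = []
    ys: list[float] = []
    for sid, vs in cohort.by_subject().items():
        if selection_rule == "baseline":
            candidates = vs[:1]
        else:
            candidates = [
                v
                for v in vs
                if measure_value(v, x_measure) is not None
                and measure_value(v, y_measure) is not None
            ]
        if not candidates:
            continue
        if selection_rule == "random_per_subject" and len(candidates) > 1:
            v = candidates[rng.integers(len(candidates))]
        else:
            v = candidates[0]
        x = measure_value(v, x_measure)
        y = measure_value(v, y_measure)
        if x is None or y is None:
            continue
        xs.append(x)
        ys.append(y)
    if len(xs) < 3:
        raise ValueError(
            f"need >= 3 subjects with both measures, have {len(xs)}"
        )
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", stats.ConstantInputWarning)
        rho, p = stats.spearmanr(xs, ys)
    if not np.isfinite(rho):
        raise ValueError("correlation undefined: a selected measure is constant")
    return CorrelationResult(
        rho=float(rho), n=len(xs), p_value=float(p), selection_rule=selection_rule
    )
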