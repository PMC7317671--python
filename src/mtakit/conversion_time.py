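"""Progression-time arithmetic.

Two complementary estimates of how long medial-temporal atrophy takes to
become visible on a discrete 0-4 rating scale:

- ``full_score_time``: years to progress one full rating unit, the
  reciprocal of a continuous annual rating change.
- ``threshold_crossing_time``: years until the hippocampal (or ventricular)
  volume change reaches the crossover threshold past which a higher rating
  is the more likely outcome.

Under the latent-uniform view (an integer rating k stands for a continuous
trait uniform on [k, k+1), mean k + 0.5), the first estimate should be about
twice the second; ``reconciliation_ratio`` reports the observed ratio.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from .cohort_model import DomainError


@dataclass
class ConversionEstimate:
    at_group: str
    method: str  # "continuous_rate" | "threshold_rate"
    years: float  # may be math.inf
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        rate = self.inputs.get("rate")
        if rate and math.isfinite(self.years):
            if self.method == "continuous_rate":
                assert abs(self.years * rate - 1.0) < 1e-9
            elif self.method == "threshold_rate":
                thr = self.inputs.get("threshold")
                if thr is not None:
                    assert abs(self.years * abs(rate) - abs(thr)) < 1e-9


def full_score_time(mean_rate: float) -> float:
    """Years to advance one full rating unit at a continuous annual rate;
    infinite when the rate is zero or negative (no progression)."""
    if not math.isfinite(mean_rate):
        raise DomainError(f"rate must be finite, got {mean_rate!r}")
    if mean_rate <= 0:
        return math.inf
    return 1.0 / mean_rate


def threshold_crossing_time(threshold: float, rate: float) -> float:
    """Years for a volume changing at ``rate`` (mm³/year) to accumulate the
    crossover ``threshold`` (mm³); magnitudes are used, so either sign
    convention works. Infinite for a zero rate."""
    for name, v in (("threshold", threshold), ("rate", rate)):
        if not math.isfinite(v):
            raise DomainError(f"{name} must be finite, got {v!r}")
    if rate == 0:
        return math.inf
    return abs(threshold) / abs(rate)


def latent_uniform_mean(integer_score: int) -> float:
    """Expected continuous trait of an integer rating k under the
    uniform-on-[k, k+1) assumption: k + 0.5."""
    if integer_score not in (0, 1, 2, 3, 4):
        raise DomainError(f"integer score must be in 0..4, got {integer_score!r}")
    if integer_score == 4:
        warnings.warn(
            "score 4 is the end-stage category; its latent interval is "
            "closed in practice and k + 0.5 extrapolates beyond the scale"
        )
    return integer_score + 0.5


def reconciliation_ratio(full_time: float, threshold_time: float) -> float:
    """Ratio of the full-score time to the threshold-crossing time.

    Under the latent-uniform assumption the expectation is about 2 (the
    average subject sits halfway to the next rating boundary)."""
    for name, v in (("full_time", full_time), ("threshold_time", threshold_time)):
        if not (math.isfinite(v) and v > 0):
            raise DomainError(f"{name} must be positive and finite, got {v!r}")
    return full_time / threshold_time
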