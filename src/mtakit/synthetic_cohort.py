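"""Synthetic longitudinal cohort generator.

The generator emulates the statistical structure the analysis pipeline
assumes: three CSF A/T groups followed over four visits, a continuous
latent medial-temporal-atrophy (MTA) trait per hemisphere that progresses
linearly with time, hippocampal (HC) and inferior-lateral-ventricle (ILV)
volumes coupled to the trait (linearly and exponentially, respectively),
two biased discretising human raters plus one continuous automated rater,
and a per-image quality-control failure process.

The model, per subject i, hemisphere h, and time-since-baseline t:

    m_ih(t)   = m0_ih + r_ih * t                         (latent trait, [0,4])
    HC_ih(t)  = a_hc - b_hc * m_ih(t) + eps_hc           (mm³, linear loss)
    ILV_ih(t) = v0 * exp(g * m_ih(t)) + eps_ilv          (mm³, convex growth)
    auto      = clip(m_ih(t) + eps_auto, 0, 4)           (continuous rating)
    human_k   = clip(round(m_ih(t) + bias_k + eps_k), 0, 4)  (integer rating)

rounding half away from zero. Baselines m0 and rates r are drawn per group
and hemisphere, with left/right coupled through a shared subject-level
component (configurable correlation).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import stats

from .cohort_model import (
    ATGroup,
    Cohort,
    CSFCutoffs,
    Diagnosis,
    HEMISPHERES,
    SubjectProfile,
    VisitRecord,
)


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (NumPy's ``round`` rounds half to even)."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class HCLink:
    """Linear hippocampal-volume link: HC = intercept - slope * m + noise."""

    intercept: float = 4800.0  # mm³ at latent trait 0
    slope: float = 900.0  # mm³ lost per latent MTA unit
    noise_sd: float = 150.0  # mm³
    floor: float = 50.0  # mm³, lower bound after noise


@dataclass(frozen=True)
class ILVLink:
    """Exponential ventricle link: ILV = v0 * exp(growth * m) + noise."""

    v0: float = 170.0  # mm³ at latent trait 0
    growth: float = 1.2  # per latent MTA unit
    noise_sd: float = 80.0  # mm³
    floor: float = 1.0  # mm³


@dataclass(frozen=True)
class RaterModel:
    """Additive bias and noise of a discretising human rater (latent units)."""

    bias: float
    noise_sd: float = 0.3


@dataclass(frozen=True)
class GroupParams:
    """Per-CSF-group simulation parameters.

    ``latent_baseline`` / ``latent_rate`` map hemisphere to (mean, sd) of the
    latent MTA trait at baseline and of its annual change. CSF and cognition
    parameters are (mean, sd) of group-conditional normals; CSF draws are
    rejection-sampled to respect the configured A/T cut-offs.
    """

    n: int
    n_mci: int
    latent_baseline: Mapping[str, tuple[float, float]]
    latent_rate: Mapping[str, tuple[float, float]]
    csf_ab42_40: tuple[float, float]
    csf_ptau: tuple[float, float]
    mmse_baseline: tuple[float, float]
    mmse_rate: tuple[float, float]
    adas_baseline: tuple[float, float]
    adas_rate: tuple[float, float]


def default_group_params() -> dict[ATGroup, GroupParams]:
    """Study-condition defaults: group sizes, SCD/MCI split, baseline and
    annual-change distributions of the continuous rating, CSF chemistry and
    cognition, per CSF group."""
    return {
        ATGroup.AnTn: GroupParams(
            n=54,
            n_mci=12,
            latent_baseline={"left": (1.26, 0.58), "right": (1.26, 0.56)},
            latent_rate={"left": (0.04, 0.04), "right": (0.04, 0.04)},
            csf_ab42_40=(0.15, 0.03),
            csf_ptau=(35.7, 10.9),
            mmse_baseline=(28.57, 1.46),
            mmse_rate=(-0.15, 0.47),
            adas_baseline=(3.41, 2.39),
            adas_rate=(-0.04, 0.38),
        ),
        ATGroup.ApTn: GroupParams(
            n=18,
            n_mci=10,
            latent_baseline={"left": (1.39, 0.71), "right": (1.40, 0.64)},
            latent_rate={"left": (0.07, 0.05), "right": (0.08, 0.05)},
            csf_ab42_40=(0.09, 0.02),
            csf_ptau=(47.9, 14.4),
            mmse_baseline=(28.06, 1.75),
            mmse_rate=(-0.49, 0.70),
            adas_baseline=(5.17, 2.41),
            adas_rate=(0.14, 0.40),
        ),
        ATGroup.ApTp: GroupParams(
            n=21,
            n_mci=10,
            latent_baseline={"left": (1.20, 0.58), "right": (1.28, 0.64)},
            latent_rate={"left": (0.13, 0.08), "right": (0.11, 0.08)},
            csf_ab42_40=(0.07, 0.02),
            csf_ptau=(113.4, 27.6),
            mmse_baseline=(27.62, 2.06),
            mmse_rate=(-1.13, 1.02),
            adas_baseline=(5.38, 3.05),
            adas_rate=(0.39, 0.50),
        ),
    }


@dataclass
class SimulationConfig:
    """Full parameterisation of the synthetic cohort."""

    groups: dict[ATGroup, GroupParams] = field(default_factory=default_group_params)
    baseline_age_mean: float = 70.1  # years
    baseline_age_sd: float = 5.4
    age_range: tuple[float, float] = (60.0, 80.0)
    visit_offsets: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0)  # years
    hc_link: HCLink = field(default_factory=HCLink)
    ilv_link: ILVLink = field(default_factory=ILVLink)
    rater_models: dict[str, RaterModel] = field(
        default_factory=lambda: {
            "rad1": RaterModel(bias=0.1),
            "rad2": RaterModel(bias=-0.55),
        }
    )
    auto_rater: str = "avra"
    auto_noise_sd: float = 0.15  # latent units
    lr_correlation: float = 0.8  # left/right latent coupling
    qc_fail_prob: float = 33.0 / 372.0  # per image
    mmse_noise_sd: float = 0.8
    adas_noise_sd: float = 0.8
    dementia_latent_threshold: float = 2.5
    cutoffs: CSFCutoffs = field(default_factory=CSFCutoffs)
    seed: int = 0

    def validate(self) -> None:
        if not self.groups or any(g.n <= 0 for g in self.groups.values()):
            raise ValueError("every simulated group must be non-empty")
        offs = self.visit_offsets
        if len(offs) < 2 or offs[0] != 0 or any(
            b <= a for a, b in zip(offs, offs[1:])
        ):
            raise ValueError("visit_offsets must start at 0 and strictly increase")
        if not (0.0 <= self.qc_fail_prob <= 1.0):
            raise ValueError("qc_fail_prob must be a probability")
        if not (-1.0 < self.lr_correlation < 1.0 or self.lr_correlation in (-1.0, 1.0)):
            raise ValueError("lr_correlation must lie in [-1, 1]")
        sds = [self.auto_noise_sd, self.mmse_noise_sd, self.adas_noise_sd,
               self.hc_link.noise_sd, self.ilv_link.noise_sd]
        sds += [r.noise_sd for r in self.rater_models.values()]
        if any(s < 0 for s in sds):
            raise ValueError("noise standard deviations must be >= 0")


def scaled(config: SimulationConfig, factor: int) -> SimulationConfig:
    """A copy of ``config`` with every group size (and MCI count) multiplied
    by ``factor`` — used for large-sample parameter-recovery checks."""
    cfg = copy.deepcopy(config)
    cfg.groups = {
        g: replace(p, n=p.n * factor, n_mci=p.n_mci * factor)
        for g, p in cfg.groups.items()
    }
    return cfg


def _trunc_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    if sd == 0:
        return np.full(size, np.clip(mean, lo, hi))
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _correlated_pair(
    rng: np.random.Generator,
    mean_sd: Mapping[str, tuple[float, float]],
    rho: float,
    n: int,
) -> dict[str, np.ndarray]:
    """Draw left/right values with correlation rho via a shared component."""
    z_shared = rng.standard_normal(n)
    out = {}
    for hemi in HEMISPHERES:
        mean, sd = mean_sd[hemi]
        z_own = rng.standard_normal(n)
        z = rho * z_shared + np.sqrt(max(0.0, 1.0 - rho**2)) * z_own
        out[hemi] = mean + sd * z
    return out


def _csf_draw(
    rng: np.random.Generator, group: ATGroup, params: GroupParams, cutoffs: CSFCutoffs, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Group-conditional CSF values, truncated to respect the A/T cut-offs."""
    ab_cut, ptau_cut = cutoffs.ab42_40, cutoffs.ptau
    big = 1e9
    if group in (ATGroup.ApTn, ATGroup.ApTp):
        ab = _trunc_normal(rng, *params.csf_ab42_40, 1e-6, ab_cut - 1e-9, n)
    else:
        ab = _trunc_normal(rng, *params.csf_ab42_40, ab_cut, big, n)
    if group in (ATGroup.ApTp, ATGroup.AnTp):
        ptau = _trunc_normal(rng, *params.csf_ptau, ptau_cut + 1e-9, big, n)
    else:
        ptau = _trunc_normal(rng, *params.csf_ptau, 1e-6, ptau_cut, n)
    return ab, ptau


def generate_cohort(config: SimulationConfig | None = None) -> Cohort:
    """Draw a full synthetic cohort.

    Deterministic in ``config.seed``: identical configs produce identical
    cohorts. The result satisfies every :mod:`mtakit.cohort_model` invariant
    and round-trips through its CSV reader.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    offsets = np.asarray(config.visit_offsets)
    n_visits = len(offsets)

    subjects: dict[str, SubjectProfile] = {}
    visits: list[VisitRecord] = []
    sid_counter = 0

    for group in sorted(config.groups, key=lambda g: g.value):
        params = config.groups[group]
        n = params.n
        ages0 = _trunc_normal(
            rng, config.baseline_age_mean, config.baseline_age_sd,
            config.age_range[0], config.age_range[1], n,
        )
        m0 = _correlated_pair(rng, params.latent_baseline, config.lr_correlation, n)
        rate = _correlated_pair(rng, params.latent_rate, config.lr_correlation, n)
        for hemi in HEMISPHERES:
            m0[hemi] = np.clip(m0[hemi], 0.0, 4.0)  # truncate latent baseline

        # latent trajectories: (n, n_visits) per hemisphere
        m = {
            h: m0[h][:, None] + rate[h][:, None] * offsets[None, :]
            for h in HEMISPHERES
        }

        hc = {}
        ilv = {}
        auto = {}
        human: dict[str, dict[str, np.ndarray]] = {r: {} for r in config.rater_models}
        for h in HEMISPHERES:
            lk = config.hc_link
            hnoise = rng.normal(0.0, lk.noise_sd, m[h].shape) if lk.noise_sd > 0 else 0.0
            hc[h] = np.maximum(lk.intercept - lk.slope * m[h] + hnoise, lk.floor)
            il = config.ilv_link
            noise = rng.normal(0.0, il.noise_sd, m[h].shape) if il.noise_sd > 0 else 0.0
            ilv[h] = np.maximum(il.v0 * np.exp(il.growth * m[h]) + noise, il.floor)
            anoise = (
                rng.normal(0.0, config.auto_noise_sd, m[h].shape)
                if config.auto_noise_sd > 0
                else 0.0
            )
            auto[h] = np.clip(m[h] + anoise, 0.0, 4.0)
            for rater, rm in config.rater_models.items():
                rnoise = (
                    rng.normal(0.0, rm.noise_sd, m[h].shape) if rm.noise_sd > 0 else 0.0
                )
                human[rater][h] = np.clip(
                    round_half_away(m[h] + rm.bias + rnoise), 0.0, 4.0
                )

        ab, ptau = _csf_draw(rng, group, params, config.cutoffs, n)
        qc_pass = rng.random((n, n_visits)) >= config.qc_fail_prob

        mmse0 = _trunc_normal(rng, *params.mmse_baseline, 0.0, 30.0, n)
        mmse_r = rng.normal(*params.mmse_rate, n) if params.mmse_rate[1] > 0 else np.full(n, params.mmse_rate[0])
        adas0 = _trunc_normal(rng, *params.adas_baseline, 0.0, 40.0, n)
        adas_r = rng.normal(*params.adas_rate, n) if params.adas_rate[1] > 0 else np.full(n, params.adas_rate[0])
        mmse_noise = (
            rng.normal(0.0, config.mmse_noise_sd, (n, n_visits))
            if config.mmse_noise_sd > 0
            else np.zeros((n, n_visits))
        )
        adas_noise = (
            rng.normal(0.0, config.adas_noise_sd, (n, n_visits))
            if config.adas_noise_sd > 0
            else np.zeros((n, n_visits))
        )
        mmse = np.clip(
            round_half_away(mmse0[:, None] + mmse_r[:, None] * offsets[None, :] + mmse_noise),
            0,
            30,
        ).astype(int)
        adas = np.clip(
            adas0[:, None] + adas_r[:, None] * offsets[None, :] + adas_noise, 0.0, None
        )

        # within each group the subjects with the most advanced baseline
        # latent trait are labelled MCI (reproduces the MCI-worse pattern)
        mean_m0 = 0.5 * (m0["left"] + m0["right"])
        order = np.argsort(-mean_m0, kind="stable")
        is_mci = np.zeros(n, dtype=bool)
        is_mci[order[: params.n_mci]] = True

        latent_mean = 0.5 * (m["left"] + m["right"])
        dementia = latent_mean >= config.dementia_latent_threshold

        for i in range(n):
            sid = f"S{sid_counter:04d}"
            sid_counter += 1
            subjects[sid] = SubjectProfile(
                subject_id=sid,
                csf_ab42_40=float(ab[i]),
                csf_ptau=float(ptau[i]),
                at_group=group,
            )
            diagnosis = Diagnosis.MCI if is_mci[i] else Diagnosis.SCD
            for j in range(n_visits):
                ratings: dict[tuple[str, str], float] = {}
                for h in HEMISPHERES:
                    ratings[(config.auto_rater, h)] = float(auto[h][i, j])
                    for rater in config.rater_models:
                        ratings[(rater, h)] = float(human[rater][h][i, j])
                visits.append(
                    VisitRecord(
                        subject_id=sid,
                        visit_index=j,
                        age_at_scan=float(ages0[i] + offsets[j]),
                        diagnosis=diagnosis,
                        ratings=ratings,
                        hc_vol={h: float(hc[h][i, j]) for h in HEMISPHERES},
                        ilv_vol={h: float(ilv[h][i, j]) for h in HEMISPHERES},
                        qc_pass=bool(qc_pass[i, j]),
                        mmse=int(mmse[i, j]),
                        adas_dwr=float(adas[i, j]),
                        dementia_dx=bool(dementia[i, j]),
                    )
                )

    registry = {r: "discrete" for r in config.rater_models}
    registry[config.auto_rater] = "continuous"
    cohort = Cohort(subjects=subjects, visits=visits, rater_registry=registry)
    cohort.validate()
    return cohort


def _noise_free_config(seed: int = 0) -> SimulationConfig:
    cfg = SimulationConfig(seed=seed)
    cfg.groups = {
        g: replace(
            p,
            n=2,
            n_mci=1,
            latent_baseline={h: (ms[0], 0.0) for h, ms in p.latent_baseline.items()},
            latent_rate={h: (ms[0], 0.0) for h, ms in p.latent_rate.items()},
        )
        for g, p in cfg.groups.items()
    }
    cfg.rater_models = {
        "rad1": RaterModel(bias=0.0, noise_sd=0.0),
        "rad2": RaterModel(bias=0.0, noise_sd=0.0),
    }
    cfg.auto_noise_sd = 0.0
    cfg.hc_link = replace(cfg.hc_link, noise_sd=0.0)
    cfg.ilv_link = replace(cfg.ilv_link, noise_sd=0.0)
    cfg.mmse_noise_sd = 0.0
    cfg.adas_noise_sd = 0.0
    cfg.qc_fail_prob = 0.0
    return cfg


FIXTURES = ("tiny", "paper_like", "noise_free")


def make_fixture(name: str, seed: int = 7) -> Cohort:
    """Deterministic cohorts for tests.

    - ``tiny``: 3 subjects (one per CSF group), 4 visits.
    - ``paper_like``: 93 subjects with the default 54/18/21 group split.
    - ``noise_free``: 6 subjects, all noise and population spread zeroed, so
      ratings are exact functions of the latent trait.
    """
    if name == "tiny":
        cfg = SimulationConfig(seed=seed)
        cfg.groups = {g: replace(p, n=1, n_mci=0) for g, p in cfg.groups.items()}
        return generate_cohort(cfg)
    if name == "paper_like":
        return generate_cohort(SimulationConfig(seed=seed))
    if name == "noise_free":
        return generate_cohort(_noise_free_config(seed=seed))
    raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURES}")
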