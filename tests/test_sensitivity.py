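"""Delta pairs, per-class kernel densities, and crossover thresholds."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mtakit.sensitivity import (
    ClassDensities,
    compute_deltas,
    crossover_threshold,
    kde_by_delta_class,
)


class TestComputeDeltas:
    def test_pair_counts_and_arithmetic(self, noise_free_cohort):
        pairs = compute_deltas(noise_free_cohort, "rad1")
        # 6 subjects x 2 hemispheres x 3 follow-ups
        assert len(pairs) == 36
        assert (pairs.delta_t > 0).all()
        # percent fields consistent with mm3 fields and the baseline
        base = noise_free_cohort.by_subject()
        row = pairs.iloc[0]
        b = base[row.subject_id][0].hc_vol[row.hemisphere]
        assert row.delta_hc_pct == pytest.approx(100 * row.delta_hc / b)

    def test_volume_change_example(self):
        # -238 mm3 on a 3000 mm3 baseline is a 7.93% loss
        assert 100 * (2762 - 3000) / 3000 == pytest.approx(-7.93, abs=0.01)

    def test_rating_delta_is_integer_difference(self, paper_like_cohort):
        pairs = compute_deltas(paper_like_cohort, "rad2")
        assert pairs.delta_mta.dtype.kind == "i"
        vs = paper_like_cohort.by_subject()
        for _, row in pairs.head(10).iterrows():
            base = vs[row.subject_id][0].ratings[("rad2", row.hemisphere)]
            fu = next(
                v for v in vs[row.subject_id] if v.visit_index == row.visit_index
            ).ratings[("rad2", row.hemisphere)]
            assert row.delta_mta == fu - base

    def test_qc_failed_pairs_dropped_and_counted(self, paper_like_cohort):
        pairs = compute_deltas(paper_like_cohort, "rad1")
        n_total_potential = sum(
            2 * (len(vs) - 1) for vs in paper_like_cohort.by_subject().values()
        )
        assert len(pairs) + pairs.attrs["n_dropped_missing_volume"] == n_total_potential
        assert pairs.attrs["n_dropped_missing_volume"] > 0  # ~9% QC failures

    def test_subject_without_baseline_skipped(self, tiny_cohort):
        c = dataclasses.replace(
            tiny_cohort,
            visits=[
                v
                for v in tiny_cohort.visits
                if not (v.subject_id == tiny_cohort.visits[0].subject_id and v.visit_index == 0)
            ],
        )
        with pytest.warns(UserWarning, match="no baseline"):
            pairs = compute_deltas(c, "rad1")
        assert tiny_cohort.visits[0].subject_id not in set(pairs.subject_id)


def _pairs_from_samples(samples: dict[int, np.ndarray]) -> pd.DataFrame:
    rows = []
    for k, xs in samples.items():
        for x in xs:
            rows.append({"delta_mta": k, "delta_hc": x})
    return pd.DataFrame(rows)


class TestKDEByDeltaClass:
    def test_density_integrates_to_one_and_mode_near_truth(self):
        rng = np.random.default_rng(1)
        xs = rng.normal(0, 1, 10_000)
        pairs = _pairs_from_samples({0: xs, 1: rng.normal(-2, 1, 100)})
        dens = kde_by_delta_class(pairs, "delta_hc")
        f0 = dens.densities[0]
        integral = np.trapezoid(f0, dens.grid)
        assert integral == pytest.approx(1.0, abs=0.01)
        assert abs(dens.grid[np.argmax(f0)]) < 0.1

    def test_identical_classes_identical_curves(self):
        rng = np.random.default_rng(1)
        xs = rng.normal(0, 1, 500)
        pairs = _pairs_from_samples({0: xs, 1: xs.copy()})
        dens = kde_by_delta_class(pairs, "delta_hc")
        np.testing.assert_allclose(dens.densities[0], dens.densities[1])

    def test_priors_sum_to_one(self, paper_like_cohort):
        pairs = compute_deltas(paper_like_cohort, "rad1")
        dens = kde_by_delta_class(pairs, "delta_hc")
        assert sum(dens.priors.values()) == pytest.approx(1.0)
        assert sum(dens.counts.values()) + dens.n_excluded_negative == len(
            pairs.dropna(subset=["delta_hc"])
        )

    def test_small_class_merged_upward(self):
        rng = np.random.default_rng(2)
        pairs = _pairs_from_samples(
            {0: rng.normal(0, 1, 50), 1: rng.normal(-2, 1, 20), 2: rng.normal(-4, 1, 3)}
        )
        with pytest.warns(UserWarning, match="pooling"):
            dens = kde_by_delta_class(pairs, "delta_hc")
        assert dens.merged
        assert set(dens.densities) == {0, "1+"}
        assert dens.counts["1+"] == 23

    def test_negative_deltas_excluded(self):
        rng = np.random.default_rng(3)
        pairs = _pairs_from_samples(
            {0: rng.normal(0, 1, 50), 1: rng.normal(-2, 1, 20), -1: rng.normal(2, 1, 7)}
        )
        dens = kde_by_delta_class(pairs, "delta_hc")
        assert dens.n_excluded_negative == 7

    def test_unchanged_class_too_small_raises(self):
        pairs = _pairs_from_samples({0: np.arange(3.0), 1: np.arange(20.0)})
        with pytest.raises(ValueError, match="unchanged-rating"):
            kde_by_delta_class(pairs, "delta_hc")


def _analytic_densities(p0: float, mu_plus: float, grid_half: float = 8.0) -> ClassDensities:
    grid = np.linspace(-grid_half, grid_half, 2001)
    return ClassDensities(
        variable="delta_hc",
        grid=grid,
        densities={0: sps.norm.pdf(grid, 0, 1), 1: sps.norm.pdf(grid, mu_plus, 1)},
        priors={0: p0, 1: 1 - p0},
        counts={0: int(1000 * p0), 1: int(1000 * (1 - p0))},
    )


class TestCrossoverThreshold:
    def test_equal_priors_symmetric_midpoint(self):
        cross = crossover_threshold(_analytic_densities(0.5, -2.0), "loss")
        assert cross.threshold == pytest.approx(-1.0, abs=1e-3)
        assert not cross.no_crossover

    def test_prior_weighted_analytic_crossing(self):
        # 0.75 phi(x) = 0.25 phi(x+2)  =>  x = -(2 + ln 3)/2
        cross = crossover_threshold(_analytic_densities(0.75, -2.0), "loss")
        assert cross.threshold == pytest.approx(-(2 + math.log(3)) / 2, abs=1e-3)

    def test_growth_direction_mirrors_loss(self):
        cross = crossover_threshold(_analytic_densities(0.5, 2.0), "growth")
        assert cross.threshold == pytest.approx(1.0, abs=1e-3)

    def test_dominated_class_yields_no_crossover(self):
        grid = np.linspace(-5, 5, 501)
        f0 = sps.norm.pdf(grid, 0, 2)
        f1 = sps.norm.pdf(grid, 0, 1)  # dominated in both tails inside grid
        dens = ClassDensities(
            "delta_hc", grid, {0: f0, 1: f1}, {0: 0.9, 1: 0.1}, {0: 90, 1: 10}
        )
        cross = crossover_threshold(dens, "loss")
        assert cross.no_crossover
        assert cross.threshold is None

    def test_threshold_sign_respects_direction(self, paper_like_cohort):
        """Loss thresholds lie in the loss tail of the unchanged-rating
        class; growth thresholds in its growth tail."""
        pairs = compute_deltas(paper_like_cohort, "rad1")
        same = pairs[pairs.delta_mta == 0]
        dens_hc = kde_by_delta_class(pairs, "delta_hc")
        cross_hc = crossover_threshold(dens_hc, "loss")
        assert cross_hc.threshold < same.delta_hc.median()  # hippocampal loss
        dens_ilv = kde_by_delta_class(pairs, "delta_ilv")
        cross_ilv = crossover_threshold(dens_ilv, "growth")
        assert cross_ilv.threshold > same.delta_ilv.median()  # ventricular growth

    def test_kde_crossover_recovers_analytic_value(self):
        """KDE estimate on 1e5 draws from 0.75 N(0,1) + 0.25 N(-2,1)
        converges to the analytic weighted crossing."""
        rng = np.random.default_rng(123)
        pairs = _pairs_from_samples(
            {0: rng.normal(0, 1, 75_000), 1: rng.normal(-2, 1, 25_000)}
        )
        dens = kde_by_delta_class(pairs, "delta_hc")
        cross = crossover_threshold(dens, "loss")
        assert cross.threshold == pytest.approx(-(2 + math.log(3)) / 2, abs=0.05)

    def test_more_rater_noise_widens_class0_and_moves_raw_crossover_left(self):
        """Noisier raters widen the unchanged-rating volume-change density
        and push the raw-density HC crossover to larger loss magnitudes
        (two seeded generator configs). The prior-weighted crossing need not
        be monotone, because noise also inflates the rating-increase prior."""
        from mtakit.synthetic_cohort import SimulationConfig, RaterModel, generate_cohort, scaled

        thresholds = {}
        widths = {}
        for noise in (0.15, 0.6):
            cfg = scaled(SimulationConfig(seed=9), 10)
            cfg.rater_models = {
                "rad1": RaterModel(bias=0.1, noise_sd=noise),
                "rad2": RaterModel(bias=-0.55, noise_sd=noise),
            }
            cohort = generate_cohort(cfg)
            pairs = compute_deltas(cohort, "rad1")
            widths[noise] = pairs[pairs.delta_mta == 0].delta_hc.std()
            dens = kde_by_delta_class(pairs, "delta_hc")
            cross = crossover_threshold(dens, "loss", weighted=False)
            thresholds[noise] = cross.threshold
        assert widths[0.6] > widths[0.15]
        assert thresholds[0.6] < thresholds[0.15] < 0
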