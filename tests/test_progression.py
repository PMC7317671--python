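"""Per-subject slopes, the discrete-slope enumeration, Kruskal-Wallis group
comparison and Bonferroni correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mtakit.cohort_model import DomainError
from mtakit.progression import (
    EXACT_KW_MAX_N,
    bonferroni_threshold,
    enumerate_discrete_slopes,
    fit_all_slopes,
    fit_subject_slope,
    group_rate_summary,
    kruskal_wallis,
    timepoint_summary,
)


class TestFitSubjectSlope:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ((1, 1, 1, 1), 0.0),  # constant rating
            ((0, 1, 1, 1), 0.15),  # step after baseline
            ((0, 0, 1, 1), 0.2),  # step at mid follow-up
            ((0, 0, 0, 1), 0.15),  # step at final visit
        ],
    )
    def test_step_patterns_over_biennial_visits(self, values, expected):
        est = fit_subject_slope((70, 72, 74, 76), values)
        assert est.slope == pytest.approx(expected, abs=1e-12)
        assert est.n_points == 4
        assert est.baseline_value == values[0]

    def test_missing_values_dropped_pairwise(self):
        est = fit_subject_slope((70, 72, 74, 76), (1.0, None, 2.0, np.nan))
        assert est.n_points == 2
        assert est.slope == pytest.approx(0.25)

    def test_errors(self):
        with pytest.raises(DomainError):
            fit_subject_slope((70,), (1,))
        with pytest.raises(DomainError):
            fit_subject_slope((70, 70), (1, 2))  # zero age variance

    @given(
        shift=st.floats(-50, 50, allow_nan=False),
        scale=st.floats(0.1, 10, allow_nan=False),
        ys=st.lists(st.floats(-5, 5, allow_nan=False), min_size=3, max_size=6),
    )
    @settings(max_examples=100, deadline=None)
    def test_age_shift_invariance_and_value_equivariance(self, shift, scale, ys):
        ages = list(range(len(ys)))
        base = fit_subject_slope(ages, ys)
        shifted = fit_subject_slope([a + shift for a in ages], ys)
        assert shifted.slope == pytest.approx(base.slope, abs=1e-6)
        scaled_fit = fit_subject_slope(ages, [y * scale for y in ys])
        assert scaled_fit.slope == pytest.approx(base.slope * scale, rel=1e-6, abs=1e-9)

    def test_matches_scipy_linregress(self):
        rng = np.random.default_rng(5)
        x = np.sort(rng.uniform(60, 80, 6))
        y = rng.normal(0, 1, 6)
        est = fit_subject_slope(x, y)
        ref = sps.linregress(x, y)
        assert est.slope == pytest.approx(ref.slope)
        assert est.intercept == pytest.approx(ref.intercept)


class TestEnumerateDiscreteSlopes:
    def test_biennial_single_step(self):
        assert enumerate_discrete_slopes((0, 2, 4, 6), "single_step") == (0.0, 0.15, 0.2)

    def test_two_visits(self):
        assert enumerate_discrete_slopes((0, 1), "single_step") == (0.0, 1.0)

    def test_max2_superset_by_brute_force(self):
        got = set(enumerate_discrete_slopes((0, 2, 4, 6), "monotone_nondecreasing_max2"))
        assert {0.0, 0.15, 0.2} <= got
        # independent brute force over all 0/1/2 monotone sequences
        from itertools import product

        expected = set()
        for seq in product((0, 1, 2), repeat=4):
            if all(b >= a for a, b in zip(seq, seq[1:])):
                expected.add(round(fit_subject_slope((0, 2, 4, 6), seq).slope, 12))
        assert got == expected

    @given(
        offs=st.lists(
            st.floats(0.5, 10, allow_nan=False), min_size=1, max_size=4
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_contains_zero_and_bounded(self, offs):
        offsets = tuple(np.cumsum([0.0] + offs))
        min_gap = min(np.diff(offsets))
        slopes = enumerate_discrete_slopes(offsets, "single_step")
        assert 0.0 in slopes
        assert all(0.0 <= s <= 1.0 / min_gap + 1e-9 for s in slopes)

    def test_errors(self):
        with pytest.raises(ValueError):
            enumerate_discrete_slopes((), "single_step")
        with pytest.raises(ValueError):
            enumerate_discrete_slopes((0, 2), "cubic_pattern")


class TestBonferroni:
    def test_study_comparison_count(self):
        thr = bonferroni_threshold(0.05, 66)
        assert thr == pytest.approx(0.000758, abs=5e-7)
        assert float(f"{thr:.2g}") == 0.00076

    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 1, 0.05), (0.05, 5, 0.01)])
    def test_trivial_cases(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    @pytest.mark.parametrize("alpha,m", [(0.0, 5), (1.0, 5), (0.05, 0), (0.05, 1.5)])
    def test_domain(self, alpha, m):
        with pytest.raises(DomainError):
            bonferroni_threshold(alpha, m)


class TestKruskalWallis:
    def test_hand_ranked_example(self):
        """Fully separated groups of 3: H = 12/(N(N+1)) sum n_j (rbar_j - rbar)^2 = 7.2."""
        h, p = kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert h == pytest.approx(7.2)
        # exact permutation p: only the 3! fully separated orderings reach H >= 7.2
        assert p == pytest.approx(6 / 1680)

    def test_identical_distributions(self):
        h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_scipy_at_large_n(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(i * 0.3, 1, 40) for i in range(3)]
        h, p = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert h == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_exact_enumeration_consistent_with_chi2_direction(self):
        # small-sample exact p should broadly agree with the approximation
        groups = [[1.0, 2.0, 9.0], [3.0, 8.0, 10.0], [4.0, 5.0, 6.0]]
        assert sum(len(g) for g in groups) <= EXACT_KW_MAX_N
        h, p_exact = kruskal_wallis(groups)
        p_chi2 = float(sps.chi2.sf(h, df=2))
        assert 0 <= p_exact <= 1
        assert abs(p_exact - p_chi2) < 0.25


class TestGroupRateSummary:
    @staticmethod
    def _slopes_frame(values_by_group):
        rows = []
        groups = {}
        i = 0
        for g, vals in values_by_group.items():
            for v in vals:
                sid = f"S{i}"
                rows.append(
                    {"subject_id": sid, "measure": "m", "slope": v,
                     "intercept": 0.0, "n_points": 4, "baseline_value": 100.0}
                )
                groups[sid] = g
                i += 1
        return pd.DataFrame(rows), groups

    def test_fully_separated_groups(self):
        df, groups = self._slopes_frame(
            {"AnTn": [1, 2, 3], "ApTn": [4, 5, 6], "ApTp": [7, 8, 9]}
        )
        s = group_rate_summary(df, groups, "m", alpha=0.05, m=1)
        assert s.kw_h == pytest.approx(7.2)
        assert s.per_group["ApTp"]["mean"] == pytest.approx(8.0)
        assert s.per_group["AnTn"]["n"] == 3

    def test_percent_scale_uses_subject_baselines(self):
        df, groups = self._slopes_frame({"A": [1.0, 2.0], "B": [3.0, 4.0]})
        s = group_rate_summary(df, groups, "m", percent=True, m=1)
        # baselines are all 100 -> percent slope = slope
        assert s.per_group["A"]["mean"] == pytest.approx(1.5)

    def test_noise_free_group_means_equal_configured_rates(self, noise_free_cohort):
        from mtakit.synthetic_cohort import _noise_free_config

        cfg = _noise_free_config(seed=7)
        slopes = fit_all_slopes(noise_free_cohort, ["mta:avra:left"])
        groups = {s: p.at_group.value for s, p in noise_free_cohort.subjects.items()}
        s = group_rate_summary(slopes, groups, "mta:avra:left", m=1)
        for g, params in cfg.groups.items():
            assert s.per_group[g.value]["mean"] == pytest.approx(
                params.latent_rate["left"][0], abs=1e-12
            )

    def test_stratum_filtering(self, paper_like_cohort):
        slopes = fit_all_slopes(paper_like_cohort, ["mta:avra:left"])
        groups = {s: p.at_group.value for s, p in paper_like_cohort.subjects.items()}
        diag = {
            sid: vs[0].diagnosis.value
            for sid, vs in paper_like_cohort.by_subject().items()
        }
        s_all = group_rate_summary(slopes, groups, "mta:avra:left", m=66)
        s_mci = group_rate_summary(
            slopes, groups, "mta:avra:left", stratum="MCI", diagnosis=diag, m=66
        )
        n_all = sum(st["n"] for st in s_all.per_group.values())
        n_mci = sum(st["n"] for st in s_mci.per_group.values())
        assert n_mci == 32  # MCI subjects in the default split
        assert n_all == 93


class TestTimepointSummary:
    def test_constant_measure_has_zero_sd(self, noise_free_cohort):
        t = timepoint_summary(noise_free_cohort, "mta:avra:left")
        assert (t["sd"] == 0.0).all()

    def test_noise_free_means_increase_at_configured_rate(self, noise_free_cohort):
        from mtakit.synthetic_cohort import _noise_free_config

        cfg = _noise_free_config(seed=7)
        t = timepoint_summary(noise_free_cohort, "mta:avra:left").reset_index()
        for g, params in cfg.groups.items():
            rate = params.latent_rate["left"][0]
            base = params.latent_baseline["left"][0]
            sub = t[t.at_group == g.value].sort_values("visit_index")
            for _, row in sub.iterrows():
                expected = base + rate * cfg.visit_offsets[int(row.visit_index)]
                assert row["mean"] == pytest.approx(expected, abs=1e-12)

    def test_row_count_tiny(self, tiny_cohort):
        t = timepoint_summary(tiny_cohort, "mta:rad1:left").reset_index()
        combos = {
            (p.at_group.value, vs[0].diagnosis.value)
            for sid, vs in tiny_cohort.by_subject().items()
            for p in [tiny_cohort.subjects[sid]]
        }
        assert len(t) == len(combos) * 4
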