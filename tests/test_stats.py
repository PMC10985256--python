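"""Statistical battery: test selection, correction, reliability, responsiveness."""

import math

import numpy as np
import pytest

from acticohort import (
    bonferroni,
    compare_groups,
    icc,
    mdc_from_icc,
    odd_even_split,
    paired_change_test,
    responsiveness,
    sample_size_from_srm,
    spearman_matrix,
    srm,
)

from conftest import make_series


class TestCompareGroups:
    def test_identical_samples_tie_p_one(self):
        x = [1.0, 1.0, 2.0, 2.0, 3.0, 10.0, 10.0, 10.0]  # non-normal, tied
        res = compare_groups(x, x)
        assert res.test == "mann_whitney"
        assert res.pvalue == pytest.approx(1.0, abs=0.01)

    def test_separated_normals_use_welch(self, rng):
        x = rng.normal(0, 1, 50)
        y = rng.normal(5, 1, 50)
        res = compare_groups(x, y)
        assert res.test == "welch_t"
        assert res.pvalue < 1e-6

    def test_heavy_tails_trigger_mann_whitney(self, rng):
        x = rng.standard_cauchy(100)
        y = rng.standard_cauchy(100)
        assert compare_groups(x, y).test == "mann_whitney"

    def test_constant_group_takes_rank_path(self):
        res = compare_groups([2.0] * 10, [1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.test == "mann_whitney"

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_nominal_type_one_error(self, rng):
        """Under a shared null the rejection rate stays near alpha."""
        rejections = 0
        reps = 2000
        for _ in range(reps):
            x = rng.normal(0, 1, 15)
            y = rng.normal(0, 1, 15)
            if compare_groups(x, y).pvalue < 0.05:
                rejections += 1
        rate = rejections / reps
        assert 0.030 <= rate <= 0.070  # ~3 MC sigma around 0.05


class TestBonferroni:
    def test_arithmetic_and_cap(self):
        adj = bonferroni([0.01, 0.2], n_families=7)
        assert adj[0] == pytest.approx(0.07)
        assert adj[1] == 1.0

    def test_vector_equals_scalar_loop(self, rng):
        p = rng.uniform(0, 1, 40)
        loop = np.array([min(1.0, v * 7) for v in p])
        assert np.allclose(bonferroni(p, 7), loop)


class TestSpearman:
    def test_monotone_transform_is_perfect(self, rng):
        import pandas as pd

        x = rng.uniform(0, 10, 30)
        clin = pd.DataFrame({"sara": x})
        digi = pd.DataFrame({"m": np.exp(x)})
        rho, _ = spearman_matrix(clin, digi)
        assert rho.loc["sara", "m"] == pytest.approx(1.0)

    def test_independent_uniforms_near_zero(self, rng):
        import pandas as pd

        rho, _ = spearman_matrix(
            pd.DataFrame({"a": rng.uniform(size=1000)}),
            pd.DataFrame({"b": rng.uniform(size=1000)}),
        )
        assert abs(rho.loc["a", "b"]) < 0.1


class TestPairedChange:
    def test_no_change_is_null(self):
        x = np.arange(10.0)
        res = paired_change_test(x, x)
        assert res.mean_change == 0.0
        assert res.pvalue == 1.0

    def test_constant_shift_wilcoxon_significant(self):
        base = np.arange(20.0)
        res = paired_change_test(base, base + 1.0)
        assert res.test == "wilcoxon"
        assert res.pvalue < 0.001
        assert res.mean_change == pytest.approx(1.0)

    def test_missing_pairs_dropped(self):
        base = np.array([1.0, 2.0, 3.0, np.nan, 5.0])
        fu = base + 2.0
        res = paired_change_test(base, fu)
        assert res.n == 4

    def test_nominal_type_one_error(self, rng):
        rejections = 0
        reps = 2000
        for _ in range(reps):
            base = rng.normal(0, 1, 12)
            fu = base + rng.normal(0, 0.5, 12)
            if paired_change_test(base, fu).pvalue < 0.05:
                rejections += 1
        assert 0.030 <= rejections / reps <= 0.070


class TestIcc:
    def test_duplicated_column_is_one(self, rng):
        x = rng.normal(10, 3, 20)
        res = icc(np.column_stack([x, x]))
        assert res.icc == pytest.approx(1.0)
        assert res.mdc95 == pytest.approx(0.0, abs=1e-5)

    def test_recovers_variance_components(self, rng):
        n = 200
        subject = rng.normal(0, 3.0, n)  # between-variance 9
        pairs = np.column_stack(
            [subject + rng.normal(0, 1.0, n), subject + rng.normal(0, 1.0, n)]
        )
        assert icc(pairs).icc == pytest.approx(0.9, abs=0.05)

    def test_independent_columns_near_zero(self, rng):
        pairs = rng.normal(0, 1, (200, 2))
        assert abs(icc(pairs).icc) < 0.1

    def test_matches_pingouin_icc2(self, rng):
        import pandas as pd
        import pingouin as pg

        n = 12
        subject = rng.normal(0, 2, n)
        pairs = np.column_stack(
            [subject + rng.normal(0, 1, n), subject + 0.5 + rng.normal(0, 1, n)]
        )
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), 2),
                "rater": np.tile([0, 1], n),
                "value": pairs.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="value")
        mask = ref.Type.isin(["ICC2", "ICC(A,1)"])  # two-way random, absolute agreement, single
        icc2 = float(ref.loc[mask, "ICC"].iloc[0])
        assert icc(pairs).icc == pytest.approx(icc2, abs=1e-10)

    def test_too_few_pairs_rejected(self, rng):
        with pytest.raises(ValueError, match="5"):
            icc(rng.normal(0, 1, (4, 2)))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            icc(np.full((8, 2), 3.0))


class TestMdc:
    def test_perfect_reliability_no_mdc(self):
        assert mdc_from_icc(10.0, 1.0) == 0.0

    def test_closed_form_value(self):
        # sd=10, icc=0.84 -> sem=4, mdc = 1.96 * sqrt(2) * 4
        assert mdc_from_icc(10.0, 0.84) == pytest.approx(1.959964 * math.sqrt(2) * 4.0, rel=1e-5)

    def test_monotone_decreasing_in_icc(self):
        vals = [mdc_from_icc(10.0, r) for r in (0.0, 0.3, 0.6, 0.9, 1.0)]
        assert vals == sorted(vals, reverse=True)

    def test_negative_icc_clipped(self):
        assert mdc_from_icc(10.0, -0.5) == mdc_from_icc(10.0, 0.0)


class TestSrm:
    def test_symmetric_changes_zero(self):
        assert srm([-2.0, -1.0, 1.0, 2.0]) == 0.0

    def test_sign_follows_mean(self, rng):
        c = rng.normal(-1.0, 0.5, 50)
        assert srm(c) < 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            srm([1.0, 1.0, 1.0])


class TestSampleSize:
    def test_unit_srm_closed_form(self):
        assert sample_size_from_srm(1.0) == 16

    def test_low_srm_closed_form(self):
        assert sample_size_from_srm(0.09) == 1938

    def test_quarter_scaling_law(self):
        for s in (0.2, 0.4, 0.8):
            n1 = sample_size_from_srm(s)
            n4 = sample_size_from_srm(s / 2)
            assert abs(n4 - 4 * n1) <= 4  # up to ceiling effects

    def test_t_solver_at_least_normal(self):
        for s in (0.3, 0.5, 1.0):
            assert sample_size_from_srm(s, solver="t") >= sample_size_from_srm(s) - 1

    def test_half_delta_quadruples(self):
        n_full = sample_size_from_srm(0.5, delta=1.0)
        n_half = sample_size_from_srm(0.5, delta=0.5)
        assert abs(n_half - 4 * n_full) <= 4

    def test_zero_srm_rejected(self):
        with pytest.raises(ValueError):
            sample_size_from_srm(0.0)

    def test_responsiveness_categories(self, rng):
        large = responsiveness(rng.normal(2.0, 1.0, 5000))
        low = responsiveness(rng.normal(0.2, 1.0, 5000))
        assert large.category == "large"
        assert low.category == "low"


class TestOddEvenSplit:
    def _week(self, pattern):
        """7-day series (Mon-Sun); pattern maps weekday -> axis1 level."""
        days = [np.full(1440, pattern(d)) for d in range(7)]
        axis1 = np.concatenate(days)
        return make_series(axis1, wear=np.ones(axis1.size, dtype=bool))

    def test_identical_days_give_identical_halves(self):
        s = self._week(lambda d: 500)
        odd, even = odd_even_split(s)
        assert odd.pct_light == even.pct_light
        assert odd.vm3 == pytest.approx(even.vm3)
        assert odd.wear_days == even.wear_days == 3

    def test_missing_even_days_error(self):
        s = self._week(lambda d: 500)
        wear = np.ones(len(s), dtype=bool)
        for d in (1, 3, 5):  # strip Tue/Thu/Sat wear
            wear[d * 1440 : (d + 1) * 1440] = False
        s = make_series(s.axis1, wear=wear)
        with pytest.raises(ValueError, match="parities"):
            odd_even_split(s)

    def test_matches_manual_partition(self, rng):
        from acticohort import summarize_subject

        axis1 = rng.integers(0, 4000, 7 * 1440)
        s = make_series(axis1, wear=np.ones(axis1.size, dtype=bool))
        odd, even = odd_even_split(s)
        dates = sorted(set(s.timestamps.date))
        manual_odd = summarize_subject(s, day_filter={d for d in dates if d.weekday() in (0, 2, 4)})
        assert odd.vm3 == pytest.approx(manual_odd.vm3)
        assert odd.n_bouts == manual_odd.n_bouts
        # Sunday belongs to neither half
        assert odd.wear_days + even.wear_days == 6
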