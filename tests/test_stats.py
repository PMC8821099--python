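"""Statistical kernels and the group-comparison battery."""

import math

import numpy as np
import pandas as pd
import pytest

from alpsim import (
    ComputationError,
    InputError,
    ParameterError,
    bonferroni_alpha,
    chi_square_2x2,
    compare_groups,
    correlate_clinical,
    format_threshold,
    pearson_r,
    t_test_independent,
)
from alpsim.cohort import CohortConfig, simulate_cohort
from alpsim.io import cohort_to_frame
from scipy import stats as sps


def closed_form_t(a, b):
    """Textbook pooled-variance two-sample t and its two-tailed p."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    return t, df, 2 * sps.t.sf(abs(t), df)


def closed_form_pearson(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    r = np.cov(x, y)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
    n = x.size
    t = r * math.sqrt((n - 2) / (1 - r**2))
    return r, 2 * sps.t.sf(abs(t), n - 2)


class TestTTest:
    def test_identical_samples(self):
        res = t_test_independent([1.0, 2, 3], [1.0, 2, 3])
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_worked_example(self):
        res = t_test_independent([1, 2, 3], [2, 3, 4])
        assert res.t == pytest.approx(-1.224744871, abs=1e-6)
        assert res.df == 4
        assert res.p == pytest.approx(0.2878641347, abs=1e-5)

    def test_antisymmetry(self):
        a, b = [1.0, 2, 3, 7], [2.0, 3, 4]
        r1 = t_test_independent(a, b)
        r2 = t_test_independent(b, a)
        assert r2.t == pytest.approx(-r1.t)
        assert r2.p == pytest.approx(r1.p)

    def test_zero_variance_equal_means(self):
        res = t_test_independent([2.0, 2.0], [2.0, 2.0, 2.0])
        assert (res.t, res.p) == (0.0, 1.0)

    def test_zero_variance_unequal_means_rejected(self):
        with pytest.raises(ComputationError):
            t_test_independent([1.0, 1.0], [2.0, 2.0])

    def test_too_small_sample_rejected(self):
        with pytest.raises(InputError):
            t_test_independent([1.0], [1.0, 2.0])

    def test_agrees_with_closed_form_on_random_inputs(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            na, nb = rng.integers(2, 30, size=2)
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), na)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), nb)
            res = t_test_independent(a, b)
            t, df, p = closed_form_t(a, b)
            assert res.t == pytest.approx(t, abs=1e-6)
            assert res.df == df
            assert res.p == pytest.approx(p, abs=1e-6)

    def test_welch_flag_changes_df(self):
        a = [1.0, 2, 3, 4, 10]
        b = [2.0, 2.1, 2.2]
        pooled = t_test_independent(a, b)
        welch = t_test_independent(a, b, welch=True)
        assert pooled.df == 6
        assert welch.df != pooled.df


class TestChiSquare:
    def test_balanced_table(self):
        res = chi_square_2x2([[10, 10], [10, 10]])
        assert res.chi2 == 0.0
        assert res.p == pytest.approx(1.0)

    def test_sex_distribution_worked_example(self):
        # men/women by group: chi2 = N(ad-bc)^2 / product of marginals
        res = chi_square_2x2([[28, 21], [21, 17]])
        n, ad_bc = 87, 28 * 17 - 21 * 21
        expected = n * ad_bc**2 / (49 * 38 * 49 * 38)
        assert res.chi2 == pytest.approx(expected, abs=1e-6)
        assert res.chi2 == pytest.approx(0.03074, abs=1e-5)
        assert res.df == 1
        assert res.p == pytest.approx(0.861, abs=5e-4)

    def test_zero_marginal_rejected(self):
        with pytest.raises(InputError):
            chi_square_2x2([[0, 0], [5, 7]])


class TestPearson:
    @pytest.mark.parametrize(
        "x,y,expected_r",
        [
            ([1, 2, 3, 4], [3, 5, 7, 9], 1.0),       # y = 2x + 1
            ([1, 2, 3, 4], [-1, -2, -3, -4], -1.0),  # y = -x
        ],
    )
    def test_perfect_correlation(self, x, y, expected_r):
        assert pearson_r(x, y).r == pytest.approx(expected_r)

    def test_worked_example(self):
        res = pearson_r([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res.r == pytest.approx(0.8)
        # closed form: t = 0.8*sqrt(3/0.36) on 3 df, two-tailed
        assert res.p == pytest.approx(closed_form_pearson(
            [1, 2, 3, 4, 5], [2, 1, 4, 3, 5])[1], abs=1e-12)
        assert res.p == pytest.approx(0.104088, abs=1e-5)

    def test_constant_sample_rejected(self):
        with pytest.raises(InputError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_agrees_with_closed_form_on_random_inputs(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = rng.integers(3, 40)
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            res = pearson_r(x, y)
            r, p = closed_form_pearson(x, y)
            assert res.r == pytest.approx(r, abs=1e-6)
            assert res.p == pytest.approx(p, abs=1e-6)


class TestBonferroni:
    def test_single_comparison(self):
        assert bonferroni_alpha(0.05, 1) == 0.05

    def test_nine_comparisons_display(self):
        thr = bonferroni_alpha(0.05, 9)
        assert thr == pytest.approx(0.05 / 9)
        assert format_threshold(thr) == "0.0055"

    def test_monotone_in_m(self):
        assert bonferroni_alpha(0.05, 10) < bonferroni_alpha(0.05, 9)

    @pytest.mark.parametrize("alpha,m", [(0.0, 3), (1.0, 3), (0.05, 0)])
    def test_invalid_inputs_rejected(self, alpha, m):
        with pytest.raises(ParameterError):
            bonferroni_alpha(alpha, m)


def fast_frames(seed, esrd_profile_=None):
    from alpsim.cohort import ArmConfig
    from alpsim.phantom import control_profile, esrd_profile

    cfg = CohortConfig(seed=seed)
    if esrd_profile_ is not None:
        cfg = CohortConfig(
            esrd=ArmConfig(label="ESRD", n=49, profile=esrd_profile_,
                           age_mean=60.0, age_sd=8.1, male_fraction=28 / 49),
            control=cfg.control, seed=seed,
        )
    frame = cohort_to_frame(simulate_cohort(cfg, fidelity="fast").records)
    return frame[frame.arm == "ESRD"], frame[frame.arm == "control"]


class TestCompareGroups:
    def test_identical_cohorts_all_null(self):
        esrd, _ = fast_frames(0)
        report = compare_groups(esrd, esrd, continuous=["alps", "age_years"],
                                categorical=["male"])
        for _, row in report.comparisons.iterrows():
            assert row.statistic == pytest.approx(0.0, abs=1e-12)
            assert row.p == pytest.approx(1.0)

    def test_missing_variable_named_in_error(self):
        esrd, control = fast_frames(0)
        with pytest.raises(InputError, match="nope"):
            compare_groups(esrd, control, continuous=["nope"])

    def test_power_under_calibrated_defaults(self):
        # the default two-arm configuration should flag the ALPS
        # difference in >95% of seeds
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            esrd, control = fast_frames(seed)
            report = compare_groups(esrd, control, continuous=["alps"])
            hits += bool(report.comparisons.iloc[0].significant)
        assert hits / n_seeds > 0.95

    def test_type_i_error_under_null(self):
        # both arms from the control profile: ALPS flagged in ~5% of seeds
        from alpsim.phantom import control_profile

        hits = 0
        n_seeds = 200
        for seed in range(n_seeds):
            esrd, control = fast_frames(seed, esrd_profile_=control_profile())
            report = compare_groups(esrd, control, continuous=["alps"])
            hits += bool(report.comparisons.iloc[0].significant)
        assert hits / n_seeds == pytest.approx(0.05, abs=0.04)

    def test_corrected_threshold_applied_only_to_listed_variables(self):
        esrd, control = fast_frames(1)
        report = compare_groups(
            esrd, control,
            continuous=["alps", "dxx_projection"],
            corrected=[f"v{i}" for i in range(8)] + ["dxx_projection"],
        )
        rows = report.comparisons.set_index("variable")
        assert rows.loc["alps", "threshold"] == 0.05
        assert rows.loc["dxx_projection", "threshold"] == pytest.approx(0.05 / 9)


class TestCorrelateClinical:
    def test_self_correlation(self):
        esrd, _ = fast_frames(2)
        esrd = esrd.assign(alps_copy=esrd.alps)
        table = correlate_clinical(esrd, ["alps_copy"])
        assert table.iloc[0].r == pytest.approx(1.0)

    def test_null_correlation_distribution(self):
        # rho = 0: |r| < 0.3 in at least 95% of n=49 cohorts
        small = 0
        n_seeds = 100
        for seed in range(n_seeds):
            cfg = CohortConfig(seed=seed, rho=0.0)
            frame = cohort_to_frame(simulate_cohort(cfg, fidelity="fast").records)
            esrd = frame[frame.arm == "ESRD"]
            table = correlate_clinical(esrd, ["pth_pg_ml"])
            small += bool(abs(table.iloc[0].r) < 0.3)
        assert small / n_seeds >= 0.95

    def test_constant_variable_flagged_not_fatal(self):
        esrd, _ = fast_frames(3)
        esrd = esrd.assign(constant=1.0)
        table = correlate_clinical(esrd, ["constant", "pth_pg_ml"])
        assert bool(table.iloc[0].flagged)
        assert not bool(table.iloc[1].flagged)
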