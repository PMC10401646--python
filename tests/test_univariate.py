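"""ROI-level means, repeated-measures ANOVA, post hocs, FDR and power."""

import numpy as np
import pandas as pd
import pytest

from placemem.glm import TrialEstimates, single_trial_estimates
from placemem.roi import ROIMask
from placemem.simulate import simulate_dataset
from placemem.univariate import (build_cohort_table,
                                 extract_roi_condition_means, fdr_threshold,
                                 paired_posthoc, required_sample_size,
                                 rm_anova)


def _estimates(t_values, conditions, runs=None):
    n = len(conditions)
    info = pd.DataFrame(dict(
        condition=conditions,
        stim_id=[f"s{i}" for i in range(n)],
        run_index=runs if runs is not None else [1] * n,
    ))
    return TrialEstimates(betas=t_values.copy(), t_values=t_values, info=info)


def _random_table(rng, n_subj=8, factors=("condition",), levels=(3,)):
    rows = []
    from itertools import product
    level_sets = [[f"{f}{i}" for i in range(k)] for f, k in zip(factors, levels)]
    for s in range(n_subj):
        for combo in product(*level_sets):
            row = dict(subject=s, mean_t=rng.standard_normal())
            row.update(dict(zip(factors, combo)))
            rows.append(row)
    return pd.DataFrame(rows)


class TestExtractRoiConditionMeans:
    def test_all_zero_data(self):
        est = _estimates(np.zeros((4, 6)), ["a", "a", "b", "b"])
        tab = extract_roi_condition_means(est, [ROIMask("r", np.arange(3))])
        assert (tab.mean_t == 0).all()

    def test_single_voxel_mask_reduction(self):
        rng = np.random.default_rng(0)
        t = rng.standard_normal((6, 5))
        est = _estimates(t, ["a", "b", "a", "b", "a", "b"])
        tab = extract_roi_condition_means(est, [ROIMask("v2", np.array([2]))])
        expect_a = t[[0, 2, 4], 2].mean()
        assert tab.set_index("condition").loc["a", "mean_t"] == pytest.approx(expect_a)

    def test_planted_monotone_profile(self, small_truth_factory):
        truth = small_truth_factory(sigma_white=0.3)
        ds = simulate_dataset(truth, n_runs=4, seed=2)
        est = single_trial_estimates(ds)
        tab = extract_roi_condition_means(
            est, [ROIMask("memory", truth.roi_voxels["memory"])])
        vals = tab.set_index("condition").mean_t
        assert vals["image"] < vals["panorama"] < vals["street"]

    def test_empty_mask_rejected(self):
        est = _estimates(np.zeros((2, 3)), ["a", "b"])
        with pytest.raises(ValueError, match="empty"):
            extract_roi_condition_means(est, [ROIMask("e", np.array([], dtype=int))])

    def test_collapse_hemisphere(self):
        est = _estimates(np.arange(8.0).reshape(2, 4), ["a", "a"])
        left = ROIMask("r", np.array([0, 1]), hemisphere="left")
        right = ROIMask("r", np.array([2, 3]), hemisphere="right")
        tab = extract_roi_condition_means(est, [left, right],
                                          collapse_hemisphere=True)
        assert len(tab) == 1
        assert tab.mean_t.iloc[0] == pytest.approx(np.arange(8.0).reshape(2, 4).mean())


class TestRmAnova:
    def test_constant_cells_give_zero_f(self):
        tab = _random_table(np.random.default_rng(0), n_subj=5)
        tab["mean_t"] = 3.14
        res = rm_anova(tab)
        assert (res.F == 0).all()
        assert (res.p == 1.0).all()

    @pytest.mark.parametrize("factors,levels", [
        (("condition",), (3,)),
        (("condition", "roi"), (3, 2)),
        (("condition", "roi", "hemisphere"), (3, 2, 2)),
    ])
    def test_matches_reference_implementation(self, factors, levels):
        AnovaRM = pytest.importorskip("statsmodels.stats.anova").AnovaRM
        rng = np.random.default_rng(42)
        for rep in range(17):
            tab = _random_table(rng, n_subj=rng.integers(4, 9),
                                factors=factors, levels=levels)
            mine = rm_anova(tab, within=list(factors))
            ref = AnovaRM(tab, "mean_t", "subject",
                          within=list(factors)).fit().anova_table
            for _, row in mine.iterrows():
                key = row.effect.replace(" x ", ":")
                assert row.F == pytest.approx(ref.loc[key, "F Value"], abs=1e-6)
                assert row.p == pytest.approx(ref.loc[key, "Pr > F"], abs=1e-6)
                assert row.df_num == int(ref.loc[key, "Num DF"])
                assert row.df_den == int(ref.loc[key, "Den DF"])

    def test_unbalanced_table_rejected(self):
        tab = _random_table(np.random.default_rng(0), n_subj=4)
        with pytest.raises(ValueError, match="balanced"):
            rm_anova(tab.iloc[:-1])

    def test_two_level_f_equals_squared_paired_t(self):
        rng = np.random.default_rng(5)
        tab = _random_table(rng, n_subj=9, factors=("roi",), levels=(2,))
        res = rm_anova(tab, within=["roi"])
        (pt,) = paired_posthoc(
            tab, [("d", dict(roi="roi0"), dict(roi="roi1"))], correction="none")
        assert res.F.iloc[0] == pytest.approx(pt.t**2, abs=1e-8)
        assert res.p.iloc[0] == pytest.approx(pt.p, abs=1e-10)

    def test_type_one_error_calibration(self):
        # null tables: rejection rate of the condition effect at alpha = .05
        rng = np.random.default_rng(11)
        rejections = 0
        n_tables = 2000
        for _ in range(n_tables):
            tab = _random_table(rng, n_subj=10)
            res = rm_anova(tab)
            rejections += res.p.iloc[0] < 0.05
        assert rejections / n_tables == pytest.approx(0.05, abs=0.02)


class TestPairedPosthoc:
    def test_identical_vectors(self):
        tab = _random_table(np.random.default_rng(0), factors=("roi",), levels=(2,))
        wide = tab.pivot(index="subject", columns="roi", values="mean_t")
        tab.loc[tab.roi == "roi1", "mean_t"] = wide["roi0"].to_numpy()
        (res,) = paired_posthoc(tab, [("d", dict(roi="roi0"), dict(roi="roi1"))])
        assert res.t == 0 and res.cohens_d == 0 and res.p_corrected == 1.0

    def test_bonferroni_multiplies(self):
        rng = np.random.default_rng(1)
        tab = _random_table(rng, n_subj=12)
        contrasts = [
            (f"{a}-{b}", dict(condition=a), dict(condition=b))
            for a, b in [("condition0", "condition1"),
                         ("condition0", "condition2"),
                         ("condition1", "condition2")]
        ]
        res = paired_posthoc(tab, contrasts)
        for r in res:
            assert r.p_corrected == pytest.approx(min(1.0, 3 * r.p))
            # Bonferroni never decreases p
            assert r.p_corrected >= r.p

    def test_matches_scipy_ttest_rel(self):
        from scipy.stats import ttest_rel
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = rng.integers(5, 20)
            a, b = rng.standard_normal((2, n))
            tab = pd.concat([
                pd.DataFrame(dict(subject=range(n), roi="A", mean_t=a)),
                pd.DataFrame(dict(subject=range(n), roi="B", mean_t=b)),
            ])
            (res,) = paired_posthoc(
                tab, [("AB", dict(roi="A"), dict(roi="B"))], correction="none")
            ref = ttest_rel(a, b)
            assert res.t == pytest.approx(ref.statistic, abs=1e-8)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-8)
            d = (a - b).mean() / (a - b).std(ddof=1)
            assert res.cohens_d == pytest.approx(d, abs=1e-8)

    def test_difference_of_differences(self):
        rng = np.random.default_rng(3)
        tab = _random_table(rng, n_subj=10, factors=("condition", "roi"),
                            levels=(2, 2))
        (res,) = paired_posthoc(tab, [(
            "dod",
            (dict(roi="roi0", condition="condition1"),
             dict(roi="roi0", condition="condition0")),
            (dict(roi="roi1", condition="condition1"),
             dict(roi="roi1", condition="condition0")),
        )], correction="none")
        wide = tab.pivot_table(index="subject", columns=["roi", "condition"],
                               values="mean_t")
        manual = (wide[("roi0", "condition1")] - wide[("roi0", "condition0")]
                  - wide[("roi1", "condition1")] + wide[("roi1", "condition0")])
        from scipy.stats import ttest_1samp
        ref = ttest_1samp(manual, 0.0)
        assert res.t == pytest.approx(ref.statistic, abs=1e-10)

    def test_too_few_pairs(self):
        tab = pd.DataFrame(dict(subject=[0, 0], roi=["A", "B"], mean_t=[1.0, 2.0]))
        with pytest.raises(ValueError, match="pairs"):
            paired_posthoc(tab, [("AB", dict(roi="A"), dict(roi="B"))])


class TestFdrThreshold:
    def test_hand_computed_step_up(self):
        mask, crit = fdr_threshold(np.array([0.001, 0.04, 0.5]), q=0.05)
        assert list(mask) == [True, False, False]
        assert crit == pytest.approx(0.001)

    def test_uniform_small_p_all_pass(self):
        mask, crit = fdr_threshold(np.full(20, 0.01), q=0.05)
        assert mask.all() and crit == pytest.approx(0.01)

    def test_all_ones_none_pass(self):
        mask, crit = fdr_threshold(np.ones(10), q=0.05)
        assert not mask.any() and crit == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fdr_threshold(np.array([]))

    def test_mask_monotone_in_q(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200) ** 2
        prev = np.zeros(200, dtype=bool)
        for q in (0.01, 0.05, 0.1, 0.2):
            mask, _ = fdr_threshold(p, q)
            assert (prev <= mask).all()
            prev = mask

    def test_matches_reference_implementation(self):
        multipletests = pytest.importorskip(
            "statsmodels.stats.multitest").multipletests
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(3, 100)) ** rng.integers(1, 4)
            mask, _ = fdr_threshold(p, 0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            assert (mask == ref).all()


class TestRequiredSampleSize:
    def test_published_effect_size(self):
        assert required_sample_size(0.76, power=0.80, alpha=0.05) == 16

    def test_medium_effect(self):
        assert required_sample_size(0.5, power=0.80, alpha=0.05) == 34

    def test_monotone_in_effect_size(self):
        ns = [required_sample_size(d) for d in (0.3, 0.5, 0.8, 1.2)]
        assert ns == sorted(ns, reverse=True)

    def test_matches_reference_power_solver(self):
        TTestPower = pytest.importorskip("statsmodels.stats.power").TTestPower
        solver = TTestPower()
        for d in (0.4, 0.76, 1.0):
            n = required_sample_size(d)
            assert solver.power(d, n, 0.05) >= 0.80
            assert solver.power(d, n - 1, 0.05) < 0.80

    @pytest.mark.parametrize("bad", [dict(effect_size_d=0),
                                     dict(effect_size_d=0.5, power=1.0),
                                     dict(effect_size_d=0.5, alpha=0.0)])
    def test_validation(self, bad):
        with pytest.raises(ValueError):
            required_sample_size(**bad)


def test_build_cohort_table_adds_subject():
    t0 = pd.DataFrame(dict(roi=["r"], hemisphere=["both"], condition=["a"],
                           mean_t=[1.0]))
    tab = build_cohort_table({0: t0, 1: t0})
    assert set(tab.subject) == {0, 1}
    assert len(tab) == 2
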