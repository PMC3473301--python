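"""Cross-validation metrics, arcsine transform, mixed ANOVA, Tukey, F-test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from codingseq import synthetic
from codingseq.evaluation import (
    _metrics,
    mixed_anova,
    run_cv,
    score_densities,
    transform_performance,
    tukey_hsd,
    variance_f_test,
)


class TestMetricsAndRunCv:
    def test_perfect_classifier_metrics(self):
        y = np.r_[np.ones(10), -np.ones(50)].astype(int)
        pct, sens, spec = _metrics(y, y)
        assert (pct, sens, spec) == (100.0, 100.0, 100.0)

    def test_constant_negative_classifier_on_one_to_five_design(self):
        y = np.r_[np.ones(10), -np.ones(50)].astype(int)
        pred = -np.ones(60, dtype=int)
        pct, sens, spec = _metrics(y, pred)
        assert pct == pytest.approx(83.33, abs=0.01)
        assert sens == 0.0 and spec == 100.0

    def test_record_count_equals_folds(self, small_contrast_fixture):
        table = run_cv(small_contrast_fixture, "imm", "codon", folds=5, seed=0)
        assert len(table) == 5
        assert set(table.columns) >= {"species", "method", "representation",
                                      "fold", "percent_correct", "sensitivity",
                                      "specificity"}
        # percent correct is the class-count weighted mix of sens and spec
        for r in table.itertuples():
            mixed = (r.sensitivity * 1 + r.specificity * 5) / 6
            assert r.percent_correct == pytest.approx(mixed, abs=1e-9)

    def test_unknown_method_rejected(self, small_contrast_fixture):
        with pytest.raises(ValueError):
            run_cv(small_contrast_fixture, "svm", "codon")


class TestScoreDensities:
    def test_identical_samples_overlap_one(self, rng):
        s = rng.normal(size=200)
        scores = np.r_[s, s]
        labels = np.r_[np.ones(200), -np.ones(200)]
        _, _, ov = score_densities(scores, labels)
        assert ov == pytest.approx(1.0)

    def test_disjoint_supports_overlap_zero(self, rng):
        scores = np.r_[rng.normal(1000.0, 0.1, 100), rng.normal(-1000.0, 0.1, 100)]
        labels = np.r_[np.ones(100), -np.ones(100)]
        _, _, ov = score_densities(scores, labels)
        assert ov < 1e-6

    def test_overlap_symmetric_in_classes(self, rng):
        scores = np.r_[rng.normal(0, 1, 150), rng.normal(1, 2, 150)]
        labels = np.r_[np.ones(150), -np.ones(150)]
        _, _, ov1 = score_densities(scores, labels)
        _, _, ov2 = score_densities(scores, -labels)
        assert ov1 == pytest.approx(ov2, abs=1e-12)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            score_densities(np.ones(5), np.ones(5))


class TestTransformPerformance:
    @pytest.mark.parametrize("y,z", [(100.0, np.pi / 2), (50.0, np.pi / 4), (0.0, 0.0)])
    def test_known_values(self, y, z):
        assert transform_performance(y) == pytest.approx(z, abs=1e-4)

    def test_monotone(self):
        ys = np.linspace(0, 100, 51)
        zs = transform_performance(ys)
        assert (np.diff(zs) > 0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            transform_performance(101.0)

    def test_variance_stabilization_for_binomial_proportions(self, rng):
        # variance of z across binomial proportions is flatter than that of y
        n = 200
        ratios = []
        for p in (0.6, 0.8, 0.95, 0.99):
            y = 100 * rng.binomial(n, p, size=4000) / n
            z = transform_performance(np.clip(y, 0, 100))
            ratios.append((np.var(y), np.var(z)))
        y_spread = max(r[0] for r in ratios) / min(r[0] for r in ratios)
        z_spread = max(r[1] for r in ratios) / min(r[1] for r in ratios)
        assert z_spread < y_spread


def _statsmodels_anova_oracle(cells):
    """Eq-style least squares on dummy-coded factors (independent route)."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    model = smf.ols(
        "z ~ C(method) + C(representation) + C(method):C(representation)"
        " + C(species)",
        data=cells,
    ).fit()
    return sm.stats.anova_lm(model, typ=1)


class TestMixedAnova:
    def test_residual_df_55_for_full_design(self):
        cells = synthetic.planted_performance_panel(n_species=12, seed=0)
        res = mixed_anova(cells)
        assert res.table.loc["Residual", "df"] == 55
        assert res.table.loc["Species", "df"] == 11
        assert res.table["df"].sum() == 2 * 3 * 12 - 1

    def test_constant_table_gives_zero_sums_of_squares(self):
        cells = synthetic.planted_performance_panel(
            n_species=4, sigma_species=0, sigma_residual=0,
            method_effect=0, representation_effect=0, interaction_effect=0,
            seed=0,
        )
        res = mixed_anova(cells)
        assert res.table["sum_sq"].abs().max() == pytest.approx(0.0, abs=1e-24)

    def test_matches_dummy_coded_least_squares_oracle(self):
        cells = synthetic.planted_performance_panel(n_species=4, seed=3)
        res = mixed_anova(cells)
        oracle = _statsmodels_anova_oracle(cells)
        pairs = {
            "Method": "C(method)",
            "Sequence": "C(representation)",
            "Method:Sequence": "C(method):C(representation)",
            "Species": "C(species)",
            "Residual": "Residual",
        }
        for mine, theirs in pairs.items():
            assert res.table.loc[mine, "sum_sq"] == pytest.approx(
                oracle.loc[theirs, "sum_sq"], abs=1e-9
            )
            assert res.table.loc[mine, "df"] == oracle.loc[theirs, "df"]
            if mine != "Residual":
                assert res.table.loc[mine, "F"] == pytest.approx(
                    oracle.loc[theirs, "F"], rel=1e-9
                )
                assert res.table.loc[mine, "p"] == pytest.approx(
                    oracle.loc[theirs, "PR(>F)"], abs=1e-12
                )

    def test_sum_of_squares_additivity(self):
        cells = synthetic.planted_performance_panel(n_species=7, seed=9)
        res = mixed_anova(cells)
        z = cells["z"].to_numpy()
        ss_total = ((z - z.mean()) ** 2).sum()
        assert res.table["sum_sq"].sum() == pytest.approx(ss_total, abs=1e-9)

    def test_variance_components(self):
        cells = synthetic.planted_performance_panel(n_species=12, seed=5)
        res = mixed_anova(cells)
        ms_species = res.table.loc["Species", "mean_sq"]
        ms_resid = res.table.loc["Residual", "mean_sq"]
        assert res.sigma_residual == pytest.approx(np.sqrt(ms_resid))
        assert res.sigma_species == pytest.approx(
            np.sqrt(max(0.0, (ms_species - ms_resid) / 6))
        )

    def test_incomplete_table_rejected(self):
        cells = synthetic.planted_performance_panel(n_species=4, seed=0)
        with pytest.raises(ValueError):
            mixed_anova(cells.iloc[:-1])


class TestTukey:
    def test_identical_means_p_one(self):
        p = tukey_hsd({"a": 1.0, "b": 1.0}, ms_residual=0.5,
                      df_residual=20, n_per_group=10)["p_adj"].iloc[0]
        assert p == pytest.approx(1.0)

    def test_matches_statsmodels_oracle(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        groups = {"g1": rng.normal(0, 1, 12), "g2": rng.normal(0.8, 1, 12),
                  "g3": rng.normal(1.5, 1, 12)}
        data = np.concatenate(list(groups.values()))
        labels = np.repeat(list(groups), 12)
        sm_res = pairwise_tukeyhsd(data, labels)
        grand = data.mean()
        ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
        ms_within = ss_within / (36 - 3)
        mine = tukey_hsd({k: v.mean() for k, v in groups.items()},
                         ms_within, 36 - 3, 12)
        np.testing.assert_allclose(
            mine["p_adj"].to_numpy(), sm_res.pvalues, atol=1e-6
        )

    def test_adjusted_p_at_least_pairwise_t(self, rng):
        means = {"a": 0.0, "b": 0.4, "c": 1.0}
        ms, df, n = 0.8, 27, 10
        res = tukey_hsd(means, ms, df, n)
        for r in res.itertuples():
            t = abs(r.diff) / np.sqrt(2 * ms / n)
            p_t = 2 * stats.t.sf(t, df)
            assert r.p_adj >= p_t - 1e-12

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            tukey_hsd({"a": 0, "b": 1}, 1.0, 0, 5)


class TestVarianceFTest:
    def test_identical_samples_give_unit_f(self, rng):
        a = rng.normal(size=30)
        F, p = variance_f_test(a, a)
        assert F == 1.0 and p == pytest.approx(1.0)

    def test_swap_inverts_f_keeps_p(self, rng):
        a, b = rng.normal(0, 1, 40), rng.normal(0, 2, 35)
        F1, p1 = variance_f_test(a, b)
        F2, p2 = variance_f_test(b, a)
        assert F1 == pytest.approx(1 / F2)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_fourfold_variance_detected(self):
        rng = np.random.default_rng(17)
        a = rng.normal(0, 2.0, 100)
        b = rng.normal(0, 1.0, 100)
        _, p = variance_f_test(a, b)
        assert p < 0.01

    def test_zero_denominator_variance_rejected(self):
        with pytest.raises(ValueError):
            variance_f_test(np.array([1.0, 2.0]), np.array([3.0, 3.0]))
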