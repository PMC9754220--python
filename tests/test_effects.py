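"""Mixed-effects estimation: fits, model selection, combined age effect,
percent transforms, multiplicity, marginal R^2."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import octmorph as om
from octmorph.effects import (FitError, age_pvalue, fit_candidate,
                              young_group_means)

from conftest import make_effects_table


class TestFitCandidate:
    def test_noiseless_exact_recovery(self):
        t = make_effects_table(60, 1, mu=300, beta_age=-0.3, beta_sex=4.0,
                               beta_sf=1.0, intercept_sd=0, resid_sd=0)
        fit = fit_candidate(t, "p", form="linear")
        assert fit["const"] == pytest.approx(300, abs=1e-6)
        assert fit["age_c"] == pytest.approx(-0.3, abs=1e-6)
        assert fit["male"] == pytest.approx(4.0, abs=1e-6)
        assert fit["scan_focus"] == pytest.approx(1.0, abs=1e-6)

    def test_quadratic_recovery_with_random_intercept(self):
        t = make_effects_table(300, 2, mu=300, beta_age=-0.29, beta_age2=-8e-4,
                               beta_sex=4.1, beta_sf=1.0, intercept_sd=14,
                               resid_sd=6)
        fit = fit_candidate(t, "p", form="quadratic")
        assert fit["male"] == pytest.approx(4.1, abs=3 * fit.se("male"))
        assert fit.re_var == pytest.approx(196, rel=0.4)
        assert fit.resid_var == pytest.approx(36, rel=0.4)

    def test_duplicated_eyes_leave_fixed_effects_unchanged(self):
        one = make_effects_table(80, 3, mu=310, beta_age=-0.2, beta_sex=3.0,
                                 resid_sd=5, both_eyes=False)
        dup = pd.concat([one, one.assign(eye="OS")], ignore_index=True)
        f1 = fit_candidate(one, "p", form="linear")
        f2 = fit_candidate(dup, "p", form="linear")
        # identical in exact ML; the residual variance sits on the zero
        # boundary for duplicated data, so the optimizer leaves ~1e-5 slack
        np.testing.assert_allclose(f2.params, f1.params, atol=1e-4)

    def test_errors(self):
        t = make_effects_table(1, 0, both_eyes=True)
        with pytest.raises(FitError):
            fit_candidate(t, "p")
        with pytest.raises(FitError):
            fit_candidate(t, "missing")
        deg = make_effects_table(30, 1)
        deg["sex"] = "F"  # no males: singular design
        with pytest.raises(FitError):
            fit_candidate(deg, "p")


class TestProfiledEngine:
    """The profiled-ML fast path fits the identical model as statsmodels."""

    @pytest.mark.parametrize("form", ["none", "linear", "quadratic"])
    def test_agrees_with_statsmodels(self, form):
        t = make_effects_table(120, 21, mu=300, beta_age=-0.3, beta_sex=4.0,
                               beta_sf=1.0, intercept_sd=14, resid_sd=6)
        a = fit_candidate(t, "p", form=form, engine="statsmodels")
        b = fit_candidate(t, "p", form=form, engine="profiled")
        np.testing.assert_allclose(b.params, a.params, atol=1e-6)
        np.testing.assert_allclose(b.cov_params, a.cov_params, rtol=1e-3)
        assert b.llf == pytest.approx(a.llf, abs=1e-5)
        assert b.re_var == pytest.approx(a.re_var, rel=1e-3)
        assert b.resid_var == pytest.approx(a.resid_var, rel=1e-3)

    def test_boundary_zero_intercept_variance(self):
        t = make_effects_table(80, 22, mu=300, beta_sex=4.0, resid_sd=6,
                               intercept_sd=0, both_eyes=False)
        fit = fit_candidate(t, "p", form="linear", engine="profiled")
        assert fit.re_var == pytest.approx(0.0, abs=1.0)

    def test_unknown_engine(self):
        t = make_effects_table(20, 23, resid_sd=1)
        with pytest.raises(ValueError, match="engine"):
            fit_candidate(t, "p", engine="mcmc")


class TestSelectAgeModel:
    def test_strong_curvature_selects_quadratic(self):
        t = make_effects_table(300, 4, beta_age=-0.3, beta_age2=-0.02,
                               resid_sd=5, intercept_sd=5)
        chosen, aic_lin, aic_quad = om.select_age_model(t, "p")
        assert chosen.form == "quadratic"
        assert aic_quad < aic_lin

    def test_pure_linear_mostly_selects_linear(self):
        picks = []
        for seed in range(6):
            t = make_effects_table(200, 100 + seed, beta_age=-0.3, resid_sd=6,
                                   intercept_sd=10)
            picks.append(om.select_age_model(t, "p")[0].form)
        assert picks.count("linear") >= 4

    def test_aic_tie_prefers_linear(self, monkeypatch):
        t = make_effects_table(50, 5, beta_age=-0.3, resid_sd=5)
        import octmorph.effects as eff

        real = eff.fit_candidate

        def fixed_aic(table, parameter, quadratic=False, form=None):
            fit = real(table, parameter, quadratic=quadratic, form=form)
            object.__setattr__(fit, "aic", 1234.5)
            return fit

        monkeypatch.setattr(eff, "fit_candidate", fixed_aic)
        chosen, aic_lin, aic_quad = eff.select_age_model(t, "p")
        assert aic_lin == aic_quad
        assert chosen.form == "linear"


class TestCombinedAgeEffect:
    def test_linear_model_combined_is_ten_beta(self):
        t = make_effects_table(100, 6, beta_age=-0.31, resid_sd=0)
        fit = fit_candidate(t, "p", form="linear")
        per10, se, ci = om.combined_age_effect(fit)
        assert per10 == pytest.approx(10 * fit["age_c"], abs=1e-9)
        assert ci[0] < per10 < ci[1]

    def test_uncentered_closed_form(self):
        # beta_age = 0, beta_age2 = b: mean yearly change over 40-80 is
        # (y(80)-y(40))/40 = 120 b, i.e. 1200 b per decade
        b = -2.5e-3
        assert om.combined_age_from_uncentered(0.0, b) * 10 == pytest.approx(1200 * b)
        assert om.combined_age_from_uncentered(-0.325, 0.0) * 10 == pytest.approx(-3.25)

    def test_centered_quadratic_consistency(self):
        t = make_effects_table(200, 7, beta_age=-0.2, beta_age2=-1e-3, resid_sd=0)
        fit = fit_candidate(t, "p", form="quadratic")
        per10, *_ = om.combined_age_effect(fit)
        assert per10 == pytest.approx(
            10 * om.combined_age_from_uncentered(fit.beta_age_uncentered,
                                                 fit.beta_age2), abs=1e-9)


class TestAgePvalue:
    def test_no_age_effect_gives_p_of_one_in_exact_fit(self):
        # y depends only on sex and focus, no noise: the quadratic and the
        # no-age fits reproduce the data identically -> LR = 0 -> p = 1
        t = make_effects_table(60, 8, beta_sex=5.0, beta_sf=1.0, resid_sd=0)
        fit = fit_candidate(t, "p", form="quadratic")
        assert age_pvalue(t, "p", fit) == pytest.approx(1.0, abs=1e-6)

    def test_strong_effect_tiny_p(self):
        t = make_effects_table(200, 9, beta_age=-0.3, resid_sd=6, intercept_sd=10)
        fit = fit_candidate(t, "p", form="quadratic")
        assert age_pvalue(t, "p", fit) < 1e-6

    def test_linear_model_uses_wald(self):
        t = make_effects_table(150, 10, beta_age=-0.3, resid_sd=6)
        fit = fit_candidate(t, "p", form="linear")
        p = age_pvalue(t, "p", fit)
        z = fit["age_c"] / fit.se("age_c")
        from scipy import stats
        assert p == pytest.approx(2 * stats.norm.sf(abs(z)))


class TestPercentTransform:
    def test_reference_ratio(self):
        # -3.25 um/decade against a young mean of 309.5 um is -1.05 %/decade
        assert -3.25 / 309.5238 * 100 == pytest.approx(-1.05, abs=0.001)

    def test_zero_effect_zero_percent(self):
        t = make_effects_table(150, 11, mu=300, beta_sex=0.0, resid_sd=0)
        est = om.fit_parameter(t, "p")
        assert est.sex_pct == pytest.approx(0.0, abs=1e-9)

    def test_invariant_under_global_rescaling(self):
        t = make_effects_table(150, 12, mu=300, beta_age=-0.3, beta_sex=4.0,
                               resid_sd=5, intercept_sd=8)
        t2 = t.assign(value=2 * t["value"])
        e1 = om.fit_parameter(t, "p")
        e2 = om.fit_parameter(t2, "p")
        assert e2.age_per10_pct == pytest.approx(e1.age_per10_pct, abs=1e-6)
        assert e2.sex_pct == pytest.approx(e1.sex_pct, abs=1e-6)
        assert e2.sex_abs == pytest.approx(2 * e1.sex_abs, abs=1e-6)

    def test_young_group_means_definition(self):
        t = make_effects_table(150, 13, mu=300, beta_sex=10.0, resid_sd=0)
        young, young_f = young_group_means(t, "p")
        sub = t[t.age <= 40]
        assert young == pytest.approx(sub.value.mean())
        assert young_f == pytest.approx(sub[sub.sex == "F"].value.mean())

    def test_empty_young_group_raises(self):
        t = make_effects_table(50, 14)
        t = t[t.age > 40]
        with pytest.raises(ValueError):
            young_group_means(t, "p")


class TestAdjustPvalues:
    def test_holm_by_hand(self):
        reject, adj = om.adjust_pvalues([0.01, 0.04], method="holm")
        np.testing.assert_allclose(adj, [0.02, 0.04])
        assert reject.all()

    def test_bh_by_hand(self):
        reject, adj = om.adjust_pvalues([0.001, 0.02, 0.03, 0.9], method="bh")
        np.testing.assert_allclose(adj, [0.004, 0.04, 0.04, 0.9])

    def test_all_ones_nothing_significant(self):
        reject, adj = om.adjust_pvalues([1.0] * 5, method="holm")
        assert not reject.any()

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            om.adjust_pvalues([0.5, 1.5])
        with pytest.raises(ValueError):
            om.adjust_pvalues([0.5], method="bonferroni-ish")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=12),
           st.sampled_from(["holm", "bh"]))
    def test_monotone_and_dominating(self, pvals, method):
        p = np.asarray(pvals)
        _, adj = om.adjust_pvalues(p, method=method)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestMarginalR2:
    def test_full_fixed_variance_is_100(self):
        t = make_effects_table(80, 15, beta_age=-0.5, beta_sex=5.0, resid_sd=0)
        fit = fit_candidate(t, "p", form="linear")
        assert om.marginal_r2(fit) == pytest.approx(100.0, abs=0.01)

    def test_zero_fixed_effects_near_zero(self):
        t = make_effects_table(150, 16, resid_sd=6, intercept_sd=10)
        fit = fit_candidate(t, "p", form="linear")
        assert om.marginal_r2(fit) < 3.0


class TestFamily:
    def test_family_adjusts_both_factors(self):
        frames = [make_effects_table(60, 20 + i, mu=300, beta_age=-0.3,
                                     beta_sex=4, resid_sd=5, intercept_sd=8,
                                     parameter=f"p{i}") for i in range(3)]
        table = pd.concat(frames, ignore_index=True)
        ests = om.fit_family(table, [f"p{i}" for i in range(3)], method="holm")
        assert len(ests) == 3
        for e in ests:
            assert e.p_age_adjusted >= e.p_age - 1e-12
            assert e.p_sex_adjusted >= e.p_sex - 1e-12
            assert e.significant_age is not None
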