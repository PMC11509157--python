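"""Count-model fitting, deviance analysis, selection and ancillary tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bordertrap.count_models as cm


def poisson_df(counts, exposure=None, **cols):
    d = {"y": counts}
    if exposure is not None:
        d["exposure"] = exposure
    d.update(cols)
    return pd.DataFrame(d)


class TestFit:
    def test_poisson_intercept_only_is_sample_mean(self):
        df = poisson_df([2, 4, 6])
        m = cm.fit(cm.ModelSpec("poisson", "y", ()), df)
        assert m.coefficients["Intercept"] == pytest.approx(np.log(4.0))
        assert m.fitted_means == pytest.approx([4.0, 4.0, 4.0])
        assert m.aic == pytest.approx(2 * m.p - 2 * m.loglik)

    def test_poisson_offset_closed_form_rate(self):
        # MLE of a constant rate is total count / total exposure = 12/4
        df = poisson_df([2, 4, 6], exposure=[1, 1, 2])
        m = cm.fit(cm.ModelSpec("poisson", "y", (), offset="exposure"), df)
        assert m.coefficients["Intercept"] == pytest.approx(np.log(3.0), abs=1e-8)

    def test_offset_scaling_shifts_only_intercept(self, rng):
        n = 200
        x = rng.normal(size=n)
        expo = rng.uniform(50, 150, size=n)
        y = rng.poisson(expo * np.exp(-2.0 + 0.3 * x))
        df = poisson_df(y, exposure=expo, x=x)
        m1 = cm.fit(cm.ModelSpec("poisson", "y", ("x",), offset="exposure"), df)
        df2 = df.assign(exposure=df["exposure"] * 7.0)
        m2 = cm.fit(cm.ModelSpec("poisson", "y", ("x",), offset="exposure"), df2)
        assert m2.coefficients["x"] == pytest.approx(m1.coefficients["x"], abs=1e-6)
        assert m2.coefficients["Intercept"] == pytest.approx(
            m1.coefficients["Intercept"] - np.log(7.0), abs=1e-6
        )

    def test_nb_on_equidispersed_data_matches_poisson(self, rng):
        n = 300
        x = rng.normal(size=n)
        y = rng.poisson(np.exp(1.0 + 0.5 * x))
        df = poisson_df(y, x=x)
        pois = cm.fit(cm.ModelSpec("poisson", "y", ("x",)), df)
        nb = cm.fit(cm.ModelSpec("negative_binomial", "y", ("x",)), df)
        assert nb.theta is not None and nb.theta > 1e3
        for k in pois.coefficients.index:
            assert nb.coefficients[k] == pytest.approx(
                pois.coefficients[k], abs=1e-4
            )

    def test_nb_recovers_overdispersion(self, rng):
        n = 500
        x = rng.normal(size=n)
        mu = np.exp(1.5 + 0.4 * x)
        theta = 2.0
        y = rng.negative_binomial(theta, theta / (theta + mu))
        m = cm.fit(cm.ModelSpec("negative_binomial", "y", ("x",)), poisson_df(y, x=x))
        assert m.theta == pytest.approx(theta, rel=0.5)
        assert m.coefficients["x"] == pytest.approx(0.4, abs=0.1)

    def test_errors_signalled_distinctly(self, rng):
        df = poisson_df([1, 2, 3, 4], x=[1.0, 2.0, 3.0, 4.0],
                        x2=[2.0, 4.0, 6.0, 8.0])
        with pytest.raises(cm.RankDeficiencyError):
            cm.fit(cm.ModelSpec("poisson", "y", ("x", "x2")), df)
        with pytest.raises(ValueError, match="negative"):
            cm.fit(cm.ModelSpec("poisson", "y", ()), poisson_df([1, -2, 3]))
        with pytest.raises(ValueError, match="positive"):
            cm.fit(
                cm.ModelSpec("poisson", "y", (), offset="exposure"),
                poisson_df([1, 2, 3], exposure=[1.0, 0.0, 2.0]),
            )

    def test_nested_model_never_beats_full_loglik(self, rng):
        n = 150
        x = rng.normal(size=n)
        y = rng.poisson(np.exp(1.0 + 0.2 * x))
        df = poisson_df(y, x=x)
        full = cm.fit(cm.ModelSpec("poisson", "y", ("x",)), df)
        null = cm.fit(cm.ModelSpec("poisson", "y", ()), df)
        assert full.loglik >= null.loglik - 1e-10


class TestAnovaDeviance:
    def test_identical_models_give_zero(self, rng):
        df = poisson_df(rng.poisson(5, size=30))
        m = cm.fit(cm.ModelSpec("poisson", "y", ()), df)
        r = cm.anova_deviance(m, m)
        assert r.statistic == 0.0 and r.pvalue == 1.0

    def test_matches_closed_form_g_test(self):
        # one binary covariate on counts 10 vs 20 with equal exposure:
        # LRT statistic is G = 2 sum O log(O/E), E = 15
        df = poisson_df([10, 20], g=["a", "b"])
        full = cm.fit(cm.ModelSpec("poisson", "y", ("C(g)",)), df)
        red = cm.fit(cm.ModelSpec("poisson", "y", ()), df)
        g = 2 * (10 * np.log(10 / 15) + 20 * np.log(20 / 15))
        r = cm.anova_deviance(full, red)
        assert r.statistic == pytest.approx(g, abs=1e-6)
        assert r.df == 1

    def test_non_nested_rejected(self, rng):
        df = poisson_df(rng.poisson(5, size=30), x=rng.normal(size=30),
                        z=rng.normal(size=30))
        mx = cm.fit(cm.ModelSpec("poisson", "y", ("x",)), df)
        mz = cm.fit(cm.ModelSpec("poisson", "y", ("z",)), df)
        with pytest.raises(ValueError):
            cm.anova_deviance(mx, mz)

    def test_deviance_table_types_run(self, rng):
        n = 120
        df = poisson_df(
            rng.poisson(5, size=n),
            x=rng.normal(size=n),
            g=rng.choice(["a", "b"], size=n),
        )
        spec = cm.ModelSpec("poisson", "y", ("x", "C(g)", "x:C(g)"))
        for kind in ("II", "III"):
            table = cm.deviance_table(spec, df, kind)
            assert [r.term for r in table] == list(spec.terms)
            assert all(r.statistic >= 0 and 0 <= r.pvalue <= 1 for r in table)


class TestBackwardAIC:
    def test_strong_single_term_never_dropped(self, rng):
        n = 200
        x = rng.normal(size=n)
        y = rng.poisson(np.exp(1.0 + 1.0 * x))
        model, log = cm.backward_aic(
            cm.ModelSpec("poisson", "y", ("x",)), poisson_df(y, x=x)
        )
        assert "x" in model.spec.terms and log == []

    def test_distance_kept_noise_dropped(self, rng):
        n = 150
        d = rng.uniform(0, 100, size=n)
        noise = rng.normal(size=n)
        y = rng.poisson(np.exp(2.0 - 0.03 * d))
        df = poisson_df(y, d=d, noise=noise)
        model, _ = cm.backward_aic(cm.ModelSpec("poisson", "y", ("d", "noise")), df)
        assert "d" in model.spec.terms
        assert "noise" not in model.spec.terms

    def test_marginality_protects_main_effects(self, rng):
        n = 200
        x = rng.normal(size=n)
        g = rng.choice([0.0, 1.0], size=n)
        y = rng.poisson(np.exp(0.5 + 0.8 * x * g))
        df = poisson_df(y, x=x, g=g)
        model, log = cm.backward_aic(
            cm.ModelSpec("poisson", "y", ("x", "g", "x:g")), df
        )
        if "x:g" in model.spec.terms:
            assert {"x", "g"} <= set(model.spec.terms)
        for entry in log:  # a main effect may only fall after its interaction
            if entry["dropped"] in ("x", "g"):
                assert any(e["dropped"] == "x:g" for e in log[: log.index(entry)])


class TestPearsonGof:
    def test_perfect_fit_is_zero(self):
        df = poisson_df([5, 5, 5, 5])
        m = cm.fit(cm.ModelSpec("poisson", "y", ()), df)
        assert cm.pearson_gof(m).statistic == pytest.approx(0.0, abs=1e-12)

    def test_well_specified_poisson_is_calibrated(self, rng):
        ratios = []
        for _ in range(50):
            y = rng.poisson(8.0, size=200)
            m = cm.fit(cm.ModelSpec("poisson", "y", ()), poisson_df(y))
            ratios.append(cm.pearson_gof(m).dispersion)
        assert 0.9 < np.median(ratios) < 1.1

    def test_overdispersion_detected(self, rng):
        theta = 2.0
        mu = 8.0
        hits = 0
        for _ in range(40):
            y = rng.negative_binomial(theta, theta / (theta + mu), size=200)
            m = cm.fit(cm.ModelSpec("poisson", "y", ()), poisson_df(y))
            hits += cm.pearson_gof(m).dispersion > 1.5
        assert hits >= 38


class TestOnewayAnova:
    def test_identical_groups(self):
        r = cm.oneway_anova([[1, 2, 3], [1, 2, 3]])
        assert r.statistic == 0.0 and r.pvalue == 1.0

    def test_hand_computation(self):
        r = cm.oneway_anova([[1, 2, 3], [4, 5, 6]])
        assert r.statistic == pytest.approx(13.5)
        assert (r.df1, r.df2) == (1, 4)

    def test_matches_scipy(self, rng):
        groups = [rng.normal(loc, 1.0, size=10) for loc in (0.0, 0.5, 1.0)]
        ours = cm.oneway_anova(groups)
        ref = stats.f_oneway(*groups)
        assert ours.statistic == pytest.approx(ref.statistic)
        assert ours.pvalue == pytest.approx(ref.pvalue)

    def test_degenerate_signalled(self):
        with pytest.raises(cm.DegenerateDataError):
            cm.oneway_anova([[3, 3], [3, 3]])

    def test_null_pvalues_uniform(self, rng):
        pvals = [
            cm.oneway_anova([rng.normal(size=8), rng.normal(size=8)]).pvalue
            for _ in range(400)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestWaldContrast:
    @pytest.fixture
    def fitted(self, rng):
        n = 400
        x = rng.normal(size=n)
        y = rng.poisson(np.exp(1.0 + 0.5 * x))
        return cm.fit(cm.ModelSpec("poisson", "y", ("x",)), poisson_df(y, x=x))

    def test_zero_contrast(self, fitted):
        z, p = cm.wald_contrast(fitted, [0.0, 0.0])
        assert z == 0.0 and p == 1.0

    def test_indicator_contrast_equals_coefficient_z(self, fitted):
        z, _ = cm.wald_contrast(fitted, [0.0, 1.0])
        beta = fitted.coefficients["x"]
        se = np.sqrt(fitted.covariance.loc["x", "x"])
        assert z == pytest.approx(beta / se)

    def test_wrong_length_rejected(self, fitted):
        with pytest.raises(ValueError):
            cm.wald_contrast(fitted, [1.0])

    def test_power_for_strong_effect(self, rng):
        hits = 0
        for _ in range(20):
            sex = np.repeat([0.0, 1.0], 200)
            y = rng.poisson(np.exp(2.0 + np.log(2.0) * sex))
            m = cm.fit(
                cm.ModelSpec("poisson", "y", ("sex",)), poisson_df(y, sex=sex)
            )
            _, p = cm.wald_contrast(m, [0.0, 1.0])
            hits += p < 0.001
        assert hits == 20
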