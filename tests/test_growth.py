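import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from fishdemog.growth import (VBGFParams, vbgf_predict, VonBertalanffyModel,
                              fit_rvbgf, confidence_ellipse, ellipses_overlap,
                              EllipseRegion)

PLAIN = VBGFParams(l_inf=36.60, k=0.44)
SPOTTED = VBGFParams(l_inf=49.32, k=0.26)


def sample(params, n=500, sd=2.0, seed=0, ages=(1, 16)):
    rng = np.random.default_rng(seed)
    age = rng.integers(*ages, size=n).astype(float)
    length = np.maximum(vbgf_predict(params, age) + rng.normal(0, sd, n), 1.0)
    return age, length


class TestPredict:
    def test_constrained_curve_through_origin(self):
        assert vbgf_predict(PLAIN, 0.0) == 0.0

    def test_asymptote(self):
        assert vbgf_predict(PLAIN, 1e6) == pytest.approx(PLAIN.l_inf, rel=1e-12)

    def test_direct_evaluation(self):
        # pooled-sample parameters at age 5
        assert vbgf_predict(VBGFParams(38.99, 0.39), 5) == pytest.approx(33.44, abs=0.005)

    @given(st.floats(10, 100), st.floats(0.05, 1.0),
           st.floats(0, 30), st.floats(0.01, 5))
    @settings(max_examples=100, deadline=None)
    def test_monotone_increasing_below_asymptote(self, l_inf, k, t, dt):
        p = VBGFParams(l_inf, k)
        a, b = vbgf_predict(p, t), vbgf_predict(p, t + dt)
        assert a < b < l_inf

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            VBGFParams(l_inf=-1, k=0.3)
        with pytest.raises(ValueError):
            VBGFParams(l_inf=40, k=0.0)


class TestFit:
    def test_noiseless_recovery_exact(self):
        age = np.arange(1.0, 16.0)
        length = vbgf_predict(PLAIN, age)
        res = VonBertalanffyModel(age, length, mode="constrained").fit()
        assert res.params.l_inf == pytest.approx(PLAIN.l_inf, abs=1e-6)
        assert res.params.k == pytest.approx(PLAIN.k, abs=1e-6)

    def test_noiseless_unconstrained_recovers_t0(self):
        truth = VBGFParams(45.0, 0.3, t0=-0.6)
        age = np.arange(1.0, 18.0)
        res = VonBertalanffyModel(age, vbgf_predict(truth, age),
                                  mode="unconstrained").fit()
        assert res.params.t0 == pytest.approx(-0.6, abs=1e-5)

    def test_single_age_class_not_identifiable(self):
        with pytest.raises(ValueError, match="identifiable"):
            VonBertalanffyModel(np.full(20, 5.0), np.linspace(30, 34, 20))

    def test_recovery_within_bootstrap_ci(self):
        age, length = sample(PLAIN, n=500, sd=2.0, seed=1)
        res = VonBertalanffyModel(age, length).fit(n_boot=300, seed=2)
        ci = res.conf_int()
        assert ci.loc["l_inf", "lower"] <= PLAIN.l_inf <= ci.loc["l_inf", "upper"]
        assert ci.loc["k", "lower"] <= PLAIN.k <= ci.loc["k", "upper"]
        assert res.params.l_inf == pytest.approx(PLAIN.l_inf, rel=0.05)
        assert res.params.k == pytest.approx(PLAIN.k, rel=0.05)

    def test_constrained_rss_at_least_unconstrained(self):
        age, length = sample(VBGFParams(40, 0.3, t0=-0.8), n=300, seed=3)
        con = VonBertalanffyModel(age, length, mode="constrained").fit()
        unc = VonBertalanffyModel(age, length, mode="unconstrained").fit()
        assert con.rss >= unc.rss - 1e-9


class TestBootstrap:
    def test_same_seed_identical_cis(self):
        age, length = sample(PLAIN, n=200, seed=4)
        model = VonBertalanffyModel(age, length)
        a = model.fit(n_boot=100, seed=9).conf_int()
        b = model.fit(n_boot=100, seed=9).conf_int()
        assert (a == b).all().all()

    def test_ci_contains_point_estimate(self):
        age, length = sample(PLAIN, n=200, seed=5)
        res = VonBertalanffyModel(age, length).fit(n_boot=200, seed=1)
        ci = res.conf_int()
        assert (ci["lower"] <= ci["estimate"]).all()
        assert (ci["estimate"] <= ci["upper"]).all()

    def test_ci_narrows_with_sample_size(self):
        widths = {}
        for n in (100, 1000):
            age, length = sample(PLAIN, n=n, seed=6)
            ci = VonBertalanffyModel(age, length).fit(n_boot=200, seed=7).conf_int()
            widths[n] = (ci["upper"] - ci["lower"]).to_numpy()
        assert (widths[1000] < widths[100]).all()

    def test_box_coverage(self):
        """The joint 95% CI box catches the generating (l_inf, k) at roughly
        nominal rate over repeated datasets (reduced replicate counts)."""
        hits = 0
        n_data = 100
        for rep in range(n_data):
            age, length = sample(PLAIN, n=150, sd=2.0, seed=10_000 + rep)
            res = VonBertalanffyModel(age, length).fit(n_boot=60, seed=rep)
            ci = res.conf_int()
            hits += (ci.loc["l_inf", "lower"] <= PLAIN.l_inf <= ci.loc["l_inf", "upper"]
                     and ci.loc["k", "lower"] <= PLAIN.k <= ci.loc["k", "upper"])
        assert 0.90 * n_data <= hits <= 0.99 * n_data


class TestEllipse:
    def test_isotropic_semi_axes(self):
        rng = np.random.default_rng(0)
        cloud = rng.standard_normal((20000, 2))
        ell = confidence_ellipse(cloud, level=0.95)
        expected = np.sqrt(stats.chi2.ppf(0.95, 2))  # ~ sqrt(5.991)
        assert ell.semi_axes == pytest.approx([expected, expected], rel=0.05)

    def test_membership_rate(self):
        rng = np.random.default_rng(1)
        cloud = rng.multivariate_normal([40, 0.4], [[4.0, -0.05], [-0.05, 0.002]],
                                        size=10000)
        ell = confidence_ellipse(cloud, level=0.95)
        assert ell.contains(cloud).mean() == pytest.approx(0.95, abs=0.02)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(2)
        cloud = rng.standard_normal((500, 2))
        shift = np.array([12.3, -4.5])
        a = confidence_ellipse(cloud)
        b = confidence_ellipse(cloud + shift)
        assert b.center == pytest.approx(a.center + shift)
        assert b.cov == pytest.approx(a.cov)

    def test_degenerate_cloud_rejected(self):
        line = np.column_stack([np.linspace(0, 1, 50), np.linspace(0, 2, 50)])
        with pytest.raises(ValueError, match="degenerate"):
            confidence_ellipse(line)

    def test_small_cloud_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            confidence_ellipse(np.random.default_rng(3).standard_normal((5, 2)))


class TestEllipseOverlap:
    def ellipse(self, cx, cy, sx=1.0, sy=1.0):
        return EllipseRegion(center=[cx, cy], cov=[[sx, 0], [0, sy]], level=0.95)

    def test_identical_overlap(self):
        assert ellipses_overlap(self.ellipse(0, 0), self.ellipse(0, 0))

    def test_containment_is_overlap(self):
        outer = self.ellipse(0, 0, 4.0, 4.0)
        inner = self.ellipse(0.2, 0.1, 0.01, 0.01)
        assert ellipses_overlap(outer, inner)
        assert ellipses_overlap(inner, outer)

    def test_morph_parameter_clouds_separate(self):
        """Ellipses built from the plain/spotted estimates and CI half-widths
        do not overlap: the morphs' growth differs."""
        # CI half-width -> sd: half-width ~ 1.96 sd
        plain = EllipseRegion(center=[36.60, 0.44],
                              cov=np.diag([(0.465 / 1.96) ** 2, (0.025 / 1.96) ** 2]))
        spotted = EllipseRegion(center=[49.32, 0.26],
                                cov=np.diag([(1.705 / 1.96) ** 2, (0.02 / 1.96) ** 2]))
        assert not ellipses_overlap(plain, spotted)

    def test_touching_ellipses_overlap(self):
        r = np.sqrt(stats.chi2.ppf(0.95, 2))
        near = self.ellipse(1.9 * r, 0.0)
        far = self.ellipse(2.1 * r, 0.0)
        assert ellipses_overlap(self.ellipse(0, 0), near)
        assert not ellipses_overlap(self.ellipse(0, 0), far)


class TestFrancis:
    def test_reparameterisation_invariance_noiseless(self):
        truth = VBGFParams(42.0, 0.35, t0=-0.4)
        age = np.arange(1.0, 16.0)
        length = vbgf_predict(truth, age)
        res = fit_rvbgf(age, length, ref_ages=(2, 10))
        grid = np.linspace(0.5, 15, 60)
        direct = VonBertalanffyModel(age, length, mode="unconstrained").fit()
        assert res.predict(grid) == pytest.approx(direct.predict(grid), abs=1e-6)
        # l1 is exactly the curve value at tau1
        assert res.l1 == pytest.approx(vbgf_predict(truth, 2.0), abs=1e-6)

    def test_back_transform_recovery(self):
        age, length = sample(VBGFParams(40.0, 0.30, t0=-0.2), n=500, sd=1.5,
                             seed=8, ages=(1, 16))
        back = fit_rvbgf(age, length, ref_ages=(2, 10)).to_vbgf()
        assert back.l_inf == pytest.approx(40.0, rel=0.05)
        assert back.k == pytest.approx(0.30, rel=0.05)

    def test_reference_ages_outside_range_warn(self):
        age, length = sample(PLAIN, n=200, seed=9, ages=(3, 9))
        res = fit_rvbgf(age, length, ref_ages=(1, 20))
        assert res.warnings

    def test_bad_reference_ages(self):
        age, length = sample(PLAIN, n=50, seed=10)
        with pytest.raises(ValueError):
            fit_rvbgf(age, length, ref_ages=(10, 2))
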