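"""Left-flat sigmoid curve, design construction, and the profile fitter."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from captraj import (
    CapConfig,
    FitOptions,
    ProfileFitter,
    SigmoidParams,
    assign_cap,
    compare_models,
    design_response,
    fit_constant,
    fit_linear,
    fit_sigmoid,
    generate_cohort,
    left_flat_sigmoid,
)
from captraj.trajectory import improvement_stat
from conftest import PROBE_TRUTH, probe_dataset, probe_scenario


class TestCurve:
    def test_flat_left_of_changepoint(self):
        p = SigmoidParams(10.0, 4.0, 300.0, 50.0)
        caps = np.array([0.0, 150.0, 299.999, 300.0])
        assert np.all(left_flat_sigmoid(caps, p) == 10.0)

    def test_degenerate_flat_model(self):
        p = SigmoidParams(10.0, 0.0, 300.0, 50.0)
        assert np.all(left_flat_sigmoid(np.linspace(0, 1000, 50), p) == 10.0)

    def test_half_logistic_ramp_value(self):
        # independent arithmetic: v0 - delta * (2/(1+e^-1) - 1) at one width
        # past the changepoint
        expected = 10.0 - 4.0 * (2.0 / (1.0 + math.exp(-1.0)) - 1.0)
        got = left_flat_sigmoid(350.0, SigmoidParams(10.0, 4.0, 300.0, 50.0))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(8.1515, abs=1e-4)

    @given(
        v0=st.floats(-10, 1e5),
        delta=st.floats(0, 1e4),
        tau=st.floats(50, 600),
        scale=st.floats(1, 300),
    )
    @settings(derandomize=True, max_examples=50)
    def test_monotone_continuous_and_bounded(self, v0, delta, tau, scale):
        p = SigmoidParams(v0, delta, tau, scale)
        grid = np.linspace(tau - 200, tau + 3000, 2001)
        vals = left_flat_sigmoid(grid, p)
        assert np.all(np.diff(vals) <= 1e-9 * max(1.0, delta))  # non-increasing
        assert left_flat_sigmoid(tau, p) == v0  # continuity at the changepoint
        assert vals[-1] >= v0 - delta - 1e-9 * max(1.0, delta)  # asymptote

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SigmoidParams(1.0, -0.1, 300.0, 50.0)
        with pytest.raises(ValueError):
            SigmoidParams(1.0, 0.1, 300.0, 0.0)


class TestDesign:
    def test_reference_coding_and_centring(self):
        ds = probe_dataset(seed=3)
        study_cols = [c for c in ds.colnames if c.startswith("study_")]
        assert len(study_cols) == len(ds.studies) - 1
        icv = ds.Z[:, ds.colnames.index("icv_centered")]
        assert abs(icv.mean()) < 1e-9 * icv.std()

    def test_min_obs_enforced(self):
        with pytest.raises(ValueError, match="minimum"):
            probe_dataset(seed=3, n_carriers=5, n_controls=5)

    def test_all_controls_with_exclude_scheme_fails(self):
        cohort = generate_cohort(probe_scenario(seed=4, n_carriers=0, n_controls=40))
        capped = assign_cap(cohort, CapConfig(control_scheme="exclude"))
        with pytest.raises(ValueError):
            design_response(capped, "probe")

    def test_collinear_design_names_columns(self):
        cohort = generate_cohort(probe_scenario(seed=5, n_carriers=60, n_controls=0))
        cohort["icv"] = 1.5e6  # constant ICV -> zero centred column
        capped = assign_cap(cohort, CapConfig())
        with pytest.raises(ValueError, match="icv_centered"):
            design_response(capped, "probe")


class TestProfileFit:
    def test_zero_noise_identifiability(self):
        # icv_coupling off so the flat level is identified exactly (with it
        # on, the intercept absorbs the population-vs-sample ICV centring)
        ds = probe_dataset(seed=1, noise=0.0, icv_coupling=0.0)
        fit = fit_sigmoid(ds)
        assert fit.converged
        assert fit.params.v0 == pytest.approx(PROBE_TRUTH.v0, rel=1e-6)
        assert fit.params.delta == pytest.approx(PROBE_TRUTH.delta, rel=1e-6)
        assert fit.params.tau == pytest.approx(PROBE_TRUTH.tau, rel=1e-6)
        assert fit.params.scale == pytest.approx(PROBE_TRUTH.scale, rel=1e-6)

    def test_profile_minimum_matches_reported_rss(self):
        ds = probe_dataset(seed=2)
        fit = fit_sigmoid(ds)
        prof_min = min(r for _, r in fit.profile_grid)
        assert prof_min == pytest.approx(fit.rss, rel=1e-8)

    def test_nesting_chain_on_declining_data(self):
        for seed in (10, 11, 12):
            ds = probe_dataset(seed=seed)
            sig, lin, const = fit_sigmoid(ds), fit_linear(ds), fit_constant(ds)
            assert const.rss >= lin.rss * (1 - 1e-6)
            assert lin.rss >= sig.rss * (1 - 1e-6)

    def test_shift_equivariance(self):
        ds = probe_dataset(seed=6)
        fitter = ProfileFitter(ds)
        base = fitter.fit()
        shifted = fitter.fit(ds.y + 123.0)
        assert shifted.params.tau == base.params.tau
        # scale/delta agree to the 1-D optimizer's x-tolerance
        assert shifted.params.scale == pytest.approx(base.params.scale, rel=1e-5)
        assert shifted.params.delta == pytest.approx(base.params.delta, rel=1e-6)
        assert shifted.params.v0 == pytest.approx(base.params.v0 + 123.0, rel=1e-8)
        assert shifted.rss == pytest.approx(base.rss, rel=1e-9)

    def test_scale_equivariance(self):
        ds = probe_dataset(seed=6)
        fitter = ProfileFitter(ds)
        base = fitter.fit()
        k = 7.5
        scaled = fitter.fit(ds.y * k)
        assert scaled.params.tau == base.params.tau
        assert scaled.params.scale == pytest.approx(base.params.scale, rel=1e-5)
        assert scaled.params.v0 == pytest.approx(base.params.v0 * k, rel=1e-8)
        assert scaled.params.delta == pytest.approx(base.params.delta * k, rel=1e-6)
        assert scaled.rss == pytest.approx(base.rss * k * k, rel=1e-9)
        assert scaled.coefs.icv_slope == pytest.approx(base.coefs.icv_slope * k, rel=1e-6)

    def test_fitted_curve_left_flat_and_monotone(self):
        ds = probe_dataset(seed=7)
        fit = fit_sigmoid(ds)
        p = fit.params
        left = np.linspace(ds.cap.min(), p.tau, 200)
        assert np.all(fit.predict_curve(left) == p.v0)
        dense = np.linspace(ds.cap.min(), ds.cap.max(), 2000)
        assert np.all(np.diff(fit.predict_curve(dense)) <= 1e-12 * max(1.0, p.delta))


class TestLinearConstant:
    def test_constant_data_zero_slope(self):
        ds = probe_dataset(seed=8, noise=0.0, truth=SigmoidParams(5000.0, 0.0, 300.0, 60.0),
                           icv_coupling=0.0,
                           study_batch_frac={"A": 0.0, "B": 0.0, "C": 0.0},
                           group_frac={"control": 0.0, "premanifest": 0.0, "manifest": 0.0})
        lin = fit_linear(ds)
        assert lin.slope == pytest.approx(0.0, abs=1e-9)
        assert lin.rss == pytest.approx(0.0, abs=1e-9)

    def test_exact_line_recovered(self):
        ds = probe_dataset(seed=9)
        y = 4.0 - 0.01 * ds.cap
        lin = ProfileFitter(ds).fit_linear(y)
        assert lin.slope == pytest.approx(-0.01, rel=1e-9)
        assert lin.rss == pytest.approx(0.0, abs=1e-12)


class TestComparison:
    def test_stat_hand_arithmetic(self):
        # rss halved, n=100, two extra sigmoid parameters
        assert improvement_stat(2.0, 1.0, 100, 7, 5) == pytest.approx((100 - 7) / 2)
        assert improvement_stat(1.0, 1.0, 100, 7, 5) == 0.0

    def test_mismatched_sizes_rejected(self):
        ds_a, ds_b = probe_dataset(seed=1), probe_dataset(seed=1, n_carriers=120)
        with pytest.raises(ValueError, match="different sizes"):
            compare_models(fit_sigmoid(ds_a), fit_linear(ds_b), fit_constant(ds_b))

    def test_bic_fallback_prefers_sigmoid_on_sigmoid_truth(self):
        ds = probe_dataset(seed=13)
        cmp = compare_models(fit_sigmoid(ds), fit_linear(ds), fit_constant(ds))
        assert cmp.sigmoid_preferred
        assert cmp.stat > 0
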