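"""Detection-function fitting, selection, GOF and the strip-width rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from nestsurvey import (
    DetectionModelSpec,
    DistanceSample,
    NumericalError,
    SchemaError,
    fit_detection,
    goodness_of_fit,
    select_detection_model,
    strip_half_width,
    truncate,
)


class TestTruncate:
    def test_fixed_w_drops_tail_and_records_tally(self):
        dists = np.concatenate([np.linspace(0, 40, 30), [55.0, 84.0]])
        s = truncate(dists, w=42.0)
        assert s.w == 42.0
        assert s.distances.max() <= 42.0
        assert s.n_discarded == 2
        assert s.n == 30

    def test_infinite_w_is_identity(self):
        dists = [1.0, 5.0, 99.0]
        s = truncate(dists, w=np.inf)
        assert s.n == 3 and s.n_discarded == 0
        np.testing.assert_array_equal(np.sort(s.distances), dists)

    def test_five_percent_of_twenty_removes_exactly_one(self):
        dists = np.arange(1.0, 21.0)  # 1..20
        s = truncate(dists, discard_fraction=0.05)
        assert s.n == 19
        assert s.n_discarded == 1
        assert s.w == 19.0  # largest retained value

    def test_errors(self):
        with pytest.raises(SchemaError, match="no observations"):
            truncate([], w=42.0)
        with pytest.raises(SchemaError):
            truncate([1.0, 2.0], w=-1.0)
        with pytest.raises(SchemaError):
            truncate([1.0], w=1.0, discard_fraction=0.05)

    def test_dataframe_labels_survive(self, obs_frame):
        s = truncate(obs_frame, w=30.0)
        assert s.habitat is not None
        assert s.habitat.shape == s.distances.shape


class TestFitDetection:
    def test_uniform_no_adjustment_is_flat(self):
        s = truncate([3.0, 10.0, 22.0, 40.0], w=42.0)
        fit = fit_detection(s, DetectionModelSpec("uniform", 0))
        assert fit.f0 == pytest.approx(1.0 / 42.0, rel=1e-12)
        assert fit.loglik == pytest.approx(-4 * np.log(42.0), rel=1e-12)
        assert fit.aic == pytest.approx(-2 * fit.loglik)

    def test_half_normal_mle_matches_grid_search(self):
        s = truncate([5.0, 10.0, 15.0, 20.0], w=42.0)
        fit = fit_detection(s, DetectionModelSpec("half-normal", 0))
        # independent oracle: dense grid over the truncated likelihood
        sigmas = np.linspace(0.1, 200.0, 20000)
        y = s.distances

        def loglik(sig):
            mu = sig * np.sqrt(np.pi / 2) * stats.norm.cdf(42.0 / sig) * 2 - sig * np.sqrt(np.pi / 2)
            mu = sig * np.sqrt(np.pi / 2) * (2 * stats.norm.cdf(42.0 / sig) - 1)
            return np.sum(-0.5 * (y / sig) ** 2) - y.size * np.log(mu)

        lls = np.array([loglik(sg) for sg in sigmas])
        sigma_star = sigmas[np.argmax(lls)]
        assert fit.sigma == pytest.approx(sigma_star, rel=1e-3)

    @pytest.mark.parametrize(
        "spec",
        [
            DetectionModelSpec("uniform", 1),
            DetectionModelSpec("uniform", 2),
            DetectionModelSpec("half-normal", 0),
            DetectionModelSpec("half-normal", 1),
        ],
        ids=str,
    )
    def test_mle_beats_parameter_grid_and_integrates_to_one(self, spec):
        rng = np.random.default_rng(3)
        y = np.abs(rng.normal(0, 14, size=50))
        s = truncate(y, w=35.0)
        fit = fit_detection(s, spec)
        # fitted density integrates to 1 (numeric quadrature, independent rule)
        integral, _ = integrate.quad(lambda x: float(fit.pdf(x)), 0.0, s.w, limit=200)
        assert integral == pytest.approx(1.0, abs=1e-6)
        # returned loglik >= loglik at any grid point (coarse oracle grid)
        k = spec.n_free_params
        rng2 = np.random.default_rng(7)
        grid = rng2.uniform(-0.9, 0.9, size=(200, k))
        if spec.key == "half-normal":
            grid[:, 0] = np.exp(rng2.uniform(np.log(2), np.log(100), size=200))
        from nestsurvey.detection import _neg_loglik

        cgrid = np.linspace(0.0, s.w, 512)
        for theta in grid:
            assert -fit.loglik <= _neg_loglik(theta, s.distances, spec.key, s.w, cgrid) + 1e-6

    def test_uniform_cosine_f0_analytic_identity(self):
        rng = np.random.default_rng(11)
        y = np.abs(rng.normal(0, 12, size=80))
        s = truncate(y, w=40.0)
        for m in (1, 2):
            fit = fit_detection(s, DetectionModelSpec("uniform", m))
            # for the uniform key the cosine terms integrate to zero over [0, w]
            assert fit.f0 * fit.w == pytest.approx(1.0 + fit.adjustments.sum(), abs=1e-8)

    def test_detection_curve_nonnegative_and_shouldered(self):
        rng = np.random.default_rng(5)
        y = np.abs(rng.normal(0, 10, size=100))
        s = truncate(y, w=30.0)
        fit = fit_detection(s, DetectionModelSpec("uniform", 2))
        xs = np.linspace(0, s.w, 1001)
        g = fit.g(xs)
        assert (g >= -1e-9).all()
        assert fit.f0 > 0
        assert fit.f0 * s.w >= 1.0 - 1e-6  # monotone non-increasing g implies f0*w >= 1

    def test_overparameterized_raises(self):
        s = truncate([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], w=10.0)
        with pytest.raises(NumericalError, match="overparameterized"):
            fit_detection(s, DetectionModelSpec("uniform", 3))


class TestModelSelection:
    def test_single_candidate_returns_it_without_delta(self, obs_frame):
        s = truncate(obs_frame, w=42.0)
        sel = select_detection_model(s, [DetectionModelSpec("half-normal", 0)])
        assert sel.best.spec == DetectionModelSpec("half-normal", 0)
        assert sel.delta_aic is None

    def test_selection_invariant_to_candidate_order(self, obs_frame):
        s = truncate(obs_frame, w=42.0)
        cands = [
            DetectionModelSpec("uniform", 0),
            DetectionModelSpec("uniform", 1),
            DetectionModelSpec("half-normal", 0),
            DetectionModelSpec("half-normal", 1),
        ]
        a = select_detection_model(s, cands)
        b = select_detection_model(s, cands[::-1])
        assert a.best.spec == b.best.spec
        assert a.delta_aic == pytest.approx(b.delta_aic)

    def test_ties_break_toward_fewer_parameters(self):
        # uniform data: adding cosine terms cannot beat the flat model by AIC,
        # and equal-loglik models must resolve to the smaller one
        rng = np.random.default_rng(1)
        s = truncate(rng.uniform(0, 42, size=200), w=42.0)
        sel = select_detection_model(
            s, [DetectionModelSpec("uniform", 1), DetectionModelSpec("uniform", 0)]
        )
        assert sel.best.spec.n_adjustments == 0

    def test_all_failures_aggregate(self):
        s = truncate([1.0, 2.0, 3.0, 4.0, 5.0], w=10.0)
        with pytest.raises(NumericalError, match="all candidate"):
            select_detection_model(s, [DetectionModelSpec("uniform", 3)])


class TestGoodnessOfFit:
    def test_chi_square_hand_example(self):
        # flat fit on [0, 30], 3 equal bins with observed counts 6, 3, 1:
        # expected 10/3 each, chi2 = sum (O-E)^2/E = 3.80, df = 2
        y = np.concatenate([
            np.linspace(0.5, 9.5, 6), np.linspace(10.5, 19.5, 3), [25.0]
        ])
        s = DistanceSample(y, w=30.0)
        fit = fit_detection(s, DetectionModelSpec("uniform", 0))
        rep = goodness_of_fit(fit, s, n_bins=3)
        assert rep.chisq_stat == pytest.approx(3.80, abs=0.01)
        assert rep.chisq_df == 2
        assert 0 <= rep.chisq_p <= 1 and 0 <= rep.ks_p <= 1 and 0 <= rep.cvm_p <= 1

    def test_perfect_fit_gives_zero_chi_square(self):
        # equal counts in every bin of a flat density
        y = np.concatenate([np.full(5, c) for c in (5.0, 15.0, 25.0)])
        s = DistanceSample(y, w=30.0)
        fit = fit_detection(s, DetectionModelSpec("uniform", 0))
        rep = goodness_of_fit(fit, s, n_bins=3)
        assert rep.chisq_stat == pytest.approx(0.0, abs=1e-12)

    def test_correct_model_passes_gof_most_of_the_time(self):
        # sampling from the fitted model itself: all three p-values should
        # exceed 0.05 in the vast majority of replicates
        rng = np.random.default_rng(2024)
        sigma, w = 15.0, 40.0
        ok = 0
        n_rep = 100
        for _ in range(n_rep):
            y = np.abs(rng.normal(0, sigma, size=400))
            y = y[y <= w][:200]
            s = DistanceSample(y, w=w)
            fit = fit_detection(s, DetectionModelSpec("half-normal", 0))
            rep = goodness_of_fit(fit, s, n_bins=6)
            ok += rep.passed(0.05)
        assert ok >= 0.90 * n_rep

    def test_sparse_bins_raise(self):
        s = DistanceSample(np.linspace(0.1, 9.9, 12), w=10.0)
        fit = fit_detection(s, DetectionModelSpec("uniform", 0))
        with pytest.raises(NumericalError, match="fewer bins"):
            goodness_of_fit(fit, s, n_bins=30)


class TestStripHalfWidth:
    def test_half_normal_closed_form(self):
        s = DistanceSample(np.array([5.0, 8.0, 12.0, 20.0, 3.0]), w=42.0)
        fit = fit_detection(s, DetectionModelSpec("half-normal", 0))
        expected = fit.sigma * np.sqrt(2.0 * np.log(1.0 / 0.9))
        assert strip_half_width(fit, tau=0.9) == pytest.approx(expected, rel=1e-6)

    def test_flat_detection_spans_the_whole_strip(self):
        s = DistanceSample(np.array([1.0, 2.0, 3.0, 4.0, 5.0]), w=42.0)
        fit = fit_detection(s, DetectionModelSpec("uniform", 0))
        for tau in (0.5, 0.9, 1.0):
            assert strip_half_width(fit, tau=tau) == pytest.approx(42.0)

    def test_habitat_specific_fits_give_habitat_specific_widths(self, default_survey):
        obs = default_survey.mnc_observations()
        sample = truncate(obs, w=44.0)
        widths = {}
        for h, sub in sample.by_habitat().items():
            if sub.n < 10:
                continue
            fit = fit_detection(sub, DetectionModelSpec("half-normal", 0))
            widths[h] = strip_half_width(fit)
        assert len(widths) >= 2
        assert len({round(v, 3) for v in widths.values()}) == len(widths)


@settings(max_examples=25, deadline=None)
@given(
    sigma=st.floats(5.0, 40.0),
    w=st.floats(20.0, 80.0),
    tau=st.floats(0.5, 0.99),
)
def test_strip_width_never_exceeds_truncation(sigma, w, tau):
    y = np.abs(np.random.default_rng(0).normal(0, sigma, size=60))
    y = np.clip(y, 0, w - 1e-6)
    s = DistanceSample(y, w=w)
    fit = fit_detection(s, DetectionModelSpec("half-normal", 0))
    assert 0.0 <= strip_half_width(fit, tau=tau) <= w
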