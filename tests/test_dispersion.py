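"""Conical-dispersion pipeline: line normalization, quadratic MSD model,
threshold curves, and the chi-squared reference for scaled deviations."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from plreg import (
    CountMatrix,
    QuadraticErrorModel,
    chisq_reference,
    run_dispersion_pipeline,
    survival_function,
    threshold_curve,
)
from plreg.dispersion import (
    decompose,
    fit_mer_line,
    fit_quadratic_msd,
    initial_error_guess,
    min_count_set,
    msd,
    normalize_to_unit_line,
    scaled_difference,
    scaled_rms_deviation,
)
from plreg.synthdata import CountGeneratorSpec, generate_counts

Q_TRUE = (10.0, 1.0, 0.01)


def conical_counts(seed, n_tags=5000, m=4, log10_range=(0.5, 3.5), **kw):
    """Synthetic conical replicate counts spanning 3 decades above the
    noise floor sqrt(q0)."""
    spec = CountGeneratorSpec(n_tags=n_tags, m_reps=m,
                              log10_range=log10_range, q_true=Q_TRUE,
                              seed=seed, **kw)
    return generate_counts(spec)


class TestMinCountSet:
    def test_zero_mean_tags_never_included(self):
        counts = CountMatrix(np.array([[0, 0], [1, 1], [2, 2], [3, 3.0]]))
        idx = min_count_set(counts, fraction=0.5)
        assert 0 not in idx

    def test_exact_smallest_selected(self):
        gbar = np.arange(1.0, 101.0)
        counts = CountMatrix(np.column_stack([gbar, gbar]))
        idx = min_count_set(counts, fraction=0.02)
        np.testing.assert_array_equal(idx, [0, 1])

    def test_ties_broken_by_tag_order(self):
        counts = CountMatrix(np.array([[2, 2], [1, 1], [1, 1], [5, 5.0]]))
        idx = min_count_set(counts, fraction=0.5)
        np.testing.assert_array_equal(idx, [1, 2])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            min_count_set(CountMatrix(np.zeros((4, 2))))


class TestInitialErrorGuess:
    def test_pooled_variance_hand_computed(self):
        # min set is the single lowest-mean tag with counts (1, 3): var = 2
        counts = CountMatrix(np.array([[1, 3], [100, 100], [200, 200.0]]))
        model = initial_error_guess(counts, q2_init=0.01, fraction=0.34)
        assert model.q0 == pytest.approx(2.0)
        assert model.q1 == 0.0
        assert model.q2 == 0.01

    def test_degenerate_variance_clamped_with_warning(self):
        counts = CountMatrix(np.array([[2, 2], [100, 100], [200, 200.0]]))
        with pytest.warns(UserWarning, match="clamped"):
            model = initial_error_guess(counts, fraction=0.34)
        assert model.q0 == 1.0

    def test_unusual_q2_warns(self):
        counts = CountMatrix(np.array([[1, 3], [100, 100], [200, 200.0]]))
        with pytest.warns(UserWarning, match="q2"):
            initial_error_guess(counts, q2_init=0.5, fraction=0.34)


class TestDecomposeMSD:
    def test_mean_deviation_split(self):
        delta, gbar = decompose([3.0, 5.0])
        assert gbar == 4.0
        np.testing.assert_allclose(delta, [-1.0, 1.0])
        assert msd(delta) == 1.0

    def test_constant_vector_zero_deviation(self):
        delta, _ = decompose([7.0, 7.0, 7.0])
        np.testing.assert_allclose(delta, 0.0)
        assert msd(delta) == 0.0

    @given(st.lists(st.floats(-1e4, 1e4), min_size=2, max_size=8))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_deviation_orthogonal_to_ones(self, g):
        delta, gbar = decompose(g)
        assert abs(np.sum(delta)) <= 1e-8 * (1 + np.max(np.abs(g)))
        np.testing.assert_allclose(delta + gbar, g, atol=1e-9)

    def test_expected_msd_matches_closed_form(self):
        """E[MSD] for m normal replicates N(mu, s) is s^2 (m-1)/m (the
        sample-mean centering removes one degree of freedom)."""
        rng = np.random.default_rng(3)
        m, s = 4, 2.0
        sims = rng.normal(10.0, s, size=(40000, m))
        msd_vals = np.sum((sims - sims.mean(1, keepdims=True)) ** 2, 1) / m
        expected = s * s * (m - 1) / m
        se = msd_vals.std() / np.sqrt(len(msd_vals))
        assert abs(msd_vals.mean() - expected) < 4 * se


class TestFitQuadraticMSD:
    def test_exact_quadratic_interpolated(self):
        gbar = np.logspace(0, 3, 40)
        msd_vals = 2.0 + 0.5 * gbar + 0.01 * gbar**2
        q = fit_quadratic_msd(gbar, msd_vals, QuadraticErrorModel(*Q_TRUE))
        np.testing.assert_allclose(q, (2.0, 0.5, 0.01), atol=1e-8)

    def test_negative_q2_clipped_and_refit(self):
        gbar = np.logspace(0, 3, 40)
        msd_vals = 2.0 + 0.5 * gbar - 1e-5 * gbar**2
        q = fit_quadratic_msd(gbar, msd_vals, QuadraticErrorModel(*Q_TRUE))
        assert q[2] == 0.0
        assert q[1] > 0

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError):
            fit_quadratic_msd(np.full(20, 5.0), np.full(20, 1.0),
                              QuadraticErrorModel(*Q_TRUE))

    def test_stochastic_recovery_from_msd_sampling_model(self):
        """MSD values drawn from their exact sampling law (scaled chi-
        squared about the conical variance) recover the variance law
        within 20% per coefficient; the (m-1)/m factor comes from the
        divisor-m MSD."""
        rng = np.random.default_rng(42)
        m, n = 4, 5000
        gbar = 10.0 ** rng.uniform(0, 3, n)
        s2 = Q_TRUE[0] + Q_TRUE[1] * gbar + Q_TRUE[2] * gbar**2
        msd_vals = s2 * rng.chisquare(m - 1, n) / m
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            q = fit_quadratic_msd(gbar, msd_vals, QuadraticErrorModel(*Q_TRUE))
        expected = (m - 1) / m * np.asarray(Q_TRUE)
        assert q[0] == pytest.approx(expected[0], rel=0.2)
        assert q[1] == pytest.approx(expected[1], rel=0.2)
        assert q[2] == pytest.approx(expected[2], rel=0.2)


class TestLineAndNormalization:
    def test_identical_replicates_unit_slope(self):
        g = np.logspace(0, 3, 200)
        cm = CountMatrix(np.column_stack([g, g, g]))
        line = fit_mer_line(cm, QuadraticErrorModel(1.0, 0, 0.01))
        ratios = line.slope / line.slope[0]
        np.testing.assert_allclose(ratios, 1.0, rtol=1e-10)

    def test_proportional_replicate_slope_ratio(self):
        g = np.logspace(0, 3, 200)
        cm = CountMatrix(np.column_stack([g, 2.0 * g]))
        line = fit_mer_line(cm, QuadraticErrorModel(1.0, 0, 0.01))
        assert line.slope[1] / line.slope[0] == pytest.approx(2.0, rel=1e-8)

    def test_normalization_round_trip_refit_is_unit(self):
        """Counts with an embedded (offset, scale) line map onto the unit
        line: refitting after normalization gives slope ratios of 1."""
        cm, truth = conical_counts(seed=3, offsets=(0.0, 5.0, 0.0, 0.0),
                                   scales=(1.0, 2.0, 1.0, 1.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            line = fit_mer_line(cm, QuadraticErrorModel(*Q_TRUE))
            assert line.slope[1] / line.slope[0] == pytest.approx(2.0,
                                                                  rel=0.05)
            norm = normalize_to_unit_line(cm, line)
            refit = fit_mer_line(norm, QuadraticErrorModel(*Q_TRUE))
        np.testing.assert_allclose(refit.slope / refit.slope[0], 1.0,
                                   rtol=0.05)

    def test_zero_slope_rejected(self):
        from plreg import LineModel

        cm = CountMatrix(np.ones((5, 2)))
        with pytest.raises(ValueError):
            normalize_to_unit_line(cm, LineModel([0.0, 0.0], [1.0, 0.0]))

    def test_negative_transformed_values_retained(self):
        from plreg import LineModel

        cm = CountMatrix(np.array([[1.0, 1.0], [10.0, 10.0]]))
        norm = normalize_to_unit_line(cm, LineModel([5.0, 5.0], [1.0, 1.0]))
        assert np.all(norm.counts[0] < 0)


class TestPipeline:
    def test_noiseless_proportional_replicates_converge_fast(self):
        g = np.logspace(0, 3, 400)
        cm = CountMatrix(np.column_stack([g, g, g]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = run_dispersion_pipeline(cm)
        assert fit.converged
        assert fit.q[1] == pytest.approx(0.0, abs=1e-6)
        assert fit.q[2] == pytest.approx(0.0, abs=1e-8)

    def test_round_trip_q_recovery_over_seeds(self):
        """Pipeline recovery of the conical law over 10 seeds, m=4, 5000
        tags, 3 decades: q2 within 20%, q1 within 30%, q0 within 50% of
        the divisor-adjusted truth."""
        m = 4
        recovered = []
        for seed in range(10):
            cm, _ = conical_counts(seed=seed, m=m)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = run_dispersion_pipeline(cm)
            recovered.append(fit.q)
        mean_q = np.mean(recovered, axis=0)
        expected = (m - 1) / m * np.asarray(Q_TRUE)
        assert mean_q[0] == pytest.approx(expected[0], rel=0.5)
        assert mean_q[1] == pytest.approx(expected[1], rel=0.3)
        assert mean_q[2] == pytest.approx(expected[2], rel=0.2)

    def test_round_trip_three_replicates(self):
        m = 3
        cm, _ = conical_counts(seed=77, m=m)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = run_dispersion_pipeline(cm)
        assert fit.q[2] == pytest.approx((m - 1) / m * Q_TRUE[2], rel=0.25)

    def test_stable_on_own_normalized_output(self):
        """Rerunning the pipeline on its own normalized output leaves the
        line essentially at unit slope and the Poisson-like and
        overdispersion coefficients nearly unchanged; the background q0 is
        the least stable coefficient (it hinges on the noisy lowest-count
        region and the re-anchored intercept)."""
        cm, _ = conical_counts(seed=5, log10_range=(0.0, 4.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = run_dispersion_pipeline(cm)
            # keep the negatives the normalization legitimately produces
            norm = normalize_to_unit_line(cm, fit.line)
            fit2 = run_dispersion_pipeline(norm)
        # absolute slope components carry the common kappa_tau attenuation,
        # so "unit" means within that factor
        np.testing.assert_allclose(fit2.line.slope, 1.0, rtol=0.03)
        assert fit2.q[1] == pytest.approx(fit.q[1], rel=0.05)
        assert fit2.q[2] == pytest.approx(fit.q[2], rel=0.05)
        assert fit2.q[0] == pytest.approx(fit.q[0], rel=0.35)

    def test_high_mean_exclusion_fraction_reported(self):
        """4% of tags built above the mean cap are reported as excluded
        from fitting while remaining in the outputs."""
        rng = np.random.default_rng(8)
        n = 2500
        g = 10 ** rng.uniform(0.5, np.log10(1500), n)
        n_high = int(round(0.04 * n))
        g[:n_high] = rng.uniform(3000, 5000, n_high)
        noise = rng.standard_normal((n, 4)) * np.sqrt(
            Q_TRUE[0] + Q_TRUE[1] * g + Q_TRUE[2] * g**2)[:, None]
        cm = CountMatrix(np.maximum(g[:, None] + noise, 0.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = run_dispersion_pipeline(cm, gmax=2000.0)
        assert fit.excluded_fraction == pytest.approx(0.04, abs=0.005)
        assert len(fit.gbar) == n  # all tags present in outputs

    def test_normal_data_tail_mass_matches_chi_squared(self):
        """The fraction of tags beyond the |d|=2-equivalent scaled-
        deviation band on purely normal data matches the chi-squared tail
        mass within binomial error."""
        cm, _ = conical_counts(seed=21, n_tags=8000, log10_range=(1.0, 3.2))
        m = cm.m_reps
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = run_dispersion_pipeline(cm)
        keep = ~(fit.mask_zero_mean | fit.mask_high_mean)
        # the fitted variance law absorbs the (m-1)/m divisor factor, so
        # the chi-squared-distributed statistic is (m-1) * drms^2
        stat = (m - 1) * fit.delta_rms[keep] ** 2
        # band: values above the chi2_{m-1} quantile matching 2-sigma
        level = stats.chi2(m - 1).ppf(0.97725)
        frac = np.mean(stat > level)
        p = 1 - 0.97725
        se = np.sqrt(p * (1 - p) / keep.sum())
        assert abs(frac - p) < 6 * se + 0.01


class TestScaledDifference:
    def test_hand_arithmetic(self):
        assert scaled_difference(4.0, 1.0, 4.0, 5.0) == 1.0

    def test_zero_for_equal_values(self):
        assert scaled_difference(3.0, 3.0, 1.0, 1.0) == 0.0

    def test_antisymmetry(self):
        assert scaled_difference(5.0, 2.0, 1.0, 2.0) == \
            -scaled_difference(2.0, 5.0, 2.0, 1.0)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            scaled_difference(1.0, 2.0, 0.0, 0.0)


class TestThresholdCurve:
    def test_hand_solved_roots(self):
        out = threshold_curve((0.0, 0.0, 0.05), 2.0, [10.0],
                              QuadraticErrorModel(0.0, 0.0, 0.05))
        x, roots = out[0]
        np.testing.assert_allclose(roots, [5.0, 20.0])

    def test_roots_reproduce_d_level_by_substitution(self):
        q = (2.0, 0.5, 0.02)
        model_x = QuadraticErrorModel(2.0, 0.5, 0.02)
        for x, roots in threshold_curve(q, 2.0, np.logspace(0, 3, 25),
                                        model_x):
            s2x = 2.0 + 0.5 * x + 0.02 * x * x
            for y in roots:
                s2y = q[0] + q[1] * y + q[2] * y * y
                d = scaled_difference(x, y, s2x, s2y)
                assert abs(abs(d) - 2.0) < 1e-6

    def test_degenerate_linear_case(self):
        # q2 = 1/d^2 kills the quadratic term; with q1 > 0 a single root
        q = (1.0, 0.5, 0.25)
        out = threshold_curve(q, 2.0, [10.0], QuadraticErrorModel(0.0, 0, 0))
        x, roots = out[0]
        assert len(roots) == 1
        s2y = q[0] + q[1] * roots[0] + q[2] * roots[0] ** 2
        assert abs(abs(scaled_difference(10.0, roots[0], 0.0, s2y)) - 2.0) \
            < 1e-6

    def test_symmetric_roles_of_x_and_y(self):
        """Under identical models for both axes, y is a root at x exactly
        when x is a root at y."""
        q = (2.0, 0.5, 0.02)
        model = QuadraticErrorModel(*q)
        x0 = 50.0
        _, roots = threshold_curve(q, 2.0, [x0], model)[0]
        for y0 in roots:
            _, back = threshold_curve(q, 2.0, [y0], model)[0]
            assert any(abs(x0 - b) < 1e-6 * x0 for b in back)


class TestSurvivalFunction:
    def test_simple_fractions(self):
        curve = survival_function([1.0, 2.0, 3.0])
        assert curve(1.5) == pytest.approx(2 / 3)
        assert curve(0.0) == 1.0
        assert curve(3.0) == 0.0

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_non_increasing_and_matches_ecdf(self, values):
        curve = survival_function(values)
        assert np.all(np.diff(curve.survival) <= 0)
        v = np.sort(np.asarray(values))
        for u, s in zip(curve.values, curve.survival):
            assert s == pytest.approx(np.mean(v > u))


class TestChisqReference:
    def test_m2_statistic_is_chi_squared_1(self):
        """For duplicates the scaled deviation statistic m*drms^2 equals
        the squared scaled difference and follows chi-squared with 1 df."""
        gbar = np.full(30000, 100.0)
        _, drms = chisq_reference(2, 30000, gbar, Q_TRUE, seed=4)
        stat = 2 * drms**2
        assert stat.mean() == pytest.approx(1.0, rel=0.03)
        ks = stats.kstest(stat, stats.chi2(1).cdf)
        assert ks.pvalue > 1e-3

    def test_m4_mean_matches_df(self):
        gbar = np.logspace(1, 3, 30000)
        _, drms = chisq_reference(4, 30000, gbar, Q_TRUE, seed=6)
        stat = 4 * drms**2
        assert stat.mean() == pytest.approx(3.0, rel=0.02)
        ks = stats.kstest(stat, stats.chi2(3).cdf)
        assert ks.pvalue > 1e-3

    def test_heavy_tailed_data_decays_slower_than_reference(self):
        """A heavy-tailed subpopulation makes the observed scaled-
        deviation survival curve decay slower than the normal reference."""
        cm, truth = conical_counts(seed=10, n_tags=6000,
                                   heavy_tail_fraction=0.05,
                                   heavy_tail_inflation=10.0)
        m = cm.m_reps
        gbar = cm.counts.mean(1)
        msd_vals = np.sum((cm.counts - gbar[:, None]) ** 2, 1) / m
        drms_obs = scaled_rms_deviation(
            msd_vals, np.maximum(gbar, 1.0), Q_TRUE) * np.sqrt(m / (m - 1))
        obs = survival_function(drms_obs)
        ref, _ = chisq_reference(m, 30000, gbar, Q_TRUE, seed=11)
        for level in (3.0, 4.0):
            assert obs(level) > ref(level)
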