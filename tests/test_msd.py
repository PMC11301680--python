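"""Apparent-D estimator, Gamma density/mixture, partitioning and rolling-D."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hyp_st
from scipy import stats
from scipy.integrate import quad

import smtrack as st
from smtrack.config import ValidationError
from smtrack import msd as M

from conftest import make_track

DT = 0.030475


class TestEstimateD:
    def test_stationary_track_is_exactly_zero(self):
        track = make_track(np.zeros((6, 2)))
        assert M.estimate_D(track, 4, DT) == 0.0

    def test_direct_arithmetic_recovers_immobile_value(self):
        # four steps of squared length 0.0048760 um^2 each:
        # D = 0.0048760 / (4 * 0.030475) = 0.04 um^2/s
        step = np.sqrt(0.0048760)
        track = make_track(np.column_stack([np.arange(5) * step, np.zeros(5)]))
        assert M.estimate_D(track, 4, DT) == pytest.approx(0.0048760 / (4 * DT), rel=1e-12)
        assert M.estimate_D(track, 4, DT) == pytest.approx(0.04, rel=1e-4)

    def test_gap_step_uses_true_lag(self):
        # one unit-lag step and one lag-2 step, each of squared length s2
        s2 = 0.01
        d = np.sqrt(s2)
        track = make_track(
            [[0, 0], [d, 0], [2 * d, 0]], frames=[0, 1, 3]
        )
        expected = 2 * s2 / (4 * 3 * DT)
        assert M.estimate_D(track, 2, DT) == pytest.approx(expected, rel=1e-12)

    def test_unbiased_at_fast_state_value(self):
        # 1e5 unconfined noise-free 4-step tracks at the fast-state D
        model = st.DiffusionModel([0.99], [[1.0]], [1.0])
        from smtrack.simulate import simulate_displacement_segments
        disp, _ = simulate_displacement_segments(model, 100_000, 4, DT, rng_seed=0)
        d2 = np.stack([(d ** 2).sum(axis=1) for d in disp])
        d_app = d2.sum(axis=1) / (4 * 4 * DT)
        assert d_app.mean() == pytest.approx(0.99, rel=0.01)

    def test_too_short_rejected(self):
        track = make_track(np.zeros((4, 2)))
        with pytest.raises(ValidationError):
            M.estimate_D(track, 4, DT)

    def test_table_counts_rejections_and_matches_scalar(self):
        rng = np.random.default_rng(5)
        rows = []
        for i, n in enumerate([3, 5, 8]):
            rows.append(make_track(rng.normal(size=(n, 2)), track_id=i))
        traj = pd.concat(rows, ignore_index=True)
        est, rej = M.estimate_D_table(traj, 4, DT)
        assert rej == {"too_short": 1}
        assert set(est["track_id"]) == {1, 2}
        for tid in (1, 2):
            scalar = M.estimate_D(traj[traj.track_id == tid], 4, DT)
            assert est.loc[est.track_id == tid, "D_app_um2s"].item() == pytest.approx(scalar)

    def test_stationary_with_noise_offset_sigma2_over_dt(self):
        # documents that D_app is apparent: pure localization noise gives
        # mean D_app = sigma^2 / dt
        sigma = 0.035
        rng = np.random.default_rng(8)
        noise = rng.standard_normal((10_000, 5, 2)) * sigma
        d2 = (np.diff(noise, axis=1) ** 2).sum(axis=2)
        d_app = d2.sum(axis=1) / (4 * 4 * DT)
        assert d_app.mean() == pytest.approx(sigma ** 2 / DT, rel=0.05)


class TestGammaPdf:
    def test_shape_one_is_exponential(self):
        x = np.linspace(0, 2, 50)
        np.testing.assert_allclose(M.gamma_pdf(x, 1, 0.3), np.exp(-x / 0.3) / 0.3)

    def test_matches_explicit_formula(self):
        from scipy.special import gamma as gamma_fn
        n, D = 4, 0.21
        x = np.linspace(1e-4, 1.5, 40)
        explicit = (n / D) ** n * x ** (n - 1) * np.exp(-n * x / D) / gamma_fn(n)
        np.testing.assert_allclose(M.gamma_pdf(x, n, D), explicit, rtol=1e-12)

    def test_normalization_and_moments_by_quadrature(self):
        total, _ = quad(lambda x: M.gamma_pdf(x, 4, 0.21), 0, np.inf)
        assert total == pytest.approx(1.0, abs=1e-9)
        mean, _ = quad(lambda x: x * M.gamma_pdf(x, 4, 0.5), 0, np.inf)
        var, _ = quad(lambda x: (x - 0.5) ** 2 * M.gamma_pdf(x, 4, 0.5), 0, np.inf)
        assert mean == pytest.approx(0.5, abs=1e-9)
        assert var == pytest.approx(0.5 ** 2 / 4, abs=1e-9)

    def test_domain_validation(self):
        with pytest.raises(ValidationError):
            M.gamma_pdf([0.1], 0, 0.2)
        with pytest.raises(ValidationError):
            M.gamma_pdf([0.1], 4, -1.0)
        with pytest.raises(ValidationError):
            M.gamma_pdf([-0.1], 4, 0.2)


class TestGammaMixture:
    def test_single_component_mle_consistency(self):
        rng = np.random.default_rng(0)
        x = rng.gamma(shape=4, scale=0.21 / 4, size=20_000)
        fit = M.fit_gamma_mixture(x, 4, 1)
        assert fit.components[0].D == pytest.approx(0.21, abs=0.01)
        assert fit.converged

    def test_three_component_recovery_with_fixed_slow_states(self):
        rng = np.random.default_rng(1)
        weights = [0.35, 0.15, 0.50]
        Ds = [0.04, 0.21, 0.99]
        comp = rng.choice(3, p=weights, size=20_000)
        x = rng.gamma(shape=4, scale=np.take(Ds, comp) / 4)
        fit = M.fit_gamma_mixture(x, 4, 3, fixed_D=[0.04, 0.21], rng_seed=2)
        np.testing.assert_allclose(fit.weights, weights, atol=0.02)
        free = [c for c in fit.components if not c.fixed]
        assert len(free) == 1
        assert free[0].D == pytest.approx(0.99, abs=0.05)

    def test_weights_sum_to_one_and_loglik_finite(self):
        rng = np.random.default_rng(2)
        x = rng.gamma(4, 0.1, size=500)
        fit = M.fit_gamma_mixture(x, 4, 2)
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.isfinite(fit.log_likelihood)

    def test_degenerate_identical_observations_no_crash(self):
        fit = M.fit_gamma_mixture(np.full(100, 0.2), 4, 2)
        assert np.isfinite(fit.log_likelihood)

    def test_zero_values_clamped_not_fatal(self):
        fit = M.fit_gamma_mixture(np.concatenate([np.zeros(50), np.full(50, 0.3)]), 4, 1)
        assert np.isfinite(fit.log_likelihood)

    def test_too_few_components_for_fixed_rejected(self):
        with pytest.raises(ValidationError):
            M.fit_gamma_mixture([0.1, 0.2], 4, 1, fixed_D=[0.04, 0.21])


class TestPartition:
    def test_twelve_localizations_give_two_windows(self):
        track = make_track(np.random.default_rng(0).normal(size=(12, 2)))
        out = M.partition_trajectories(track, 5)
        assert out["track_id"].nunique() == 2
        assert len(out) == 10

    @pytest.mark.parametrize("n,expected", [(5, 1), (4, 0)])
    def test_window_edge_cases(self, n, expected):
        track = make_track(np.zeros((n, 2)))
        out = M.partition_trajectories(track, 5)
        assert out["track_id"].nunique() == expected
        if expected:
            pd.testing.assert_frame_equal(
                out[["frame", "x_um", "y_um"]].reset_index(drop=True),
                track[["frame", "x_um", "y_um"]],
            )

    @given(sizes=hyp_st.lists(hyp_st.integers(1, 23), min_size=1, max_size=8))
    @settings(deadline=None, max_examples=30)
    def test_conservation_property(self, sizes):
        rng = np.random.default_rng(0)
        traj = pd.concat(
            [make_track(rng.normal(size=(n, 2)), track_id=i) for i, n in enumerate(sizes)],
            ignore_index=True,
        )
        out = M.partition_trajectories(traj, 5)
        assert len(out) == sum(5 * (n // 5) for n in sizes)
        # never merges: each subtrack maps to exactly one parent
        assert (out.groupby("track_id")["parent_track_id"].nunique() == 1).all()

    def test_partitioning_blind_to_mobility(self):
        rng = np.random.default_rng(3)
        slow = make_track(rng.normal(scale=0.01, size=(13, 2)), track_id=0)
        fast = make_track(rng.normal(scale=1.0, size=(13, 2)), track_id=1)
        out = M.partition_trajectories(pd.concat([slow, fast], ignore_index=True), 5)
        per_parent = out.groupby("parent_track_id")["track_id"].nunique()
        assert per_parent[0] == per_parent[1] == 2


class TestClassifyMobility:
    @pytest.mark.parametrize("d,expected", [
        (0.0, "immobile"), (0.04, "immobile"), (0.0401, "mobile"), (0.99, "mobile"),
    ])
    def test_threshold_boundary(self, d, expected):
        assert M.classify_mobility(d) == expected


class TestRollingD:
    def test_stationary_track_all_zero(self):
        series = M.rolling_D(make_track(np.zeros((20, 2))), 5, DT)
        assert series.shape == (16,)
        assert np.all(series == 0.0)

    def test_constant_step_length_gives_constant_series(self):
        d = 0.1
        pos = np.column_stack([np.arange(12) * d, np.zeros(12)])
        series = M.rolling_D(make_track(pos), 5, DT)
        np.testing.assert_allclose(series, d ** 2 / (4 * DT))

    def test_short_track_empty(self):
        assert M.rolling_D(make_track(np.zeros((4, 2))), 5, DT).size == 0

    def test_detects_immobile_to_mobile_switch(self):
        rng = np.random.default_rng(4)
        slow = rng.normal(scale=np.sqrt(2 * 0.02 * DT), size=(100, 2))
        fast = rng.normal(scale=np.sqrt(2 * 1.0 * DT), size=(100, 2))
        pos = np.vstack([[0, 0], np.cumsum(np.vstack([slow, fast]), axis=0)])
        series = M.rolling_D(make_track(pos), 5, DT)
        assert series[:90].mean() < series[-90:].mean()


class TestGammaLawProperty:
    def test_empirical_d_app_is_gamma_distributed(self):
        # single-state unconfined noise-free simulation: D_app over 4-step
        # tracks follows Gamma(shape 4, mean D)
        from smtrack.simulate import simulate_displacement_segments
        D = 0.21
        model = st.DiffusionModel([D], [[1.0]], [1.0])
        disp, _ = simulate_displacement_segments(model, 10_000, 4, DT, rng_seed=11)
        d_app = np.array([(d ** 2).sum() / (4 * 4 * DT) for d in disp])
        p = stats.kstest(d_app, stats.gamma(a=4, scale=D / 4).cdf).pvalue
        assert p > 0.01
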