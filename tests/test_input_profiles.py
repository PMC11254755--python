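"""Flow algebra, grids, Gaussian step schedules and the Lorenz drive."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from chemres.input_profiles import (
    FlowSettings,
    LorenzParams,
    ProfileError,
    balance_with_water,
    concentration_from_flow,
    concentration_to_flow,
    gaussian_step_profile,
    integrate_lorenz,
    lorenz_profile,
    lorenz_rhs,
    make_constant_profile,
    residence_time,
    sample_classification_grid,
)


class TestFlowAlgebra:
    def test_flow_from_concentration_matches_dilution_formula(self, settings):
        # 50 mM from a 300 mM stock at 217.5 ul/min total flow
        assert concentration_to_flow(50.0, settings, "dha") == pytest.approx(36.25)

    @pytest.mark.parametrize("c_in,expected", [(0.0, 0.0), (300.0, 217.5)])
    def test_flow_limits(self, settings, c_in, expected):
        assert concentration_to_flow(c_in, settings, "dha") == pytest.approx(expected)

    def test_unreachable_concentration_names_channel(self, settings):
        with pytest.raises(ProfileError, match="dha"):
            concentration_to_flow(400.0, settings, "dha")

    @hsettings(max_examples=50, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=300.0))
    def test_round_trip(self, c):
        settings = FlowSettings()
        flow = concentration_to_flow(c, settings, "dha")
        assert concentration_from_flow(flow, settings, "dha") == pytest.approx(
            c, abs=1e-9
        )

    @pytest.mark.parametrize(
        "volume,flow,expected", [(435.0, 217.5, 2.0), (217.5, 217.5, 1.0), (870.0, 217.5, 4.0)]
    )
    def test_residence_time(self, volume, flow, expected):
        s = FlowSettings(total_flow=flow, reactor_volume=volume)
        assert residence_time(s) == pytest.approx(expected)

    def test_nonpositive_settings_rejected(self):
        with pytest.raises(ProfileError):
            FlowSettings(total_flow=0.0)
        with pytest.raises(ProfileError):
            FlowSettings(reactor_volume=-1.0)


class TestClassificationGrid:
    def test_grid_counts_and_ranges(self):
        grid = sample_classification_grid(n=132, seed=7)
        assert grid.n_points == 132
        assert np.all(grid.raw[:, 0] >= 10) and np.all(grid.raw[:, 0] <= 150)
        assert np.all(grid.raw[:, 1] >= 10) and np.all(grid.raw[:, 1] <= 50)
        assert np.all((grid.normalized >= 0) & (grid.normalized <= 1))

    def test_normalization_is_affine(self):
        grid = sample_classification_grid(n=20, seed=0)
        lo = np.array([10.0, 10.0])
        span = np.array([140.0, 40.0])
        np.testing.assert_allclose(grid.normalized, (grid.raw - lo) / span)

    def test_seeded_determinism(self):
        a = sample_classification_grid(n=50, seed=3)
        b = sample_classification_grid(n=50, seed=3)
        np.testing.assert_array_equal(a.raw, b.raw)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ProfileError):
            sample_classification_grid(n=5, range_1=(10.0, 10.0))


class TestGaussianStepProfile:
    def test_segment_count_and_hold(self):
        profile = gaussian_step_profile(duration_s=3600.0, hold_s=60.0, seed=0)
        assert profile.n_segments == 60
        assert np.all(profile.hold_s == 60.0)

    def test_zero_sd_gives_constant_flow(self):
        profile = gaussian_step_profile(sd_flow=0.0, duration_s=600.0, seed=0)
        np.testing.assert_allclose(profile.flows["dha"], 36.25)

    def test_sample_mean_matches_sampling_distribution(self):
        # 10,000 draws: sample mean within 3 standard errors of 36.25
        profile = gaussian_step_profile(
            duration_s=600_000.0, hold_s=60.0, seed=11
        )
        draws = profile.flows["dha"]
        assert draws.size == 10_000
        se = 10.36 / np.sqrt(draws.size)
        assert abs(draws.mean() - 36.25) < 3 * se

    def test_negative_draws_clipped(self):
        profile = gaussian_step_profile(
            mean_flow=5.0, sd_flow=20.0, duration_s=6000.0, seed=2
        )
        assert np.all(profile.flows["dha"] >= 0)

    def test_partial_final_segment_truncated(self):
        profile = gaussian_step_profile(duration_s=150.0, hold_s=60.0, seed=0)
        assert profile.n_segments == 3
        assert profile.hold_s[-1] == pytest.approx(30.0)
        assert profile.duration_s == pytest.approx(150.0)

    def test_mean_flow_above_total_rejected(self, settings):
        with pytest.raises(ProfileError):
            gaussian_step_profile(mean_flow=300.0, duration_s=600.0, seed=0)


class TestWaterBalance:
    def test_total_flow_conserved_exactly(self, settings):
        profile = gaussian_step_profile(duration_s=1200.0, seed=5)
        total = sum(profile.flows.values())
        np.testing.assert_array_equal(total, np.full(profile.n_segments, 217.5))

    def test_three_channel_example(self, settings):
        profile = make_constant_profile(
            {"dha": 50.0, "naoh": 30.0 * 200 / 217.5, "form": 50.0 * 600 / 217.5},
            duration_s=60.0,
            settings=settings,
        )
        # flows: 36.25 + 30 + 50 -> water fills to 217.5
        np.testing.assert_allclose(profile.flows["water"], 101.25)

    def test_reagents_exceeding_total_flow_rejected(self, settings):
        profile = make_constant_profile({"dha": 50.0}, duration_s=60.0)
        profile.flows["dha"] = np.array([500.0])
        with pytest.raises(ProfileError, match="t=0"):
            balance_with_water(profile, settings)


class TestLorenz:
    def test_fixed_points_are_stationary(self):
        # nontrivial fixed points (+-sqrt(72), +-sqrt(72), 27) for rho=28
        for sign in (1.0, -1.0):
            state = np.array([sign * np.sqrt(72.0), sign * np.sqrt(72.0), 27.0])
            deriv = lorenz_rhs(0.0, state, 10.0, 28.0, 8.0 / 3.0)
            np.testing.assert_allclose(deriv, 0.0, atol=1e-9)

    def test_trajectory_bounded_over_long_run(self):
        params = LorenzParams()
        _, traj = integrate_lorenz(params, duration=120.0, n_points=2000)
        assert np.all(np.isfinite(traj))
        assert np.abs(traj).max() < 100.0
        assert np.all(traj[:, 2] > 0)

    def test_integration_converges_under_tolerance_refinement(self):
        # compare from the shared initial condition (no chaotic transient)
        params = LorenzParams(transient=0.0)
        _, a = integrate_lorenz(params, 10.0, 500, rtol=1e-9, atol=1e-12)
        _, b = integrate_lorenz(params, 10.0, 500, rtol=1e-11, atol=1e-13)
        np.testing.assert_allclose(a, b, atol=1e-4)

    def test_profile_scale_ratios(self):
        profile = lorenz_profile(duration_s=3600.0, hold_s=20.0)
        params = LorenzParams()
        sds = {}
        model_duration = 3600.0 * params.time_compression
        _, traj = integrate_lorenz(params, model_duration, 4096)
        raw_sd = traj.std(axis=0)
        for i, axis in enumerate("xyz"):
            ch = params.axis_channels[axis]
            sds[axis] = profile.concentrations[ch].std() / raw_sd[i]
        # per-axis scale factors 1.4 : 1.0 : 1.3 (hold discretisation ~ few %)
        assert sds["x"] / sds["y"] == pytest.approx(1.4, rel=0.05)
        assert sds["z"] / sds["y"] == pytest.approx(1.3, rel=0.05)

    def test_negative_concentration_instructs_rescaling(self):
        params = LorenzParams(baselines_mM={"naoh": 1.0, "dha": 50.0, "form": 50.0})
        with pytest.raises(ProfileError, match="baseline"):
            lorenz_profile(params, duration_s=3600.0)

    def test_all_concentrations_nonnegative_by_default(self):
        profile = lorenz_profile(duration_s=7200.0)
        for name, arr in profile.concentrations.items():
            assert np.all(arr >= 0), name
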