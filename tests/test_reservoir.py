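"""Surrogate reservoir: network generation, CSTR physics, observation."""

import numpy as np
import pytest

from chemres.input_profiles import gaussian_step_profile, make_constant_profile
from chemres.reservoir import (
    CRNSpec,
    Reaction,
    ReservoirConfig,
    ReservoirError,
    ReservoirTrace,
    bin_average,
    generate_random_crn,
    observation_weights,
    observe,
    simulate_cstr,
    steady_state_features,
)


class TestNetworkGeneration:
    def test_seeded_determinism(self):
        a = generate_random_crn(seed=42)
        b = generate_random_crn(seed=42)
        assert a.species == b.species
        assert [r.format() for r in a.reactions] == [r.format() for r in b.reactions]
        assert a.input_map == b.input_map

    def test_bookkeeping(self):
        crn = generate_random_crn(n_species=40, n_reactions=120, seed=1)
        assert crn.n_species == 40
        assert crn.n_reactions == 120

    def test_every_input_species_consumed(self):
        crn = generate_random_crn(seed=9)
        consumed = {s for rxn in crn.reactions for s, _ in rxn.reactants}
        for channel, target in crn.input_map.items():
            assert target in consumed, channel

    def test_mass_conservation_in_closed_system(self):
        # size-weighted total is a conserved linear combination when k_f=0
        crn = generate_random_crn(n_species=12, n_reactions=30, seed=5)
        R, S, k = crn.stoichiometry()
        sizes = np.array([crn.sizes[s] for s in crn.species], dtype=float)
        np.testing.assert_allclose(S @ sizes, 0.0, atol=1e-12)

    def test_infeasible_fractions_rejected(self):
        with pytest.raises(ReservoirError):
            generate_random_crn(frac_bimolecular=0.9, frac_autocatalytic=0.5)


class TestCSTRSimulation:
    def test_pure_flow_equilibrium(self, inert_crn, quiet_config):
        profile = make_constant_profile({"dha": 20.0}, duration_s=300.0)
        trace = simulate_cstr(inert_crn, profile, quiet_config, x0=[20.0])
        np.testing.assert_allclose(trace.values, 20.0, rtol=1e-6)

    def test_inert_species_matches_closed_form(self, inert_crn, quiet_config):
        profile = make_constant_profile({"dha": 50.0}, duration_s=240.0)
        trace = simulate_cstr(
            inert_crn, profile, quiet_config, rtol=1e-10, atol=1e-12
        )
        t_min = trace.time_s / 60.0
        expected = 50.0 * (1.0 - np.exp(-0.5 * t_min))
        np.testing.assert_allclose(trace.values[:, 0], expected, rtol=1e-6, atol=1e-8)

    def test_initial_state_gap_decays_at_flow_rate(self, inert_crn, quiet_config):
        profile = make_constant_profile({"dha": 10.0}, duration_s=600.0)
        a = simulate_cstr(inert_crn, profile, quiet_config, x0=[0.0],
                          rtol=1e-10, atol=1e-12)
        b = simulate_cstr(inert_crn, profile, quiet_config, x0=[30.0],
                          rtol=1e-10, atol=1e-12)
        gap = b.values[:, 0] - a.values[:, 0]
        expected = 30.0 * np.exp(-0.5 * a.time_s / 60.0)
        np.testing.assert_allclose(gap, expected, rtol=1e-6, atol=1e-8)

    def test_piecewise_inputs_and_state_continuity(self, inert_crn, quiet_config):
        profile = gaussian_step_profile(duration_s=300.0, hold_s=60.0, seed=4,
                                        constant_mM={})
        trace = simulate_cstr(inert_crn, profile, quiet_config)
        assert np.all(np.isfinite(trace.values))
        # continuity: no jumps larger than what k_f allows over one sample
        steps = np.abs(np.diff(trace.values[:, 0]))
        assert steps.max() < 1.0

    def test_fading_memory_on_fixture_network(self, default_crn):
        config = ReservoirConfig()
        profile = gaussian_step_profile(duration_s=660.0, seed=3)
        a = simulate_cstr(default_crn, profile, config)
        b = simulate_cstr(
            default_crn, profile, config, x0=np.full(default_crn.n_species, 5.0)
        )
        i5 = int(np.argmin(np.abs(a.time_s - 600.0)))  # 5 residence times
        rel = np.abs(a.values - b.values).max(axis=1)[i5] / np.abs(a.values).max()
        assert rel < 0.01

    def test_negative_initial_state_rejected(self, inert_crn, quiet_config):
        profile = make_constant_profile({"dha": 10.0}, duration_s=60.0)
        with pytest.raises(ReservoirError):
            simulate_cstr(inert_crn, profile, quiet_config, x0=[-1.0])

    def test_unmapped_profile_channel_rejected(self, inert_crn, quiet_config):
        profile = make_constant_profile({"dha": 10.0, "naoh": 5.0}, duration_s=60.0)
        with pytest.raises(ReservoirError, match="naoh"):
            simulate_cstr(inert_crn, profile, quiet_config)


class TestNonlinearity:
    def test_steady_state_map_violates_additivity(self, default_crn):
        # f(u1+u2) differs from f(u1)+f(u2)-f(0): what makes XOR learnable.
        # Inputs are form/naoh deviations from the grid-minimum baseline,
        # with DHA and CaCl2 held at their experimental constants.
        config = ReservoirConfig(noise_cv=0.0, noise_floor=0.0,
                                 identity_observation=True)

        def features(form, naoh):
            profile = make_constant_profile(
                {"form": form, "naoh": naoh, "dha": 50.0, "cacl2": 15.0},
                duration_s=600.0,
            )
            trace = simulate_cstr(default_crn, profile, config,
                                  equilibration_min=20.0)
            return steady_state_features(trace)

        f0 = features(10.0, 10.0)
        f1 = features(80.0, 10.0)
        f2 = features(10.0, 30.0)
        f12 = features(80.0, 30.0)
        additive = f1 + f2 - f0
        diff = f12 - additive
        # the interaction term carries a few per cent of the response norm
        assert np.linalg.norm(diff) / np.linalg.norm(f12 - f0) > 0.02
        assert np.abs(diff).max() > 0.5  # mM: well above integrator noise


class TestObservation:
    def test_identity_without_noise_is_lossless(self, inert_crn):
        profile = make_constant_profile({"dha": 10.0}, duration_s=60.0)
        config = ReservoirConfig(noise_cv=0.0, noise_floor=0.0,
                                 identity_observation=True)
        trace = simulate_cstr(inert_crn, profile, config)
        observed = observe(trace, config, seed=1)
        np.testing.assert_array_equal(observed.values, trace.values)

    def test_outputs_nonnegative_under_noise(self, default_crn):
        profile = make_constant_profile(
            {"form": 50.0, "naoh": 30.0, "dha": 50.0, "cacl2": 15.0},
            duration_s=120.0,
        )
        config = ReservoirConfig(noise_cv=0.5, noise_floor=0.5)
        trace = simulate_cstr(default_crn, profile, config)
        observed = observe(trace, config, seed=0)
        assert np.all(observed.values >= 0)

    def test_channel_count(self, default_crn):
        profile = make_constant_profile(
            {"form": 50.0, "naoh": 30.0, "dha": 50.0, "cacl2": 15.0},
            duration_s=60.0,
        )
        config = ReservoirConfig(n_channels=106)
        trace = simulate_cstr(default_crn, profile, config)
        observed = observe(trace, config, seed=0)
        assert observed.values.shape[1] == 106
        assert len(observed.channels) == 106

    def test_observation_map_fixed_noise_varies(self, default_crn):
        profile = make_constant_profile(
            {"form": 50.0, "naoh": 30.0, "dha": 50.0, "cacl2": 15.0},
            duration_s=60.0,
        )
        config = ReservoirConfig()
        trace = simulate_cstr(default_crn, profile, config)
        quiet = ReservoirConfig(noise_cv=0.0, noise_floor=0.0)
        a = observe(trace, quiet, seed=1)
        b = observe(trace, quiet, seed=2)
        np.testing.assert_array_equal(a.values, b.values)  # map is the instrument
        c = observe(trace, config, seed=1)
        d = observe(trace, config, seed=2)
        assert not np.array_equal(c.values, d.values)      # noise is per run

    def test_abundance_weights_deterministic(self, default_crn):
        w1 = observation_weights(default_crn)
        w2 = observation_weights(default_crn)
        np.testing.assert_array_equal(w1, w2)
        assert np.all(w1 >= 0)


class TestFeatureExtraction:
    def test_window_sample_count_and_constant_value(self):
        time_s = np.arange(0, 600, 0.5)
        trace = ReservoirTrace(time_s, np.full((time_s.size, 2), 7.0), ["a", "b"])
        feats = steady_state_features(trace, window_min=5.0)
        np.testing.assert_allclose(feats, 7.0)

    def test_linear_ramp_averages_to_midpoint(self):
        time_s = np.arange(0, 600.5, 0.5)  # inclusive 10-minute window
        ramp = np.linspace(2.0, 4.0, time_s.size)
        trace = ReservoirTrace(time_s, ramp[:, None], ["a"])
        feats = steady_state_features(trace, window_min=10.0)
        assert feats[0] == pytest.approx(3.0, abs=2e-3)

    def test_window_longer_than_trace_rejected(self):
        time_s = np.arange(0, 60, 0.5)
        trace = ReservoirTrace(time_s, np.zeros((time_s.size, 1)), ["a"])
        with pytest.raises(ReservoirError):
            steady_state_features(trace, window_min=10.0)


class TestBinAverage:
    def test_bin_width_and_constant_signal(self):
        time_s = np.arange(0, 100, 0.5)
        trace = ReservoirTrace(time_s, np.full((time_s.size, 1), 3.0), ["a"])
        binned = bin_average(trace, bin_s=10.0)
        assert binned.time_s.size == 10
        np.testing.assert_allclose(binned.values, 3.0)

    def test_noise_variance_shrinks_by_bin_size(self, rng):
        time_s = np.arange(0, 3000, 0.5)
        noise = rng.normal(0.0, 1.0, size=(time_s.size, 1))
        trace = ReservoirTrace(time_s, noise - noise.min(), ["a"])
        binned = bin_average(trace, bin_s=10.0)
        ratio = binned.values.var() / trace.values.var()
        assert ratio == pytest.approx(1 / 20, rel=0.25)

    def test_bin_smaller_than_sampling_rejected(self):
        time_s = np.arange(0, 100, 0.5)
        trace = ReservoirTrace(time_s, np.zeros((time_s.size, 1)), ["a"])
        with pytest.raises(ReservoirError):
            bin_average(trace, bin_s=0.1)

    def test_trailing_partial_bin_dropped(self):
        time_s = np.arange(0, 95, 0.5)  # 9.5 full bins
        trace = ReservoirTrace(time_s, np.zeros((time_s.size, 1)), ["a"])
        binned = bin_average(trace, bin_s=10.0)
        assert binned.time_s.size == 9
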