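"""Synthetic generators: parametric kernels, spiking, the depressing-synapse
model against its closed forms, forward sensors, ribbon tables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retinaln.errors import IntegrationError, ParameterError
from retinaln.kinetics import step_kinetics
from retinaln.ln import LinearFilter, generator_signal
from retinaln.stimulus import make_gaussian_noise, make_step
from retinaln.synth import (
    DepressingSynapse,
    GroundTruthLN,
    Identity,
    calibrate_count_noise_sd,
    make_ground_truth_filter,
    make_ribbon_dataset,
    simulate_depressing_release,
    simulate_epsc,
    simulate_fluorescence,
    simulate_ln_response,
    simulate_spikes,
)
from retinaln.morphometrics import fit_ribbon_regression
from retinaln.presets import bipolar_filter, get_preset


class TestGroundTruthFilter:
    def test_monophasic_when_trough_absent(self):
        f = make_ground_truth_filter(1.0, 0.0, 0.05, 0.08, 1e-3, 0.5)
        assert f.metadata["true_biphasic_index"] == 0.0
        assert f.metadata["true_zero_cross_s"] is None

    def test_mirrored_lobes_give_unit_index(self):
        # identical delayed gamma, equal amplitude: symmetric lobes
        f = make_ground_truth_filter(1.0, 1.0, 0.03, 0.03, 1e-3, 0.8,
                                     trough_delay_s=0.25)
        assert f.metadata["true_biphasic_index"] == pytest.approx(1.0, abs=1e-3)

    def test_window_too_short_for_second_lobe_rejected(self):
        with pytest.raises(ParameterError):
            make_ground_truth_filter(1.0, 0.6, 0.05, 0.08, 1e-3, T_filt_s=0.05)

    def test_first_lobe_is_positive_on_convention(self, biphasic_filter):
        i_peak = np.argmax(np.abs(biphasic_filter.taps))
        first_extreme = biphasic_filter.taps[: i_peak + 1].max()
        assert first_extreme > 0


class TestNonlinearities:
    def test_cumulative_gaussian_is_monotone_and_bounded(self):
        from retinaln.synth import CumulativeGaussian
        nl = CumulativeGaussian(midpoint=1.0, slope_sd=0.5, amplitude=10.0, baseline=2.0)
        g = np.linspace(-5, 5, 1001)
        out = nl(g)
        assert np.all(np.diff(out) >= 0)
        assert out.min() >= 2.0 and out.max() <= 12.0
        assert nl(np.array([1.0]))[0] == pytest.approx(7.0)  # half-max at midpoint


class TestLNResponse:
    def test_impulse_identity_returns_contrast(self, noise_stim):
        imp = LinearFilter(np.array([1.0 / noise_stim.dt, 0.0]), noise_stim.dt)
        resp = simulate_ln_response(GroundTruthLN(imp, Identity()), noise_stim)
        assert np.allclose(resp, noise_stim.contrast)

    def test_step_response_matches_convolution_oracle(self):
        preset = get_preset("ons")
        filt = preset.ground_truth_filter()
        step = make_step(1000.0, 0.5, 0.5, 0.5, 2.0, 1e-3)
        resp = simulate_ln_response(GroundTruthLN(filt, Identity()), step)
        c = step.contrast
        oracle = np.array([
            filt.dt * sum(filt.taps[k] * c[n - k] for k in range(min(filt.taps.size, n + 1)))
            for n in range(900, 910)
        ])
        assert np.allclose(resp[900:910], oracle, rtol=1e-9)

    def test_fixed_seed_reproducible(self, noise_stim, biphasic_filter):
        cell = GroundTruthLN(biphasic_filter, Identity())
        a = simulate_ln_response(cell, noise_stim, noise_sd=1.0, seed=5)
        b = simulate_ln_response(cell, noise_stim, noise_sd=1.0, seed=5)
        assert np.array_equal(a, b)

    def test_dt_mismatch_rejected(self, noise_stim):
        bad = LinearFilter(np.ones(10), 2e-3)
        with pytest.raises(ParameterError):
            simulate_ln_response(GroundTruthLN(bad, Identity()), noise_stim)


class TestSpikes:
    def test_constant_rate_poisson_count(self):
        rate, dur, dt = 40.0, 50.0, 1e-3
        drive = np.full(int(dur / dt), rate)
        train = simulate_spikes(drive, dt, seed=21)
        expected = rate * dur
        assert abs(train.n_spikes - expected) <= 4 * np.sqrt(expected)

    def test_zero_rate_gives_empty_train(self):
        train = simulate_spikes(np.zeros(1000), 1e-3, seed=1)
        assert train.n_spikes == 0

    def test_refractory_enforced(self):
        drive = np.full(20000, 500.0)
        train = simulate_spikes(drive, 1e-3, refractory_s=0.005, seed=2)
        assert train.n_spikes > 100
        assert np.diff(train.spike_times).min() >= 0.005

    def test_negative_rates_rejected(self):
        with pytest.raises(ParameterError):
            simulate_spikes(np.ones(100), 1e-3, rate_map=lambda d: d - 10.0)


class TestDepressingSynapse:
    def test_steady_state_release_matches_closed_form(self):
        syn = DepressingSynapse(100.0, 5.0, 0.2, 0.3)
        drive = np.full(30000, 1.5)  # 3 s = 10 tau_r at dt=1e-4
        release, _ = simulate_depressing_release(drive, 1e-4, syn)
        r_ss = syn.steady_state_release(1.5)
        settled = release[int(5 * 0.3 / 1e-4):]
        assert settled.mean() == pytest.approx(r_ss, rel=0.01)

    def test_subthreshold_drive_releases_nothing(self):
        syn = DepressingSynapse(100.0, 5.0, 2.0, 0.3)
        drive = np.full(5000, 1.0)
        release, occupancy = simulate_depressing_release(drive, 1e-4, syn)
        assert np.all(release == 0.0)
        assert np.all(occupancy == 100.0)

    def test_paired_pulse_ratio_matches_impulse_approximation(self):
        dt, tau_r = 1e-4, 0.2
        syn = DepressingSynapse(100.0, 900.0, 0.0, tau_r)
        pulse = int(0.001 / dt)
        for delta in (0.05, 0.1, 0.2, 0.4):
            n = int((1.0 + delta) / dt)
            drive = np.zeros(n)
            i0, i1 = int(0.2 / dt), int((0.2 + delta) / dt)
            drive[i0:i0 + pulse] = 1.0
            drive[i1:i1 + pulse] = 1.0
            release, occ = simulate_depressing_release(drive, dt, syn)
            released1 = release[i0:i0 + pulse].sum() * dt
            released2 = release[i1:i1 + pulse].sum() * dt
            f = (occ[i0] - occ[i0 + pulse]) / occ[i0]  # measured depletion fraction
            predicted = 1.0 - f * np.exp(-delta / tau_r)
            assert released2 / released1 == pytest.approx(predicted, rel=0.02)

    def test_recovery_complete_at_twenty_tau(self):
        dt, tau_r = 1e-4, 0.05
        syn = DepressingSynapse(100.0, 900.0, 0.0, tau_r)
        pulse = int(0.001 / dt)
        delta = 20 * tau_r
        n = int((delta + 0.5) / dt)
        drive = np.zeros(n)
        i0, i1 = int(0.2 / dt), int((0.2 + delta) / dt)
        drive[i0:i0 + pulse] = 1.0
        drive[i1:i1 + pulse] = 1.0
        release, _ = simulate_depressing_release(drive, dt, syn)
        ratio = release[i1:i1 + pulse].sum() / release[i0:i0 + pulse].sum()
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_halving_dt_converges(self):
        bip = bipolar_filter(dt_s=1e-4)
        step = make_step(1000.0, 0.5, 0.2, 0.5, 1.0, 1e-4)
        drive = generator_signal(bip, step)
        syn = DepressingSynapse(100.0, 20.0, 0.5, 0.3)
        coarse, _ = simulate_depressing_release(drive, 1e-4, syn)
        bip2 = bipolar_filter(dt_s=5e-5)
        step2 = make_step(1000.0, 0.5, 0.2, 0.5, 1.0, 5e-5)
        fine, _ = simulate_depressing_release(generator_signal(bip2, step2), 5e-5, syn)
        diff = coarse - fine[::2]
        assert np.sqrt(np.mean(diff**2)) <= 0.01 * np.sqrt(np.mean(coarse**2))

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        k=st.floats(0.5, 50.0),
        theta=st.floats(0.0, 1.0),
        tau=st.floats(0.05, 1.0),
    )
    def test_occupancy_never_leaves_pool_bounds(self, seed, k, theta, tau):
        rng = np.random.default_rng(seed)
        drive = np.abs(rng.normal(0, 2.0, 5000))
        syn = DepressingSynapse(50.0, k, theta, tau)
        _, occ = simulate_depressing_release(drive, 1e-4, syn)
        assert occ.min() >= 0.0 and occ.max() <= 50.0

    def test_unstable_step_raises_with_suggestion(self):
        syn = DepressingSynapse(100.0, 5000.0, 0.0, 0.3)
        with pytest.raises(IntegrationError, match="dt"):
            simulate_depressing_release(np.full(100, 5.0), 1e-3, syn)


class TestForwardSensors:
    def test_epsc_delta_release_peak(self):
        dt, tau, q, n_ves = 1e-4, 0.002, 5.0, 20.0
        release = np.zeros(2000)
        release[500] = n_ves / dt
        current = simulate_epsc(release, dt, quantal_amp_pA=q, quantal_kernel_tau_s=tau)
        kern_peak = 1.0 / (1.0 - np.exp(-dt / tau)) * (1 - np.exp(-dt / tau)) / tau
        assert current.min() == pytest.approx(-n_ves * q * kern_peak, rel=0.05)

    def test_epsc_zero_release_is_noise_only(self):
        quiet = simulate_epsc(np.zeros(1000), 1e-4)
        assert np.all(quiet == 0.0)
        noisy = simulate_epsc(np.zeros(5000), 1e-4, noise_sd=2.0, seed=3)
        assert abs(noisy.mean()) < 0.2 and noisy.std() == pytest.approx(2.0, rel=0.1)

    def test_preset_step_epscs_order_transient_below_sustained(self):
        bip = bipolar_filter(dt_s=1e-4)
        step = make_step(1000.0, 0.5, 0.5, 0.5, 2.0, 1e-4)
        drive = generator_signal(bip, step)
        pcts = {}
        for name in ("ont", "ons"):
            syn = get_preset(name).depressing_synapse()
            release, _ = simulate_depressing_release(drive, 1e-4, syn)
            epsc = simulate_epsc(release, 1e-4)
            pcts[name] = step_kinetics(epsc, 1e-4, 0.5, 0.5).steady_state_pct
        assert pcts["ont"] < pcts["ons"]

    def test_fluorescence_frame_rate_and_steady_level(self):
        dt, tau, rate = 1e-4, 0.06, 50.0
        release = np.full(int(4.0 / dt), rate)
        frames = simulate_fluorescence(release, dt, sensor_tau_s=tau)
        assert frames.size == int(4.0 * 58.25)
        assert frames[-50:].mean() == pytest.approx(rate * tau, rel=0.02)

    def test_fluorescence_zero_release_noise_only(self):
        frames = simulate_fluorescence(np.zeros(10000), 1e-4, noise_sd=0.5, seed=9)
        assert abs(frames.mean()) < 0.2


class TestRibbonDataset:
    def test_type6_volumes_two_to_three_fold_larger(self):
        ds = make_ribbon_dataset(n_per_type=200, seed=31)
        vols = {"6": [], "5i": []}
        for rec in ds:
            if rec.bipolar_type in vols:
                vols[rec.bipolar_type].append(rec.ribbon_volume)
        ratio = np.mean(vols["6"]) / np.mean(vols["5i"])
        assert 2.0 <= ratio <= 3.0

    def test_noiseless_counts_regress_perfectly(self):
        ds = make_ribbon_dataset(n_per_type=50, count_noise_sd=0.0, seed=5)
        fit = fit_ribbon_regression(ds, predictor="volume", response="count")
        assert fit.r_squared > 0.9999  # rounding to integer counts only

    def test_variance_matched_noise_hits_target_r2(self):
        r2s = [
            fit_ribbon_regression(make_ribbon_dataset(n_per_type=25, seed=s)).r_squared
            for s in range(10)
        ]
        assert np.mean(r2s) == pytest.approx(0.66, abs=0.05)

    def test_variance_matching_oracle_closed_form(self, rng):
        vols = rng.lognormal(-4.0, 0.5, 5000)
        sigma = calibrate_count_noise_sd(vols, 1e5, 0.66)
        assert sigma**2 == pytest.approx(np.var(1e5 * vols) * (0.34 / 0.66), rel=1e-9)

    def test_reproducible_under_seed(self):
        a = make_ribbon_dataset(n_per_type=10, seed=77)
        b = make_ribbon_dataset(n_per_type=10, seed=77)
        assert all(
            (x.ribbon_volume, x.vesicle_count, x.bipolar_type, x.target)
            == (y.ribbon_volume, y.vesicle_count, y.bipolar_type, y.target)
            for x, y in zip(a, b)
        )
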