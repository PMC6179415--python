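"""The synthetic-data generator: IRFs, Poisson histograms, reflectance
spectra and full protocol datasets with ground truth."""

import numpy as np
import pytest

from myofluor import fit_decay, tau_mean
from myofluor.decay import BiExpParams
from myofluor.simulate import (
    Trajectory,
    control_scenario,
    glucose_depletion_scenario,
    hypoxia_scenario,
    scenario_by_name,
    simulate_decay_histogram,
    simulate_irf,
    simulate_protocol,
    simulate_reflectance,
    SpectralTemplates,
)

from conftest import BIN_WIDTH, N_BINS, PERIOD


class TestSimulateIrf:
    def test_subbin_fwhm_degenerates_to_delta(self):
        irf = simulate_irf(0.5 * BIN_WIDTH, n_bins=N_BINS, bin_width=BIN_WIDTH)
        assert np.sum(irf.weights > 0) == 1

    @pytest.mark.parametrize("fwhm", [0.1, 0.25, 1.0])
    def test_unit_sum(self, fwhm):
        irf = simulate_irf(fwhm, n_bins=N_BINS, bin_width=BIN_WIDTH)
        assert irf.weights.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("fwhm", [0.25, 0.8])
    def test_self_measured_fwhm(self, fwhm):
        irf = simulate_irf(fwhm, n_bins=N_BINS, bin_width=BIN_WIDTH)
        w = irf.weights
        half = w.max() / 2.0
        above = np.flatnonzero(w >= half)
        lo, hi = above[0], above[-1]
        # linear interpolation of the half-maximum crossings
        left = lo - (w[lo] - half) / (w[lo] - w[lo - 1])
        right = hi + (w[hi] - half) / (w[hi] - w[hi + 1])
        assert (right - left) * BIN_WIDTH == pytest.approx(fwhm, abs=BIN_WIDTH)

    @pytest.mark.parametrize("fwhm", [0.0, -1.0, 2.5])
    def test_out_of_range_fwhm_rejected(self, fwhm):
        with pytest.raises(ValueError, match="FWHM"):
            simulate_irf(fwhm)


class TestSimulateDecayHistogram:
    def test_zero_total_gives_empty_histogram(self, gaussian_irf, control_params):
        hist = simulate_decay_histogram(control_params, gaussian_irf, 0, rng=0)
        assert hist.counts.sum() == 0

    def test_realized_totals_follow_poisson_law(self, gaussian_irf, control_params):
        n_target = 1e5
        totals = [
            simulate_decay_histogram(
                control_params, gaussian_irf, n_target, rng=seed, channel_id="CH2"
            ).total_counts
            for seed in range(100)
        ]
        assert abs(np.mean(totals) - n_target) < 3 * np.sqrt(n_target / 100)
        # per-draw spread consistent with Poisson
        assert np.std(totals) == pytest.approx(np.sqrt(n_target), rel=0.35)

    def test_seed_reproducibility(self, gaussian_irf, control_params):
        h1 = simulate_decay_histogram(control_params, gaussian_irf, 1e5, rng=5)
        h2 = simulate_decay_histogram(control_params, gaussian_irf, 1e5, rng=5)
        assert np.array_equal(h1.counts, h2.counts)

    def test_monte_carlo_error_shrinks_with_counts(self, gaussian_irf):
        truth = BiExpParams(a1=0.87, a2=0.13, tau1=0.82, tau2=3.47)
        spreads = []
        for total in (1e4, 1e5, 1e6):
            recovered = [
                fit_decay(
                    simulate_decay_histogram(truth, gaussian_irf, total, rng=seed),
                    gaussian_irf,
                ).tau_mean
                for seed in range(8)
            ]
            spreads.append(np.std(recovered))
        assert spreads[0] > spreads[1] > spreads[2]


class TestTrajectory:
    def test_flat_before_delayed_onset(self):
        traj = Trajectory(baseline=1.0, plateau=2.0, delay=120.0)
        t = np.arange(0.0, 299.0, 5.0)
        assert np.all(traj.value(t) == 1.0)
        assert traj.value(301.0) > 1.0

    def test_continuous_at_reperfusion_handover(self):
        traj = Trajectory(baseline=1.0, plateau=2.0, rise_tau=45.0, fall_tau=120.0)
        just_before = traj.value(749.999)
        just_after = traj.value(750.001)
        assert just_after == pytest.approx(just_before, rel=1e-4)

    def test_returns_toward_baseline_in_reperfusion(self):
        traj = Trajectory(baseline=1.0, plateau=2.0)
        assert abs(traj.value(1500.0) - 1.0) < 0.01


class TestSimulateReflectance:
    def test_zero_templates_give_flat_unit_transmission(self):
        tmpl = SpectralTemplates(
            oxy_myoglobin=((544.0, 9.0, 0.0), (578.0, 9.0, 0.0)),
            deoxy_myoglobin=((560.0, 12.0, 0.0),),
            reduced_cytochrome_c=((550.0, 7.0, 0.0),),
            isosbestic_level=0.0,
        )
        sample, white = simulate_reflectance(tmpl, 1.0, 0.0, noise=0.0)
        np.testing.assert_allclose(sample.intensities, white.intensities)

    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            simulate_reflectance(SpectralTemplates(), 1.5, 0.0, noise=0.0)

    def test_seeded_noise_reproducible(self):
        s1, _ = simulate_reflectance(SpectralTemplates(), 0.5, 0.2, noise=0.02, rng=9)
        s2, _ = simulate_reflectance(SpectralTemplates(), 0.5, 0.2, noise=0.02, rng=9)
        np.testing.assert_array_equal(s1.intensities, s2.intensities)


@pytest.fixture(scope="module")
def tiny_hypoxia():
    return simulate_protocol(
        hypoxia_scenario(), n_hearts=2, seed=123, n_bins=64, counts_scale=0.01
    )


class TestSimulateProtocol:

    def test_full_protocol_has_306_time_points(self, tiny_hypoxia):
        heart = tiny_hypoxia[0]
        assert heart.times.size == 306
        assert all(len(v) == 306 for v in heart.histograms.values())
        assert len(heart.spectra) == 306

    def test_truth_flat_before_switch_plus_delay(self, tiny_hypoxia):
        truth = tiny_hypoxia[0].truth
        ch2 = truth[truth.channel == "CH2"]
        pre = ch2[ch2.time_s < 300.0]
        assert pre.tau1.nunique() == 1
        assert pre.alpha1.nunique() == 1

    def test_control_truth_constant_throughout(self):
        spec = control_scenario()
        hearts = simulate_protocol(spec, 1, seed=4, n_bins=64, counts_scale=0.01)
        ch2 = hearts[0].truth.query("channel == 'CH2'")
        assert ch2.tau1.nunique() == 1
        assert ch2.tau2.nunique() == 1

    def test_identical_seeds_bitwise_identical(self):
        a = simulate_protocol(hypoxia_scenario(), 1, seed=77, n_bins=64, counts_scale=0.01)
        b = simulate_protocol(hypoxia_scenario(), 1, seed=77, n_bins=64, counts_scale=0.01)
        for ch in a[0].histograms:
            for ha, hb in zip(a[0].histograms[ch], b[0].histograms[ch]):
                assert np.array_equal(ha.counts, hb.counts)
        for (sa, _), (sb, _) in zip(a[0].spectra, b[0].spectra):
            np.testing.assert_array_equal(sa.intensities, sb.intensities)

    def test_hearts_differ_from_each_other(self, tiny_hypoxia):
        h0, h1 = tiny_hypoxia
        assert not np.array_equal(
            h0.histograms["CH2"][0].counts, h1.histograms["CH2"][0].counts
        )

    def test_truth_sufficient_for_recovery_checks(self, tiny_hypoxia):
        truth = tiny_hypoxia[0].truth
        ch_rows = truth[truth.channel == "CH2"]
        assert {"alpha1", "tau1", "tau2", "tau_mean", "expected_counts"} <= set(
            ch_rows.columns
        )
        # recorded tau_mean is consistent with the recorded components
        row = ch_rows.iloc[0]
        p = BiExpParams(a1=row.alpha1, a2=1 - row.alpha1, tau1=row.tau1, tau2=row.tau2)
        assert row.tau_mean == pytest.approx(tau_mean(p))

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            scenario_by_name("ischemia")

    def test_glucose_depletion_ch2_declines_without_plateau(self):
        spec = glucose_depletion_scenario()
        counts = spec.channels["CH2"].total_counts
        mid = counts.value(450.0)
        end = counts.value(745.0)
        assert counts.value(100.0) > mid > end  # still falling at insult end
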