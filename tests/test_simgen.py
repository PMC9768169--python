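"""Generator-level checks: telegraph statistics, reporter timing, track MSDs,
scene rendering photometry, FRAP closed forms, cluster-scene geometry."""

import numpy as np
import pytest

from txlive import simgen
from txlive.simgen import (
    FrapSimParams,
    GroundTruthScene,
    SpotTruth,
    TelegraphParams,
    render_scene,
    simulate_cluster_scene,
    simulate_frap_curve,
    simulate_locus_track,
    simulate_reporter_pair,
    simulate_telegraph,
)


class TestTelegraph:
    def test_absorbing_on_state(self):
        tr = simulate_telegraph(
            TelegraphParams(k_on=1.0, k_off=0.0, k_init=0.0, duration=100, dt=1,
                            seed=0, start_on=True)
        )
        assert tr.on_fraction == 1.0

    def test_stationary_occupancy(self):
        # stationary ON fraction k_on/(k_on+k_off) = 0.5; SE from the
        # integrated autocorrelation time 1/(k_on+k_off) over duration T
        k = 1.0
        T = 10_000.0
        tr = simulate_telegraph(
            TelegraphParams(k_on=k, k_off=k, k_init=0.0, duration=T, dt=1, seed=7)
        )
        n_eff = T / (2.0 / (k + k))
        se = 0.5 / np.sqrt(n_eff)
        assert abs(tr.on_fraction - 0.5) < 3 * se

    def test_initiations_per_on_period(self):
        # brute-force event counting over many bursts: mean initiations per
        # completed ON period should be k_init / k_off = 10
        tr = simulate_telegraph(
            TelegraphParams(k_on=5.0, k_off=1.0, k_init=10.0, duration=20_000,
                            dt=1.0, seed=3, start_on=True)
        )
        # reconstruct ON intervals from exact switch times
        switches = np.concatenate([[0.0], tr.switch_times])
        counts = []
        for i in range(0, len(switches) - 1, 2):  # started ON: even index = ON start
            a, b = switches[i], switches[i + 1]
            counts.append(np.count_nonzero((tr.events >= a) & (tr.events < b)))
        counts = np.asarray(counts, dtype=float)
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - 10.0) < 3 * se

    def test_events_only_during_on(self):
        tr = simulate_telegraph(
            TelegraphParams(k_on=0.5, k_off=0.5, k_init=8.0, duration=500, dt=0.5,
                            seed=11, start_on=True)
        )
        assert tr.events.size > 0
        # intervals alternate ON/OFF starting ON; every event must fall in an
        # even-numbered (ON) interval of the exact switch path
        bounds = np.concatenate([[0.0], tr.switch_times, [tr.params.duration]])
        idx = np.searchsorted(bounds, tr.events, side="right") - 1
        assert np.all(idx % 2 == 0)

    def test_rejects_negative_rates(self):
        with pytest.raises(ValueError):
            TelegraphParams(k_on=-1, k_off=1, k_init=1, duration=10)
        with pytest.raises(ValueError):
            TelegraphParams(k_on=np.nan, k_off=1, k_init=1, duration=10)

    def test_seed_reproducibility(self):
        p = TelegraphParams(k_on=1, k_off=1, k_init=2, duration=100, dt=1, seed=42)
        a, b = simulate_telegraph(p), simulate_telegraph(p)
        assert np.array_equal(a.state, b.state)
        assert np.array_equal(a.events, b.events)


class TestReporterPair:
    def test_true_delay_from_printed_geometry(self):
        tr = simulate_reporter_pair([10.0], separation_kb=11.2,
                                    elongation_rate_kb_per_min=2.8, duration=60)
        assert tr.true_delay == pytest.approx(4.0)

    def test_zero_separation_identical_traces(self):
        tr = simulate_reporter_pair([5.0, 12.0], separation_kb=0.0,
                                    elongation_rate_kb_per_min=2.0,
                                    dwell_min=3.0, stochastic_dwell=False, duration=30)
        assert tr.true_delay == 0.0
        assert np.array_equal(tr.mcp, tr.pcp)

    def test_pcp_onset_time(self):
        # rate 1 kb/min, separation 5 kb, single event at t=10 -> pcp onset 15
        tr = simulate_reporter_pair([10.0], separation_kb=5.0,
                                    elongation_rate_kb_per_min=1.0,
                                    dwell_min=2.0, dt=1.0, stochastic_dwell=False,
                                    duration=30)
        onset = tr.times[np.nonzero(tr.pcp > 0)[0][0]]
        assert onset == 15.0
        onset_mcp = tr.times[np.nonzero(tr.mcp > 0)[0][0]]
        assert onset_mcp == 10.0

    def test_zero_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_reporter_pair([1.0], elongation_rate_kb_per_min=0.0)


class TestLocusTrack:
    def test_frozen_particle(self):
        pos = simulate_locus_track(0.0, 1.0, 50, 0.03, n_tracks=3, seed=0)
        assert np.all(pos == 0)

    def test_brownian_ensemble_msd(self):
        # 4 * 0.0037 * t at t ~ 1 s -> ~0.0148 um^2
        d = 0.0037
        pos = simulate_locus_track(d, 1.0, 40, 0.03, n_tracks=3000, seed=5)
        lag = 33  # 0.99 s
        disp = (pos[:, lag, :] - pos[:, 0, :]) / 1000.0  # nm -> um
        msd = float(np.mean(np.sum(disp**2, axis=1)))
        t = lag * 0.03
        assert msd == pytest.approx(4 * d * t, rel=0.05)

    def test_subdiffusive_slope(self):
        from txlive.dynamics import msd_fit

        pos = simulate_locus_track(0.005, 0.5, 100, 0.03, n_tracks=800, seed=6)
        fit = msd_fit(list(pos), 0.03, max_lag_steps=66, unit="nm")
        assert abs(fit.alpha - 0.5) < 0.05

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            simulate_locus_track(0.01, 0.0, 10, 0.03)
        with pytest.raises(ValueError):
            simulate_locus_track(0.01, 2.5, 10, 0.03)

    def test_localization_noise_added(self):
        quiet = simulate_locus_track(0.0, 1.0, 100, 0.03,
                                     localization_sigma_nm=30.0, n_tracks=20, seed=9)
        assert np.std(quiet) == pytest.approx(30.0, rel=0.1)


class TestRenderScene:
    def test_empty_scene_constant(self):
        img = render_scene(GroundTruthScene(shape=(32, 32), background=7.0))
        assert np.all(img == 7.0)

    def test_gaussian_integral(self, single_spot_scene):
        scene, img = single_spot_scene
        s = scene.spots[0]
        total = float((img - scene.background).sum())
        analytic = 2 * np.pi * s.amplitude * s.psf_sigma_px**2
        assert total == pytest.approx(analytic, rel=0.01)

    def test_disk_mean_linearity(self):
        from txlive.spots import measure_spot

        imgs = []
        for amp in (50.0, 100.0):
            sc = GroundTruthScene(
                shape=(40, 40), background=3.0,
                spots=[SpotTruth(0, 0, 20.0, 20.0, amp, 1.5)],
            )
            imgs.append(render_scene(sc)[0, 0] - 3.0)
        m1, _ = measure_spot(imgs[0], (20.0, 20.0))
        m2, _ = measure_spot(imgs[1], (20.0, 20.0))
        assert m2 == pytest.approx(2 * m1, rel=1e-9)

    def test_spot_outside_frame_rejected(self):
        with pytest.raises(ValueError):
            GroundTruthScene(shape=(16, 16),
                             spots=[SpotTruth(0, 0, 20.0, 5.0, 10.0, 1.0)])

    def test_noise_seeded(self):
        sc = GroundTruthScene(shape=(16, 16), background=10.0,
                              read_sigma=2.0, poisson_gain=1.0, seed=3)
        assert np.array_equal(render_scene(sc), render_scene(sc))


class TestFrapCurve:
    def test_value_at_zero_is_baseline(self):
        t, y = simulate_frap_curve(FrapSimParams(baseline=0.41, f_mobile=0.492,
                                                 tau=26.3, noise_sigma=0.0))
        assert t[0] == 0.0
        assert y[0] == pytest.approx(0.41)

    def test_plateau(self):
        p = FrapSimParams(baseline=0.41, f_mobile=0.492, tau=5.0, dt=4.0,
                          n_points=200, noise_sigma=0.0)
        _, y = simulate_frap_curve(p)
        assert y[-1] == pytest.approx(0.902, abs=1e-3)

    def test_half_rise_time(self):
        # closed form: I(t) - baseline = f/2 at t = tau * ln 2
        p = FrapSimParams(baseline=0.3, f_mobile=0.5, tau=20.0, dt=0.01,
                          n_points=20_000, noise_sigma=0.0)
        t, y = simulate_frap_curve(p)
        half = 0.3 + 0.25
        t_half = t[np.argmin(np.abs(y - half))]
        assert t_half == pytest.approx(20.0 * np.log(2), abs=0.02)

    def test_invariant_bounds(self):
        with pytest.raises(ValueError):
            FrapSimParams(baseline=0.8, f_mobile=0.5)
        with pytest.raises(ValueError):
            FrapSimParams(tau=0.0)


class TestClusterScene:
    def test_colocalized_at_zero_median(self):
        truth = simulate_cluster_scene(distance_median_nm=0.0, dispersion=0.0, seed=0)
        assert truth.nearest_distance_nm == pytest.approx(0.0, abs=1e-9)

    def test_ground_truth_median_recovery(self):
        d = [simulate_cluster_scene(state="ON", seed=i).nearest_distance_nm
             for i in range(1000)]
        assert np.median(d) == pytest.approx(289.0, rel=0.05)

    def test_nearest_is_brute_force_minimum(self):
        for seed in range(20):
            truth = simulate_cluster_scene(seed=seed, n_clusters=6)
            ay, ax = truth.anchor_yx_px
            d = np.hypot(truth.cluster_yx_px[:, 0] - ay,
                         truth.cluster_yx_px[:, 1] - ax) * 130.0
            assert truth.nearest_distance_nm == pytest.approx(float(d.min()))
            assert truth.nearest_index == int(np.argmin(d))

    def test_decoys_farther_than_designated_nearest(self):
        for seed in range(20):
            truth = simulate_cluster_scene(seed=seed)
            assert truth.nearest_index == 0
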