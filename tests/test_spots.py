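"""Spot detection/localization accuracy, disk measurement, linking and SNR."""

import warnings

import numpy as np
import pytest

from txlive import simgen
from txlive.imgproc import NucleusRecord
from txlive.spots import (
    SpotRecord,
    compute_snr,
    count_foci,
    detect_and_refine,
    link_tracks,
    measure_spot,
)


def _nucleus(mean=10.0, sd=1.0, label=1):
    return NucleusRecord(label=label, n_pixels=100, mean_intensity=mean,
                         sd_intensity=sd, center_of_mass_nm=(0.0, 0.0))


class TestDetectAndRefine:
    def test_subpixel_accuracy_noiseless(self, single_spot_scene):
        _, img = single_spot_scene
        (s,) = detect_and_refine(img, threshold=50)
        assert abs(s.y_px - 50.3) < 0.05
        assert abs(s.x_px - 20.7) < 0.05
        assert s.sigma_px == pytest.approx(1.5, abs=0.01)

    def test_two_spots_match_brute_force_maxima(self):
        scene = simgen.GroundTruthScene(
            shape=(60, 60), background=2.0,
            spots=[simgen.SpotTruth(0, 0, 20.0, 20.0, 80.0, 1.3),
                   simgen.SpotTruth(0, 0, 20.0, 30.0, 60.0, 1.3)],
        )
        img = simgen.render_scene(scene)[0, 0]
        found = detect_and_refine(img, threshold=30)
        assert len(found) == 2
        # oracle: exhaustive scan for pixels that are strict 5x5-neighborhood maxima
        maxima = []
        for y in range(2, 58):
            for x in range(2, 58):
                patch = img[y - 2 : y + 3, x - 2 : x + 3]
                if img[y, x] == patch.max() and img[y, x] > 30:
                    maxima.append((y, x))
        assert len(maxima) == len(found)
        maxima.sort(key=lambda m: m[1])
        centers = sorted([(s.y_px, s.x_px) for s in found], key=lambda c: c[1])
        for (my, mx), (sy, sx) in zip(maxima, centers):
            assert abs(my - sy) <= 1.0 and abs(mx - sx) <= 1.0

    def test_blank_noise_false_positive_rate(self):
        sigma = 2.0
        n_hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            img = rng.normal(0, sigma, size=(64, 64))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                found = detect_and_refine(img, threshold=5 * sigma)
            n_hits += bool(found)
        assert n_hits <= 1  # zero spots in >= 99% of replicates

    def test_border_candidates_dropped_with_warning(self):
        img = np.zeros((20, 20))
        img[1, 1] = 100.0
        with pytest.warns(UserWarning, match="border"):
            found = detect_and_refine(img, threshold=10)
        assert found == []

    def test_even_diameter_rejected(self):
        with pytest.raises(ValueError):
            detect_and_refine(np.zeros((10, 10)), expected_diameter_px=4)

    def test_roi_restricts_search(self, single_spot_scene):
        _, img = single_spot_scene
        found = detect_and_refine(img, threshold=50, roi=(41, 60, 11, 30))
        assert len(found) == 1
        assert detect_and_refine(img, threshold=50, roi=(0, 19, 0, 19)) == []


class TestMeasureSpot:
    def test_uniform_image(self):
        img = np.full((30, 30), 7.0)
        disk_mean, rel = measure_spot(img, (15.0, 15.0), nucleus=_nucleus(mean=7.0))
        assert disk_mean == 7.0
        assert rel == 1.0

    def test_ratio_invariant_under_scaling(self):
        rng = np.random.default_rng(5)
        img = rng.uniform(1, 5, size=(30, 30))
        nuc1 = _nucleus(mean=float(img.mean()))
        m1, r1 = measure_spot(img, (15.0, 15.0), nucleus=nuc1)
        c = 3.7
        nuc2 = _nucleus(mean=float(img.mean()) * c)
        m2, r2 = measure_spot(img * c, (15.0, 15.0), nucleus=nuc2)
        assert m2 == pytest.approx(c * m1)
        assert r2 == pytest.approx(r1)

    def test_disk_mean_equals_naive_loop(self, single_spot_scene):
        _, img = single_spot_scene
        cy, cx, r = 50.3, 20.7, 6
        disk_mean, _ = measure_spot(img, (cy, cx), radius_px=r)
        vals = [img[y, x]
                for y in range(img.shape[0]) for x in range(img.shape[1])
                if (y - cy) ** 2 + (x - cx) ** 2 <= r**2]
        assert disk_mean == pytest.approx(np.mean(vals), abs=0)

    def test_nonpositive_nucleus_mean_raises(self):
        with pytest.raises(ValueError):
            measure_spot(np.ones((20, 20)), (10.0, 10.0), nucleus=_nucleus(mean=0.0))

    def test_partial_disk_flagged(self):
        rec = SpotRecord(channel="", frame=0, y_px=2.0, x_px=2.0,
                         sigma_px=1.0, amplitude=1.0)
        measure_spot(np.ones((30, 30)), rec)
        assert rec.partial_disk


def _spot(frame, y, x):
    return SpotRecord(channel="", frame=frame, y_px=y, x_px=x, sigma_px=1.0, amplitude=1.0)


class TestLinkTracks:
    def test_stationary_spot_retained(self):
        frames = {f: [_spot(f, 10.0, 10.0)] for f in range(60)}
        tracks = link_tracks(frames)
        assert len(tracks) == 1
        assert tracks[0].longest_consecutive_run() == 60

    def test_gap_memory_splits_tracks(self):
        frames = {f: [_spot(f, 5.0, 5.0)] for f in [0, 1, 2, 6, 7, 8]}  # 3-frame gap
        one = link_tracks(frames, memory_frames=4, min_consecutive=0)
        assert len(one) == 1
        assert list(one[0].gaps) == [0, 0, 3, 0, 0]
        two = link_tracks(frames, memory_frames=2, min_consecutive=0)
        assert len(two) == 2

    def test_min_consecutive_cutoff(self):
        # "more than 50 consecutive frames": 49 and exactly 50 are discarded, 51 kept
        for n, kept in [(49, 0), (50, 0), (51, 1)]:
            frames = {f: [_spot(f, 1.0, 1.0)] for f in range(n)}
            assert len(link_tracks(frames)) == kept

    def test_search_range_limits_links(self):
        frames = {0: [_spot(0, 10.0, 10.0)], 1: [_spot(1, 10.0, 15.0)]}
        assert len(link_tracks(frames, min_consecutive=0)) == 2
        assert len(link_tracks(frames, search_range_px=6, min_consecutive=0)) == 1

    def test_permutation_invariance_within_frame(self):
        rng = np.random.default_rng(7)
        base = {}
        for f in range(10):
            base[f] = [_spot(f, 10.0 + 0.3 * f, 10.0), _spot(f, 30.0, 30.0 - 0.2 * f),
                       _spot(f, 50.0, 20.0)]
        t1 = link_tracks(base, min_consecutive=0)
        shuffled = {f: list(rng.permutation(np.array(sp, dtype=object)))
                    for f, sp in base.items()}
        t2 = link_tracks(shuffled, min_consecutive=0)
        key = lambda tr: tuple((s.frame, s.y_px, s.x_px) for s in tr.spots)
        assert sorted(map(key, t1)) == sorted(map(key, t2))

    def test_tie_broken_by_smallest_displacement(self):
        frames = {0: [_spot(0, 10.0, 10.0)],
                  1: [_spot(1, 10.0, 11.5), _spot(1, 10.0, 10.5)]}
        tracks = link_tracks(frames, min_consecutive=0)
        linked = [t for t in tracks if len(t.spots) == 2][0]
        assert linked.spots[1].x_px == 10.5


class TestSnr:
    def test_direct_ratio(self):
        img = np.full((30, 30), 10.0)
        assert compute_snr(img, (15.0, 15.0), _nucleus(mean=10.0, sd=2.0)) == 5.0

    def test_scale_invariance(self):
        rng = np.random.default_rng(8)
        img = rng.uniform(5, 15, size=(40, 40))
        nuc = _nucleus(mean=float(img.mean()), sd=float(img.std()))
        s1 = compute_snr(img, (20.0, 20.0), nuc)
        c = 2.5
        nuc2 = _nucleus(mean=nuc.mean_intensity * c, sd=nuc.sd_intensity * c)
        s2 = compute_snr(img * c, (20.0, 20.0), nuc2)
        assert s2 == pytest.approx(s1)

    def test_constructed_snr_recovery(self):
        # plateau 30 over noise sigma 3 -> SNR ~ 10; average over 50 seeds
        vals = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            noise = rng.normal(0, 3.0, size=(64, 64))
            img = noise.copy()
            yy, xx = np.mgrid[0:64, 0:64]
            img[((yy - 32) ** 2 + (xx - 32) ** 2) <= 4] += 30.0
            # sigma_N measured over the nucleus background (away from the spot)
            nuc = _nucleus(mean=1.0, sd=float(noise.std()))
            vals.append(compute_snr(img, (32.0, 32.0), nuc, radius_px=2.0))
        assert np.mean(vals) == pytest.approx(10.0, rel=0.10)

    def test_zero_sd_raises(self):
        with pytest.raises(ValueError):
            compute_snr(np.ones((10, 10)), (5.0, 5.0), _nucleus(sd=0.0))


class TestCountFoci:
    def test_flat_image_no_foci(self):
        mask = np.ones((32, 32), dtype=bool)
        n, mean = count_foci(np.full((32, 32), 5.0), mask, prominence=10)
        assert n == 0 and np.isnan(mean)

    def test_five_rendered_foci(self):
        scene = simgen.GroundTruthScene(
            shape=(64, 64), background=1.0,
            spots=[simgen.SpotTruth(0, 0, y, x, 20.0, 1.2)
                   for y, x in [(10, 10), (10, 50), (32, 32), (50, 12), (52, 50)]],
        )
        img = simgen.render_scene(scene)[0, 0]
        mask = np.ones((64, 64), dtype=bool)
        n, mean = count_foci(img, mask, prominence=10)
        assert n == 5
        assert mean == pytest.approx(21.0, rel=0.05)

    def test_threshold_above_prominence(self):
        scene = simgen.GroundTruthScene(
            shape=(32, 32), background=1.0,
            spots=[simgen.SpotTruth(0, 0, 16, 16, 20.0, 1.2)],
        )
        img = simgen.render_scene(scene)[0, 0]
        n, _ = count_foci(img, np.ones((32, 32), dtype=bool), prominence=25)
        assert n == 0

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            count_foci(np.ones((8, 8)), np.zeros((8, 8), dtype=bool), prominence=1)


def test_localization_degrades_monotonically_with_noise():
    """RMSE on rendered spots grows with read noise but stays sub-pixel."""
    rmses = []
    for read_sigma in (0.0, 2.0, 6.0):
        errs = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            y0, x0 = 30 + rng.uniform(-0.5, 0.5), 30 + rng.uniform(-0.5, 0.5)
            sc = simgen.GroundTruthScene(
                shape=(60, 60), background=5.0, read_sigma=read_sigma, seed=seed,
                spots=[simgen.SpotTruth(0, 0, y0, x0, 100.0, 1.4)],
            )
            img = simgen.render_scene(sc)[0, 0]
            found = detect_and_refine(img, threshold=50)
            if found:
                errs.append((found[0].y_px - y0) ** 2 + (found[0].x_px - x0) ** 2)
        rmses.append(np.sqrt(np.mean(errs)))
    assert rmses[0] < 0.05
    assert rmses[0] <= rmses[1] <= rmses[2]
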