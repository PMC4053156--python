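"""Nuclear-detection pipeline: binning, filtering, detection accuracy,
calibration search."""

import dataclasses

import numpy as np
import pytest

import ki67calib as k
from ki67calib.dia import (BIN_MODERATE, BIN_NEGATIVE, BIN_STRONG, BIN_WEAK,
                           DIA_0, DIA_1, DIA_2, PROFILES, calibrate_settings,
                           classify_intensity, detect_nuclei,
                           nuclear_intensity, run_dia, segment_tumour)
from ki67calib.errors import ConfigError, EmptyTumourError
from ki67calib.synthetic import (CellProfile, SpotSpec, place_nuclei,
                                 render_spot, true_li, TUMOUR_POSITIVE,
                                 TUMOUR_NEGATIVE)

from conftest import easy_spec


class TestClassifyIntensity:
    @pytest.mark.parametrize("value,settings,expected", [
        (240.0, DIA_2, BIN_NEGATIVE),
        (220.0, DIA_1, BIN_NEGATIVE),    # weak threshold 210
        (220.0, DIA_2, BIN_WEAK),        # weak threshold 229
        (150.0, DIA_0, BIN_STRONG),
        (150.0, DIA_1, BIN_STRONG),
        (150.0, DIA_2, BIN_STRONG),
        (200.0, DIA_1, BIN_WEAK),
        (170.0, DIA_1, BIN_MODERATE),
    ])
    def test_bin_assignment(self, value, settings, expected):
        assert classify_intensity(value, settings) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigError):
            classify_intensity(300.0, DIA_1)

    def test_raising_weak_threshold_never_lowers_positivity(self):
        # every object keeps or gains positivity when 1+ reaches further up
        low = DIA_1                                  # weak 210
        high = dataclasses.replace(DIA_1, weak_threshold=229.0)
        for v in np.linspace(0, 230, 47):
            if classify_intensity(v, low) != BIN_NEGATIVE:
                assert classify_intensity(v, high) != BIN_NEGATIVE


class TestSettings:
    def test_profiles_satisfy_threshold_ordering(self):
        for s in PROFILES.values():
            assert (s.strong_threshold <= s.moderate_threshold
                    <= s.weak_threshold <= s.upper_intensity_threshold)
            assert s.min_nuclear_size_um2 <= s.max_nuclear_size_um2

    def test_inconsistent_thresholds_rejected(self):
        with pytest.raises(ConfigError):
            k.DIASettings(weak_threshold=100.0, moderate_threshold=188.0)


class TestNuclearIntensity:
    def test_grey_input_maps_to_itself(self):
        img = np.full((5, 5, 3), 173, dtype=np.uint8)
        assert np.all(nuclear_intensity(img) == 173.0)

    def test_background_above_all_upper_thresholds(self, easy_spots):
        g = nuclear_intensity(easy_spots[0].image)
        corner = g[:20, :20].mean()     # outside the spot: bare glass
        assert all(corner > s.upper_intensity_threshold
                   for s in PROFILES.values())

    def test_strongly_stained_nucleus_maps_below_strong_threshold(self):
        spec = SpotSpec(spot_diameter_um=100, cell_density_per_mm2=0.0,
                        noise_sd=1.0)
        c = (spec.image_size_px - 1) / 2
        cell = CellProfile(0, c, c, 10.0, TUMOUR_POSITIVE, 150.0)
        spot = render_spot([cell], spec)
        g = nuclear_intensity(spot.image)
        assert g[int(c), int(c)] <= 162.0 + 3 * spec.noise_sd


class TestDetection:
    def _two_nuclei_spot(self):
        spec = SpotSpec(spot_diameter_um=100, cell_density_per_mm2=0.0,
                        noise_sd=2.0)
        c = spec.image_size_px / 2
        truth = [CellProfile(0, c - 30, c, 9.0, TUMOUR_POSITIVE, 140.0),
                 CellProfile(1, c + 30, c, 9.0, TUMOUR_NEGATIVE, 218.0)]
        return render_spot(truth, spec)

    def test_two_separated_nuclei_detected(self):
        spot = self._two_nuclei_spot()
        objs = detect_nuclei(nuclear_intensity(spot.image),
                             np.ones_like(spot.tumour_mask), DIA_1,
                             spot.spec.resolution_um_per_px)
        assert len(objs) == 2
        bins = sorted(o.bin for o in objs)
        assert bins == sorted([BIN_STRONG, BIN_NEGATIVE])

    def test_min_size_filter_between_profiles(self):
        # a ~25 um^2 speck survives the vendor-default minimum (20) but not
        # the visually tuned minimum (45), even after the slight apparent
        # growth that dark objects gain from threshold smoothing
        spec = SpotSpec(spot_diameter_um=100, cell_density_per_mm2=0.0,
                        noise_sd=1.0)
        c = spec.image_size_px / 2
        r_px = np.sqrt(25.0 / np.pi) / spec.resolution_um_per_px
        truth = [CellProfile(0, c, c, r_px, TUMOUR_POSITIVE, 140.0)]
        spot = render_spot(truth, spec)
        g = nuclear_intensity(spot.image)
        mask = np.ones_like(spot.tumour_mask)
        res = spec.resolution_um_per_px
        assert len(detect_nuclei(g, mask, DIA_0, res)) == 1
        assert len(detect_nuclei(g, mask, DIA_1, res)) == 0

    def test_empty_mask_detects_nothing(self):
        g = np.full((50, 50), 150.0)
        assert detect_nuclei(g, np.zeros((50, 50), bool), DIA_1, 0.5) == []

    def test_nonpositive_resolution_rejected(self):
        with pytest.raises(ConfigError):
            detect_nuclei(np.zeros((5, 5)), np.ones((5, 5), bool), DIA_1, 0.0)

    def test_raising_min_size_never_adds_objects(self, easy_spots):
        spot = easy_spots[0]
        g = nuclear_intensity(spot.image)
        res = spot.spec.resolution_um_per_px
        totals = [len(detect_nuclei(g, spot.tumour_mask,
                                    dataclasses.replace(DIA_1,
                                                        min_nuclear_size_um2=s),
                                    res))
                  for s in (20.0, 40.0, 45.0, 60.0)]
        assert all(a >= b for a, b in zip(totals, totals[1:]))


class TestRunDIA:
    def test_easy_regime_matches_ground_truth(self, easy_spots):
        for spot in easy_spots:
            res = run_dia(spot, DIA_1)
            n_truth = sum(1 for c in spot.truth if c.is_tumour)
            assert abs(res.total_profiles - n_truth) <= 0.05 * n_truth
            assert abs(res.li_percent - spot.true_li_percent) <= 2.0

    def test_detected_centroids_match_truth(self, easy_spots):
        spot = easy_spots[1]
        res = run_dia(spot, DIA_1)
        truth = [c for c in spot.truth if c.is_tumour]
        pts = np.array([(c.x, c.y) for c in truth])
        used = set()
        matched = 0
        for o in res.objects:
            d = np.hypot(pts[:, 0] - o.centroid_px[0],
                         pts[:, 1] - o.centroid_px[1])
            j = int(np.argmin(d))
            if j not in used and d[j] <= truth[j].radius_px:
                used.add(j)
                matched += 1
        assert matched >= 0.95 * len(res.objects)

    def test_bins_partition_total(self, easy_spots):
        res = run_dia(easy_spots[0], DIA_1)
        assert sum(res.bin_counts.values()) == res.total_profiles
        assert res.positive_count <= res.total_profiles

    def test_deterministic(self, easy_spots):
        assert run_dia(easy_spots[0], DIA_1) == run_dia(easy_spots[0], DIA_1)

    def test_weak_threshold_monotone_in_li_on_fixed_objects(self, easy_spots):
        res = run_dia(easy_spots[2], DIA_1)
        lis = []
        for weak in (210.0, 220.0, 229.0):
            s = dataclasses.replace(DIA_1, weak_threshold=weak)
            pos = sum(1 for o in res.objects
                      if classify_intensity(o.mean_intensity, s)
                      != BIN_NEGATIVE)
            lis.append(100.0 * pos / res.total_profiles)
        assert lis == sorted(lis)

    def test_overlap_allowance_never_increases_detections(self):
        totals = []
        for allowance in (0.0, 0.3, 0.6):
            spec = SpotSpec(spot_diameter_um=300.0,
                            cell_density_per_mm2=2500.0,
                            true_li_percent=30.0, seed=17,
                            overlap_allowance=allowance)
            totals.append(run_dia(k.generate_spot(spec), DIA_1).total_profiles)
        assert all(a >= b for a, b in zip(totals, totals[1:]))


class TestSegmentTumour:
    def test_oracle_returns_generator_mask(self, easy_spots):
        assert segment_tumour(easy_spots[0], "oracle") is \
            easy_spots[0].tumour_mask

    def test_classifier_close_to_truth_on_default_spot(self, default_spot):
        mask = segment_tumour(default_spot, "classifier")
        truth = default_spot.tumour_mask
        iou = (mask & truth).sum() / (mask | truth).sum()
        assert iou >= 0.8

    def test_background_only_image_is_empty_tumour(self):
        spec = SpotSpec(spot_diameter_um=150, cell_density_per_mm2=0.0)
        spot = render_spot([], spec)
        with pytest.raises(EmptyTumourError):
            segment_tumour(spot, "classifier")


@pytest.fixture(scope="module")
def lymph_spots():
    """Spots whose small lymphocytes depress the LI unless size-filtered."""
    spots, refs = [], []
    for seed, li in zip((21, 22, 23), (15.0, 30.0, 55.0)):
        spec = SpotSpec(spot_diameter_um=400.0,
                        cell_density_per_mm2=1200.0,
                        true_li_percent=li, seed=seed,
                        lymphocyte_density_per_mm2=600.0)
        spot = k.generate_spot(spec)
        spots.append(spot)
        refs.append(spot.true_li_percent)
    return spots, refs


class TestCalibration:
    def test_singleton_space_returns_that_candidate(self, lymph_spots):
        spots, refs = lymph_spots
        out = calibrate_settings(spots, refs,
                                 {"min_nuclear_size_um2": [45.0]})
        assert out.settings.min_nuclear_size_um2 == 45.0
        assert len(out.evaluations) == 1

    def test_size_search_removes_lymphocyte_bias(self, lymph_spots):
        spots, refs = lymph_spots
        out = calibrate_settings(spots, refs,
                                 {"min_nuclear_size_um2": [20.0, 45.0]})
        assert out.settings.min_nuclear_size_um2 == 45.0

    def test_returned_candidate_minimizes_objective(self, lymph_spots):
        spots, refs = lymph_spots
        out = calibrate_settings(
            spots, refs, {"min_nuclear_size_um2": [20.0, 40.0, 45.0],
                          "weak_threshold": [210.0, 229.0]})
        assert len(out.evaluations) == 6
        assert all(out.bias <= b + 1e-12 for _, b, _ in out.evaluations)
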