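import numpy as np
import pytest

from conftest import random_spot_images
from oracles import accepted_maxima_oracle
from polyqhcs import incquant, nucseg, synthio
from polyqhcs.errors import InputError
from polyqhcs.nucseg import FieldImage


def _gauss(img, center, sigma, amplitude):
    rr, cc = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    img += amplitude * np.exp(
        -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2))


def _segmented(field):
    return nucseg.segment_nuclei(field, 4000)


class TestFindMaxima:
    def test_constant_image_no_calls(self):
        assert incquant.find_maxima(np.full((32, 32), 7.0), None, 10) == []

    def test_single_gaussian_peak(self):
        img = np.full((41, 41), 500.0)
        _gauss(img, (20, 20), 2.0, 3000.0)
        calls = incquant.find_maxima(img, None, 150)
        assert [c.center for c in calls] == [(20, 20)]

    def test_plateau_single_topmost_leftmost_call(self):
        img = np.zeros((9, 9))
        img[4:6, 3:6] = 10.0  # 2x3 plateau
        calls = incquant.find_maxima(img, None, 5)
        assert [c.center for c in calls] == [(4, 3)]

    def test_prominence_strictness(self):
        # secondary peak with prominence exactly equal to tolerance: rejected
        img = np.zeros((7, 15))
        img[3, 3] = 1000.0
        img[3, 4:11] = 100.0  # ridge: highest saddle level 100
        img[3, 11] = 250.0    # prominence exactly 150
        assert len(incquant.find_maxima(img, None, 150)) == 1
        assert len(incquant.find_maxima(img, None, 149)) == 2

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_flood_oracle(self, seed):
        img = random_spot_images(1, seed=seed)[0]
        for tol in (1, 50, 150, 1000):
            ours = [c.center for c in incquant.find_maxima(img, None, tol)]
            assert ours == accepted_maxima_oracle(img, None, tol)

    def test_masked_matches_oracle(self, rng):
        img = rng.integers(0, 500, (16, 16)).astype(float)
        mask = rng.uniform(size=(16, 16)) < 0.7
        for tol in (1, 50, 150):
            ours = [c.center for c in incquant.find_maxima(img, mask, tol)]
            assert ours == accepted_maxima_oracle(img, mask, tol)

    def test_tolerance_monotone_subset(self, rng):
        for _ in range(20):
            img = rng.integers(0, 400, (16, 16)).astype(float)
            prev = None
            for tol in (1, 50, 150, 1000):
                cur = {c.center for c in incquant.find_maxima(img, None, tol)}
                if prev is not None:
                    assert cur <= prev
                prev = cur

    def test_nonpositive_tolerance_rejected(self):
        with pytest.raises(InputError):
            incquant.find_maxima(np.zeros((4, 4)), None, 0)

    def test_labels_assign_compartments(self):
        img = np.zeros((10, 10))
        img[2, 2] = 500.0
        img[7, 7] = 500.0
        labels = np.zeros((10, 10), dtype=int)
        labels[:5, :5] = 1
        calls = incquant.find_maxima(img, None, 100, labels=labels)
        comp = {c.center: (c.compartment, c.parent_label) for c in calls}
        assert comp[(2, 2)] == ("nuclear", 1)
        assert comp[(7, 7)] == ("extra_nuclear", None)


class TestClassifyACN:
    def test_strict_inequality_at_threshold(self):
        spec = synthio.SynthImageSpec(seed=3, field_shape=(256, 256),
                                      n_nuclei=10, acn_fraction=0.0,
                                      ena_density=0)
        field, _ = synthio.make_field(spec)
        mask = _segmented(field)
        for rec in mask.nuclei:
            rec.i_max_ch2 = 2000.0  # exactly at threshold
        pct = incquant.classify_acn(mask, field.ch2, 2000)
        assert pct == 0.0
        assert not any(rec.is_acn for rec in mask.nuclei)

    def test_planted_fraction_recovered_exactly(self, clean_field):
        field, truth = clean_field
        mask = _segmented(field)
        pct = incquant.classify_acn(mask, field.ch2, 2000)
        assert pct == pytest.approx(100.0 * truth.n_acn / len(truth.nuclei))

    def test_one_in_ten(self):
        spec = synthio.SynthImageSpec(seed=8, field_shape=(256, 256),
                                      n_nuclei=10, acn_fraction=0.1,
                                      touching_pair_fraction=0.0,
                                      ena_density=0)
        field, _ = synthio.make_field(spec)
        mask = _segmented(field)
        assert incquant.classify_acn(mask, field.ch2, 2000) == 10.0

    def test_zero_cells_missing_not_zero(self):
        mask = nucseg.NuclearMask(labels=np.zeros((8, 8), dtype=int),
                                  threshold_used=100, nuclei=[])
        assert incquant.classify_acn(mask, np.zeros((8, 8)), 2000) is None


class TestNuclearAggregates:
    def _field_one_acn(self, k):
        nuclear = np.zeros((64, 64))
        rr, cc = np.mgrid[0:64, 0:64]
        nuclear[np.hypot(rr - 32, cc - 32) < 14] = 10000
        ch2 = np.full((64, 64), 500.0)
        centers = [(32, 32), (32, 24), (26, 36)][:k]
        for ctr in centers:
            _gauss(ch2, ctr, 1.5, 3000.0)
        field = FieldImage(np.stack([nuclear, ch2]).astype(np.uint16))
        mask = nucseg.segment_nuclei(field, 4000)
        incquant.classify_acn(mask, field.ch2, 2000)
        return mask, field.ch2

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_planted_spot_counts(self, k):
        mask, ch2 = self._field_one_acn(k)
        nas = incquant.count_nuclear_aggregates(mask, ch2, 150)
        assert nas == k
        assert mask.nuclei[0].na_count == k

    def test_no_acns_missing(self):
        spec = synthio.SynthImageSpec(seed=4, field_shape=(256, 256),
                                      n_nuclei=8, acn_fraction=0.0,
                                      ena_density=0)
        field, _ = synthio.make_field(spec)
        mask = _segmented(field)
        incquant.classify_acn(mask, field.ch2, 2000)
        assert incquant.count_nuclear_aggregates(mask, field.ch2) is None


class TestExtraNuclearAndTotal:
    def test_no_planted_enas_zero(self):
        spec = synthio.SynthImageSpec(seed=6, field_shape=(256, 256),
                                      n_nuclei=10, acn_fraction=0.0,
                                      ena_density=0)
        field, _ = synthio.make_field(spec)
        mask = _segmented(field)
        count, per_cell = incquant.extra_nuclear_aggregates(mask, field.ch2)
        assert count == 0 and per_cell == 0.0

    def test_planted_enas_per_cell(self, clean_field):
        field, truth = clean_field
        mask = _segmented(field)
        count, per_cell = incquant.extra_nuclear_aggregates(mask, field.ch2)
        assert count == len(truth.extra_nuclear_spots)
        assert per_cell == count / len(truth.nuclei)

    def test_spot_on_nuclear_pixel_counted_nuclear(self):
        nuclear = np.zeros((64, 64))
        rr, cc = np.mgrid[0:64, 0:64]
        nuclear[np.hypot(rr - 32, cc - 32) < 14] = 10000
        ch2 = np.full((64, 64), 500.0)
        _gauss(ch2, (32, 32), 1.5, 3000.0)  # on a nuclear pixel
        field = FieldImage(np.stack([nuclear, ch2]).astype(np.uint16))
        mask = nucseg.segment_nuclei(field, 4000)
        incquant.classify_acn(mask, field.ch2, 2000)
        ena_count, _ = incquant.extra_nuclear_aggregates(mask, field.ch2)
        assert ena_count == 0
        assert incquant.count_nuclear_aggregates(mask, field.ch2) == 1

    def test_blank_channel_zero_totals(self):
        count, ratio = incquant.total_aggregates(np.zeros((64, 64)), 10)
        assert count == 0 and ratio == 0.0

    def test_total_prominence_rule(self):
        ch2 = np.full((64, 64), 100.0)
        _gauss(ch2, (20, 20), 1.5, 1500.0)  # prominence 1500: counted
        _gauss(ch2, (45, 45), 1.5, 500.0)   # prominence 500: not at tol 1000
        count, _ = incquant.total_aggregates(ch2, 1, noise_tolerance=1000)
        assert count == 1
        count150, _ = incquant.total_aggregates(ch2, 1, noise_tolerance=150)
        assert count150 == 2


class TestAreaAndBackground:
    def test_no_acns_zero_area_fraction(self):
        spec = synthio.SynthImageSpec(seed=12, field_shape=(256, 256),
                                      n_nuclei=10, acn_fraction=0.0,
                                      ena_density=0)
        field, _ = synthio.make_field(spec)
        mask = _segmented(field)
        incquant.classify_acn(mask, field.ch2, 2000)
        assert incquant.aggregate_area(mask, field.ch2) == 0.0

    def test_area_fraction_arithmetic(self):
        labels = np.zeros((40, 40), dtype=np.int32)
        labels[0:10, 0:20] = 1   # 200 px, all bright
        labels[20:30, 0:20] = 2  # 200 px nucleus, dark
        labels[30:40, 0:20] = 3  # 200 px nucleus, dark
        ch2 = np.zeros((40, 40))
        ch2[0:10, 0:20] = 3000.0
        recs = [nucseg.NucleusRecord(label=i, area=200, centroid=(0, 0),
                                     roundness=1.0, mean_nuclear_intensity=0,
                                     i_max_ch2=float(ch2[labels == i].max()))
                for i in (1, 2, 3)]
        mask = nucseg.NuclearMask(labels=labels, threshold_used=1, nuclei=recs)
        incquant.classify_acn(mask, ch2, 2000)
        frac = incquant.aggregate_area(mask, ch2, area_threshold=969)
        assert frac == pytest.approx(200 / 600)

    def test_acn_only_denominator_switch(self):
        labels = np.zeros((20, 40), dtype=np.int32)
        labels[0:10, 0:20] = 1
        labels[10:20, 0:20] = 2
        ch2 = np.zeros((20, 40))
        ch2[0:10, 0:20] = 3000.0
        recs = [nucseg.NucleusRecord(label=i, area=200, centroid=(0, 0),
                                     roundness=1.0, mean_nuclear_intensity=0,
                                     i_max_ch2=float(ch2[labels == i].max()))
                for i in (1, 2)]
        mask = nucseg.NuclearMask(labels=labels, threshold_used=1, nuclei=recs)
        incquant.classify_acn(mask, ch2, 2000)
        assert incquant.aggregate_area(mask, ch2) == pytest.approx(0.5)
        assert incquant.aggregate_area(
            mask, ch2, all_nuclei_denominator=False) == pytest.approx(1.0)

    def test_mean_background_uniform(self):
        assert incquant.mean_background(np.full((16, 16), 500.0)) == 500.0

    def test_mean_background_excludes_at_and_above_cutoff(self):
        img = np.concatenate([np.full(128, 1000.0), np.full(128, 3000.0)])
        assert incquant.mean_background(img.reshape(16, 16)) == 1000.0
        img2 = np.concatenate([np.full(128, 1000.0), np.full(128, 2000.0)])
        assert incquant.mean_background(img2.reshape(16, 16)) == 1000.0

    def test_mean_background_tracks_cytoplasm_level(self):
        spec = synthio.SynthImageSpec(seed=2, field_shape=(256, 256),
                                      n_nuclei=0, acn_fraction=0.0,
                                      ena_density=0, cytoplasm_level=700.0,
                                      noise_sd=30.0)
        field, _ = synthio.make_field(spec)
        se = 3 * 30.0 / np.sqrt(field.ch2.size)
        assert incquant.mean_background(field.ch2) == pytest.approx(700.0, abs=5 * se + 0.5)

    def test_median_imax(self):
        recs = [nucseg.NucleusRecord(label=i, area=1, centroid=(0, 0),
                                     roundness=1, mean_nuclear_intensity=0,
                                     i_max_ch2=v)
                for i, v in enumerate([1.0, 2.0, 3.0])]
        assert incquant.median_imax(recs) == 2.0
        assert incquant.median_imax([]) is None


class TestPerinuclearMarker:
    def test_uniform_marker_equal_rings(self, clean_field):
        field, _ = clean_field
        mask = _segmented(field)
        incquant.classify_acn(mask, field.ch2, 2000)
        means = incquant.perinuclear_intensity(mask, np.full(field.shape, 321.0))
        assert all(v == pytest.approx(321.0) for v in means.values())

    def test_acn_suppression_ratio(self):
        spec = synthio.SynthImageSpec(
            seed=19, field_shape=(384, 384), n_nuclei=24, acn_fraction=0.5,
            touching_pair_fraction=0.0, ena_density=0, marker_level=2000.0,
            marker_acn_suppression=0.5, noise_sd=5.0)
        field, _ = synthio.make_field(spec)
        mask = _segmented(field)
        incquant.classify_acn(mask, field.ch2, 2000)
        means = incquant.perinuclear_intensity(mask, field.marker)
        acn = [means[r.label] for r in mask.nuclei if r.is_acn]
        non = [means[r.label] for r in mask.nuclei if not r.is_acn]
        ratio = np.mean(acn) / np.mean(non)
        assert 0.4 < ratio < 0.65

    def test_marker_positive_fraction_extremes(self, clean_field):
        field, _ = clean_field
        mask = _segmented(field)
        marker = np.full(field.shape, 800.0)
        assert incquant.marker_positive_fraction(mask, marker, 0.0) == 100.0
        assert incquant.marker_positive_fraction(mask, marker, 65536.0) == 0.0

    def test_planted_positive_fraction(self):
        spec = synthio.SynthImageSpec(
            seed=23, field_shape=(512, 512), n_nuclei=40, acn_fraction=0.0,
            touching_pair_fraction=0.0, ena_density=0, marker_level=2000.0,
            marker_positive_fraction=0.9, noise_sd=5.0)
        field, truth = synthio.make_field(spec)
        mask = _segmented(field)
        pct = incquant.marker_positive_fraction(mask, field.marker, 1000.0)
        assert pct == pytest.approx(90.0, abs=2.0)


class TestPooling:
    def test_nas_per_cell_identity(self, default_field):
        field, _ = default_field
        mask = _segmented(field)
        fq = incquant.quantify_field(mask, field.ch2, well_id="w")
        wm = incquant.pool_wells([fq])[0]
        n_acn = sum(1 for r in mask.nuclei if r.is_acn)
        assert wm.nas_per_cell == pytest.approx(
            wm.nas_per_acn * n_acn / wm.tot_cells)
        assert 0 <= wm.pct_acn <= 100
        assert wm.mean_background < 2000
        assert 0 <= wm.na_area_frac <= 1

    def test_counts_pool_by_summation(self):
        fq1 = incquant.FieldQuant("w", "f1", tot_cells=10, n_acn=2,
                                  imax_values=[1.0], na_count_sum=4,
                                  ena_count=1, total_agg_count=5,
                                  na_area_sum=10, nuclear_area_sum=100,
                                  background_sum=1000.0, background_n=10)
        fq2 = incquant.FieldQuant("w", "f2", tot_cells=30, n_acn=6,
                                  imax_values=[3.0], na_count_sum=12,
                                  ena_count=3, total_agg_count=15,
                                  na_area_sum=30, nuclear_area_sum=300,
                                  background_sum=3000.0, background_n=30)
        wm = incquant.pool_wells([fq1, fq2])[0]
        assert wm.tot_cells == 40
        assert wm.pct_acn == 20.0
        assert wm.nas_per_acn == 2.0
        assert wm.enas_per_cell == 0.1
        assert wm.na_area_frac == 0.1
        assert wm.mean_background == 100.0

    def test_empty_well_metrics_missing(self):
        fq = incquant.FieldQuant("w", "f", tot_cells=0, n_acn=0,
                                 imax_values=[], na_count_sum=0, ena_count=0,
                                 total_agg_count=0, na_area_sum=0,
                                 nuclear_area_sum=0, background_sum=0.0,
                                 background_n=0)
        wm = incquant.pool_wells([fq])[0]
        assert wm.pct_acn is None
        assert wm.nas_per_acn is None
        assert wm.median_imax is None
        assert wm.na_area_frac is None
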