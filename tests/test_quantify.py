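import numpy as np
import pytest

from inclusion_screen import quantify as q
from inclusion_screen import synthetic as syn
from inclusion_screen.synthetic import _vignette

from conftest import disc_image, match_cells_to_truth


class TestShadeCorrect:
    def test_flat_image_identity(self):
        img = q.FluorImage(np.full((96, 96), 300.0))
        out = q.shade_correct(img)
        np.testing.assert_allclose(out.pixels, img.pixels, atol=1e-8)

    def test_vignette_removed_on_synthetic_truth(self):
        v = 60.0
        px = 200.0 + _vignette((256, 256), v)
        out = q.shade_correct(q.FluorImage(px))
        assert np.ptp(out.pixels) < 0.1 * v

    def test_mean_preserved(self):
        px = 200.0 + _vignette((128, 128), 80.0)
        out = q.shade_correct(q.FluorImage(px))
        assert abs(out.pixels.mean() - px.mean()) <= 0.01 * px.mean()

    def test_idempotent(self):
        px = 200.0 + _vignette((160, 160), 50.0)
        once = q.shade_correct(q.FluorImage(px))
        twice = q.shade_correct(once)
        np.testing.assert_allclose(twice.pixels, once.pixels, atol=1e-6)

    def test_flatfield_reference_mode(self):
        ref = 200.0 + _vignette((64, 64), 40.0)
        img = q.FluorImage(ref * 2.0)
        out = q.shade_correct(img, model="flatfield_reference", reference=ref)
        assert np.ptp(out.pixels) < 1e-8

    def test_unknown_model(self):
        with pytest.raises(ValueError):
            q.shade_correct(q.FluorImage(np.ones((8, 8))), model="spline")


class TestEstimateBackground:
    def test_constant_image(self, default_params):
        level, bg_map = q.estimate_background(
            q.FluorImage(np.full((64, 64), 200.0)), default_params
        )
        assert level == pytest.approx(200.0)
        np.testing.assert_allclose(bg_map, 200.0)

    @pytest.mark.parametrize(
        "method", ["tile_percentile", "median", "rolling_ball", "global"]
    )
    def test_cells_do_not_bias_estimate(self, method):
        # cells at +600 covering < 30% of pixels; estimate within +/-5 units
        img = disc_image(
            shape=(128, 128),
            discs=[(r, c, 9, 600.0) for r in (30, 64, 98) for c in (30, 64, 98)],
        )
        params = q.SegmentationParams(
            background_method=method, background_radius_px=24
        )
        level, _ = q.estimate_background(img, params)
        assert abs(level - 200.0) <= 5.0

    @pytest.mark.parametrize("method", ["tile_percentile", "median", "global"])
    def test_translation_equivariance(self, method):
        rng = np.random.default_rng(0)
        px = 200.0 + rng.normal(0, 5, (96, 96)).clip(-100)
        params = q.SegmentationParams(background_method=method, background_radius_px=16)
        lvl1, _ = q.estimate_background(q.FluorImage(px), params)
        lvl2, _ = q.estimate_background(q.FluorImage(px + 37.0), params)
        assert lvl2 - lvl1 == pytest.approx(37.0, abs=1e-6)

    def test_saturated_image_rejected(self, default_params):
        img = q.FluorImage(np.full((32, 32), 65535.0))
        with pytest.raises(ValueError):
            q.estimate_background(img, default_params)


class TestSegmentCells:
    def test_uniform_image_empty_mask(self, default_params):
        img = q.FluorImage(np.full((64, 64), 200.0))
        _, bg = q.estimate_background(img, default_params)
        assert q.segment_cells(img, bg, default_params).max() == 0

    def test_printed_threshold_semantics(self, default_params):
        # >=300 difference isolates a cell; 250 does not
        for delta, expected in [(250.0, 0), (400.0, 1)]:
            img = disc_image(discs=[(64, 64, 10, delta)])
            _, bg = q.estimate_background(img, default_params)
            assert q.segment_cells(img, bg, default_params).max() == expected

    def test_all_synthetic_cells_found(self, small_cfg, default_params):
        imgs, truth = syn.generate_plate_images(
            [syn.StrainSpec("s", "g", true_inclusion_prob=0.5)], small_cfg, seed=2
        )
        img = q.shade_correct(imgs[0])
        _, bg = q.estimate_background(img, default_params)
        mask = q.segment_cells(img, bg, default_params)
        n_truth = truth.wells["A01"]["n_cells"]
        assert mask.max() == n_truth
        # each detected label overlaps exactly one truth disc
        labels = truth.cell_labels[img.image_id]
        for lbl in range(1, mask.max() + 1):
            overlap = np.unique(labels[mask == lbl])
            assert len(overlap[overlap > 0]) == 1

    def test_area_gating(self):
        img = disc_image(discs=[(64, 64, 3, 500.0)])  # ~29 px < min area 50
        params = q.SegmentationParams()
        _, bg = q.estimate_background(img, params)
        assert q.segment_cells(img, bg, params).max() == 0

    def test_border_policy(self):
        img = disc_image(discs=[(5, 64, 8, 500.0)])
        _, bg = q.estimate_background(img, q.SegmentationParams())
        excl = q.segment_cells(img, bg, q.SegmentationParams(border_policy="exclude"))
        incl = q.segment_cells(img, bg, q.SegmentationParams(border_policy="include"))
        assert excl.max() == 0 and incl.max() == 1

    def test_raising_delta_never_grows_foreground(self):
        img = disc_image(discs=[(40, 40, 10, 350.0), (90, 90, 10, 800.0)])
        _, bg = q.estimate_background(img, q.SegmentationParams())
        sizes = []
        for delta in (300.0, 400.0, 900.0):
            mask = q.segment_cells(img, bg, q.SegmentationParams(cell_delta=delta))
            sizes.append((mask > 0).sum())
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_intensity_shift_invariance(self, default_params):
        img = disc_image(discs=[(64, 64, 10, 400.0)])
        shifted = q.FluorImage(img.pixels + 123.0)
        _, bg1 = q.estimate_background(img, default_params)
        _, bg2 = q.estimate_background(shifted, default_params)
        np.testing.assert_array_equal(
            q.segment_cells(img, bg1, default_params),
            q.segment_cells(shifted, bg2, default_params),
        )


class TestSegmentInclusions:
    def _run(self, img, params=None):
        params = params or q.SegmentationParams()
        _, bg = q.estimate_background(img, params)
        cm = q.segment_cells(img, bg, params)
        return cm, q.segment_inclusions(img, cm, params)

    def test_empty_cell_mask_gives_empty_inclusions(self, default_params):
        img = q.FluorImage(np.full((64, 64), 200.0))
        inc = q.segment_inclusions(img, np.zeros((64, 64), dtype=np.int32), default_params)
        assert not inc.any()

    def test_printed_threshold_semantics(self):
        # >=400 above the cellular level isolates an inclusion; 350 does not
        for delta, expected in [(350.0, False), (450.0, True)]:
            img = disc_image(
                discs=[(64, 64, 10, 500.0)], puncta=[(64, 64, 2, delta)]
            )
            cm, inc = self._run(img)
            assert cm.max() == 1
            assert inc.any() == expected

    def test_mask_nesting(self, small_cfg):
        imgs, _ = syn.generate_plate_images(
            [syn.StrainSpec("s", "g", true_inclusion_prob=0.8)], small_cfg, seed=9
        )
        img = q.shade_correct(imgs[0])
        cm, inc = self._run(img)
        assert not (inc & (cm == 0)).any()

    def test_min_area_suppresses_single_pixels(self):
        img = disc_image(discs=[(64, 64, 10, 500.0)])
        img.pixels[64, 64] += 450.0  # lone hot pixel
        cm, inc = self._run(img)
        assert not inc.any()

    def test_raising_delta_never_grows_inclusions(self):
        img = disc_image(
            discs=[(64, 64, 12, 500.0)],
            puncta=[(60, 60, 2, 450.0), (70, 70, 2, 900.0)],
        )
        counts = []
        for delta in (400.0, 600.0, 1000.0):
            params = q.SegmentationParams(inclusion_delta=delta)
            cm, inc = self._run(img, params)
            counts.append(inc.sum())
        assert counts[0] >= counts[1] >= counts[2]

    def test_truth_flags_recovered_with_noise(self, default_params):
        cfg = syn.ImagingConfig(
            image_shape=(192, 192), cells_per_image=(25, 35), noise_sd=20.0
        )
        total = correct = 0
        for seed in range(3):
            imgs, truth = syn.generate_plate_images(
                [syn.StrainSpec("s", "g", true_inclusion_prob=0.4)], cfg, seed=seed
            )
            img = q.shade_correct(imgs[0])
            _, bg = q.estimate_background(img, default_params)
            cm = q.segment_cells(img, bg, default_params)
            inc = q.segment_inclusions(img, cm, default_params)
            records = q.score_cells(img, cm, inc)
            n_truth, matched = match_cells_to_truth(truth, imgs[0], cm, records)
            total += n_truth
            correct += sum(a == b for a, b in matched)
        assert correct / total >= 0.95


class TestScoring:
    def test_no_inclusions(self):
        img = disc_image(discs=[(40, 40, 8, 500.0), (90, 90, 8, 500.0)])
        params = q.SegmentationParams()
        _, bg = q.estimate_background(img, params)
        cm = q.segment_cells(img, bg, params)
        records = q.score_cells(img, cm, np.zeros_like(cm, dtype=bool))
        assert len(records) == 2
        assert not any(r.has_inclusion for r in records)

    def test_every_cell_with_inclusion(self):
        img = disc_image(
            discs=[(40, 40, 8, 500.0), (90, 90, 8, 500.0)],
            puncta=[(40, 40, 2, 600.0), (90, 90, 2, 600.0)],
        )
        params = q.SegmentationParams()
        _, bg = q.estimate_background(img, params)
        cm = q.segment_cells(img, bg, params)
        inc = q.segment_inclusions(img, cm, params)
        records = q.score_cells(img, cm, inc)
        assert all(r.has_inclusion for r in records)

    def test_mean_intensity_of_flat_cell_exact(self):
        img = disc_image(discs=[(64, 64, 10, 500.0)])
        params = q.SegmentationParams()
        _, bg = q.estimate_background(img, params)
        cm = q.segment_cells(img, bg, params)
        records = q.score_cells(img, cm, np.zeros_like(cm, dtype=bool))
        assert records[0].mean_intensity == pytest.approx(700.0)

    def test_score_well_bounds_and_conservation(self):
        records = [
            q.CellRecord("i", lbl, 100, 500.0, int(flag), 5 * int(flag), bool(flag))
            for lbl, flag in enumerate([1, 0, 1, 0, 0, 0, 1, 0, 0, 0], start=1)
        ]
        pheno = q.score_well(records, min_cells_for_scoring=5)
        assert pheno.pct_inclusion == pytest.approx(30.0)
        assert 0 <= pheno.pct_inclusion <= 100
        assert round(pheno.n_cells * pheno.pct_inclusion / 100) == 3
        assert pheno.qc_pass

    def test_score_well_extremes(self):
        none = [q.CellRecord("i", 1, 50, 400.0, 0, 0, False)] * 10
        allinc = [q.CellRecord("i", 1, 50, 400.0, 1, 4, True)] * 10
        assert q.score_well(none, min_cells_for_scoring=5).pct_inclusion == 0.0
        assert q.score_well(allinc, min_cells_for_scoring=5).pct_inclusion == 100.0

    def test_empty_well(self):
        pheno = q.score_well([], well="A01")
        assert pheno.n_cells == 0
        assert np.isnan(pheno.pct_inclusion)
        assert not pheno.qc_pass

    def test_qc_gate(self):
        records = [q.CellRecord("i", 1, 50, 400.0, 0, 0, False)] * 10
        assert not q.score_well(records, min_cells_for_scoring=300).qc_pass

    def test_planted_probability_recovered(self):
        cfg = syn.ImagingConfig(image_shape=(256, 256), cells_per_image=(50, 70))
        imgs, truth = syn.generate_plate_images(
            [syn.StrainSpec("s", "g", true_inclusion_prob=0.4)],
            cfg, replicates=10, seed=21,
        )
        records = []
        for img in imgs:
            records.extend(q.quantify_image(img))
        assert len(records) >= 500
        pheno = q.score_well(records, min_cells_for_scoring=300)
        se = 100 * np.sqrt(0.4 * 0.6 / len(records))
        assert abs(pheno.pct_inclusion - 40.0) <= 3 * se


class TestRoundTrip:
    def test_write_then_load_plate(self, tmp_path, small_cfg):
        strains = [syn.StrainSpec("s1", "g1", true_inclusion_prob=0.3)]
        imgs, truth = syn.generate_plate_images(strains, small_cfg, seed=0)
        syn.write_plate(imgs, truth, tmp_path)
        loaded = q.load_plate(tmp_path / "images", tmp_path / "platemap.csv")
        assert len(loaded) == len(imgs)
        np.testing.assert_allclose(loaded[0].pixels, np.round(imgs[0].pixels), atol=0)
        assert loaded[0].strain_id == "s1"
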