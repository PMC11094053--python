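"""Phantom generator: analytic volumes, infarct morphology, degradation, splits."""

import numpy as np
import pytest

from cinefunc import phantom as ph


class TestGeneratePhantom:
    def test_raster_volume_matches_closed_form_disk(self):
        """Single labeled slice, r=8 px at 0.4 mm: cavity volume ~ pi r^2 dz."""
        cfg = ph.PhantomConfig(n_slices=3, n_phases=4, image_size=64,
                               endo_radius_px=8.0, wall_thickness_px=4.0,
                               contraction_fraction=0.0, empty_slice_margin=1,
                               seed=0)
        _, gt = ph.generate_phantom_stack(cfg)
        analytic_per_slice_mm3 = np.pi * (8 * 0.4) ** 2 * 6.0
        assert analytic_per_slice_mm3 == pytest.approx(193.0, abs=0.1)
        voxels = int((gt.masks[1, 0] == ph.CAVITY).sum())
        raster_mm3 = voxels * 0.4 * 0.4 * 6.0
        assert raster_mm3 == pytest.approx(analytic_per_slice_mm3, rel=0.05)

    def test_shapes_and_empty_margins(self, small_phantom):
        cfg, stack, gt = small_phantom
        assert stack.data.shape == (cfg.n_slices, cfg.n_phases, 64, 64)
        assert gt.masks.shape == stack.data.shape
        assert not gt.masks[0].any() and not gt.masks[-1].any()
        for s in cfg.labeled_slices:
            assert gt.masks[s, 0].any()

    def test_label_set_and_disjointness(self, small_phantom):
        _, _, gt = small_phantom
        assert set(np.unique(gt.masks)) <= {0, 1, 2}

    def test_no_contraction_gives_static_masks_and_zero_ef(self):
        cfg = ph.PhantomConfig(n_slices=4, n_phases=6, image_size=48,
                               endo_radius_px=8.0, wall_thickness_px=4.0,
                               contraction_fraction=0.0, empty_slice_margin=1,
                               seed=3)
        _, gt = ph.generate_phantom_stack(cfg)
        np.testing.assert_array_equal(gt.masks[:, gt.ed_phase], gt.masks[:, gt.es_phase])
        assert gt.analytic_ef_percent == pytest.approx(0.0)
        assert gt.analytic_edv_ml == gt.analytic_esv_ml

    def test_seeded_determinism(self, small_phantom):
        cfg, stack, gt = small_phantom
        stack2, gt2 = ph.generate_phantom_stack(cfg)
        np.testing.assert_array_equal(stack.data, stack2.data)
        np.testing.assert_array_equal(gt.masks, gt2.masks)

    def test_volume_profile_has_extrema_at_ed_es(self, small_phantom):
        _, _, gt = small_phantom
        per_phase = (gt.masks == ph.CAVITY).sum(axis=(0, 2, 3))
        assert int(np.argmax(per_phase)) == gt.ed_phase == 0
        assert int(np.argmin(per_phase)) == gt.es_phase

    def test_contraction_ef_closed_form(self):
        """EF = 100 (1 - (1-f)^2) for a uniform radial shrink by f."""
        f = 0.3
        cfg = ph.PhantomConfig(n_slices=4, n_phases=10, image_size=64,
                               endo_radius_px=10.0, wall_thickness_px=4.0,
                               contraction_fraction=f, empty_slice_margin=1, seed=0)
        _, gt = ph.generate_phantom_stack(cfg)
        assert gt.analytic_ef_percent == pytest.approx(100 * (1 - (1 - f) ** 2))

    def test_geometry_exceeding_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            ph.PhantomConfig(image_size=32, endo_radius_px=14.0,
                             wall_thickness_px=4.0)

    def test_raster_error_decreases_with_finer_spacing(self):
        """Halving the pixel spacing (same physical geometry) shrinks the error."""
        errors = []
        for size, r, spacing in [(64, 8.0, 0.8), (128, 16.0, 0.4)]:
            cfg = ph.PhantomConfig(n_slices=3, n_phases=4, image_size=size,
                                   pixel_spacing_mm=spacing, endo_radius_px=r,
                                   wall_thickness_px=r / 2,
                                   contraction_fraction=0.2,
                                   empty_slice_margin=1, seed=5)
            _, gt = ph.generate_phantom_stack(cfg)
            voxels = int((gt.masks[1, 0] == ph.CAVITY).sum())
            raster = voxels * spacing**2 * 6.0
            analytic = np.pi * (r * spacing) ** 2 * 6.0
            errors.append(abs(raster - analytic) / analytic)
        assert errors[1] < errors[0]


class TestInfarct:
    @staticmethod
    def _base(seed=0):
        cfg = ph.PhantomConfig(n_slices=4, n_phases=6, image_size=64,
                               endo_radius_px=10.0, wall_thickness_px=6.0,
                               contraction_fraction=0.25,
                               empty_slice_margin=1, seed=seed)
        return cfg, ph.generate_phantom_stack(cfg)[1]

    def test_zero_thinning_is_identity(self):
        _, gt = self._base()
        spec = ph.InfarctSpec(0, 90, 0.0, (1,))
        out = ph.apply_infarct(gt, spec)
        np.testing.assert_array_equal(out.masks, gt.masks)

    def test_sector_thinning_reduces_annulus_area_as_predicted(self):
        """90 deg sector at thinning 0.5: pixel-count loss matches the continuous sector geometry."""
        _, gt = self._base()
        spec = ph.InfarctSpec(0, 90, 0.5, (1, 2))
        out = ph.apply_infarct(gt, spec)
        r, w = 10.0, 6.0
        expected_ratio = ((r + w) ** 2 - (r + w / 2) ** 2) / (4 * ((r + w) ** 2 - r**2))
        before = int((gt.masks[1, 0] == ph.MYOCARDIUM).sum())
        after = int((out.masks[1, 0] == ph.MYOCARDIUM).sum())
        assert after < before
        assert (before - after) / before == pytest.approx(expected_ratio, rel=0.2)
        # cavity untouched
        np.testing.assert_array_equal(out.masks[1, 0] == ph.CAVITY,
                                      gt.masks[1, 0] == ph.CAVITY)

    def test_full_circle_thinning_halves_wall(self):
        _, gt = self._base()
        spec = ph.InfarctSpec(0, 360, 0.5, (1,))
        out = ph.apply_infarct(gt, spec)
        cy, cx = gt.geometry["center"]
        yy, xx = np.mgrid[0:64, 0:64]
        rr = np.hypot(yy - cy, xx - cx)
        r_endo = gt.geometry["radius_table"][1, 0]
        outer_before = rr[gt.masks[1, 0] == ph.MYOCARDIUM].max()
        outer_after = rr[out.masks[1, 0] == ph.MYOCARDIUM].max()
        assert outer_after - r_endo == pytest.approx((outer_before - r_endo) / 2, abs=1.0)

    def test_unlabeled_slice_rejected(self):
        _, gt = self._base()
        with pytest.raises(ValueError, match="no labeled ventricle"):
            ph.apply_infarct(gt, ph.InfarctSpec(0, 90, 0.5, (0,)))

    def test_invalid_thinning_rejected(self):
        with pytest.raises(ValueError):
            ph.InfarctSpec(0, 90, 1.0, (1,))


class TestDegradation:
    def test_best_score_is_identity(self, small_phantom):
        _, stack, _ = small_phantom
        out = ph.inject_degradation(stack, ph.QualityScore(1, 1, 1), seed=0)
        np.testing.assert_array_equal(out.data, stack.data)

    def test_noise_monotone_in_score(self, small_phantom):
        """Background SD strictly larger at noise score 4 than 2, same seed."""
        _, stack, gt = small_phantom
        bg = gt.masks[2, 0] == 0
        sds = []
        for score in (2, 4):
            out = ph.inject_degradation(stack, ph.QualityScore(1, score, 1), seed=7)
            sds.append(out.data[2, 0][bg].std())
        assert sds[1] > sds[0]

    def test_seeded_determinism(self, small_phantom):
        _, stack, _ = small_phantom
        q = ph.QualityScore(3, 3, 2)
        a = ph.inject_degradation(stack, q, seed=9)
        b = ph.inject_degradation(stack, q, seed=9)
        np.testing.assert_array_equal(a.data, b.data)

    def test_masks_untouched_by_design(self, small_phantom):
        """Degradation acts on intensities only; ground truth is separate state."""
        _, stack, gt = small_phantom
        before = gt.masks.copy()
        ph.inject_degradation(stack, ph.QualityScore(4, 4, 4), seed=0)
        np.testing.assert_array_equal(gt.masks, before)


class TestQualityScore:
    @pytest.mark.parametrize("q,total", [((1, 1, 1), 3), ((4, 4, 4), 12),
                                         ((2, 2, 2), 6), ((2, 1, 4), 7)])
    def test_total(self, q, total):
        assert ph.total_quality_score(ph.QualityScore(*q)) == total

    def test_component_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ph.QualityScore(0, 1, 1)
        with pytest.raises(ValueError):
            ph.QualityScore(1, 5, 1)


class TestSplit:
    ANIMALS = [(f"I{i}", "infarct") for i in range(7)] + \
              [(f"S{i}", "sham") for i in range(4)]

    def test_cohort_composition(self):
        """11 animals (7 infarct, 4 sham) at counts (6,2,3) stratify to 4+2/1+1/2+1."""
        split = ph.split_animals(self.ANIMALS, (6, 2, 3), seed=0)
        groups = dict(self.ANIMALS)

        def comp(subset):
            return sorted(groups[a] for a in subset)

        assert comp(split.train) == ["infarct"] * 4 + ["sham"] * 2
        assert comp(split.validation) == ["infarct", "sham"]
        assert comp(split.test) == ["infarct"] * 2 + ["sham"]

    def test_disjoint_and_stratified_over_seeds(self):
        for seed in range(100):
            split = ph.split_animals(self.ANIMALS, (6, 2, 3), seed=seed)
            all_ids = set(split.train) | set(split.validation) | set(split.test)
            assert len(all_ids) == 11
            assert len(split.train) == 6 and len(split.test) == 3

    def test_degenerate_all_train(self):
        split = ph.split_animals(self.ANIMALS, (11, 0, 0), seed=1)
        assert len(split.train) == 11
        assert not split.validation and not split.test

    def test_bad_counts_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            ph.split_animals(self.ANIMALS, (6, 2, 2), seed=0)

    def test_explicit_quotas(self):
        q = {"train": {"infarct": 4, "sham": 2},
             "validation": {"infarct": 1, "sham": 1},
             "test": {"infarct": 2, "sham": 1}}
        split = ph.split_animals(self.ANIMALS, (6, 2, 3), seed=0, quotas=q)
        assert len(split.train) == 6


class TestPerturbMasks:
    def test_zero_magnitude_is_copy(self, small_phantom):
        _, _, gt = small_phantom
        out = ph.perturb_masks(gt.masks, 0.0, seed=0)
        np.testing.assert_array_equal(out, gt.masks)

    def test_disagreement_grows_with_magnitude(self, small_phantom):
        from cinefunc.metrics import dice
        _, _, gt = small_phantom
        ref = gt.masks[2, 0]
        scores = []
        for mag in (0.4, 2.0):
            pert = ph.perturb_masks(gt.masks[2:3, 0:1], mag, seed=11)[0, 0]
            scores.append(dice(pert == 1, ref == 1))
        assert scores[1] < scores[0]
        assert set(np.unique(pert)) <= {0, 1, 2}
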