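"""Segmentation network: preprocessing, augmentation, the transfer schedule contract."""

import numpy as np
import pytest

from cinefunc import model as mdl
from cinefunc import phantom as ph


def phantom_frames(seed, n_phantoms=3, size=64):
    """ED/ES frames with labels from clean phantoms, ready for training."""
    out = []
    rng = np.random.default_rng(seed)
    for j in range(n_phantoms):
        cfg = ph.PhantomConfig(n_slices=4, n_phases=6, image_size=size,
                               endo_radius_px=rng.uniform(0.12, 0.2) * size,
                               wall_thickness_px=0.06 * size,
                               contraction_fraction=0.3, empty_slice_margin=1,
                               seed=seed * 100 + j)
        stack, gt = ph.generate_phantom_stack(cfg)
        for s in range(cfg.n_slices):
            for p in (gt.ed_phase, gt.es_phase):
                img = mdl.preprocess(stack.data[s, p], input_size=size)
                out.append((img, gt.masks[s, p]))
    return out


class TestPreprocess:
    def test_rescale_to_input_size(self, rng):
        img = rng.random((64, 80))
        out = mdl.preprocess(img, input_size=256)
        assert out.shape == (256, 256)
        assert out.min() == pytest.approx(0.0) and out.max() == pytest.approx(1.0)

    def test_native_size_is_normalization_only(self, rng):
        img = rng.random((256, 256))
        out = mdl.preprocess(img, input_size=256, normalization="none")
        np.testing.assert_array_equal(out, img)

    def test_mask_labels_preserved_by_nearest_neighbor(self):
        mask = np.zeros((40, 40), np.uint8)
        mask[10:20, 10:20] = 2
        _, m = mdl.preprocess(np.ones((40, 40)), mask, input_size=96)
        assert set(np.unique(m)) <= {0, 2}

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            mdl.preprocess(np.empty((0, 0)))

    def test_nonfinite_rejected(self):
        img = np.ones((8, 8))
        img[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            mdl.preprocess(img)


class TestAugment:
    def _blob(self):
        img = np.zeros((32, 32))
        mask = np.zeros((32, 32), np.uint8)
        img[10:14, 4:8] = 1.0
        mask[10:14, 4:8] = 1
        return img, mask

    def test_flip_mirrors_image_and_mask_jointly(self):
        img, mask = self._blob()
        fi, fm = mdl.flip_pair(img, mask)
        col = lambda m: np.average(np.nonzero(m)[1])
        assert col(fm) == pytest.approx(31 - col(mask))
        np.testing.assert_array_equal(fi > 0, fm > 0)

    def test_four_quarter_rotations_are_identity(self):
        img, mask = self._blob()
        ri, rm = img, mask
        for _ in range(4):
            ri, rm = mdl.rotate_pair(ri, rm, 90)
        np.testing.assert_array_equal(ri, img)
        np.testing.assert_array_equal(rm, mask)

    def test_seeded_determinism(self):
        img, mask = self._blob()
        pol = mdl.AugmentPolicy(seed=5)
        a = mdl.augment(img, mask, pol)
        b = mdl.augment(img, mask, pol)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_photometric_touches_image_only(self):
        img, mask = self._blob()
        pol = mdl.AugmentPolicy(flip_lr=False, rotation_deg=0, zoom=1.0,
                                lighting=0.4, seed=3)
        ai, am = mdl.augment(img, mask, pol)
        np.testing.assert_array_equal(am, mask)
        assert not np.array_equal(ai, img)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mdl.augment(np.zeros((8, 8)), np.zeros((9, 9), np.uint8),
                        mdl.AugmentPolicy())


class TestPredict:
    def test_labels_in_range_and_source_geometry(self, rng):
        net = mdl.SegNet(channels=4, input_size=32, seed=0)
        img = rng.random((48, 56))
        mask = mdl.predict(net, img)
        assert mask.shape == (48, 56)
        assert set(np.unique(mask)) <= {0, 1, 2}

    def test_eval_determinism(self, rng):
        net = mdl.SegNet(channels=4, input_size=32, seed=1)
        img = rng.random((32, 32))
        np.testing.assert_array_equal(mdl.predict(net, img), mdl.predict(net, img))


class TestScheduleContract:
    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            mdl.TrainSchedule(frozen_epochs=7, checkpoint_every=10)
        with pytest.raises(ValueError):
            mdl.TrainSchedule(frozen_max_lr=0.0)

    def test_frozen_phase_leaves_body_bit_identical(self):
        train = phantom_frames(1, n_phantoms=1, size=32)
        net = mdl.SegNet(channels=4, input_size=32, seed=0)
        before = net.state_dict()
        sched = mdl.TrainSchedule(frozen_epochs=2, frozen_max_lr=1e-2,
                                  unfrozen_epochs=0, unfrozen_max_lr=1e-3,
                                  checkpoint_every=2, batch_size=4)
        best, records = mdl.train_transfer(net, train, train[:4], sched, seed=0)
        body = net.parameter_groups()["body"]
        for k in body:
            np.testing.assert_array_equal(best.params[k], before[k])
        assert not np.array_equal(best.params["wh"], before["wh"])

    def test_checkpoint_counts_and_selection(self):
        train = phantom_frames(2, n_phantoms=1, size=32)
        net = mdl.SegNet(channels=4, input_size=32, seed=0)
        sched = mdl.TrainSchedule(frozen_epochs=4, frozen_max_lr=1e-2,
                                  unfrozen_epochs=6, unfrozen_max_lr=3e-3,
                                  checkpoint_every=2, batch_size=4)
        best, records = mdl.train_transfer(net, train, train[:4], sched, seed=0)
        assert sum(r.phase == "frozen" for r in records) == 2
        assert sum(r.phase == "unfrozen" for r in records) == 3
        best_rec = max(records, key=lambda r: r.validation_dice)
        assert mdl.validation_dice(best, train[:4]) == \
            pytest.approx(best_rec.validation_dice)

    def test_run_directory_artifacts(self, tmp_path):
        import json
        train = phantom_frames(3, n_phantoms=1, size=32)
        net = mdl.SegNet(channels=4, input_size=32, seed=0)
        sched = mdl.TrainSchedule(frozen_epochs=2, frozen_max_lr=1e-2,
                                  unfrozen_epochs=2, unfrozen_max_lr=3e-3,
                                  checkpoint_every=2, batch_size=4)
        mdl.train_transfer(net, train, train[:4], sched, seed=0,
                           run_dir=tmp_path / "run")
        manifest = json.loads((tmp_path / "run" / "manifest.json").read_text())
        assert len(manifest) == 2
        assert sum(m["selected"] for m in manifest) == 1
        assert (tmp_path / "run" / "training_log.csv").exists()

    def test_empty_sets_rejected(self):
        net = mdl.SegNet(channels=4, input_size=32, seed=0)
        with pytest.raises(ValueError):
            mdl.train_transfer(net, [], [], mdl.TrainSchedule())


class TestLearning:
    def test_one_cycle_capped_at_max(self):
        lrs = [mdl.one_cycle_lr(s, 100, 1e-2) for s in range(100)]
        assert max(lrs) <= 1e-2 + 1e-12
        assert lrs[0] < max(lrs)

    def test_training_improves_validation_dice(self):
        train = phantom_frames(4, n_phantoms=2, size=48)
        val = phantom_frames(5, n_phantoms=1, size=48)
        net = mdl.SegNet(channels=6, input_size=48, seed=0)
        baseline = mdl.validation_dice(net, val)
        sched = mdl.TrainSchedule(frozen_epochs=5, frozen_max_lr=1e-2,
                                  unfrozen_epochs=10, unfrozen_max_lr=1e-2,
                                  checkpoint_every=5, batch_size=8)
        best, _ = mdl.train_transfer(net, train, val, sched, seed=0)
        assert mdl.validation_dice(best, val) > baseline

    def test_soft_dice_gradient_matches_finite_differences(self, rng):
        net = mdl.SegNet(channels=3, input_size=8, seed=0)
        x = rng.random((2, 8, 8))
        y = rng.integers(0, 3, (2, 8, 8))
        logits, cache = net.forward(x, want_cache=True)
        _, dlog = mdl.soft_dice_loss(logits, y)
        grads = net.backward(cache, dlog)
        eps = 1e-6
        for key in ("w1", "w3", "wh", "b2"):
            p = net.params[key]
            idx = tuple(0 for _ in p.shape)
            p[idx] += eps
            l1, _ = mdl.soft_dice_loss(net.forward(x), y)
            p[idx] -= 2 * eps
            l2, _ = mdl.soft_dice_loss(net.forward(x), y)
            p[idx] += eps
            num = (l1 - l2) / (2 * eps)
            assert grads[key][idx] == pytest.approx(num, rel=1e-4, abs=1e-9)
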