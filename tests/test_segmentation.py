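import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cascadeseg.errors import ContractError, DataError, EmptyMaskError
from cascadeseg.extent import ExtentInterval
from cascadeseg.metrics import dice
from cascadeseg.optim import OptimizerConfig
from cascadeseg.phantom import PhantomSpec, generate_cohort, generate_phantom
from cascadeseg.segmentation import (AugmentSpec, CropSpec, SegPrediction,
                                     VoxelSegmenter, center_of_mass,
                                     coarse_segment, fuse_2d3d, refine_segment,
                                     soft_dice_loss, train_segmenter)

from conftest import true_extent


class TestSoftDiceLoss:
    def test_identity_near_zero(self):
        t = np.zeros((4, 4, 4))
        t[1:3, 1:3, 1:3] = 1
        assert soft_dice_loss(t, t) < 0.06  # eps-limited

    def test_disjoint_near_one(self):
        t = np.zeros(100)
        t[:50] = 1
        assert soft_dice_loss(1 - t, t) > 0.98

    def test_closed_form_uniform_half(self):
        # pred uniform 0.5 on N=8 voxels, target k=2 ones:
        # loss = 1 - (k + 1) / (N/2 + k + 1) = 4/7
        pred = np.full(8, 0.5)
        target = np.zeros(8)
        target[:2] = 1
        assert soft_dice_loss(pred, target) == pytest.approx(4.0 / 7.0, rel=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ContractError):
            soft_dice_loss(np.zeros((2, 2)), np.zeros((2, 3)))

    def test_out_of_range_pred(self):
        with pytest.raises(ContractError):
            soft_dice_loss(np.array([1.5]), np.array([1.0]))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_bounds_and_dsc_relation(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(64)
        t = (rng.random(64) > 0.5).astype(float)
        loss = soft_dice_loss(p, t)
        assert 0.0 <= loss <= 1.0
        # on binary predictions, 1 - loss approaches DSC as eps -> 0
        pb = (p > 0.5).astype(float)
        loss_b = soft_dice_loss(pb, t, eps=1e-12)
        if pb.sum() + t.sum() > 0:
            dsc = 2 * (pb * t).sum() / (pb.sum() + t.sum())
            assert loss_b == pytest.approx(1.0 - dsc, abs=1e-9)


class TestCenterOfMass:
    def test_single_voxel(self):
        m = np.zeros((6, 6, 6))
        m[3, 4, 5] = 1
        assert center_of_mass(m) == (3, 4, 5)

    def test_two_voxels(self):
        m = np.zeros((4, 4, 4))
        m[0, 0, 0] = m[2, 0, 0] = 1
        assert center_of_mass(m) == (1, 0, 0)

    def test_random_blob_matches_enumeration(self):
        rng = np.random.default_rng(5)
        m = (rng.random((8, 8, 8)) > 0.7).astype(np.uint8)
        zs, ys, xs = np.nonzero(m)
        expected = tuple(int(np.floor(c.mean() + 0.5)) for c in (zs, ys, xs))
        assert center_of_mass(m) == expected

    def test_empty_mask(self):
        with pytest.raises(EmptyMaskError):
            center_of_mass(np.zeros((3, 3, 3)))


class TestFusion:
    def _pred(self, mask):
        return SegPrediction(structure="s", mask=mask, stage="coarse")

    def test_idempotent(self):
        m = (np.random.default_rng(0).random((5, 5, 5)) > 0.5).astype(np.uint8)
        fused = fuse_2d3d(self._pred(m), self._pred(m))
        np.testing.assert_array_equal(fused.mask, m)
        assert fused.stage == "fused_2d3d"

    def test_disjoint_volumes_add(self):
        a = np.zeros((4, 4, 4), dtype=np.uint8)
        b = np.zeros((4, 4, 4), dtype=np.uint8)
        a[0], b[2] = 1, 1
        fused = fuse_2d3d(self._pred(a), self._pred(b))
        assert fused.mask.sum() == a.sum() + b.sum()

    def test_commutative(self):
        rng = np.random.default_rng(1)
        a = (rng.random((4, 4, 4)) > 0.5).astype(np.uint8)
        b = (rng.random((4, 4, 4)) > 0.5).astype(np.uint8)
        np.testing.assert_array_equal(fuse_2d3d(self._pred(a), self._pred(b)).mask,
                                      fuse_2d3d(self._pred(b), self._pred(a)).mask)

    def test_recall_never_decreases(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            a = (rng.random((6, 6, 6)) > 0.6).astype(np.uint8)
            b = (rng.random((6, 6, 6)) > 0.6).astype(np.uint8)
            gt = (rng.random((6, 6, 6)) > 0.6).astype(np.uint8)
            if gt.sum() == 0:
                continue
            fused = fuse_2d3d(self._pred(a), self._pred(b)).mask
            rec = lambda m: (m & gt).sum() / gt.sum()
            assert rec(fused) >= max(rec(a), rec(b)) - 1e-12

    def test_grid_mismatch(self):
        with pytest.raises(ContractError):
            fuse_2d3d(self._pred(np.zeros((2, 2, 2), dtype=np.uint8)),
                      self._pred(np.zeros((3, 3, 3), dtype=np.uint8)))


class _ExactIntensityOracle(VoxelSegmenter):
    """Refine-stage oracle: recovers the structure by its exact noiseless HU."""

    def __init__(self, structure, value):
        super().__init__([structure], "3d")
        self.value = value

    def predict_mask(self, data, intensity_kind="preprocessed", extent=None,
                     structure=None, threshold=0.5):
        return (np.abs(np.asarray(data) - self.value) < 1e-6).astype(np.uint8)


class TestRefine:
    def test_oracle_model_recovers_truth(self, noiseless_phantom):
        spec, (vol, sset) = noiseless_phantom
        gt = sset.masks["bladder"]
        coarse = SegPrediction("bladder", gt, "coarse")
        oracle = _ExactIntensityOracle("bladder", 80.0 + 1000.0)
        refined = refine_segment(coarse, vol, oracle,
                                 CropSpec(center=None, box_shape=(20, 30, 30)))
        assert refined.stage == "refined"
        assert dice(refined.mask, gt) == 1.0

    def test_zero_outside_crop_box(self, noiseless_phantom):
        spec, (vol, sset) = noiseless_phantom
        coarse = SegPrediction("bladder", sset.masks["bladder"], "coarse")
        box = (6, 8, 8)
        refined = refine_segment(coarse, vol, _ExactIntensityOracle("bladder", 1080.0),
                                 CropSpec(center=None, box_shape=box))
        zc, yc, xc = center_of_mass(coarse.mask)
        outside = refined.mask.copy()
        outside[max(zc - 3, 0): zc + 3, max(yc - 4, 0): yc + 4,
                max(xc - 4, 0): xc + 4] = 0
        assert outside.sum() == 0

    def test_edge_center_clamps_box(self, noiseless_phantom):
        spec, (vol, sset) = noiseless_phantom
        m = np.zeros(vol.shape, dtype=np.uint8)
        m[0, 0, 0] = 1
        coarse = SegPrediction("bladder", m, "coarse")
        refined = refine_segment(coarse, vol, _ExactIntensityOracle("bladder", 1080.0),
                                 CropSpec(center=None, box_shape=(8, 8, 8)))
        assert refined.mask.shape == vol.shape

    def test_empty_coarse_falls_back_with_warning(self, noiseless_phantom):
        spec, (vol, _) = noiseless_phantom
        coarse = SegPrediction("bladder", np.zeros(vol.shape, dtype=np.uint8), "coarse")
        with pytest.warns(UserWarning):
            out = refine_segment(coarse, vol, _ExactIntensityOracle("bladder", 1080.0),
                                 CropSpec(center=None, box_shape=(8, 8, 8)))
        assert out is coarse


class TestTrainedCascade:
    def test_training_dsc(self, small_cohort, bladder_extents, trained_bladder):
        dscs = []
        for vol, sset in small_cohort:
            pred = coarse_segment(trained_bladder["coarse"], vol,
                                  bladder_extents[sset.volume_id], (24, 24))
            dscs.append(dice(pred.mask, sset.masks["bladder"]))
        assert np.mean(dscs) >= 0.8

    def test_refine_does_not_degrade(self, small_cohort, bladder_extents,
                                     trained_bladder):
        coarse_d, refine_d = [], []
        for vol, sset in small_cohort:
            pred = coarse_segment(trained_bladder["coarse"], vol,
                                  bladder_extents[sset.volume_id], (24, 24))
            coarse_d.append(dice(pred.mask, sset.masks["bladder"]))
            refined = refine_segment(pred, vol, trained_bladder["refine"],
                                     CropSpec(center=None,
                                              box_shape=trained_bladder["box"]))
            refine_d.append(dice(refined.mask, sset.masks["bladder"]))
        assert np.median(refine_d) >= np.median(coarse_d) - 0.01

    def test_coarse_centroid_near_truth(self, small_cohort, bladder_extents,
                                        trained_bladder):
        vol, sset = small_cohort[0]
        pred = coarse_segment(trained_bladder["coarse"], vol,
                              bladder_extents[sset.volume_id], (24, 24))
        assert pred.mask.any()
        got = np.array(center_of_mass(pred.mask))
        want = np.array(center_of_mass(sset.masks["bladder"]))
        assert np.all(np.abs(got - want) <= 2)

    def test_native_coarse_equals_direct(self, small_cohort, bladder_extents):
        opt = OptimizerConfig(learning_rate=0.1, epochs=6, seed=1)
        model = train_segmenter(small_cohort[:3], "bladder", "3d", opt,
                                AugmentSpec(hflip=False, rotation_range=(0, 0)),
                                extents=bladder_extents)
        vol, sset = small_cohort[0]
        ext = bladder_extents[sset.volume_id]
        direct = model.predict_mask(vol.data, vol.intensity_kind, ext)
        via_coarse = coarse_segment(model, vol, ext, coarse_shape=None)
        np.testing.assert_array_equal(via_coarse.mask, direct)

    def test_invalid_extent_rejected(self, small_cohort, trained_bladder):
        vol, _ = small_cohort[0]
        with pytest.raises(ContractError):
            coarse_segment(trained_bladder["coarse"], vol, None, (24, 24))
        with pytest.raises(ContractError):
            coarse_segment(trained_bladder["coarse"], vol,
                           ExtentInterval(0, vol.n_slices + 5), (24, 24))


@pytest.fixture(scope="module")
def vertebra_model():
    from cascadeseg.extent import pad_extent
    cohort = generate_cohort(PhantomSpec(grid_shape=(32, 48, 48)), n=4, seed=21)
    extents = {}
    for vol, sset in cohort:
        union = sset.masks["vertebra_l4"] | sset.masks["vertebra_l5"]
        zs = np.flatnonzero(union.any(axis=(1, 2)))
        extents[sset.volume_id] = pad_extent(
            ExtentInterval(int(zs.min()), int(zs.max())), vol.n_slices, 1)
    opt = OptimizerConfig(learning_rate=0.1, epochs=60, seed=2)
    model = train_segmenter(cohort, ["vertebra_l4", "vertebra_l5"], "3d", opt,
                            AugmentSpec(), extents=extents)
    return cohort, model, extents


class TestMultiLabel:
    def test_two_channels(self, vertebra_model):
        _, model, _ = vertebra_model
        assert model.structures == ["vertebra_l4", "vertebra_l5"]
        assert model.W.shape[1] == 2

    def test_argmax_assigns_blocks_disjointly(self, vertebra_model):
        cohort, model, extents = vertebra_model
        vol, sset = cohort[0]
        masks = model.predict_multilabel(vol.data, vol.intensity_kind,
                                         extents[sset.volume_id])
        overlap = masks["vertebra_l4"] & masks["vertebra_l5"]
        assert overlap.sum() == 0
        for name in ("vertebra_l4", "vertebra_l5"):
            assert dice(masks[name], sset.masks[name]) > 0.5, name


class TestTrainingContracts:
    def test_structure_missing_everywhere(self, small_cohort):
        opt = OptimizerConfig(epochs=2)
        with pytest.raises(DataError):
            train_segmenter(small_cohort, "gallbladder", "3d", opt)

    def test_augmentation_changes_stream(self):
        cohort = generate_cohort(PhantomSpec(grid_shape=(24, 32, 32)), n=2, seed=3)
        opt = OptimizerConfig(learning_rate=0.1, epochs=3, seed=4)
        plain = train_segmenter(cohort, "bladder", "3d", opt,
                                AugmentSpec(hflip=False, rotation_range=(0, 0)))
        rotated = train_segmenter(cohort, "bladder", "3d", opt,
                                  AugmentSpec(hflip=False, rotation_range=(-30, 30)))
        assert plain.stream_digest_ != rotated.stream_digest_

    def test_fixed_seed_reproducible(self):
        cohort = generate_cohort(PhantomSpec(grid_shape=(24, 32, 32)), n=2, seed=3)
        opt = OptimizerConfig(learning_rate=0.1, epochs=4, seed=7)
        m1 = train_segmenter(cohort, "bladder", "3d", opt, AugmentSpec())
        m2 = train_segmenter(cohort, "bladder", "3d", opt, AugmentSpec())
        np.testing.assert_array_equal(m1.W, m2.W)
        vol, _ = cohort[0]
        np.testing.assert_array_equal(m1.predict_mask(vol.data, vol.intensity_kind),
                                      m2.predict_mask(vol.data, vol.intensity_kind))

    def test_optimizer_config_validation(self):
        with pytest.raises(ContractError):
            OptimizerConfig(beta1=1.0)
        with pytest.raises(ContractError):
            OptimizerConfig(epsilon=0.0)
        cfg = OptimizerConfig()
        assert (cfg.beta1, cfg.beta2, cfg.epsilon) == (0.9, 0.999, 1e-8)

    def test_checkpoint_round_trip(self, trained_bladder, small_cohort):
        model = trained_bladder["coarse"]
        clone = VoxelSegmenter.from_params(model.get_params())
        vol, _ = small_cohort[0]
        np.testing.assert_array_equal(
            clone.predict_mask(vol.data, vol.intensity_kind),
            model.predict_mask(vol.data, vol.intensity_kind))
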