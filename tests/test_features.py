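import numpy as np
import pytest

from srcstroke import (
    AsymmetryMap,
    DWStudy,
    PatchConfig,
    ValidationError,
    extract_features,
    select_training_samples,
)


def toy_study(shape=(12, 12, 5), fill=None):
    vols = {}
    for i, c in enumerate(("b0", "dwi", "adc")):
        vols[c] = np.full(shape, float(fill[i])) if fill else np.arange(
            np.prod(shape), dtype=float
        ).reshape(shape) * (i + 1)
    return DWStudy(**vols, brain_mask=np.ones(shape, dtype=np.uint8))


def toy_asym(shape=(12, 12, 5), value=0.0):
    return AsymmetryMap(asym=np.full(shape, float(value)))


class TestPatchConfig:
    @pytest.mark.parametrize(
        "mode,expected", [("2d", 36), ("3d", 108)]
    )
    def test_feature_length_four_channels(self, mode, expected):
        cfg = PatchConfig(radius=1, mode=mode)
        assert cfg.feature_length == expected

    def test_invalid_radius(self):
        with pytest.raises(ValidationError):
            PatchConfig(radius=0)


class TestExtractFeatures:
    def test_layout_channel_blocks(self):
        study = toy_study(fill=(1.0, 2.0, 3.0))
        asym = toy_asym(value=4.0)
        cfg = PatchConfig(radius=1, mode="2d")
        f = extract_features(study, asym, [(5, 5, 2)], cfg)[0]
        expected = np.repeat([1.0, 2.0, 3.0, 4.0], 9)
        np.testing.assert_allclose(f, expected)

    def test_border_replication(self):
        study = toy_study(fill=(7.0, 7.0, 7.0))
        asym = toy_asym(value=7.0)
        cfg = PatchConfig(radius=1, mode="2d")
        corner = extract_features(study, asym, [(0, 0, 0)], cfg)[0]
        assert (corner == 7.0).all()

    def test_translation_consistency(self, rng):
        shape = (16, 16, 4)
        vols = [rng.uniform(0, 255, shape) for _ in range(4)]
        cfg = PatchConfig(radius=1, mode="3d")

        def study_at(shift):
            rolled = [np.roll(v, shift, axis=0) for v in vols]
            s = DWStudy(b0=rolled[0], dwi=rolled[1], adc=rolled[2])
            return s, AsymmetryMap(asym=np.abs(rolled[3]))

        s0, a0 = study_at(0)
        s1, a1 = study_at(3)
        f0 = extract_features(s0, a0, [(6, 7, 2)], cfg)
        f1 = extract_features(s1, a1, [(9, 7, 2)], cfg)
        np.testing.assert_allclose(f0, f1)

    def test_out_of_volume_voxel_rejected(self):
        study = toy_study()
        with pytest.raises(ValidationError, match="outside"):
            extract_features(study, toy_asym(), [(20, 0, 0)], PatchConfig())


def brute_force_boundary_negatives(gt, brain):
    """Oracle: iterate 6-connected dilation until new voxels >= |GT|."""
    from scipy import ndimage

    struct = ndimage.generate_binary_structure(3, 1)
    cur = gt.copy()
    while True:
        cur = ndimage.binary_dilation(cur, structure=struct)
        ring = cur & brain & ~gt
        if ring.sum() >= gt.sum():
            return ring


class TestTrainingSamples:
    def _setup(self, shape=(20, 20, 3)):
        gt = np.zeros(shape, dtype=bool)
        gt[8:10, 9:14, 1] = True  # 10 voxels
        brain = np.ones(shape, dtype=bool)
        study = toy_study(shape, fill=(1.0, 2.0, 3.0))
        return gt, brain, study, toy_asym(shape)

    def test_boundary_scheme_balanced_and_adjacent(self):
        gt, brain, study, asym = self._setup()
        ss = select_training_samples(gt, brain, study, asym, PatchConfig())
        assert ss.positives.shape[0] == 10
        assert ss.negatives.shape[0] >= 10
        want = brute_force_boundary_negatives(gt, brain)
        got = np.zeros_like(gt)
        got[tuple(ss.negative_voxels.T)] = True
        np.testing.assert_array_equal(got, want)

    def test_minimal_dilation_count(self):
        gt, brain, study, asym = self._setup()
        ss = select_training_samples(gt, brain, study, asym, PatchConfig())
        # one fewer dilation step must under-fill the balance condition
        from scipy import ndimage

        struct = ndimage.generate_binary_structure(3, 1)
        one_step = ndimage.binary_dilation(gt, structure=struct) & brain & ~gt
        assert one_step.sum() >= gt.sum()  # first step suffices here
        assert ss.negatives.shape[0] == one_step.sum()

    def test_random_provenance(self, rng):
        gt, brain, study, asym = self._setup()
        ss = select_training_samples(
            gt, brain, study, asym, PatchConfig(), provenance="random", rng=rng
        )
        assert ss.provenance == "random"
        assert ss.negatives.shape[0] == ss.positives.shape[0]
        neg = np.zeros_like(gt)
        neg[tuple(ss.negative_voxels.T)] = True
        assert not (neg & gt).any()

    def test_empty_gt_rejected(self):
        gt, brain, study, asym = self._setup()
        with pytest.raises(ValidationError):
            select_training_samples(
                np.zeros_like(gt), brain, study, asym, PatchConfig()
            )

    def test_gt_filling_brain_rejected(self):
        shape = (6, 6, 2)
        gt = np.ones(shape, dtype=bool)
        study = toy_study(shape, fill=(1.0, 1.0, 1.0))
        with pytest.raises(ValidationError, match="no negatives"):
            select_training_samples(gt, gt.copy(), study, toy_asym(shape), PatchConfig())

    def test_extra_global_negatives_double_count(self, rng):
        gt, brain, study, asym = self._setup()
        base = select_training_samples(gt, brain, study, asym, PatchConfig())
        extra = select_training_samples(
            gt, brain, study, asym, PatchConfig(), rng=rng, extra_global_negatives=True
        )
        assert extra.negatives.shape[0] == 2 * base.negatives.shape[0]
        assert extra.provenance == "boundary+global"
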