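"""Imaging arm: preprocessing, augmentation, radiomics, network mechanics."""

import numpy as np
import pandas as pd
import pytest

from seqprog.imaging import (FEATURE_COUNT, RadiomicsConfig, SUVParams,
                             UNEXtractor, UNEXtractorConfig, UNet3D,
                             UNetConfig, augment, extract_hcr, gini_select,
                             load_nifti, preprocess, save_nifti,
                             train_unextractor)
from seqprog.synthetic_cohort import PhantomConfig, generate_phantom

RNG = np.random.default_rng(11)


class TestPreprocess:
    def test_output_ranges_and_mask_dtype(self, phantom):
        ct, pet, mask = phantom
        ct01, pet01, mask01 = preprocess(ct, pet, mask, spacing=(2, 2, 2),
                                         target_spacing=2.0, crop_size_mm=48.0)
        for vol in (ct01, pet01):
            assert vol.min() >= 0.0 and vol.max() <= 1.0
        assert mask01.dtype == np.uint8
        assert set(np.unique(mask01)) <= {0, 1}
        assert ct01.shape == (24, 24, 24)

    def test_hu_below_clip_maps_to_zero(self):
        ct = np.full((8, 8, 8), -500.0)
        pet = np.zeros((8, 8, 8))
        mask = np.zeros((8, 8, 8), np.uint8)
        mask[3:5, 3:5, 3:5] = 1
        ct01, _, _ = preprocess(ct, pet, mask, spacing=(1, 1, 1),
                                crop_size_mm=8.0, suv=None)
        assert np.allclose(ct01, 0.0)

    def test_suv_factor_matches_hand_computation(self):
        params = SUVParams()   # 75 kg, 420 MBq, 105 min delay
        decayed = 420e6 * 2 ** (-105.0 / 109.77)
        expected = 75e3 / decayed
        assert params.factor() == pytest.approx(expected, rel=1e-12)
        # a known activity concentration converts exactly
        conc = 5000.0   # Bq/ml
        assert conc * params.factor() == pytest.approx(conc * expected)

    def test_second_application_is_identity(self, phantom):
        ct, pet, mask = phantom
        out1 = preprocess(ct, pet, mask, spacing=(2, 2, 2), target_spacing=2.0,
                          crop_size_mm=48.0)
        out2 = preprocess(*out1, spacing=(2, 2, 2), target_spacing=2.0,
                          crop_size_mm=48.0, suv=None,
                          ct_clip=(0, 1), pet_clip=(0, 1))
        for a, b in zip(out1, out2):
            assert np.allclose(a, b, atol=1e-6)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty mask"):
            preprocess(np.zeros((4, 4, 4)), np.zeros((4, 4, 4)),
                       np.zeros((4, 4, 4)))


class TestAugment:
    def _triple(self):
        ct = RNG.uniform(0, 1, (10, 10, 10))
        pet = RNG.uniform(0, 1, (10, 10, 10))
        mask = (RNG.uniform(size=(10, 10, 10)) > 0.7).astype(np.uint8)
        return ct, pet, mask

    def test_zero_probability_is_identity(self):
        ct, pet, mask = self._triple()
        ct2, pet2, mask2, applied = augment(ct, pet, mask, seed=0, p=0.0)
        assert np.array_equal(ct, ct2) and np.array_equal(pet, pet2)
        assert np.array_equal(mask, mask2)
        assert not any(applied.values())

    def test_flip_applied_twice_is_identity(self):
        ct, pet, mask = self._triple()
        assert np.array_equal(np.flip(np.flip(ct, 0), 0), ct)

    def test_transforms_act_identically_on_all_volumes(self):
        ct, pet, mask = self._triple()
        for seed in range(30):
            _, _, mask2, applied = augment(ct, pet, mask, seed=seed,
                                           noise_sd=0.0)
            if applied["flip"] and not applied["rotation"]:
                assert np.array_equal(mask2, np.flip(mask, 0))

    def test_intensities_clipped_after_noise(self):
        ct, pet, mask = self._triple()
        for seed in range(10):
            ct2, pet2, _, _ = augment(ct, pet, mask, seed=seed, noise_sd=0.5)
            assert ct2.min() >= 0.0 and ct2.max() <= 1.0
            assert pet2.min() >= 0.0 and pet2.max() <= 1.0

    def test_flip_frequency_is_one_half(self):
        small = np.zeros((2, 2, 2))
        m = np.zeros((2, 2, 2), np.uint8)
        flips = sum(augment(small, small, m, seed=s, noise_sd=0.0)[3]["flip"]
                    for s in range(10_000))
        assert abs(flips / 10_000 - 0.5) < 0.015


class TestRadiomics:
    @pytest.fixture(scope="class")
    def features(self, phantom):
        ct, pet, mask = phantom
        return extract_hcr(ct, pet, mask,
                           RadiomicsConfig(voxel_size_mm=(2, 2, 2)))

    def test_default_census_is_200(self, features):
        assert len(features) == FEATURE_COUNT == 200
        assert np.isfinite(features.to_numpy()).all()

    def test_family_decomposition(self, features):
        counts = {
            "shape": 14, "firstorder": 18, "glcm": 24, "glrlm": 16,
            "glszm": 16, "gldm": 14, "ngtdm": 5,
        }
        idx = features.index
        assert sum(idx.str.startswith("shape_")) == counts["shape"]
        for fam, k in counts.items():
            if fam == "shape":
                continue
            for mod in ("ct", "pet"):
                assert sum(idx.str.startswith(f"{mod}_{fam}_")) == k

    def test_constant_region_first_order_closed_forms(self):
        vol = np.full((12, 12, 12), 7.0)
        mask = np.zeros((12, 12, 12), np.uint8)
        mask[4:8, 4:8, 4:8] = 1
        f = extract_hcr(vol, vol, mask, RadiomicsConfig())
        n = 64
        assert f["ct_firstorder_Variance"] == 0.0
        assert f["ct_firstorder_Energy"] == pytest.approx(n * 49.0)
        assert f["ct_firstorder_Mean"] == 7.0

    def test_pet_mean_equals_masked_average(self, phantom, features):
        ct, pet, mask = phantom
        assert features["pet_firstorder_Mean"] == pytest.approx(
            pet[mask.astype(bool)].mean())

    def test_first_order_invariant_to_axial_flip(self, phantom):
        ct, pet, mask = phantom
        cfg = RadiomicsConfig(voxel_size_mm=(2, 2, 2))
        a = extract_hcr(ct, pet, mask, cfg)
        b = extract_hcr(np.flip(ct, 0), np.flip(pet, 0), np.flip(mask, 0), cfg)
        fo = [k for k in a.index if "_firstorder_" in k]
        assert np.allclose(a[fo], b[fo], rtol=1e-10)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty mask"):
            extract_hcr(np.zeros((4, 4, 4)), np.zeros((4, 4, 4)),
                        np.zeros((4, 4, 4)))


class TestGiniSelect:
    def _table(self, seed, n=150, informative=3, total=20):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, total))
        logits = X[:, :informative] @ np.full(informative, 2.0)
        y = (logits + 0.3 * rng.normal(size=n) > 0).astype(int)
        cols = [f"f{i}" for i in range(total)]
        return pd.DataFrame(X, columns=cols), y

    def test_returns_k_features_and_normalized_importances(self):
        X, y = self._table(0)
        names, imp = gini_select(X, y, k=6, n_trees=300, seed=0)
        assert len(names) == 6
        assert imp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_planted_signal_recovered(self):
        hits = 0
        for seed in range(20):
            X, y = self._table(seed)
            names, _ = gini_select(X, y, k=6, n_trees=300, seed=seed)
            hits += {"f0", "f1", "f2"} <= set(names)
        assert hits >= 19

    def test_single_class_raises(self):
        X, _ = self._table(1)
        with pytest.raises(ValueError, match="both classes"):
            gini_select(X, np.ones(len(X)), k=6, n_trees=10)


class TestNetworksMechanics:
    def test_unet_output_shape_and_probability_range(self):
        model = UNet3D(UNetConfig(channels=(4, 8, 16)), seed=0)
        x = RNG.uniform(0, 1, (2, 16, 16, 16))
        probs = model.forward(x).data
        assert probs.shape == (2, 16, 16, 16)
        assert probs.min() >= 0.0 and probs.max() <= 1.0

    def test_indivisible_shape_raises(self):
        model = UNet3D(UNetConfig(channels=(4, 8, 16)), seed=0)
        with pytest.raises(ValueError, match="divisible"):
            model.forward(RNG.uniform(size=(1, 10, 10, 10)))

    def test_untrained_dsc_is_near_chance(self, phantom):
        from seqprog.metrics import dice_similarity
        from seqprog.survival_core import voxel_classify

        ct, _, mask = phantom
        model = UNet3D(UNetConfig(), seed=0)
        probs = model.forward((np.clip(ct, -200, 250) + 200) / 450.0).data[0]
        dsc = dice_similarity(voxel_classify(np.clip(probs, 0, 1)), mask)
        assert dsc < 0.5

    def test_unextractor_default_dlr_width_is_six(self):
        cfg = UNEXtractorConfig()
        assert cfg.dlr_width == 6
        assert cfg.pooled_width == 8 + 16 + 32 == 56

    def test_unextractor_outputs(self):
        model = UNEXtractor(UNEXtractorConfig(channels=(4, 8, 16)), seed=0)
        x = RNG.uniform(0, 1, (2, 2, 16, 16, 16))
        seg, dlr, q = model.forward(x)
        assert seg.shape == (2, 16, 16, 16)
        assert dlr.shape == (2, 6)
        assert q.shape == (2,)

    def test_tap_level_out_of_range_raises(self):
        with pytest.raises(ValueError, match="tap level"):
            UNEXtractor(UNEXtractorConfig(channels=(4, 8), tap_levels=(0, 5)))

    def test_pooled_vector_invariant_to_spatial_shuffle_of_constant_input(self):
        model = UNEXtractor(UNEXtractorConfig(channels=(4, 8, 16)), seed=0)
        x = np.full((1, 2, 16, 16, 16), 0.4, dtype=np.float32)
        _, dlr1, _ = model.forward(x)
        # constant input is trivially invariant to any spatial permutation
        perm = x.reshape(1, 2, -1)[:, :, RNG.permutation(16 ** 3)].reshape(x.shape)
        _, dlr2, _ = model.forward(perm)
        assert np.allclose(dlr1.data, dlr2.data, atol=1e-6)

    def test_seed_replay_reproduces_loss_trajectory(self):
        vols = RNG.uniform(0, 1, (6, 2, 8, 8, 8)).astype(np.float32)
        masks = (RNG.uniform(size=(6, 8, 8, 8)) > 0.8).astype(np.float32)
        labels = np.array([0, 1, 0, 1, 0, 1])
        logs = []
        for _ in range(2):
            model = UNEXtractor(UNEXtractorConfig(channels=(4, 8),
                                                  tap_levels=(0, 1)), seed=4)
            logs.append(train_unextractor(model, vols, masks, labels,
                                          epochs=3, batch_size=3, seed=4))
        assert logs[0] == logs[1]

    def test_joint_training_learns_a_pet_encoded_label(self):
        """Phantoms whose PET uptake encodes the label are classified
        well above chance after brief joint training (scaled-down run)."""
        from seqprog.metrics import auroc

        def make(n, seed):
            rng = np.random.default_rng(seed)
            vols, masks, labels = [], [], []
            for i in range(n):
                z = float(rng.normal())
                cfg = PhantomConfig(seed=seed * 500 + i, aggressiveness=z,
                                    grid_shape=(16, 16, 16),
                                    center_mm=tuple(rng.uniform(13, 19, 3)),
                                    semi_axes_mm=tuple(rng.uniform(5, 8, 3)))
                ct, pet, mask = generate_phantom(cfg)
                vols.append(np.stack([(np.clip(ct, -200, 250) + 200) / 450.0,
                                      np.clip(pet / 6.0, 0, 1)]))
                masks.append(mask)
                labels.append(int(z > 0))
            return (np.stack(vols), np.stack(masks).astype(np.float32),
                    np.array(labels))

        Xtr, Mtr, ytr = make(60, 1)
        Xte, _, yte = make(30, 2)
        model = UNEXtractor(UNEXtractorConfig(channels=(4, 8, 16)), seed=0)
        train_unextractor(model, Xtr, Mtr, ytr, epochs=8, batch_size=6,
                          seed=0, lambda_seg=1.0)
        _, _, q = model.forward(Xte)
        assert auroc(q.data, yte) > 0.8

    def test_lambda_zero_reduces_to_pure_prognostic_training(self):
        vols = RNG.uniform(0, 1, (4, 2, 8, 8, 8)).astype(np.float32)
        masks = (RNG.uniform(size=(4, 8, 8, 8)) > 0.8).astype(np.float32)
        labels = np.array([0, 1, 0, 1])
        model = UNEXtractor(UNEXtractorConfig(channels=(4, 8),
                                              tap_levels=(0, 1)), seed=1)
        log = train_unextractor(model, vols, masks, labels, lambda_seg=0.0,
                                epochs=2, batch_size=2, seed=1)
        assert np.isfinite(log).all()


def test_nifti_round_trip(tmp_path, phantom):
    ct, _, mask = phantom
    save_nifti(tmp_path / "ct.nii.gz", ct.astype(np.float32), 2.0)
    save_nifti(tmp_path / "mask.nii.gz", mask, 2.0)
    ct2, vs = load_nifti(tmp_path / "ct.nii.gz")
    mask2, _ = load_nifti(tmp_path / "mask.nii.gz")
    assert vs == 2.0
    assert np.allclose(ct2, ct.astype(np.float32))
    assert np.array_equal(mask2, mask)
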