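"""Pixel-wise mixup and the few-shot harness."""

import numpy as np
import pytest

import gafsense as gs
from gafsense.augmentation import SUPPORTED_RATIOS
from gafsense.errors import InvalidArgumentError, ProtocolError

from .conftest import make_image


def flat_image(value, res=32):
    return make_image(np.full((res, res, 3), value))


class TestMixImages:
    def test_weighted_pixel_arithmetic(self):
        out = gs.mix_images(flat_image(100), flat_image(50), a=0.8, primary_class="a", donor_class="b")
        assert (out.pixels == 90).all()
        assert out.parent_class == "a" and out.a_used == 0.8

    def test_identical_parents_reproduce_primary(self, rng):
        px = rng.integers(0, 256, size=(32, 32, 3))
        out = gs.mix_images(make_image(px), make_image(px.copy()), a=0.77)
        np.testing.assert_array_equal(out.pixels, px)

    @pytest.mark.parametrize("a", SUPPORTED_RATIOS)
    def test_standard_ratio_grid_accepted(self, a):
        out = gs.mix_images(flat_image(200), flat_image(0), a=a, primary_class="x", donor_class="y")
        assert out.pixels[0, 0, 0] == round(a * 200)

    @pytest.mark.parametrize("a", [0.5, 1.0, 0.2, 1.3])
    def test_invalid_weight_rejected(self, a):
        with pytest.raises(InvalidArgumentError):
            gs.mix_images(flat_image(1), flat_image(2), a=a)

    def test_same_class_pair_rejected(self):
        with pytest.raises(InvalidArgumentError):
            gs.mix_images(flat_image(1), flat_image(2), a=0.8, primary_class="a", donor_class="a")

    def test_shape_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            gs.mix_images(flat_image(1, 32), flat_image(2, 64), a=0.8)

    def test_output_bounded_by_parents(self, rng):
        p = make_image(rng.integers(0, 256, size=(32, 32, 3)))
        d = make_image(rng.integers(0, 256, size=(32, 32, 3)))
        out = gs.mix_images(p, d, a=0.75, primary_class="a", donor_class="b")
        lo = np.minimum(p.pixels, d.pixels)
        hi = np.maximum(p.pixels, d.pixels)
        assert (out.pixels >= lo).all() and (out.pixels <= hi).all()


@pytest.fixture
def three_shot_images(rng):
    images, labels = [], []
    for c in range(4):
        for _ in range(3):
            images.append(make_image(rng.integers(0, 256, size=(32, 32, 3))))
            labels.append(f"class_{c}")
    return images, np.array(labels, dtype=object)


class TestAugmentTrainingSet:
    def test_tops_up_every_class_to_target(self, three_shot_images):
        images, labels = three_shot_images
        out_imgs, out_labels, prov = gs.augment_training_set(
            images, labels, gs.MixSpec(a=0.85, target_per_class=50, seed=0)
        )
        classes, counts = np.unique(out_labels, return_counts=True)
        assert set(counts) == {50}
        assert len(prov) == 4 * 47  # 47 synthetic per class on 3 real shots
        assert len(out_imgs) == 200

    def test_real_images_pass_through_untouched(self, three_shot_images):
        images, labels = three_shot_images
        out_imgs, out_labels, _ = gs.augment_training_set(images, labels, gs.MixSpec(seed=0))
        for orig, out in zip(images, out_imgs):
            assert out is orig
        np.testing.assert_array_equal(out_labels[: len(labels)], labels)

    def test_target_equal_to_real_count_adds_nothing(self, three_shot_images):
        images, labels = three_shot_images
        out_imgs, _, prov = gs.augment_training_set(
            images, labels, gs.MixSpec(target_per_class=3, seed=0)
        )
        assert len(out_imgs) == len(images) and prov == []

    def test_deterministic_in_seed(self, three_shot_images):
        images, labels = three_shot_images
        a_imgs, _, a_prov = gs.augment_training_set(images, labels, gs.MixSpec(seed=5))
        b_imgs, _, b_prov = gs.augment_training_set(images, labels, gs.MixSpec(seed=5))
        assert a_prov == b_prov
        for x, y in zip(a_imgs, b_imgs):
            np.testing.assert_array_equal(x.pixels, y.pixels)

    def test_synthetic_labels_follow_primary_not_donor(self, three_shot_images):
        images, labels = three_shot_images
        out_imgs, out_labels, prov = gs.augment_training_set(images, labels, gs.MixSpec(seed=1))
        for img, lab, rec in zip(out_imgs[len(images) :], out_labels[len(images) :], prov):
            assert isinstance(img, gs.SyntheticImage)
            assert str(lab) == img.parent_class == rec["parent_class"]
            assert img.donor_class != img.parent_class

    def test_single_class_rejected(self, rng):
        imgs = [make_image(rng.integers(0, 256, size=(32, 32, 3))) for _ in range(3)]
        with pytest.raises(InvalidArgumentError):
            gs.augment_training_set(imgs, ["a", "a", "a"], gs.MixSpec(seed=0))

    def test_invalid_mix_spec_rejected(self):
        with pytest.raises(InvalidArgumentError):
            gs.MixSpec(a=0.4).validate()


@pytest.fixture(scope="module")
def result(wine_dataset):
    return gs.fewshot_experiment(
        wine_dataset, head="LDA", k_shots=3, reps=6, seed=2,
        spec=gs.MixSpec(a=0.85, seed=2),
    )


class TestFewShot:
    def test_paired_reports_share_splits(self, result):
        assert result.plain.seeds == result.augmented.seeds
        assert len(result.plain.accuracies) == len(result.augmented.accuracies) == 6

    def test_test_pool_excludes_training_shots(self, result):
        # 70 recordings, 21 shots -> 49 test predictions per repetition
        assert result.plain.confusion.sum() == 6 * 49
        assert result.augmented.confusion.sum() == 6 * 49

    def test_augmentation_does_not_hurt_on_clean_data(self, result):
        diff = result.augmented.mean_accuracy - result.plain.mean_accuracy
        assert diff >= -0.01

    def test_p_value_is_probability(self, result):
        assert 0.0 <= result.p_value <= 1.0

    def test_excessive_shots_rejected(self, wine_dataset):
        with pytest.raises(ProtocolError):
            gs.fewshot_experiment(wine_dataset, k_shots=10, reps=1)
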