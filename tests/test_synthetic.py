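"""Synthetic dataset generator, stratified splitting and image-folder I/O."""

import numpy as np
import pytest

from purecl.exceptions import ConfigError, DataError
from purecl.synthetic import (LabeledImage, LesionParams, SyntheticDatasetSpec,
                              default_lesion_params, generate_synthetic_dataset,
                              read_image_folder, scale_class_separation,
                              stratified_split, write_image_folder)


def _spec(**kw):
    base = dict(n_classes=3, n_per_class=10, image_size=(64, 64), seed=7)
    base.update(kw)
    return SyntheticDatasetSpec(**base)


class TestGenerator:
    def test_counts_labels_and_pixel_domain(self):
        images = generate_synthetic_dataset(_spec(n_per_class=100))
        assert len(images) == 300
        labels = np.array([im.label for im in images])
        assert [int((labels == k).sum()) for k in range(3)] == [100, 100, 100]
        for im in images[::37]:
            im.validate(n_classes=3)
            assert im.pixels.shape == (3, 64, 64)
            assert im.pixels.dtype == np.float32

    def test_bit_identical_given_same_seed(self):
        a = generate_synthetic_dataset(_spec())
        b = generate_synthetic_dataset(_spec())
        for x, y in zip(a, b):
            assert x.id == y.id and x.label == y.label
            np.testing.assert_array_equal(x.pixels, y.pixels)
        c = generate_synthetic_dataset(_spec(seed=8))
        assert any(not np.array_equal(x.pixels, y.pixels) for x, y in zip(a, c))

    def test_jitter_increases_intra_class_variance(self):
        def mean_intra_mse(images):
            per_class = []
            for k in {im.label for im in images}:
                group = np.stack([im.pixels for im in images if im.label == k])
                centroid = group.mean(axis=0)
                per_class.append(((group - centroid) ** 2).mean())
            return float(np.mean(per_class))

        calm = mean_intra_mse(generate_synthetic_dataset(
            _spec(intra_class_jitter=0.0, background_clutter=0.0)))
        noisy = mean_intra_mse(generate_synthetic_dataset(
            _spec(intra_class_jitter=0.5, background_clutter=0.0)))
        assert calm < noisy

    def test_separability_dial_is_monotone_for_nearest_centroid(self):
        def centroid_accuracy(spec):
            images = generate_synthetic_dataset(spec)
            x = np.stack([im.pixels.ravel() for im in images])
            y = np.array([im.label for im in images])
            centroids = np.stack([x[y == k].mean(axis=0) for k in range(spec.n_classes)])
            d = ((x[:, None, :] - centroids[None]) ** 2).sum(axis=2)
            return float((d.argmin(axis=1) == y).mean())

        accs = [centroid_accuracy(scale_class_separation(_spec(n_per_class=30), f))
                for f in (0.5, 1.0, 2.0)]
        assert accs[0] <= accs[1] <= accs[2]

    @pytest.mark.parametrize("bad,msg", [
        (dict(n_classes=1), "n_classes"),
        (dict(image_size=(16, 64)), "image_size"),
        (dict(background_clutter=1.5), "background_clutter"),
        (dict(intra_class_jitter=-0.1), "intra_class_jitter"),
    ])
    def test_invalid_spec_names_offending_field(self, bad, msg):
        with pytest.raises(ConfigError, match=msg):
            generate_synthetic_dataset(_spec(**bad))

    def test_oversized_lesion_radius_rejected(self):
        lesions = (
            LesionParams((2, 3), (30.0, 40.0), (0.5, 0.3, 0.1)),
            LesionParams((2, 3), (2.0, 4.0), (0.7, 0.6, 0.1)),
        )
        with pytest.raises(ConfigError, match="spot_radius"):
            generate_synthetic_dataset(_spec(n_classes=2, lesion_params=lesions))


class TestSpecYaml:
    def test_roundtrip_preserves_spec_and_dataset(self, tmp_path):
        spec = _spec(n_per_class=4, background_clutter=0.3,
                     lesion_params=tuple(default_lesion_params(3)))
        spec.to_yaml(tmp_path / "spec.yaml")
        back = SyntheticDatasetSpec.from_yaml(tmp_path / "spec.yaml")
        assert back == spec
        a = generate_synthetic_dataset(spec)
        b = generate_synthetic_dataset(back)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.pixels, y.pixels)


class TestStratifiedSplit:
    def test_paper_ratio_split_sizes(self):
        images = generate_synthetic_dataset(_spec(n_per_class=100))
        split = stratified_split(images, (0.7, 0.2, 0.1), seed=0)
        assert (len(split.train), len(split.val), len(split.test)) == (210, 60, 30)
        for part, expect in zip(split, (70, 20, 10)):
            labels = np.array([im.label for im in part])
            for k in range(3):
                assert int((labels == k).sum()) == expect

    def test_partition_is_disjoint_and_exhaustive(self, small_dataset):
        split = stratified_split(small_dataset, (0.5, 0.25, 0.25), seed=3)
        ids = [im.id for part in split for im in part]
        assert sorted(ids) == sorted(im.id for im in small_dataset)
        assert len(set(ids)) == len(ids)

    def test_per_class_counts_within_one_of_exact_ratio(self, small_dataset):
        ratios = (0.6, 0.3, 0.1)
        split = stratified_split(small_dataset, ratios, seed=5)
        for part, r in zip(split, ratios):
            labels = np.array([im.label for im in part])
            for k in range(3):
                exact = r * 8
                assert abs(int((labels == k).sum()) - exact) <= 1

    def test_degenerate_all_train_ratio(self, small_dataset):
        split = stratified_split(small_dataset, (1.0, 0.0, 0.0), seed=0)
        assert len(split.train) == len(small_dataset)
        assert not split.val and not split.test

    def test_deterministic_given_seed(self, small_dataset):
        a = stratified_split(small_dataset, (0.7, 0.2, 0.1), seed=11)
        b = stratified_split(small_dataset, (0.7, 0.2, 0.1), seed=11)
        assert [im.id for im in a.train] == [im.id for im in b.train]
        assert [im.id for im in a.test] == [im.id for im in b.test]

    def test_small_class_and_bad_ratios_rejected(self, small_dataset):
        two = [im for im in small_dataset if im.label == 0][:2] + \
              [im for im in small_dataset if im.label == 1]
        with pytest.raises(DataError, match="class 0"):
            stratified_split(two, (0.7, 0.2, 0.1), seed=0)
        with pytest.raises(ConfigError, match="ratios"):
            stratified_split(small_dataset, (0.7, 0.2, 0.2), seed=0)


class TestImageFolderIO:
    def test_roundtrip_preserves_labels_and_quantized_pixels(self, tmp_path, small_dataset):
        subset = small_dataset[::4]
        write_image_folder(subset, tmp_path / "ds")
        back = read_image_folder(tmp_path / "ds")
        assert len(back) == len(subset)
        by_id = {im.id: im for im in subset}
        for im in back:
            src = by_id[im.id]
            assert im.label == src.label
            assert np.abs(im.pixels - src.pixels).max() <= 1.0 / 255.0 + 1e-7

    def test_lexicographic_directory_order_defines_labels(self, tmp_path):
        gen = np.random.default_rng(0)
        mk = lambda i, lab: LabeledImage(gen.random((3, 32, 32), dtype=np.float32), lab, f"i{i}")
        write_image_folder([mk(0, 0), mk(1, 1)], tmp_path / "ds", class_names=["b", "a"])
        back = read_image_folder(tmp_path / "ds")
        # directory "a" sorts first, so the image written under "b" gets label 1
        labels = {im.id: im.label for im in back}
        assert labels == {"i0": 1, "i1": 0}

    def test_constant_image_quantization_bound(self, tmp_path):
        im = LabeledImage(np.full((3, 32, 32), 0.5, dtype=np.float32), 0, "c")
        dummy = LabeledImage(np.zeros((3, 32, 32), dtype=np.float32), 1, "d")
        write_image_folder([im, dummy], tmp_path / "ds")
        back = {i.id: i for i in read_image_folder(tmp_path / "ds")}
        assert np.abs(back["c"].pixels - 0.5).max() <= 1.0 / 255.0

    def test_missing_and_invalid_inputs_raise(self, tmp_path):
        with pytest.raises(IOError):
            read_image_folder(tmp_path / "absent")
        (tmp_path / "empty").mkdir()
        with pytest.raises(IOError, match="no class"):
            read_image_folder(tmp_path / "empty")
        bad = tmp_path / "bad" / "cls"
        bad.mkdir(parents=True)
        (bad / "junk.png").write_text("not an image")
        with pytest.raises(IOError, match="junk.png"):
            read_image_folder(tmp_path / "bad")
        with pytest.raises(DataError):
            write_image_folder([], tmp_path / "out")
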