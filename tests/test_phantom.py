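"""Phantom generator: determinism, layer decomposition, planted biases."""
import numpy as np
import pytest
from scipy.stats import chi2_contingency

from cxrdebias.errors import EmptyDatasetError, InvalidProfileError, InvalidSpecError
from cxrdebias.image import RadiographImage
from cxrdebias.manifest import LABEL_NODULE, LABEL_NORMAL
from cxrdebias.phantom import (
    Ellipse,
    MARKER_COLS,
    MARKER_ROWS,
    PhantomSpec,
    SiteProfile,
    apply_site_bias,
    generate_dataset,
    generate_sample,
    sample_rng,
)


class TestGenerateSample:
    def test_same_spec_and_seed_is_bit_identical(self, default_spec):
        a = generate_sample(default_spec, LABEL_NODULE, sample_rng(default_spec, 3))
        b = generate_sample(default_spec, LABEL_NODULE, sample_rng(default_spec, 3))
        assert np.array_equal(a.image.pixels, b.image.pixels)
        assert a.nodule_centers == b.nodule_centers

    def test_zero_rib_amplitude_gives_zero_rib_layer(self):
        spec = PhantomSpec(seed=1, rib_amplitude=0.0)
        s = generate_sample(spec, LABEL_NORMAL, sample_rng(spec, 0))
        assert np.all(s.rib_layer == 0.0)

    def test_mask_area_matches_per_pixel_ellipse_oracle(self):
        """Rasterized mask equals brute-force per-pixel inclusion testing."""
        spec = PhantomSpec(
            image_size=256,
            lung_ellipses=(
                Ellipse((120.0, 80.0), (60.0, 40.0)),
                Ellipse((120.0, 176.0), (60.0, 40.0)),
            ),
        )
        mask = spec.true_mask()
        oracle = np.zeros((256, 256), dtype=bool)
        for r in range(256):
            for c in range(256):
                for (cr, cc), (a, b) in [
                    ((120.0, 80.0), (60.0, 40.0)),
                    ((120.0, 176.0), (60.0, 40.0)),
                ]:
                    if ((r - cr) / a) ** 2 + ((c - cc) / b) ** 2 <= 1.0:
                        oracle[r, c] = True
        assert np.array_equal(mask.pixels, oracle)
        assert mask.area == int(oracle.sum())

    def test_nodule_class_has_blob_and_centers_inside_mask(self, default_spec):
        s = generate_sample(default_spec, LABEL_NODULE, sample_rng(default_spec, 5))
        assert len(s.nodule_centers) >= 1
        assert s.nodule_layer.max() > 0
        for r, c in s.nodule_centers:
            assert s.true_mask.pixels[r, c]

    def test_non_nodule_class_has_no_blob(self, default_spec):
        s = generate_sample(default_spec, LABEL_NORMAL, sample_rng(default_spec, 5))
        assert s.nodule_centers == []
        assert np.all(s.nodule_layer == 0.0)

    def test_layer_decomposition_recovers_image(self, default_spec):
        """image = clip(base + ribs + nodule + marker) up to 8-bit rounding."""
        s = generate_sample(default_spec, LABEL_NODULE, sample_rng(default_spec, 7))
        assert np.abs(s.image_float() - s.composed_float()).max() <= 1.0 / 255.0
        rib_free = s.image_float() - s.rib_layer
        assert np.abs(rib_free - s.rib_free_float()).max() <= 1.0 / 255.0

    def test_oversized_nodule_is_rejected(self):
        with pytest.raises(InvalidSpecError):
            PhantomSpec(nodule_diameter_px=60)

    def test_out_of_bounds_ellipse_is_rejected(self):
        with pytest.raises(InvalidSpecError):
            PhantomSpec(
                lung_ellipses=(
                    Ellipse((10.0, 80.0), (62.0, 34.0)),
                    Ellipse((138.0, 174.0), (62.0, 34.0)),
                )
            )


class TestGenerateDataset:
    def test_class_counts_match_requested(self, tmp_path):
        spec = PhantomSpec(seed=0, image_size=64, nodule_diameter_px=8)
        manifest, _ = generate_dataset(spec, 154, 93, out_dir=tmp_path)
        assert len(manifest) == 247
        counts = manifest.class_counts(active_only=False)
        assert counts[LABEL_NODULE] == 154
        assert counts[LABEL_NORMAL] == 93
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / "phantom_spec.json").exists()

    def test_zero_mislabel_fraction_means_labels_agree(self, small_dataset):
        manifest, _ = small_dataset
        assert (manifest.df["emitted_label"] == manifest.df["true_label"]).all()

    def test_mislabel_count_is_rounded_fraction(self):
        spec = PhantomSpec(seed=3, mislabel_fraction=0.2)
        manifest, samples = generate_dataset(spec, 20, 5)
        flipped = manifest.df[manifest.df["mislabeled"]]
        assert len(flipped) == 4  # round(0.2 * 20)
        # mislabels live in the emitted-nodule pool with non-nodule content
        assert (flipped["emitted_label"] == LABEL_NODULE).all()
        assert (flipped["true_label"] == LABEL_NORMAL).all()
        for s in samples:
            assert s.mislabeled == (s.emitted_label != s.true_label)

    def test_empty_dataset_is_rejected(self, default_spec):
        with pytest.raises(EmptyDatasetError):
            generate_dataset(default_spec, 0, 0)

    def test_site_assignment_is_round_robin(self):
        spec = PhantomSpec(
            seed=0,
            site_profiles=(SiteProfile(0, 1, 1), SiteProfile(0.05, 1.1, 0.9)),
        )
        manifest, _ = generate_dataset(spec, 4, 4)
        assert list(manifest.df["site_id"]) == [0, 1, 0, 1, 0, 1, 0, 1]

    def test_dataset_determinism(self):
        spec = PhantomSpec(seed=11)
        _, a = generate_dataset(spec, 3, 3)
        _, b = generate_dataset(spec, 3, 3)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.image.pixels, sb.image.pixels)


class TestMarkerConfounder:
    def test_perfect_correlation_predicts_class(self):
        spec = PhantomSpec(seed=5, marker_enabled=True, marker_class_correlation=1.0)
        _, samples = generate_dataset(spec, 30, 30)
        for s in samples:
            has_marker = s.marker_layer.max() > 0
            assert has_marker == (s.emitted_label == LABEL_NODULE)

    def test_half_correlation_is_class_independent(self):
        """Chi-square independence of marker presence and class at 0.5."""
        spec = PhantomSpec(
            seed=1234,
            image_size=64,
            nodule_diameter_px=8,
            marker_enabled=True,
            marker_class_correlation=0.5,
        )
        _, samples = generate_dataset(spec, 250, 250)
        table = np.zeros((2, 2))
        for s in samples:
            has_marker = int(s.marker_layer.max() > 0)
            is_nodule = int(s.emitted_label == LABEL_NODULE)
            table[has_marker, is_nodule] += 1
        _, p, _, _ = chi2_contingency(table)
        assert p > 0.01

    def test_marker_sits_in_the_corner_block(self):
        spec = PhantomSpec(seed=5, marker_enabled=True, marker_class_correlation=1.0)
        s = generate_sample(spec, LABEL_NODULE, sample_rng(spec, 0))
        support = np.nonzero(s.marker_layer)
        assert support[0].min() >= MARKER_ROWS[0] and support[0].max() < MARKER_ROWS[1]
        assert support[1].min() >= MARKER_COLS[0] and support[1].max() < MARKER_COLS[1]


class TestSiteBias:
    def test_identity_profile_is_a_no_op(self, small_dataset):
        _, samples = small_dataset
        img = samples[0].image
        out = apply_site_bias(img, SiteProfile(0.0, 1.0, 1.0))
        assert np.array_equal(out.pixels, img.pixels)

    def test_brightness_offset_shifts_constant_image(self):
        img = RadiographImage(np.full((32, 32), 128, dtype=np.uint8))
        out = apply_site_bias(img, SiteProfile(0.1, 1.0, 1.0))
        expected = round((128 / 255 + 0.1) * 255)
        assert np.all(out.pixels == expected)

    def test_gamma_follows_power_law(self):
        img = RadiographImage(np.full((32, 32), 128, dtype=np.uint8))
        out = apply_site_bias(img, SiteProfile(0.0, 1.0, 2.0))
        expected = round((128 / 255) ** 2 * 255)
        assert np.all(out.pixels == expected)

    def test_non_positive_gamma_is_rejected(self, small_dataset):
        _, samples = small_dataset
        with pytest.raises(InvalidProfileError):
            apply_site_bias(samples[0].image, SiteProfile(0.0, 1.0, 0.0))
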