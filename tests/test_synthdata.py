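import json

import numpy as np
import pytest

from tendonquant.maturity import classify_image
from tendonquant.synthdata import (
    DabPhantomSpec, FiberPhantomSpec, NucleiPhantomSpec, StageSeriesSpec,
    derive_seed, generate_dab_phantom, generate_fiber_phantom,
    generate_nuclei_phantom, generate_stage_series,
)


class TestNucleiPhantom:
    def test_zero_density_rejected(self):
        with pytest.raises(ValueError):
            NucleiPhantomSpec(target_density=0.0)

    def test_count_fixed_by_construction(self):
        spec = NucleiPhantomSpec(image_size=(512, 512), pixel_size_um=1.0,
                                 target_density=2000.0, seed=7)
        _, truth = generate_nuclei_phantom(spec)
        assert truth["count"] == round(2000 * 0.512 * 0.512)

    def test_deterministic_for_fixed_seed(self):
        spec = NucleiPhantomSpec(image_size=(128, 128), seed=42)
        img1, t1 = generate_nuclei_phantom(spec)
        img2, t2 = generate_nuclei_phantom(spec)
        assert np.array_equal(img1.pixels, img2.pixels)
        assert np.array_equal(t1["label_map"], t2["label_map"])

    def test_nuclei_do_not_overlap(self):
        spec = NucleiPhantomSpec(image_size=(256, 256), target_density=2500,
                                 seed=9)
        _, truth = generate_nuclei_phantom(spec)
        labels = truth["label_map"]
        # every label present exactly once as a connected blob
        ids = np.unique(labels)
        assert len(ids) == truth["count"] + 1

    def test_unsatisfiable_density_names_achievable(self):
        spec = NucleiPhantomSpec(image_size=(64, 64), target_density=50000,
                                 nucleus_area_mean=60.0, seed=1)
        with pytest.raises(RuntimeError, match="achievable density"):
            generate_nuclei_phantom(spec)


class TestFiberPhantom:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            FiberPhantomSpec(fraction_green=0.5, fraction_yellow=0.5,
                             fraction_red=0.5, fraction_background=0.0)

    def test_ratio_targets_validated_against_rule(self):
        with pytest.raises(ValueError, match="red"):
            FiberPhantomSpec(class_ratio_targets={
                "green": 0.8, "yellow": 1.4, "red": 1.5})

    def test_all_red_pixels_satisfy_red_rule(self):
        spec = FiberPhantomSpec(image_size=(50, 50), fraction_green=0,
                                fraction_yellow=0, fraction_red=1.0,
                                fraction_background=0.0,
                                class_ratio_targets={"green": 0.8,
                                                     "yellow": 1.4,
                                                     "red": 2.0}, seed=2)
        image, _ = generate_fiber_phantom(spec)
        r = image.pixels[:, :, 0].astype(float)
        g = image.pixels[:, :, 1].astype(float)
        assert np.all(r / g >= 1.8)

    def test_class_counts_exact_up_to_rounding(self):
        spec = FiberPhantomSpec(image_size=(100, 100), fraction_green=0.2,
                                fraction_yellow=0.3, fraction_red=0.5,
                                fraction_background=0.0, seed=3)
        _, truth = generate_fiber_phantom(spec)
        assert truth["counts"] == {"background": 0, "green": 2000,
                                   "yellow": 3000, "red": 5000}

    def test_background_below_mask_threshold(self):
        spec = FiberPhantomSpec(image_size=(60, 60), fraction_green=0.2,
                                fraction_yellow=0.2, fraction_red=0.2,
                                fraction_background=0.4, seed=4)
        image, truth = generate_fiber_phantom(spec)
        bg = image.pixels[truth["class_map"] == 0].astype(int)
        assert np.all(bg.sum(axis=1) < 140)

    def test_generated_classes_match_classifier_exactly(self):
        spec = FiberPhantomSpec(image_size=(80, 80), seed=5)
        image, truth = generate_fiber_phantom(spec)
        assert np.array_equal(classify_image(image.pixels), truth["class_map"])

    def test_deterministic(self):
        spec = FiberPhantomSpec(image_size=(40, 40), seed=6)
        a, _ = generate_fiber_phantom(spec)
        b, _ = generate_fiber_phantom(spec)
        assert np.array_equal(a.pixels, b.pixels)


class TestDabPhantom:
    def test_zero_fraction_all_negative(self):
        spec = DabPhantomSpec(image_size=(32, 32), positive_fraction=0.0, seed=1)
        _, truth = generate_dab_phantom(spec)
        assert truth["n_positive"] == 0

    def test_positive_count_exact(self):
        spec = DabPhantomSpec(image_size=(200, 200), positive_fraction=0.35,
                              seed=2)
        _, truth = generate_dab_phantom(spec)
        assert abs(truth["n_positive"] - 14000) <= 1

    def test_noise_free_bit_identical(self):
        spec = DabPhantomSpec(image_size=(64, 64), noise_sd=0.0, seed=3)
        a, _ = generate_dab_phantom(spec)
        b, _ = generate_dab_phantom(spec)
        assert np.array_equal(a.pixels, b.pixels)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            DabPhantomSpec(positive_fraction=1.2)


class TestStageSeries:
    def test_design_defaults(self):
        spec = StageSeriesSpec()
        assert spec.n_technical == 3
        assert spec.n_biological == 3
        assert spec.stages == (9, 11, 13, 15, 17, 19)

    def test_manifest_combinatorics(self, tmp_path):
        spec = StageSeriesSpec(stages=(9, 13, 19), base_seed=1,
                               image_size=(64, 64))
        manifest = generate_stage_series(spec, tmp_path / "out")
        for modality in ("he", "psr_pol", "dab"):
            assert (manifest["modality"] == modality).sum() == 27

    def test_refuses_nonempty_dir_without_overwrite(self, tmp_path):
        out = tmp_path / "out"
        out.mkdir()
        (out / "junk.txt").write_text("x")
        spec = StageSeriesSpec(stages=(9,), image_size=(64, 64))
        with pytest.raises(FileExistsError):
            generate_stage_series(spec, out)
        generate_stage_series(spec, out, overwrite=True)  # flag unlocks

    def test_manifest_reproducible_bit_exactly(self, tmp_path):
        spec = StageSeriesSpec(stages=(9,), base_seed=3, image_size=(64, 64))
        generate_stage_series(spec, tmp_path / "a")
        generate_stage_series(spec, tmp_path / "b")
        a = (tmp_path / "a" / "manifest.csv").read_bytes()
        b = (tmp_path / "b" / "manifest.csv").read_bytes()
        assert a == b
        img = sorted((tmp_path / "a" / "images").iterdir())[0]
        twin = tmp_path / "b" / "images" / img.name
        assert img.read_bytes() == twin.read_bytes()

    def test_ground_truth_sidecars_parse(self, tmp_path):
        spec = StageSeriesSpec(stages=(13,), base_seed=2, image_size=(64, 64))
        manifest = generate_stage_series(spec, tmp_path / "out")
        row = manifest[manifest["modality"] == "dab"].iloc[0]
        sidecar = (tmp_path / "out" / row["ground_truth_path"]).with_suffix(".json")
        scalars = json.loads(sidecar.read_text())
        assert "dab_positive_pct" in scalars

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="study design"):
            StageSeriesSpec(stages=(9, 10))


def test_derive_seed_is_stable_and_bounded():
    s1 = derive_seed(5, "TmAM", 9, 1, 1, "he")
    s2 = derive_seed(5, "TmAM", 9, 1, 1, "he")
    s3 = derive_seed(5, "TmAM", 9, 1, 2, "he")
    assert s1 == s2 != s3
    assert 0 <= s1 < 2**31
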