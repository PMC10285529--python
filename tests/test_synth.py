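"""Synthetic scene generator: determinism, feature contracts, fixtures."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import ndimage

from netquant.errors import UsageError
from netquant.features import LoGParams, log_response
from netquant.segment import ChannelImage
from netquant.synth import (
    CLASS_PRESETS,
    PlacementError,
    SceneSpec,
    emit_fixture_set,
    preset_config,
    preset_scene,
    render_scene,
)


def scene(seed=0, **kw):
    defaults = dict(objects=(replace(CLASS_PRESETS["PMN"], count=5),), seed=seed)
    defaults.update(kw)
    return SceneSpec(**defaults)


class TestRenderScene:
    def test_object_counts_match_spec(self):
        _, _, truth = render_scene(scene())
        assert truth.class_counts == {"PMN": 5}
        assert len(truth.objects) == 5

    def test_pmn_only_scene_has_blank_extracellular_channel(self):
        _, extra, _ = render_scene(scene())
        # background 100 + noise sd 5: nothing near the 300 threshold
        assert extra.max() < 200

    def test_same_seed_is_bit_identical(self):
        t1, e1, g1 = render_scene(scene(seed=11))
        t2, e2, g2 = render_scene(scene(seed=11))
        np.testing.assert_array_equal(t1, t2)
        np.testing.assert_array_equal(e1, e2)
        assert [o.bounding_box for o in g1.objects] == [o.bounding_box for o in g2.objects]

    def test_different_seeds_differ(self):
        t1, _, _ = render_scene(scene(seed=1))
        t2, _, _ = render_scene(scene(seed=2))
        assert not np.array_equal(t1, t2)

    def test_masks_disjoint_without_overlap(self):
        spec = preset_scene("mixed_coculture", seed=4)
        _, _, truth = render_scene(spec)
        stack = np.stack([o.pixel_mask for o in truth.objects])
        assert stack.sum(axis=0).max() <= 1

    def test_rnd_measured_brightness_within_spec_range(self):
        spec = scene(objects=(replace(CLASS_PRESETS["RND"], count=4),), seed=3)
        total, _, truth = render_scene(spec)
        lo, hi = CLASS_PRESETS["RND"].mean_total_range
        for obj in truth.objects:
            interior = ndimage.binary_erosion(obj.pixel_mask)
            assert lo <= total[interior].mean() <= hi

    def test_measured_features_in_spec_ranges(self):
        """Interior (1-px eroded) feature measurements of rendered
        objects fall inside their generating ranges for >= 99% of
        objects across seeds."""
        checked = 0
        violations = 0
        for seed in range(12):
            spec = preset_scene("mixed_coculture", seed + 50)
            total, extra, truth = render_scene(spec)
            for obj in truth.objects:
                preset = CLASS_PRESETS[obj.label]
                interior = ndimage.binary_erosion(obj.pixel_mask)
                lo_a, hi_a = preset.area_range
                ok = lo_a * 0.85 <= obj.area <= hi_a * 1.15  # dilation-fit slack
                if preset.mean_total_range[1] > 0:
                    lo, hi = preset.mean_total_range
                    ok &= lo <= total[interior].mean() <= hi
                if preset.mean_extra_range[1] > 0:
                    lo, hi = preset.mean_extra_range
                    ok &= lo <= extra[interior].mean() <= hi
                checked += 1
                violations += not ok
        assert checked > 100
        assert violations / checked <= 0.01

    def test_net_sd_exceeds_artifact_sd_at_matched_brightness(self):
        """The NET/artifact discriminator: heterogeneous NET texture has
        far higher brightness SD than a smooth patch of equal mean."""
        net = replace(CLASS_PRESETS["NET"], mean_extra_range=(500, 560))
        art = replace(CLASS_PRESETS["EXTRA_ARTIFACT"], mean_extra_range=(500, 560))
        for seed in range(5):
            _, e_net, g_net = render_scene(scene(objects=(replace(net, count=1),),
                                                 seed=seed))
            _, e_art, g_art = render_scene(scene(objects=(replace(art, count=1),),
                                                 seed=seed))
            sd_net = e_net[g_net.objects[0].pixel_mask].std()
            sd_art = e_art[g_art.objects[0].pixel_mask].std()
            assert sd_net > 3 * sd_art

    def test_bacteria_log_magnitude_below_cells(self):
        spec = scene(objects=(
            replace(CLASS_PRESETS["BACTERIA"], count=2),
            replace(CLASS_PRESETS["PMN"], count=2),
        ), seed=8)
        total, _, truth = render_scene(spec)
        logr = log_response(ChannelImage(total, "total_dna", "x"), LoGParams())
        mags = {"BACTERIA": [], "PMN": []}
        for obj in truth.objects:
            interior = ndimage.binary_erosion(obj.pixel_mask)
            mags[obj.label].append(abs(logr[interior].mean()))
        assert max(mags["BACTERIA"]) < min(mags["PMN"])

    def test_impossible_density_raises_placement_error(self):
        spec = SceneSpec(
            shape=(64, 64),
            objects=(replace(CLASS_PRESETS["NET"], count=4),),
            seed=0,
        )
        with pytest.raises(PlacementError):
            render_scene(spec)

    def test_scene_smaller_than_minimum_rejected(self):
        with pytest.raises(UsageError):
            SceneSpec(shape=(32, 32))


class TestFixtureEmission:
    def test_clean_separation_files_on_disk(self, tmp_path):
        files = emit_fixture_set("clean_separation", tmp_path, seed=1, n_images=3)
        assert len(files["tiffs"]) == 3 and all(p.exists() for p in files["tiffs"])
        assert len(files["xmls"]) == 3
        assert files["truth_csv"][0].exists()
        assert files["config"][0].exists()

    def test_emitted_tiff_and_xml_are_consistent(self, tmp_path):
        import pandas as pd

        from netquant.io import read_two_channel_tiff, read_voc_annotations

        files = emit_fixture_set("clean_separation", tmp_path, seed=2, n_images=2)
        truth = pd.read_csv(files["truth_csv"][0])
        for tiff, xml in zip(files["tiffs"], files["xmls"]):
            total, extra = read_two_channel_tiff(tiff)
            assert total.shape == (256, 256) == extra.shape
            boxes = read_voc_annotations(xml)
            assert len(boxes) == (truth["source_id"] == tiff.name).sum()

    def test_emitted_config_loads(self, tmp_path):
        from netquant.config import load_config

        files = emit_fixture_set("uneven_background", tmp_path, seed=3, n_images=1)
        config = load_config(files["config"][0])
        assert "PMN" in config.classifier.classes

    def test_uneven_background_images_contain_artifact_truth(self, tmp_path):
        import pandas as pd

        files = emit_fixture_set("uneven_background", tmp_path, seed=4, n_images=4)
        truth = pd.read_csv(files["truth_csv"][0])
        per_image = truth.groupby("source_id")["label"].apply(
            lambda s: (s == "EXTRA_ARTIFACT").sum())
        assert (per_image >= 1).all()

    def test_unknown_preset_rejected(self, tmp_path):
        with pytest.raises(UsageError):
            emit_fixture_set("nonexistent", tmp_path, seed=0)
        with pytest.raises(UsageError):
            preset_scene("nonexistent", 0)
        with pytest.raises(UsageError):
            preset_config("nonexistent")
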