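import json
from dataclasses import replace

import numpy as np
import pytest

from chromatex import (GenerationError, SceneSpec, generate_foci_scene,
                       generate_texture_scene, generate_tma_scene, read_image, write_scene)


class TestSceneSpecValidation:
    def test_control_with_clumps_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(texture_regime="control", clumpiness=0.2)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(noise_sd=-1)

    def test_tiny_radii_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(nucleus_radius_range=(1.0, 5.0))


class TestTextureScene:
    def test_determinism_bit_identical(self, treated_spec):
        a = generate_texture_scene(treated_spec)
        b = generate_texture_scene(treated_spec)
        np.testing.assert_array_equal(a.channels["dapi"].values, b.channels["dapi"].values)
        np.testing.assert_array_equal(a.truth_nuclei.labels, b.truth_nuclei.labels)

    def test_different_seeds_differ(self, treated_spec):
        a = generate_texture_scene(treated_spec)
        b = generate_texture_scene(replace(treated_spec, seed=treated_spec.seed + 1))
        assert (a.channels["dapi"].values != b.channels["dapi"].values).any()

    def test_nucleus_count(self, control_spec):
        scene = generate_texture_scene(replace(control_spec, n_nuclei=12))
        assert scene.truth_nuclei.n_labels == 12

    def test_nuclei_disjoint_and_inside_canvas(self, treated_spec):
        scene = generate_texture_scene(treated_spec)
        labels = scene.truth_nuclei.labels
        # labels are exclusive by construction; check none touch the border
        assert labels[0, :].max() == 0 and labels[-1, :].max() == 0
        assert labels[:, 0].max() == 0 and labels[:, -1].max() == 0

    def test_mean_intensity_conserved_between_regimes(self):
        # bright clumps are balanced by dark ones, so regime changes pattern
        # while the nuclear mean stays at base_level
        means = {}
        for regime, cl in (("control", 0.0), ("treated", 0.6)):
            vals = []
            for k in range(5):
                spec = SceneSpec(texture_regime=regime, clumpiness=cl, noise_sd=0.0,
                                 field_sd=0.0, seed=100 + k)
                scene = generate_texture_scene(spec)
                inside = scene.truth_nuclei.labels > 0
                vals.append(scene.channels["dapi"].values[inside].mean())
            means[regime] = np.mean(vals)
        assert means["treated"] == pytest.approx(means["control"], rel=0.02)

    def test_impossible_packing_raises(self):
        with pytest.raises(GenerationError):
            generate_texture_scene(SceneSpec(height=64, width=64, n_nuclei=40))


class TestFociScene:
    def test_zero_foci_pure_background(self):
        scene = generate_foci_scene(SceneSpec(foci_per_nucleus=0, noise_sd=0.0, seed=3))
        assert scene.truth_foci == []
        assert scene.channels["foci"].values.max() == 0

    def test_counts_and_in_nucleus(self):
        scene = generate_foci_scene(SceneSpec(foci_per_nucleus=7, n_nuclei=10, seed=3))
        assert len(scene.truth_foci) == 70
        for lab, r, c in scene.truth_foci:
            assert scene.truth_nuclei.labels[r, c] == lab

    def test_pairwise_separation(self):
        spec = SceneSpec(foci_per_nucleus=9, seed=5)
        scene = generate_foci_scene(spec)
        by_nucleus = {}
        for lab, r, c in scene.truth_foci:
            by_nucleus.setdefault(lab, []).append((r, c))
        min_sep = 4 * spec.focus_sigma
        for pts in by_nucleus.values():
            for i in range(len(pts)):
                for j in range(i + 1, len(pts)):
                    d = np.hypot(pts[i][0] - pts[j][0], pts[i][1] - pts[j][1])
                    assert d >= min_sep


class TestTmaScene:
    def test_zero_epithelium(self):
        scene = generate_tma_scene(SceneSpec(epithelium_fraction=0.0, seed=2))
        assert (scene.truth_compartments.labels == 0).all()
        assert scene.channels["cytokeratin"].values[scene.truth_core].max() <= \
            5 * scene.spec.noise_sd + 1

    def test_epithelium_fraction_tracks_request(self):
        scene = generate_tma_scene(SceneSpec(epithelium_fraction=0.5, seed=2))
        core = scene.truth_core
        frac = (scene.truth_compartments.labels[core] > 0).mean()
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_compartments_partition_core(self):
        scene = generate_tma_scene(SceneSpec(seed=4))
        labels = scene.truth_compartments.labels
        assert set(np.unique(labels)) <= {0, 1, 2}
        # compartments live inside the core only
        assert (labels[~scene.truth_core] == 0).all()
        # nuclei are the nuclear compartment
        assert ((scene.truth_nuclei.labels > 0) == (labels == 2)).all()

    def test_excessive_fraction_rejected(self):
        with pytest.raises(ValueError):
            generate_tma_scene(SceneSpec(epithelium_fraction=0.99, seed=1))


class TestSceneIO:
    def test_write_scene_round_trip(self, tmp_path, treated_spec):
        scene = generate_texture_scene(treated_spec)
        sidecar = write_scene(scene, tmp_path, "s")
        back = read_image(tmp_path / "s.tif", 0)
        np.testing.assert_array_equal(back.values, scene.channels["dapi"].values)
        meta = json.loads((tmp_path / "s_truth.json").read_text())
        assert meta["nuclei"]["count"] == scene.truth_nuclei.n_labels
        assert meta["spec"]["seed"] == treated_spec.seed
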