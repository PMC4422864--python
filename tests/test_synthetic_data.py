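import json

import numpy as np
import pytest

from atlas_msi.core_model_io.model import StudyDesign, ValidationError
from atlas_msi.registration import SectionTransform, cord_length
from atlas_msi.synthetic_data import (
    DeformSpec,
    EffectSpec,
    NoiseModel,
    PanelFeature,
    default_effects,
    default_panel,
    expected_feature_maps,
    generate_atlas,
    generate_section,
    generate_study,
    roi_landmarks,
    simulate_region_profiles,
)


def independent_cord_scan(mask):
    """Max row run length via a plain per-row loop (independent oracle)."""
    best = 0
    for row in np.asarray(mask, bool):
        run = 0
        for px in row:
            run = run + 1 if px else 0
            best = max(best, run)
    return best


class TestGenerateAtlas:
    def test_three_sections_strictly_increasing_cords(self, atlas3):
        sections, truth = atlas3
        cords = truth["cord_lengths"]
        assert len(sections) == 3 and len(set(cords)) == 3
        assert cords == sorted(cords)

    def test_determinism(self):
        a, _ = generate_atlas(2, (56, 80), seed=5)
        b, _ = generate_atlas(2, (56, 80), seed=5)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.labels, sb.labels)
            np.testing.assert_array_equal(sa.image, sb.image)

    def test_cord_length_matches_independent_scan(self, atlas3):
        sections, truth = atlas3
        for sec, cord in zip(sections, truth["cord_lengths"]):
            assert independent_cord_scan(sec.roi_mask("hippocampus")) == cord

    def test_too_small_shape_rejected(self):
        with pytest.raises(ValidationError, match="too small"):
            generate_atlas(1, (16, 16), seed=0)

    def test_all_rois_present_and_hemispheres_assignable(self, atlas3):
        sections, _ = atlas3
        for sec in sections:
            for roi in ("cortex", "striatum", "hippocampus", "thalamus"):
                assert sec.roi_mask(roi).any()
            lab = sec.labels > 0
            assert (sec.hemisphere_mask("L") | sec.hemisphere_mask("R"))[lab].all()


class TestGenerateSection:
    def test_identity_deform_is_identity(self, atlas3):
        sec = atlas3[0][0]
        img, lab, pairs, tf = generate_section(sec, DeformSpec())
        np.testing.assert_array_equal(img, sec.image)
        np.testing.assert_array_equal(lab, sec.labels)
        for a, s in pairs:
            assert a == s

    def test_pure_translation_displaces_landmarks_exactly(self, atlas3):
        sec = atlas3[0][0]
        img, lab, pairs, tf = generate_section(sec, DeformSpec(translate_px=(5, -3)))
        for a, s in pairs:
            assert s[0] - a[0] == pytest.approx(5.0, abs=1e-9)
            assert s[1] - a[1] == pytest.approx(-3.0, abs=1e-9)

    def test_serialized_transform_reproduces_landmarks(self, atlas3, tmp_path):
        sec = atlas3[0][1]
        d = DeformSpec(rotation_deg=4, scale_x=1.03, scale_y=0.97, shear=0.02,
                       translate_px=(3, 2), bspline_amplitude_px=2.0, seed=9)
        img, lab, pairs, tf = generate_section(sec, d)
        tf.to_json(tmp_path / "t.json")
        back = SectionTransform.from_json(tmp_path / "t.json")
        atlas_pts = np.array([a for a, _ in pairs])
        section_pts = np.array([s for _, s in pairs])
        np.testing.assert_allclose(back.apply(atlas_pts), section_pts, atol=1e-6)

    def test_at_least_8_landmarks(self, atlas3):
        assert len(roi_landmarks(atlas3[0][0])) >= 8

    def test_excessive_deformation_rejected(self, atlas3):
        with pytest.raises(ValidationError, match="out of frame"):
            generate_section(atlas3[0][0], DeformSpec(translate_px=(60, 0)))


class TestExpectedMaps:
    def test_effect_halves_right_cortex(self, atlas3):
        sec = atlas3[0][0]
        panel = [PanelFeature(146.07, baseline=100.0)]
        eff = [EffectSpec(146.07, "cortex", "R", "R192Q-CSD", -1.0)]
        maps = expected_feature_maps(sec, panel, eff, "R192Q-CSD")
        cortex = sec.roi_mask("cortex")
        left = maps[0][cortex & sec.hemisphere_mask("L")]
        right = maps[0][cortex & sec.hemisphere_mask("R")]
        assert right.mean() == pytest.approx(0.5 * left.mean())
        null_maps = expected_feature_maps(sec, panel, eff, "WT-CSD")
        nl = null_maps[0][cortex & sec.hemisphere_mask("L")].mean()
        nr = null_maps[0][cortex & sec.hemisphere_mask("R")].mean()
        assert nl == pytest.approx(nr)


@pytest.fixture(scope="module")
def tiny_study(tmp_path_factory):
    out = tmp_path_factory.mktemp("tiny_study")
    sizes = {("WT", "CSD"): 2, ("R192Q", "CSD"): 2}
    design = StudyDesign.default(sizes)
    manifest = generate_study(
        design, seed=21, out_dir=out, n_atlas_sections=2,
        noise=NoiseModel(poisson_scale=1.0, mz_drift_ppm_sd=10.0,
                         baseline_amplitude=2.0, animal_scale_sd=0.02),
    )
    return out, manifest


class TestGenerateStudy:
    def test_outputs_exist(self, tiny_study):
        out, manifest = tiny_study
        assert (out / "study.yaml").exists() and (out / "design.csv").exists()
        for sec in manifest["config"]["sections"]:
            assert (out / sec["imzml"]).exists()
            sid = sec["section_id"]
            assert (out / "truth" / f"{sid}_transform.json").exists()

    def test_duplicate_section_rejected(self, tmp_path):
        import pandas as pd
        t = pd.DataFrame({"animal_id": ["a", "a"], "genotype": ["WT", "WT"],
                          "condition": ["CSD", "CSD"]})
        with pytest.raises(ValidationError):
            generate_study(StudyDesign(t), seed=0, out_dir=tmp_path)

    def test_effect_must_reference_panel(self, tmp_path, default_design):
        with pytest.raises(ValidationError, match="unknown panel feature"):
            generate_study(default_design,
                           effects=[EffectSpec(999.0, "cortex", "R", "R192Q-CSD", -1.0)],
                           seed=0, out_dir=tmp_path)

    def test_effect_region_must_be_in_legend(self, tmp_path, default_design):
        with pytest.raises(ValidationError, match="legend"):
            generate_study(default_design,
                           effects=[EffectSpec(146.07, "amygdala", "R", "R192Q-CSD", -1.0)],
                           seed=0, out_dir=tmp_path)

    def test_seed_reproducibility(self, tmp_path):
        sizes = {("WT", "CSD"): 2}
        a = generate_study(StudyDesign.default(sizes), seed=4, out_dir=tmp_path / "a")
        b = generate_study(StudyDesign.default(sizes), seed=4, out_dir=tmp_path / "b")
        sid = a["config"]["sections"][0]["imzml"]
        assert (tmp_path / "a" / sid).with_suffix(".ibd").read_bytes() == \
               (tmp_path / "b" / sid).with_suffix(".ibd").read_bytes()

    def test_poisson_dispersion(self, tmp_path):
        """Monte-Carlo: var/mean of planted pixel counts ~= poisson_scale."""
        from atlas_msi.core_model_io.imzml import read_imzml
        from atlas_msi.feature_extraction import extract_datacube
        from atlas_msi.core_model_io.model import FeatureDef

        sizes = {("WT", "Naive"): 1}
        scale = 2.0
        man = generate_study(
            StudyDesign.default(sizes), effects=[], seed=8, out_dir=tmp_path,
            noise=NoiseModel(poisson_scale=scale, mz_drift_ppm_sd=0.0,
                             baseline_amplitude=0.0, animal_scale_sd=0.0),
        )
        sec = man["config"]["sections"][0]
        ds = read_imzml(tmp_path / sec["imzml"])
        # pixel counts of the 176.8 feature (flat region pattern) in one ROI
        truth = np.load(tmp_path / "truth" / f"{sec['section_id']}_maps.npz")
        panel_mzs = [p["mz"] for p in man["truth"]["panel"]]
        fi = panel_mzs.index(176.8)
        cube = extract_datacube(ds, [FeatureDef(176.8, 176.8 - 0.3, 176.8 + 0.3)])
        expected_per_px = truth["amplitudes"][:, fi]
        sel = expected_per_px > expected_per_px.max() * 0.9  # uniform-amplitude pixels
        counts = cube.values[sel, 0]
        assert sel.sum() > 400
        ratio = counts.var() / counts.mean()
        assert ratio == pytest.approx(scale, rel=0.1)

    def test_noiseless_no_effects_identical_animals(self, tmp_path):
        sizes = {("WT", "Naive"): 2}
        man = generate_study(
            StudyDesign.default(sizes), effects=[], seed=3, out_dir=tmp_path,
            n_atlas_sections=1,
            noise=NoiseModel(poisson_scale=0.0, mz_drift_ppm_sd=0.0,
                             baseline_amplitude=0.0, animal_scale_sd=0.0),
            deform_kwargs=dict(max_translate=0, max_rotation=0, max_scale=0,
                               max_shear=0, bspline_amplitude=0),
        )
        arrays = []
        for sec in man["config"]["sections"]:
            t = np.load(tmp_path / "truth" / f"{sec['section_id']}_maps.npz")
            arrays.append(t["amplitudes"])
        np.testing.assert_allclose(arrays[0], arrays[1])


def test_generate_study_unexpected_kwargs():
    with pytest.raises(ValidationError):
        NoiseModel(poisson_scale=-1.0)


class TestSimulateRegionProfiles:
    def test_planted_effect_shows_in_group_means(self, atlas3, default_design):
        prof = simulate_region_profiles(
            default_design, atlas3[0][0], seed=2,
            noise=NoiseModel(poisson_scale=0.0, animal_scale_sd=0.0))
        groups = dict(zip(default_design.table["animal_id"], default_design.groups))
        prof = prof.assign(group=prof["animal_id"].map(groups))
        sub = prof[(prof.roi == "cortex") & np.isclose(prof.feature_mz, 146.07)]
        eff = sub[sub.group == "R192Q-CSD"]
        l = eff[eff.hemisphere == "L"].value.mean()
        r = eff[eff.hemisphere == "R"].value.mean()
        assert r == pytest.approx(0.5 * l, rel=1e-9)
        ctl = sub[sub.group == "WT-CSD"]
        assert ctl[ctl.hemisphere == "L"].value.mean() == pytest.approx(
            ctl[ctl.hemisphere == "R"].value.mean(), rel=1e-9)
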