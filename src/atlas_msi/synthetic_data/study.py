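"""Complete synthetic-study generation.

Per animal and molecular class one imzML section is produced from a
deformed phantom of the toy atlas: each panel feature contributes a
Gaussian peak whose pixelwise amplitude is baseline x region pattern
x 2^lfc for pixels whose (group, region, hemisphere) matches a planted
effect, a smooth low-frequency baseline is added, the expected spectrum is
Poisson-sampled, and the peak positions are perturbed by a per-sample
linear mass-calibration drift.  Ground-truth tables (effects, transforms,
landmarks, atlas-frame expected feature maps) are written alongside.
"""
from __future__ import annotations

import json
import uuid as _uuid
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from ..core_model_io.imzml import write_imzml
from ..core_model_io.labelmap import write_labelmap
from ..core_model_io.model import (
    AtlasSection,
    MSIDataset,
    StudyDesign,
    ValidationError,
)
from .atlas import generate_atlas
from .deform import DeformSpec, generate_section

__all__ = [
    "EffectSpec", "NoiseModel", "PanelFeature",
    "default_panel", "default_effects",
    "expected_feature_maps", "generate_study",
]


@dataclass(frozen=True)
class EffectSpec:
    """A planted group x region x hemisphere intensity effect."""

    feature_mz: float
    region: str
    hemisphere: str  # 'L', 'R' or 'both'
    group: str       # e.g. 'R192Q-CSD'
    log2_fold_change: float
    baseline_intensity: float | None = None  # None -> panel feature baseline

    def __post_init__(self):
        if self.hemisphere not in ("L", "R", "both"):
            raise ValidationError(f"bad hemisphere {self.hemisphere!r}")
        if self.baseline_intensity is not None and self.baseline_intensity <= 0:
            raise ValidationError("baseline_intensity must be > 0")


@dataclass(frozen=True)
class NoiseModel:
    poisson_scale: float = 1.0        # var/mean of sampled counts; 0 = noiseless
    mz_drift_ppm_sd: float = 30.0     # per-sample linear calibration error
    baseline_amplitude: float = 5.0   # expected counts of the smooth baseline
    peak_width_da: float = 0.08       # Gaussian sigma of generated peaks
    animal_scale_sd: float = 0.05     # lognormal per-animal global intensity scatter

    def __post_init__(self):
        for name, v in asdict(self).items():
            if v < 0:
                raise ValidationError(f"NoiseModel.{name} must be >= 0")


@dataclass(frozen=True)
class PanelFeature:
    mz: float
    molecular_class: str = "metabolite"
    baseline: float = 100.0
    pattern: dict = field(default_factory=dict)  # region -> multiplier (default 1)

    def multiplier(self, region: str) -> float:
        return float(self.pattern.get(region, 1.0))


def default_panel():
    """Eight metabolite-window features with distinct region patterns."""
    return [
        PanelFeature(146.07, baseline=120, pattern={"cortex": 1.3, "thalamus": 1.1, "other": 0.7}),
        PanelFeature(151.90, baseline=90, pattern={"striatum": 1.4, "other": 0.8}),
        PanelFeature(158.30, baseline=150, pattern={"hippocampus": 1.6, "other": 0.6}),
        PanelFeature(163.70, baseline=80, pattern={"thalamus": 1.5, "cortex": 0.8}),
        PanelFeature(170.20, baseline=110, pattern={"striatum": 1.2, "hippocampus": 0.9}),
        PanelFeature(176.80, baseline=100, pattern={}),
        PanelFeature(180.60, baseline=95, pattern={"thalamus": 0.8, "hippocampus": 1.3}),
        PanelFeature(183.40, baseline=130, pattern={"cortex": 0.7, "other": 1.2}),
    ]


def default_effects():
    """Effects confined to the R192Q-CSD group, lower in the right (CSD)
    hemisphere, |log2FC| in [0.5, 1]."""
    return [
        EffectSpec(146.07, "cortex", "R", "R192Q-CSD", -1.0),
        EffectSpec(146.07, "thalamus", "R", "R192Q-CSD", -0.8),
        EffectSpec(170.20, "striatum", "R", "R192Q-CSD", -0.6),
        EffectSpec(158.30, "hippocampus", "R", "R192Q-CSD", -0.5),
    ]


#: default profile grids per molecular class: (lo, hi, spacing) Da.
DEFAULT_GRIDS = {
    "metabolite": (145.0, 186.0, 0.02),
    "peptide": (1700.0, 1760.0, 0.02),
    "protein": (10000.0, 12000.0, 2.0),
}


def expected_feature_maps(atlas_section: AtlasSection, panel, effects, group: str):
    """Atlas-frame expected (noiseless) amplitude map per panel feature.

    Returns an array (n_features, h, w); background pixels are 0.
    """
    labels = atlas_section.labels
    h, w = labels.shape
    maps = np.zeros((len(panel), h, w))
    hemi_R = atlas_section.hemisphere_mask("R")
    for fi, feat in enumerate(panel):
        amp = np.zeros((h, w))
        for lab, region in atlas_section.legend.items():
            amp[labels == lab] = feat.baseline * feat.multiplier(region)
        for eff in effects:
            if eff.group != group or abs(eff.feature_mz - feat.mz) > 1e-6:
                continue
            base = eff.baseline_intensity or feat.baseline
            region_mask = atlas_section.roi_mask(eff.region)
            if eff.hemisphere == "both":
                hemi = np.ones_like(hemi_R)
            else:
                hemi = hemi_R if eff.hemisphere == "R" else ~hemi_R
            sel = region_mask & hemi
            amp[sel] = base * feat.multiplier(eff.region) * 2.0 ** eff.log2_fold_change
        maps[fi] = amp
    return maps


def simulate_region_profiles(design: StudyDesign, atlas_section: AtlasSection,
                             panel=None, effects=None,
                             noise: NoiseModel | None = None, seed: int = 0,
                             rois=("cortex", "striatum", "hippocampus", "thalamus")):
    """Animal-level region profiles drawn directly from the truth model.

    Skips the imaging stages: per animal x ROI x hemisphere x feature, the
    mean intensity is the region's expected value times a per-animal
    lognormal scale, plus Gaussian noise with the variance a Poisson pixel
    average over the region would have.  Used for fast repeated-seed
    calibration checks of the statistics stage.
    """
    import pandas as pd

    design.validate()
    panel = panel or default_panel()
    effects = default_effects() if effects is None else effects
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    groups = dict(zip(design.table["animal_id"], design.groups))

    maps_by_group = {}
    rows = []
    hemi = {"L": atlas_section.hemisphere_mask("L"),
            "R": atlas_section.hemisphere_mask("R")}
    for aid in design.table["animal_id"]:
        g = groups[aid]
        if g not in maps_by_group:
            maps_by_group[g] = expected_feature_maps(atlas_section, panel, effects, g)
        maps = maps_by_group[g]
        scale = float(np.exp(rng.normal(0.0, noise.animal_scale_sd))) \
            if noise.animal_scale_sd > 0 else 1.0
        for roi in rois:
            mask = atlas_section.roi_mask(roi)
            for h in ("L", "R"):
                sel = mask & hemi[h]
                n = int(sel.sum())
                if n == 0:
                    continue
                for fi, feat in enumerate(panel):
                    mu = float(maps[fi][sel].mean()) * scale
                    sd = np.sqrt(noise.poisson_scale * max(mu, 1e-12) / n)
                    v = mu + (rng.normal(0.0, sd) if sd > 0 else 0.0)
                    rows.append({"animal_id": aid, "roi": roi, "hemisphere": h,
                                 "n_pixels": n, "feature_mz": feat.mz,
                                 "value": float(v)})
    return pd.DataFrame(rows)


def _sample_counts(expected, rng, poisson_scale):
    if poisson_scale <= 0:
        return expected
    return poisson_scale * rng.poisson(expected / poisson_scale)


def generate_study(
    design: StudyDesign,
    effects=None,
    noise: NoiseModel | None = None,
    feature_panel=None,
    seed: int = 0,
    out_dir=None,
    molecular_class: str = "metabolite",
    n_atlas_sections: int = 3,
    atlas_shape=(56, 80),
    atlas_pad: int = 8,
    grid=None,
    deform_kwargs=None,
) -> dict:
    """Write a complete synthetic study to *out_dir*; returns its manifest.

    With a fixed *seed* the study is byte-reproducible.
    """
    design.validate()
    effects = default_effects() if effects is None else effects
    noise = noise or NoiseModel()
    panel = [f for f in (feature_panel or default_panel())
             if f.molecular_class == molecular_class]
    if not panel:
        raise ValidationError(f"feature panel has no {molecular_class!r} features")
    lo, hi, spacing = grid or DEFAULT_GRIDS[molecular_class]
    out_dir = Path(out_dir)
    for sub in ("atlas", "sections", "truth"):
        (out_dir / sub).mkdir(parents=True, exist_ok=True)

    from .atlas import LEGEND
    regions = set()
    sections_legend = set(LEGEND.values())
    for eff in effects:
        regions.add(eff.region)
        if not any(abs(f.mz - eff.feature_mz) < 1e-6 for f in panel):
            raise ValidationError(f"effect references unknown panel feature {eff.feature_mz}")
    unknown = regions - sections_legend
    if unknown:
        raise ValidationError(f"effect regions not in atlas legend: {unknown}")

    rng = np.random.default_rng(seed)
    atlas, atlas_truth = generate_atlas(n_atlas_sections, atlas_shape, seed=seed,
                                        pad=atlas_pad)
    for k, sec in enumerate(atlas):
        write_labelmap(sec, out_dir / "atlas" / f"{sec.section_id}.png",
                       out_dir / "atlas" / f"{sec.section_id}.json")
    (out_dir / "truth" / "atlas.json").write_text(json.dumps(atlas_truth, indent=1))

    mz_axis = np.arange(lo, hi + spacing / 2, spacing)
    sigma = noise.peak_width_da
    seen = set()
    transforms_truth, landmarks_truth, sections_manifest = {}, {}, []
    groups = dict(zip(design.table["animal_id"], design.groups))
    drifts = {}

    for ai, row in enumerate(design.table.itertuples()):
        key = (row.animal_id, molecular_class)
        if key in seen:
            raise ValidationError(f"duplicate section for {key}")
        seen.add(key)
        sec_id = f"{row.animal_id}_{molecular_class}"
        atlas_idx = ai % n_atlas_sections
        a_rng = np.random.default_rng(seed + 7919 * (ai + 1))

        dkw = dict(deform_kwargs or {})
        deform = DeformSpec.random(a_rng, **dkw)
        image, labels, lm_pairs, tf = generate_section(atlas[atlas_idx], deform)

        # atlas-frame expected maps, warped into the section frame
        maps = expected_feature_maps(atlas[atlas_idx], panel, effects,
                                     groups[row.animal_id])
        from .deform import invert_transform_points
        h, w = labels.shape
        rows_g, cols_g = np.nonzero(labels > 0)
        pts = np.stack([cols_g, rows_g], axis=1).astype(float)
        src = invert_transform_points(tf, pts)
        from scipy import ndimage as ndi
        amp = np.stack([
            ndi.map_coordinates(maps[fi], [src[:, 1], src[:, 0]], order=1,
                                mode="constant", cval=0.0)
            for fi in range(len(panel))
        ], axis=1)  # (n_pixels, n_features)

        scale = float(np.exp(a_rng.normal(0.0, noise.animal_scale_sd))) \
            if noise.animal_scale_sd > 0 else 1.0
        amp = amp * scale

        # per-sample linear mass-calibration drift applied to peak positions
        slope = 1.0 + (a_rng.normal(0.0, noise.mz_drift_ppm_sd * 1e-6)
                       if noise.mz_drift_ppm_sd > 0 else 0.0)
        offset = (a_rng.normal(0.0, noise.mz_drift_ppm_sd * 1e-6 * lo)
                  if noise.mz_drift_ppm_sd > 0 else 0.0)
        drifts[sec_id] = {"slope": slope, "offset": offset}
        centers = np.array([f.mz for f in panel]) * slope + offset
        profiles = np.exp(-0.5 * ((mz_axis[None, :] - centers[:, None]) / sigma) ** 2)

        expected = amp @ profiles
        if noise.baseline_amplitude > 0:
            shape_fn = 0.5 * (1 + np.cos((mz_axis - lo) / (hi - lo) * np.pi))
            expected = expected + noise.baseline_amplitude * scale * shape_fn[None, :]
        counts = _sample_counts(expected, a_rng, noise.poisson_scale)

        ds = MSIDataset(
            coords=pts.astype(int),
            mz_axis=mz_axis.copy(),
            intensities=counts,
            meta={
                "molecular_class": molecular_class,
                "polarity": "-" if molecular_class == "metabolite" else "+",
                "raster_um": 100.0,
                "animal_id": row.animal_id,
                "section_id": sec_id,
                "mass_range": (float(lo), float(hi)),
                "postmortem_min": float(2.0 + 3.0 * a_rng.random()),
            },
        ).validate()
        imzml_path = write_imzml(
            ds, out_dir / "sections" / f"{sec_id}.imzML", intensity_dtype="f4",
            ibd_uuid=_uuid.UUID(bytes=a_rng.bytes(16), version=4))

        sec_obj = AtlasSection(image=image, labels=labels, legend=dict(atlas[atlas_idx].legend),
                               ap_mm=atlas[atlas_idx].ap_mm,
                               midline_col=atlas[atlas_idx].midline_col,
                               section_id=sec_id).validate()
        write_labelmap(sec_obj, out_dir / "sections" / f"{sec_id}_labels.png",
                       out_dir / "sections" / f"{sec_id}_labels.json")

        tf.to_json(out_dir / "truth" / f"{sec_id}_transform.json")
        transforms_truth[sec_id] = {"atlas_index": atlas_idx,
                                    "deform": {**asdict(deform),
                                               "translate_px": list(deform.translate_px),
                                               "bspline_grid": list(deform.bspline_grid)}}
        landmarks_truth[sec_id] = [[list(a), list(s)] for a, s in lm_pairs]
        np.savez_compressed(out_dir / "truth" / f"{sec_id}_maps.npz",
                            expected_maps=maps, amplitudes=amp, coords=pts.astype(int))
        sections_manifest.append({
            "animal_id": row.animal_id, "section_id": sec_id,
            "imzml": str(imzml_path.relative_to(out_dir)),
            "atlas_index": atlas_idx,
        })

    design.to_csv(out_dir / "design.csv")
    truth = {
        "effects": [
            {**asdict(e)} for e in effects
        ],
        "panel": [{"mz": f.mz, "class": f.molecular_class, "baseline": f.baseline,
                   "pattern": f.pattern} for f in panel],
        "noise": asdict(noise),
        "drifts": drifts,
        "transforms": transforms_truth,
        "seed": seed,
    }
    (out_dir / "truth" / "study.json").write_text(json.dumps(truth, indent=1))
    (out_dir / "truth" / "landmarks.json").write_text(json.dumps(landmarks_truth))

    config = {
        "molecular_class": molecular_class,
        "grid": [float(lo), float(hi), float(spacing)],
        "n_atlas_sections": n_atlas_sections,
        "atlas_shape": list(atlas_shape),
        "seed": seed,
        "sections": sections_manifest,
        "preprocess": {"gauss_width_da": 0.02, "gauss_cycles": 2},
        # the per-bin max over ~10^5 Poisson-noisy pixels rides high above
        # per-spectrum noise; a stricter study-level SNR keeps junk out
        "snr_min": 6.0,
    }
    (out_dir / "study.yaml").write_text(yaml.safe_dump(config))
    return {"out_dir": str(out_dir), "config": config, "truth": truth}
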