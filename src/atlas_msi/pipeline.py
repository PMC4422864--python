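"""End-to-end orchestration of a study analysis.

simulate -> preprocess -> align -> base-peak features -> register ->
ROI/hemisphere statistics.  Operates on a study directory as written by
:func:`atlas_msi.synthetic_data.study.generate_study` (the same layout a
converted real study would use).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_model_io.imzml import read_imzml
from .core_model_io.labelmap import read_labelmap
from .core_model_io.model import StudyDesign
from .core_model_io.tables import write_feature_table, write_stats_table
from .feature_extraction import (
    compute_base_peak_spectrum,
    extract_datacube,
    pick_peaks,
    variance_stabilize,
)
from .preprocessing import PreprocConfig, align_spectra, preprocess_dataset, resample_dataset
from .registration import (
    SectionTransform,
    apply_transform,
    evaluate_registration,
    register_section,
    select_atlas_section,
)
from .roi_stats import extract_region_profiles, run_study_statistics

__all__ = ["load_study", "run_pipeline"]


def load_study(study_dir):
    study_dir = Path(study_dir)
    config = yaml.safe_load((study_dir / "study.yaml").read_text())
    design = StudyDesign.from_csv(study_dir / "design.csv")
    atlas = []
    for k in range(config["n_atlas_sections"]):
        sid = f"atlas{k:03d}"
        atlas.append(read_labelmap(study_dir / "atlas" / f"{sid}.png",
                                   study_dir / "atlas" / f"{sid}.json"))
    return config, design, atlas


def run_pipeline(study_dir, use_truth_transforms: bool = False,
                 snr_min: float | None = None, alpha: float = 0.05,
                 write_outputs: bool = True, out_subdir: str = "results"):
    """Run the full analysis on a study directory.

    Returns a dict with the stats table, features, profiles, alignment
    model, and per-section registration diagnostics.  With
    ``use_truth_transforms=True`` the generator's serialized truth
    transforms replace the registration stage (used for scaled-down
    repeated simulations; the registration stage has its own recovery
    checks).
    """
    study_dir = Path(study_dir)
    config, design, atlas = load_study(study_dir)
    lo, hi, spacing = config["grid"]
    mclass = config["molecular_class"]

    pconf = PreprocConfig.for_class(
        mclass, **{k: v for k, v in config.get("preprocess", {}).items()
                   if k in ("gauss_width_da", "gauss_cycles", "tophat_window_da")})

    # stream: read -> preprocess one section at a time (float32) so that at
    # most one extra copy of a section is alive
    pre = []
    for sec in config["sections"]:
        ds = read_imzml(study_dir / sec["imzml"])
        ds.intensities = np.asarray(ds.intensities, dtype=np.float32)
        pre.append(preprocess_dataset(ds, pconf))
        del ds

    model, recal = align_spectra(pre)
    del pre
    grid = np.arange(lo, hi + spacing / 2, spacing)
    common = recal
    for i in range(len(common)):
        common[i] = resample_dataset(common[i], grid)

    bps = compute_base_peak_spectrum(common)
    if snr_min is None:
        snr_min = float(config.get("snr_min", 3.0))
    features = pick_peaks(bps, snr_min=snr_min, gauss_width_da=pconf.gauss_width_da)
    if not features:
        raise RuntimeError("no features picked on the base peak spectrum")

    landmarks_truth = {}
    lm_path = study_dir / "truth" / "landmarks.json"
    if lm_path.exists():
        landmarks_truth = json.loads(lm_path.read_text())

    profiles = []
    registration_rows = []
    for sec, ds in zip(config["sections"], common):
        sec_id = sec["section_id"]
        cube = extract_datacube(ds, features)
        cube = variance_stabilize(cube, mclass)

        sec_labels = read_labelmap(study_dir / "sections" / f"{sec_id}_labels.png",
                                   study_dir / "sections" / f"{sec_id}_labels.json")
        idx, sel_info = select_atlas_section(sec_labels.roi_mask("hippocampus"), atlas)
        fixed = atlas[idx]
        if use_truth_transforms:
            tf = SectionTransform.from_json(study_dir / "truth" / f"{sec_id}_transform.json")
            report = None
        else:
            tf, report = register_section(sec_labels.image, fixed.image)
        aligned = apply_transform(cube, tf, fixed.labels.shape)
        prof = extract_region_profiles(aligned, fixed)
        profiles.append(prof)

        row = {"section_id": sec_id, "atlas_section": idx,
               "true_atlas_section": sec.get("atlas_index"),
               **{f"select_{k}": v for k, v in sel_info.items()}}
        if report is not None:
            row.update({"metric_before": report.metric_before,
                        "metric_after": report.metric_after,
                        "converged": report.converged})
        if sec_id in landmarks_truth and report is not None:
            pairs = [(tuple(a), tuple(s)) for a, s in landmarks_truth[sec_id]]
            tre = evaluate_registration(tf, pairs,
                                        raster_um=ds.meta.get("raster_um", 100.0))
            row.update({"tre_mean_px": tre["mean_px"], "tre_mean_um": tre["mean_um"]})
        registration_rows.append(row)

    profiles = pd.concat(profiles, ignore_index=True)
    table = run_study_statistics(profiles, design, alpha=alpha)

    result = {
        "stats": table,
        "features": features,
        "profiles": profiles,
        "alignment": model,
        "registration": pd.DataFrame(registration_rows),
        "base_peak": bps,
    }
    if write_outputs:
        out = study_dir / out_subdir
        out.mkdir(exist_ok=True)
        write_stats_table(table, out / "stats.tsv")
        write_feature_table(features, out / "features.tsv")
        model.to_json(out / "alignment.json")
        result["registration"].to_csv(out / "registration.tsv", sep="\t", index=False)
    return result
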