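"""Region-of-interest hemisphere statistics, BH correction, study
randomization, and the metabolite-ratio post-mortem QC.

The unit of analysis is the animal: per-animal ROI x hemisphere mean
intensities, never individual pixels (pixel-level testing would be
pseudo-replication at n = 5-6 animals per group).
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .core_model_io.model import (
    REQUIRED_ROIS,
    AtlasSection,
    DataCube,
    StudyDesign,
    ValidationError,
)
from .core_model_io.tables import STATS_COLUMNS

__all__ = [
    "extract_region_profiles",
    "paired_hemisphere_test",
    "group_test",
    "bh_adjust",
    "run_study_statistics",
    "block_randomize",
    "qc_metabolite_ratio",
]


def extract_region_profiles(aligned_cube: DataCube, atlas_section: AtlasSection,
                            rois=REQUIRED_ROIS) -> pd.DataFrame:
    """Per ROI x hemisphere mean feature values over retained pixels.

    Returns a long-form frame with columns animal_id, roi, hemisphere,
    n_pixels, feature_mz, value.  ROIs with zero retained pixels are
    omitted (the omission is recorded in the cube provenance).
    """
    if not aligned_cube.transform_applied:
        raise ValidationError("cube must be registered onto the atlas grid first")
    h, w = atlas_section.labels.shape
    idx = aligned_cube.coords[:, 1] * w + aligned_cube.coords[:, 0]
    order = np.argsort(idx)
    if not np.array_equal(idx[order], np.arange(h * w)):
        raise ValidationError("aligned cube must cover the atlas grid")
    values = aligned_cube.values[order].reshape(h, w, -1)
    valid = aligned_cube.valid[order].reshape(h, w)

    animal_id = aligned_cube.meta.get("animal_id")
    rows = []
    for roi in rois:
        roi_mask = atlas_section.roi_mask(roi)
        for hemi in ("L", "R"):
            sel = roi_mask & atlas_section.hemisphere_mask(hemi) & valid
            n = int(sel.sum())
            if n == 0:
                aligned_cube.log(f"extract_region_profiles: {roi}/{hemi} empty, omitted")
                continue
            means = values[sel].mean(axis=0)
            for f, v in zip(aligned_cube.features, means):
                rows.append({"animal_id": animal_id, "roi": roi, "hemisphere": hemi,
                             "n_pixels": n, "feature_mz": f.center_mz, "value": float(v)})
    return pd.DataFrame(rows)


def _paired_values(profiles: pd.DataFrame, roi: str, feature_mz: float):
    sub = profiles[(profiles["roi"] == roi)
                   & (np.isclose(profiles["feature_mz"], feature_mz))]
    piv = sub.pivot_table(index="animal_id", columns="hemisphere", values="value")
    piv = piv.dropna(subset=[c for c in ("L", "R") if c in piv.columns])
    if "L" not in piv.columns or "R" not in piv.columns:
        return np.empty(0), np.empty(0)
    return piv["L"].to_numpy(), piv["R"].to_numpy()


def paired_hemisphere_test(profiles: pd.DataFrame, roi: str, feature_mz: float):
    """Two-sided paired t on per-animal (L - R) differences.

    Returns (t, p, estimate) with estimate = mean(L - R), df = n - 1.
    With zero variance the df-appropriate limit is reported: p = 1 for a
    zero mean difference, p = 0 (t = +/-inf) otherwise.
    """
    left, right = _paired_values(profiles, roi, feature_mz)
    n = len(left)
    if n < 2:
        raise ValidationError(
            f"paired test needs >=2 animals with both hemispheres ({roi}, {feature_mz})")
    d = left - right
    est = float(d.mean())
    if np.allclose(d.std(ddof=1), 0.0):
        if math.isclose(est, 0.0, abs_tol=1e-300):
            return 0.0, 1.0, est
        return math.copysign(math.inf, est), 0.0, est
    t, p = stats.ttest_rel(left, right)
    return float(t), float(p), est


def group_test(values_a, values_b, equal_var: bool = True):
    """Two-sided two-sample t; estimate = mean(a) - mean(b).

    Equal-variance (pooled) by default; Welch via ``equal_var=False``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("group test needs >=2 animals per group")
    est = float(a.mean() - b.mean())
    if np.allclose(np.concatenate([a - a.mean(), b - b.mean()]), 0.0):
        if math.isclose(est, 0.0, abs_tol=1e-300):
            return 0.0, 1.0, est
        return math.copysign(math.inf, est), 0.0, est
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p), est


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, in input order.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def run_study_statistics(profiles: pd.DataFrame, design: StudyDesign,
                         alpha: float = 0.05, between=None,
                         equal_var: bool = True,
                         bh_family: str = "roi_comparison") -> pd.DataFrame:
    """Full comparison plan over every feature x ROI.

    (a) paired L-vs-R within each genotype x condition group;
    (b) unpaired between-group tests on matched hemispheres (default:
    R192Q-CSD vs WT-CSD, each hemisphere).  BH is applied within each
    (ROI x comparison) family across features (``bh_family='global'``
    pools everything instead); significant <=> q < alpha.
    """
    design.validate()
    missing = set(design.table["animal_id"]) - set(profiles["animal_id"])
    if missing:
        raise ValidationError(f"profiles missing animals: {sorted(missing)}")
    groups = dict(zip(design.table["animal_id"], design.groups))
    prof = profiles.copy()
    prof["group"] = prof["animal_id"].map(groups)
    if between is None:
        between = [("R192Q-CSD", "WT-CSD", "L"), ("R192Q-CSD", "WT-CSD", "R")]

    features = sorted(prof["feature_mz"].unique())
    rois = [r for r in REQUIRED_ROIS if r in set(prof["roi"])]
    rows = []
    for roi in rois:
        for feature in features:
            for g in sorted(prof["group"].unique()):
                sub = prof[prof["group"] == g]
                left, right = _paired_values(sub, roi, feature)
                if len(left) < 2:
                    continue
                t, p, est = paired_hemisphere_test(sub, roi, feature)
                rows.append({
                    "feature_mz": feature, "roi": roi,
                    "comparison": f"{g}:L-vs-R", "n": len(left),
                    "mean_a": float(left.mean()), "mean_b": float(right.mean()),
                    "estimate": est,
                    "direction": "L>R" if est > 0 else ("L<R" if est < 0 else "none"),
                    "t": t, "p_raw": p,
                })
            for g1, g2, hemi in between:
                sub = prof[(prof["roi"] == roi) & (prof["hemisphere"] == hemi)
                           & np.isclose(prof["feature_mz"], feature)]
                a = sub.loc[sub["group"] == g1, "value"].to_numpy()
                b = sub.loc[sub["group"] == g2, "value"].to_numpy()
                if len(a) < 2 or len(b) < 2:
                    continue
                t, p, est = group_test(a, b, equal_var=equal_var)
                rows.append({
                    "feature_mz": feature, "roi": roi,
                    "comparison": f"{g1}-vs-{g2}:{hemi}", "n": len(a) + len(b),
                    "mean_a": float(a.mean()), "mean_b": float(b.mean()),
                    "estimate": est,
                    "direction": "up" if est > 0 else ("down" if est < 0 else "none"),
                    "t": t, "p_raw": p,
                })
    table = pd.DataFrame(rows, columns=[c for c in STATS_COLUMNS
                                        if c not in ("q_bh", "significant")])
    if table.empty:
        table["q_bh"] = []
        table["significant"] = []
        return table
    q = np.empty(len(table))
    if bh_family == "global":
        q[:] = bh_adjust(table["p_raw"].to_numpy())
    else:
        for _, idx in table.groupby(["roi", "comparison"]).groups.items():
            q[table.index.get_indexer(idx)] = bh_adjust(table.loc[idx, "p_raw"].to_numpy())
    table["q_bh"] = q
    table["significant"] = table["q_bh"] < alpha
    return table


def block_randomize(design: StudyDesign, slots_per_slide: int, seed: int = 0) -> StudyDesign:
    """Distribute animals across slides maximizing per-slide group diversity.

    Greedy round-robin: each slot takes an animal from the group with the
    largest remaining count among groups not yet on the slide (falling back
    to all groups once every remaining group is represented), with seeded
    random tie-breaking.  Positions within a slide and the acquisition
    order are then randomized.
    """
    if slots_per_slide < 1:
        raise ValidationError("slots_per_slide must be >= 1")
    design.validate()
    rng = np.random.default_rng(seed)
    t = design.table.copy().reset_index(drop=True)
    pools: dict[str, list] = {}
    for aid, g in zip(t["animal_id"], design.groups):
        pools.setdefault(g, []).append(aid)
    for g in pools:
        pools[g] = list(rng.permutation(pools[g]))

    n_slides = math.ceil(len(t) / slots_per_slide)
    assignment = {}
    for slide in range(n_slides):
        in_slide: list[str] = []
        for _ in range(slots_per_slide):
            remaining = {g: v for g, v in pools.items() if v}
            if not remaining:
                break
            fresh = {g: v for g, v in remaining.items() if g not in in_slide}
            cand = fresh or remaining
            top = max(len(v) for v in cand.values())
            best = sorted(g for g, v in cand.items() if len(v) == top)
            g = best[int(rng.integers(len(best)))]
            aid = pools[g].pop()
            assignment[aid] = slide
            in_slide.append(g)

    t["slide_id"] = t["animal_id"].map(assignment)
    pos = np.empty(len(t), dtype=int)
    for slide in range(n_slides):
        idx = np.flatnonzero(t["slide_id"].to_numpy() == slide)
        pos[idx] = rng.permutation(len(idx))
    t["slide_position"] = pos
    order = np.empty(len(t), dtype=int)
    k = 0
    for slide in rng.permutation(n_slides):
        idx = np.flatnonzero(t["slide_id"].to_numpy() == slide)
        for i in rng.permutation(idx):
            order[i] = k
            k += 1
    t["acquisition_order"] = order
    return StudyDesign(t).validate()


def qc_metabolite_ratio(profiles: pd.DataFrame, numerator_mz: float,
                        denominator_mz: float, times: dict) -> dict:
    """Per-animal whole-section intensity ratio vs post-mortem time.

    *times* maps animal_id -> post-mortem minutes.  Returns per-animal
    ratios plus the Pearson correlation with time; a zero-variance ratio
    vector is reported as r = 0 with ``degenerate=True``.
    """
    ratios = {}
    excluded = []
    for aid, sub in profiles.groupby("animal_id"):
        def wmean(mz):
            s = sub[np.isclose(sub["feature_mz"], mz)]
            if s.empty:
                raise ValidationError(f"feature {mz} absent from profiles")
            return np.average(s["value"], weights=s["n_pixels"])
        num, den = wmean(numerator_mz), wmean(denominator_mz)
        if den <= 0:
            excluded.append(aid)
            continue
        ratios[aid] = float(num / den)
    common = [a for a in ratios if a in times]
    r_vec = np.array([ratios[a] for a in common])
    t_vec = np.array([times[a] for a in common])
    out = {"ratios": ratios, "excluded": excluded, "n": len(common)}
    if len(common) < 3 or np.allclose(r_vec.std(), 0) or np.allclose(t_vec.std(), 0):
        out.update({"r": 0.0, "p": 1.0, "degenerate": True})
        return out
    r, p = stats.pearsonr(r_vec, t_vec)
    out.update({"r": float(r), "p": float(p), "degenerate": False})
    return out
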