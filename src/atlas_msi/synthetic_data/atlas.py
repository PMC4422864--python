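"""Toy coronal-section atlas generator.

Sections carry the four ROIs (cortex, striatum, hippocampus, thalamus) plus
an "other brain tissue" label and a hemisphere midline.  The hippocampus
maximum horizontal cord length grows strictly with section index so that
atlas-section selection is identifiable by construction.
"""
from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..core_model_io.model import AtlasSection, ValidationError

__all__ = ["LEGEND", "generate_atlas"]

LEGEND = {1: "cortex", 2: "striatum", 3: "hippocampus", 4: "thalamus", 5: "other"}

#: grayscale level per label (0 = background)
_GRAY = {0: 0.0, 1: 0.75, 2: 0.55, 3: 0.9, 4: 0.4, 5: 0.6}

MIN_SHAPE = (48, 64)


def _ellipse(yy, xx, cy, cx, ay, ax):
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def generate_atlas(n_sections: int, shape=(64, 96), seed: int = 0,
                   ap_range=(-1.22, -1.94), pad: int = 0):
    """Generate *n_sections* toy atlas sections.

    Returns ``(sections, truth)`` where truth records per-section
    hippocampus cord lengths and anteroposterior positions.  *pad* adds an
    empty border (px) around each section so that large planted
    deformations keep the whole brain in frame.
    """
    if n_sections < 1:
        raise ValidationError("n_sections must be >= 1")
    h, w = shape
    if h < MIN_SHAPE[0] or w < MIN_SHAPE[1]:
        raise ValidationError(
            f"shape {shape} too small to draw all regions (min {MIN_SHAPE})")

    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    brain = _ellipse(yy, xx, cy, cx, 0.42 * h, 0.41 * w)
    inner = _ellipse(yy, xx, cy, cx, 0.33 * h, 0.32 * w)

    ap_mm = (np.linspace(*ap_range, n_sections) if n_sections > 1
             else np.array([np.mean(ap_range)]))
    sections, cords = [], []
    for k in range(n_sections):
        labels = np.zeros((h, w), dtype=np.int32)
        labels[brain] = 5
        labels[brain & ~inner] = 1  # cortex ring

        # hippocampus: shallow arched band, width strictly increasing with k
        width_k = int(round(w * (0.22 + 0.09 * k)))
        if width_k >= int(2 * 0.32 * w) - 2:
            raise ValidationError(
                f"section {k}: hippocampus width exceeds inner brain extent; "
                "reduce n_sections or enlarge shape")
        thick = max(6, h // 7)
        curv = thick * 0.5
        u = (xx - cx) / (width_k / 2.0)
        y0 = 0.36 * h + curv * u**2
        hipp = (np.abs(u) <= 1.0) & (yy >= y0) & (yy <= y0 + thick) & inner
        labels[hipp & (labels == 5)] = 3

        # thalamus: central ellipse below the hippocampus
        thal = _ellipse(yy, xx, 0.64 * h, cx, 0.11 * h, 0.15 * w)
        labels[thal & (labels == 5)] = 4

        # striatum: two lateral ellipses
        for sx in (cx - 0.22 * w, cx + 0.22 * w):
            stri = _ellipse(yy, xx, 0.42 * h, sx, 0.09 * h, 0.075 * w)
            labels[stri & (labels == 5)] = 2

        for lab in (1, 2, 3, 4):
            if not (labels == lab).any():
                raise ValidationError(f"section {k}: region {LEGEND[lab]} empty")

        rng = np.random.default_rng(None if seed is None else seed + 1000 * k)
        image = np.zeros((h, w))
        for lab, g in _GRAY.items():
            image[labels == lab] = g
        image += 0.06 * np.exp(-(((yy - cy) / (0.5 * h)) ** 2 +
                                 ((xx - cx) / (0.5 * w)) ** 2))
        image[~brain] = 0.0
        # strong-ish smooth texture gives local registration something to track
        texture = ndimage.gaussian_filter(rng.normal(0, 1, (h, w)), 1.5)
        image += 0.06 * texture * brain
        image = ndimage.gaussian_filter(image, 0.8)
        image = np.clip(image, 0, 1)

        if pad:
            image = np.pad(image, pad)
            labels = np.pad(labels, pad)
        sec = AtlasSection(image=image, labels=labels, legend=dict(LEGEND),
                           ap_mm=float(ap_mm[k]), midline_col=w // 2 + pad,
                           section_id=f"atlas{k:03d}").validate()
        sections.append(sec)
        from ..registration import cord_length  # local import avoids cycle at module load
        cords.append(cord_length(labels == 3))

    if any(b <= a for a, b in zip(cords[:-1], cords[1:])):
        raise ValidationError(f"hippocampus cord lengths not strictly increasing: {cords}")
    truth = {"cord_lengths": cords, "ap_mm": ap_mm.tolist(),
             "region_pixel_counts": [
                 {LEGEND[lab]: int((s.labels == lab).sum()) for lab in LEGEND}
                 for s in sections]}
    return sections, truth
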