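"""Phantom section generation: geometric deformation of an atlas section.

The *truth* transform maps atlas-frame points into the section frame,
``T(p) = A(p + D(p))`` (the exact convention the registration module
recovers), so serialized truth transforms map atlas landmarks onto section
landmarks exactly.  The section image itself is rendered through the
numerically inverted transform.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..core_model_io.model import AtlasSection, ValidationError
from ..registration import SectionTransform, build_affine, _invert_affine, _apply_affine

__all__ = ["DeformSpec", "generate_section", "roi_landmarks", "invert_transform_points"]


@dataclass
class DeformSpec:
    rotation_deg: float = 0.0
    scale_x: float = 1.0
    scale_y: float = 1.0
    shear: float = 0.0
    translate_px: tuple = (0.0, 0.0)
    bspline_amplitude_px: float = 0.0
    bspline_grid: tuple = (4, 4)  # (nx, ny) control points
    seed: int = 0

    def __post_init__(self):
        if self.scale_x <= 0 or self.scale_y <= 0:
            raise ValidationError("scales must be positive")
        if self.bspline_amplitude_px < 0:
            raise ValidationError("bspline amplitude must be >= 0")

    @classmethod
    def random(cls, rng, max_translate=5.0, max_rotation=5.0, max_scale=0.05,
               max_shear=0.05, bspline_amplitude=2.0, bspline_grid=(4, 4)):
        return cls(
            rotation_deg=rng.uniform(-max_rotation, max_rotation),
            scale_x=float(np.exp(rng.uniform(-max_scale, max_scale))),
            scale_y=float(np.exp(rng.uniform(-max_scale, max_scale))),
            shear=rng.uniform(-max_shear, max_shear),
            translate_px=(rng.uniform(-max_translate, max_translate),
                          rng.uniform(-max_translate, max_translate)),
            bspline_amplitude_px=bspline_amplitude,
            seed=int(rng.integers(0, 2**31 - 1)),
        )

    def to_transform(self, shape) -> SectionTransform:
        h, w = shape
        center = ((w - 1) / 2.0, (h - 1) / 2.0)
        affine = build_affine(self.rotation_deg, self.scale_x, self.scale_y,
                              self.shear, self.translate_px, center)
        nx, ny = self.bspline_grid
        rng = np.random.default_rng(self.seed)
        disp = rng.uniform(-self.bspline_amplitude_px, self.bspline_amplitude_px,
                           size=(max(ny, 2), max(nx, 2), 2))
        # pin the border control points so tissue is not pushed out of frame
        disp[0, :, :] = disp[-1, :, :] = disp[:, 0, :] = disp[:, -1, :] = 0.0
        if self.bspline_amplitude_px == 0:
            disp[:] = 0.0
        gx = max(nx, 2)
        gy = max(ny, 2)
        return SectionTransform(
            affine=affine,
            bspline_disp=disp,
            control_origin=(0.0, 0.0),
            control_spacing=((w - 1) / (gx - 1), (h - 1) / (gy - 1)),
            shape=(h, w),
        )


def invert_transform_points(tf: SectionTransform, pts, n_iter: int = 25):
    """Numerically invert ``T(p) = A(p + D(p))`` at section-frame points."""
    r = _apply_affine(_invert_affine(tf.affine), np.asarray(pts, dtype=float))
    p = r.copy()
    for _ in range(n_iter):
        p = r - tf.displacement(p)
    return p


def roi_landmarks(section: AtlasSection, min_count: int = 8) -> np.ndarray:
    """Region-boundary extrema landmarks, (N, 2) in (x, y); N >= min_count."""
    pts = []
    for roi in ("cortex", "striatum", "hippocampus", "thalamus"):
        mask = section.roi_mask(roi)
        ys, xs = np.nonzero(mask)
        for idx in (xs.argmin(), xs.argmax(), ys.argmin(), ys.argmax()):
            pts.append((int(xs[idx]), int(ys[idx])))
    uniq = sorted(set(pts))
    if len(uniq) < min_count:
        raise ValidationError(f"only {len(uniq)} distinct landmarks found")
    return np.asarray(uniq, dtype=float)


def generate_section(atlas_section: AtlasSection, deform: DeformSpec):
    """Deform an atlas section into a phantom 'histology' section.

    Returns ``(image, labels, landmark_pairs, transform)`` where
    *landmark_pairs* is a list of (atlas_xy, section_xy) and *transform* is
    the serializable truth transform (atlas -> section frame).
    """
    atlas_section.validate()
    shape = atlas_section.labels.shape
    tf = deform.to_transform(shape)

    atlas_lm = roi_landmarks(atlas_section)
    section_lm = tf.apply(atlas_lm)
    pairs = [(tuple(a), tuple(s)) for a, s in zip(atlas_lm, section_lm)]

    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w]
    q = np.stack([cols.ravel(), rows.ravel()], axis=1).astype(float)
    p = invert_transform_points(tf, q)
    px, py = p[:, 0], p[:, 1]

    image = ndimage.map_coordinates(atlas_section.image, [py, px], order=1,
                                    mode="constant", cval=0.0).reshape(h, w)
    labels = ndimage.map_coordinates(atlas_section.labels, [py, px], order=0,
                                     mode="constant", cval=0).reshape(h, w)

    lys, lxs = np.nonzero(atlas_section.labels > 0)
    fw = tf.apply(np.stack([lxs, lys], axis=1).astype(float))
    inside = ((fw[:, 0] >= 0) & (fw[:, 0] <= w - 1) &
              (fw[:, 1] >= 0) & (fw[:, 1] <= h - 1))
    if inside.mean() < 0.9:
        raise ValidationError(
            f"deformation pushed {100 * (1 - inside.mean()):.1f}% of labeled "
            "pixels out of frame (>10% allowed)")
    return image, labels, pairs, tf
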