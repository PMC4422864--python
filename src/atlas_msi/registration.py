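"""Atlas-section selection and two-stage (affine + B-spline) registration.

Transforms map points of the *atlas* (fixed) frame into the *section*
(moving) frame, the pull-back convention used to resample section images
and MSI cubes onto the atlas grid:  ``out[p] = section[T(p)]``.

Functionally the stored map is ``T(p) = A(p + D(p))`` where ``A`` is the
affine stage and ``D`` the B-spline displacement field evaluated in the
atlas frame (the B-spline stage refines the affine-resampled image).
Points are ``(x, y)`` = (column, row).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize
from scipy.interpolate import RectBivariateSpline
from skimage.registration import optical_flow_ilk

from .core_model_io.model import AtlasSection, DataCube, ValidationError

__all__ = [
    "SectionTransform",
    "RegistrationReport",
    "build_affine",
    "identity_affine",
    "cord_length",
    "select_atlas_section",
    "register_affine",
    "register_bspline",
    "register_section",
    "apply_transform",
    "warp_image",
    "evaluate_registration",
]


def build_affine(rotation_deg=0.0, scale_x=1.0, scale_y=1.0, shear=0.0,
                 translate=(0.0, 0.0), center=(0.0, 0.0)) -> np.ndarray:
    """2x3 affine (acting on (x, y) column vectors) about *center*:
    rotation . shear . scale, plus translation."""
    if scale_x <= 0 or scale_y <= 0:
        raise ValidationError("scales must be positive")
    th = np.deg2rad(rotation_deg)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    K = np.array([[1.0, shear], [0.0, 1.0]])
    S = np.diag([scale_x, scale_y])
    M = R @ K @ S
    c = np.asarray(center, dtype=float)
    b = c - M @ c + np.asarray(translate, dtype=float)
    return np.hstack([M, b[:, None]])


def identity_affine() -> np.ndarray:
    return np.hstack([np.eye(2), np.zeros((2, 1))])


def _apply_affine(affine, pts):
    pts = np.asarray(pts, dtype=float)
    return pts @ affine[:, :2].T + affine[:, 2]


def _invert_affine(affine):
    M = affine[:, :2]
    if abs(np.linalg.det(M)) < 1e-12:
        raise ValidationError("affine is singular")
    Mi = np.linalg.inv(M)
    return np.hstack([Mi, (-Mi @ affine[:, 2])[:, None]])


@dataclass
class SectionTransform:
    """Affine plus B-spline displacement grid mapping atlas -> section frame."""

    affine: np.ndarray
    bspline_disp: np.ndarray | None = None   # (ny, nx, 2) xy displacements, px
    control_origin: tuple = (0.0, 0.0)       # (x0, y0)
    control_spacing: tuple = (1.0, 1.0)      # (sx, sy)
    shape: tuple = (0, 0)                    # atlas-frame (h, w)

    def __post_init__(self):
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (2, 3):
            raise ValidationError("affine must be a 2x3 matrix")
        if abs(np.linalg.det(self.affine[:, :2])) < 1e-12:
            raise ValidationError("affine must be invertible")
        if self.bspline_disp is not None:
            self.bspline_disp = np.asarray(self.bspline_disp, dtype=float)
            if not np.all(np.isfinite(self.bspline_disp)):
                raise ValidationError("B-spline displacements must be finite")

    def _splines(self):
        d = self.bspline_disp
        ny, nx = d.shape[:2]
        x0, y0 = self.control_origin
        sx, sy = self.control_spacing
        xs = x0 + np.arange(nx) * sx
        ys = y0 + np.arange(ny) * sy
        kx = min(3, nx - 1)
        ky = min(3, ny - 1)
        return (
            RectBivariateSpline(ys, xs, d[:, :, 0], kx=kx, ky=ky),
            RectBivariateSpline(ys, xs, d[:, :, 1], kx=kx, ky=ky),
        )

    def displacement(self, pts) -> np.ndarray:
        """B-spline displacement D(p) at atlas-frame points (N, 2)."""
        pts = np.asarray(pts, dtype=float)
        if self.bspline_disp is None or not self.bspline_disp.any():
            return np.zeros_like(pts)
        sx_spl, sy_spl = self._splines()
        dx = sx_spl.ev(pts[:, 1], pts[:, 0])
        dy = sy_spl.ev(pts[:, 1], pts[:, 0])
        return np.stack([dx, dy], axis=1)

    def apply(self, pts) -> np.ndarray:
        """Map atlas-frame points (N, 2) into the section frame."""
        pts = np.asarray(pts, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = _apply_affine(self.affine, pts + self.displacement(pts))
        return out[0] if single else out

    def to_json(self, path) -> None:
        d = {
            "affine": self.affine.tolist(),
            "control_origin": list(self.control_origin),
            "control_spacing": list(self.control_spacing),
            "shape": list(self.shape),
        }
        if self.bspline_disp is not None:
            d["bspline_disp"] = self.bspline_disp.tolist()
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, path) -> "SectionTransform":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            affine=np.asarray(d["affine"]),
            bspline_disp=np.asarray(d["bspline_disp"]) if "bspline_disp" in d else None,
            control_origin=tuple(d["control_origin"]),
            control_spacing=tuple(d["control_spacing"]),
            shape=tuple(d["shape"]),
        )


@dataclass
class RegistrationReport:
    atlas_section_id: str = ""
    metric_before: float = float("nan")
    metric_after: float = float("nan")
    landmark_tre_px: float = float("nan")
    converged: bool = True
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Atlas section selection


def cord_length(mask: np.ndarray) -> int:
    """Longest horizontal run of True pixels along any single row."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValidationError("empty hippocampus mask")
    best = 0
    for row in mask:
        # run lengths via diff of padded cumulative indices
        padded = np.concatenate([[0], row.view(np.uint8), [0]])
        d = np.diff(padded)
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)
        if len(starts):
            best = max(best, int((ends - starts).max()))
    return best


def select_atlas_section(hippocampus_mask: np.ndarray,
                         atlas: list[AtlasSection]) -> tuple[int, dict]:
    """Pick the atlas section whose hippocampus maximum cord length is
    closest to the section's; ties go to the more anterior (larger ap_mm)."""
    target = cord_length(hippocampus_mask)
    scored = []
    for i, sec in enumerate(atlas):
        cl = cord_length(sec.roi_mask("hippocampus"))
        scored.append((abs(cl - target), -sec.ap_mm, i, cl))
    scored.sort()
    diff, _, best, cl = scored[0]
    info = {"section_cord": target, "atlas_cord": cl, "abs_diff": diff,
            "tie": len(scored) > 1 and scored[1][0] == diff}
    return best, info


# ---------------------------------------------------------------------------
# Warping and the MSE metric


def warp_image(image, transform_pts_fn, out_shape, order=1):
    """Resample *image* onto the atlas grid: out[p] = image[T(p)].

    Returns (warped, valid) where valid marks in-frame pixels.
    """
    h, w = out_shape
    rows, cols = np.mgrid[0:h, 0:w]
    pts = np.stack([cols.ravel(), rows.ravel()], axis=1).astype(float)
    q = transform_pts_fn(pts)
    qx, qy = q[:, 0], q[:, 1]
    ih, iw = image.shape[:2]
    valid = (qx >= 0) & (qx <= iw - 1) & (qy >= 0) & (qy <= ih - 1)
    sampled = ndimage.map_coordinates(
        np.asarray(image, dtype=float), [qy, qx], order=order,
        mode="constant", cval=0.0, prefilter=(order > 1))
    sampled[~valid] = np.nan if np.issubdtype(np.asarray(image).dtype, np.floating) else 0
    return sampled.reshape(h, w), valid.reshape(h, w)


def _mse(fixed, warped, valid):
    ok = valid & np.isfinite(warped)
    if ok.sum() < 0.25 * fixed.size:
        return 1e6
    d = fixed[ok] - warped[ok]
    return float(np.mean(d * d))


def _pyramid(img, factor):
    if factor == 1:
        return np.asarray(img, dtype=float)
    sm = ndimage.gaussian_filter(np.asarray(img, dtype=float), sigma=factor / 2.0)
    return sm[::factor, ::factor]


def _image_moments(img):
    """Intensity centroid and covariance of a nonnegative image."""
    img = np.clip(np.asarray(img, dtype=float), 0, None)
    total = img.sum()
    if total <= 0:
        raise ValidationError("blank image in registration input")
    rows, cols = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    cx = (cols * img).sum() / total
    cy = (rows * img).sum() / total
    dx, dy = cols - cx, rows - cy
    cov = np.array([
        [(dx * dx * img).sum(), (dx * dy * img).sum()],
        [(dx * dy * img).sum(), (dy * dy * img).sum()],
    ]) / total
    return np.array([cx, cy]), cov


def _sqrtm2(S):
    vals, vecs = np.linalg.eigh(S)
    return vecs @ np.diag(np.sqrt(np.maximum(vals, 1e-12))) @ vecs.T


def _moments_init(moving, fixed):
    """Moment-matching affine (fixed -> moving): aligns intensity centroids
    and principal axes; a robust basin for the subsequent local search."""
    c_f, S_f = _image_moments(fixed)
    c_m, S_m = _image_moments(moving)
    M = _sqrtm2(S_m) @ np.linalg.inv(_sqrtm2(S_f))
    b = c_m - M @ c_f
    return np.hstack([M, b[:, None]])


def register_affine(moving, fixed, levels=(4, 2, 1), maxiter=200):
    """Estimate the affine (atlas -> section) minimising masked MSE.

    Initialised by intensity-moment matching (centroid + principal axes),
    then refined over a multi-resolution pyramid with a Powell search on
    the affine matrix entries directly.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if not (np.all(np.isfinite(moving)) and np.all(np.isfinite(fixed))):
        raise ValidationError("non-finite pixels in registration input")
    h, w = fixed.shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    report = RegistrationReport()

    w0, v0 = warp_image(moving, lambda p: p, fixed.shape)
    report.metric_before = _mse(fixed, w0, v0)

    A0 = _moments_init(moving, fixed)
    M0, b0 = A0[:, :2], A0[:, 2]
    t0 = M0 @ center + b0 - center  # displacement of the fixed center

    # x -> affine: M = M0 + 0.05 * x[:4]; center displacement t0 + x[4:]
    def x_to_affine(x):
        M = M0 + 0.05 * x[:4].reshape(2, 2)
        t = t0 + x[4:]
        b = center + t - M @ center
        return np.hstack([M, b[:, None]])

    x = np.zeros(6)
    for f in levels:
        fx = _pyramid(fixed, f)
        mv = _pyramid(moving, f)

        def objective(p, f=f, fx=fx, mv=mv):
            A = x_to_affine(p)

            def tf(pts):
                return _apply_affine(A, pts * f) / f

            wv, vv = warp_image(mv, tf, fx.shape)
            return _mse(fx, wv, vv)

        res = optimize.minimize(objective, x, method="Powell",
                                options={"maxiter": maxiter, "xtol": 1e-4, "ftol": 1e-8})
        x = res.x
        if not res.success:
            report.notes.append(f"level {f}: {res.message}")

    affine = x_to_affine(x)
    wv, vv = warp_image(moving, lambda p: _apply_affine(affine, p), fixed.shape)
    report.metric_after = _mse(fixed, wv, vv)
    report.converged = report.metric_after <= report.metric_before + 1e-12
    if not report.converged:  # never worse than identity
        affine = identity_affine()
        report.metric_after = report.metric_before
        report.notes.append("affine stage rejected (metric increased); identity kept")
    return affine, report


def register_bspline(moving, fixed, init_affine, grid_spacing_px=None,
                     flow_radius=5, n_flow_iter=3):
    """B-spline refinement after the affine stage.

    The residual dense displacement between the fixed image and the
    affine-resampled moving image is estimated with iterative Lucas-Kanade
    optical flow (refined over ``n_flow_iter`` warp/re-estimate rounds),
    projected onto a control-point grid (default spacing = image extent / 8
    per axis), and composed as ``T(p) = A(p + D(p))``.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    h, w = fixed.shape
    if grid_spacing_px is None:
        grid_spacing_px = (max(1.0, (w - 1) / 8.0), max(1.0, (h - 1) / 8.0))
    sx, sy = grid_spacing_px
    if sx > w or sy > h:
        raise ValidationError("B-spline control grid coarser than the image")

    affine = np.asarray(init_affine, dtype=float)
    warped, valid = warp_image(moving, lambda p: _apply_affine(affine, p), fixed.shape)
    metric_affine = _mse(fixed, warped, valid)

    rows, cols = np.mgrid[0:h, 0:w]
    pts = np.stack([cols.ravel(), rows.ravel()], axis=1).astype(float)
    D = np.zeros((h, w, 2))  # dense displacement in the fixed frame, xy

    def sample_D(field, p):
        dx = ndimage.map_coordinates(field[:, :, 0], [p[:, 1], p[:, 0]],
                                     order=1, mode="nearest")
        dy = ndimage.map_coordinates(field[:, :, 1], [p[:, 1], p[:, 0]],
                                     order=1, mode="nearest")
        return np.stack([dx, dy], axis=1)

    for _ in range(n_flow_iter):
        def tf_dense(p):
            return _apply_affine(affine, p + sample_D(D, p))

        warped, valid = warp_image(moving, tf_dense, fixed.shape)
        filled = np.where(np.isfinite(warped), warped, fixed)
        # flow u: filled(r + u_row, c + u_col) ~= fixed(r, c)
        flow = optical_flow_ilk(fixed, filled, radius=flow_radius)
        flow = ndimage.gaussian_filter(flow, sigma=(0, 1.5, 1.5))
        u = np.stack([flow[1], flow[0]], axis=-1).reshape(-1, 2)
        # compose: D'(p) = u(p) + D(p + u(p))
        D = (u + sample_D(D, pts + u)).reshape(h, w, 2)

    nx = int(np.floor((w - 1) / sx)) + 1
    ny = int(np.floor((h - 1) / sy)) + 1
    xs = np.round(np.linspace(0, w - 1, max(nx, 2))).astype(int)
    ys = np.round(np.linspace(0, h - 1, max(ny, 2))).astype(int)
    disp = np.zeros((len(ys), len(xs), 2))
    disp[:, :, 0] = D[:, :, 0][np.ix_(ys, xs)]
    disp[:, :, 1] = D[:, :, 1][np.ix_(ys, xs)]

    tf = SectionTransform(
        affine=affine,
        bspline_disp=disp,
        control_origin=(float(xs[0]), float(ys[0])),
        control_spacing=(float(xs[1] - xs[0]), float(ys[1] - ys[0])),
        shape=(h, w),
    )
    wv, vv = warp_image(moving, tf.apply, fixed.shape)
    metric_after = _mse(fixed, wv, vv)
    report = RegistrationReport(metric_before=metric_affine, metric_after=metric_after)
    if metric_after > metric_affine:
        # contraction guarantee: drop the refinement rather than degrade
        tf.bspline_disp = np.zeros_like(tf.bspline_disp)
        report.metric_after = metric_affine
        report.notes.append("B-spline stage rejected (metric increased)")
    return tf, report


def register_section(moving, fixed, grid_spacing_px=None):
    """Affine stage followed by B-spline refinement; returns
    (SectionTransform, RegistrationReport)."""
    affine, rep_a = register_affine(moving, fixed)
    tf, rep_b = register_bspline(moving, fixed, affine, grid_spacing_px)
    rep_b.metric_before = rep_a.metric_before
    rep_b.converged = rep_a.converged and rep_b.metric_after <= rep_a.metric_before + 1e-12
    rep_b.notes = rep_a.notes + rep_b.notes
    return tf, rep_b


# ---------------------------------------------------------------------------
# Applying transforms to images, label maps, and cubes


def apply_transform(obj, transform: SectionTransform, target_shape):
    """Resample a section-frame object onto the atlas grid.

    Grayscale images use linear interpolation (out-of-frame -> NaN); integer
    label maps nearest-neighbour (out-of-frame -> 0); DataCubes are
    resampled channel-wise with linear interpolation and out-of-frame
    pixels flagged invalid rather than zero-filled.
    """
    if isinstance(obj, DataCube):
        return _apply_transform_cube(obj, transform, target_shape)
    arr = np.asarray(obj)
    if arr.ndim != 2:
        raise ValidationError("expected a 2-D image or label map")
    if np.issubdtype(arr.dtype, np.integer):
        warped, valid = warp_image(arr.astype(float), transform.apply, target_shape, order=0)
        warped = np.nan_to_num(warped, nan=0.0).astype(arr.dtype)
        warped[~valid] = 0
        return warped
    warped, valid = warp_image(arr.astype(float), transform.apply, target_shape, order=1)
    warped[~valid] = np.nan
    return warped


def _apply_transform_cube(cube: DataCube, transform, target_shape):
    h, w = target_shape
    src_h = cube.coords[:, 1].max() + 1
    src_w = cube.coords[:, 0].max() + 1
    rows, cols = np.mgrid[0:h, 0:w]
    pts = np.stack([cols.ravel(), rows.ravel()], axis=1).astype(float)
    q = transform.apply(pts)
    qx, qy = q[:, 0], q[:, 1]

    # validity of source pixels as an image
    src_valid = np.zeros((src_h, src_w))
    ok = cube.valid if cube.valid is not None else np.ones(len(cube.coords), bool)
    src_valid[cube.coords[ok, 1], cube.coords[ok, 0]] = 1.0
    vmap = ndimage.map_coordinates(src_valid, [qy, qx], order=1,
                                   mode="constant", cval=0.0)
    in_frame = (qx >= 0) & (qx <= src_w - 1) & (qy >= 0) & (qy <= src_h - 1)
    valid = in_frame & (vmap > 0.99)

    values = np.full((h * w, len(cube.features)), np.nan)
    chan = np.zeros((src_h, src_w))
    for j in range(len(cube.features)):
        chan[:] = 0.0
        chan[cube.coords[ok, 1], cube.coords[ok, 0]] = cube.values[ok, j]
        values[valid, j] = ndimage.map_coordinates(
            chan, [qy[valid], qx[valid]], order=1, mode="constant", cval=0.0)

    out = DataCube(
        coords=np.stack([cols.ravel(), rows.ravel()], axis=1),
        features=list(cube.features),
        values=values,
        valid=valid,
        transform_applied=True,
        provenance=list(cube.provenance),
        meta=dict(cube.meta),
    )
    out.log("apply_transform: resampled onto atlas grid "
            f"({h}x{w}); {int(valid.sum())} valid pixels")
    return out.validate()


def evaluate_registration(transform: SectionTransform, landmark_pairs,
                          raster_um: float = 100.0) -> dict:
    """Landmark target-registration-error statistics in px and µm.

    *landmark_pairs* is a sequence of (atlas_xy, section_xy) pairs.
    """
    pairs = list(landmark_pairs)
    if len(pairs) < 3:
        raise ValidationError("need at least 3 landmark pairs")
    atlas_pts = np.asarray([p[0] for p in pairs], dtype=float)
    section_pts = np.asarray([p[1] for p in pairs], dtype=float)
    mapped = transform.apply(atlas_pts)
    err = np.linalg.norm(mapped - section_pts, axis=1)
    return {
        "mean_px": float(err.mean()),
        "max_px": float(err.max()),
        "mean_um": float(err.mean() * raster_um),
        "max_um": float(err.max() * raster_um),
        "n": len(pairs),
    }
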