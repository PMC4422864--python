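"""Per-spectrum conditioning and cross-sample m/z alignment.

Order of operations per pixel: Gauss smoothing -> TopHat baseline
subtraction -> TIC normalization, with the alignment (recalibration) model
fitted on per-sample mean spectra and applied to every pixel's m/z axis.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .core_model_io.model import MSIDataset, ValidationError

__all__ = [
    "PreprocConfig",
    "AlignmentModel",
    "gauss_smooth",
    "tophat_baseline",
    "tic_normalize",
    "preprocess_dataset",
    "align_spectra",
    "ZeroTICError",
    "CLASS_MATCH_TOL",
]

#: Class presets for smoothing (width in Da, number of cycles).
CLASS_SMOOTH = {
    "metabolite": (0.02, 2),
    "peptide": (0.02, 2),
    "protein": (2.0, 4),
}

#: Peak matching tolerance for alignment, per class (Da).
CLASS_MATCH_TOL = {"metabolite": 0.1, "peptide": 0.3, "protein": 2.0}


@dataclass
class PreprocConfig:
    gauss_width_da: float = 0.02
    gauss_cycles: int = 2
    tophat_window_da: float | None = None  # default: 25 x gauss_width_da

    def __post_init__(self):
        if self.gauss_width_da <= 0:
            raise ValidationError("gauss_width_da must be > 0")
        if self.gauss_cycles < 1:
            raise ValidationError("gauss_cycles must be >= 1")
        if self.tophat_window_da is None:
            self.tophat_window_da = 25.0 * self.gauss_width_da
        if self.tophat_window_da <= self.gauss_width_da:
            raise ValidationError("tophat_window_da must exceed gauss_width_da")

    @classmethod
    def for_class(cls, molecular_class: str, **overrides) -> "PreprocConfig":
        width, cycles = CLASS_SMOOTH[molecular_class]
        kw = {"gauss_width_da": width, "gauss_cycles": cycles}
        kw.update(overrides)
        return cls(**kw)


class ZeroTICError(ValidationError):
    """Raised for a spectrum with no positive intensity (pixel is to be
    flagged and excluded downstream, never silently zero-filled)."""


def _grid_spacing(mz_axis) -> float:
    d = np.diff(mz_axis)
    return float(d.mean())


def gauss_smooth(spectrum, mz_axis, config: PreprocConfig):
    """Gaussian smoothing: convolution with a kernel of sigma =
    ``gauss_width_da``, applied ``gauss_cycles`` times.  Total intensity is
    conserved up to boundary truncation."""
    spectrum = np.asarray(spectrum, dtype=float)
    spacing = _grid_spacing(mz_axis)
    if spacing > config.gauss_width_da + 1e-12:
        raise ValidationError(
            f"grid spacing {spacing:.4g} Da coarser than kernel width "
            f"{config.gauss_width_da:.4g} Da"
        )
    sigma_pts = config.gauss_width_da / spacing
    out = spectrum
    for _ in range(config.gauss_cycles):
        out = ndimage.gaussian_filter1d(out, sigma_pts, mode="nearest", truncate=8.0)
    return out


def tophat_baseline(spectrum, mz_axis, config: PreprocConfig):
    """Morphological TopHat: spectrum minus its opening with a flat
    structuring element of width ``tophat_window_da``."""
    spectrum = np.asarray(spectrum, dtype=float)
    spacing = _grid_spacing(mz_axis)
    size = max(3, int(round(config.tophat_window_da / spacing)))
    if size > len(spectrum):
        raise ValidationError(
            f"TopHat window ({size} points) wider than spectrum ({len(spectrum)})"
        )
    opened = ndimage.grey_opening(spectrum, size=size, mode="nearest")
    out = spectrum - opened
    return np.maximum(out, 0.0)


def tic_normalize(spectrum):
    """Scale a spectrum to unit total ion count."""
    spectrum = np.asarray(spectrum, dtype=float)
    tic = spectrum.sum()
    if tic <= 0:
        raise ZeroTICError("zero-TIC spectrum; pixel must be flagged, not zero-filled")
    return spectrum / tic


def preprocess_dataset(dataset: MSIDataset, config: PreprocConfig | None = None,
                       normalize: bool = True) -> MSIDataset:
    """Smooth + baseline-subtract (+ TIC-normalize) every pixel of a
    profile-mode dataset.  Zero-TIC pixels are dropped and recorded in
    ``meta['excluded_pixels']``."""
    if dataset.centroided:
        raise ValidationError("preprocessing operates on profile-mode spectra")
    if config is None:
        config = PreprocConfig.for_class(dataset.meta.get("molecular_class", "metabolite"))
    mz = dataset.mz_axis
    spacing = _grid_spacing(mz)
    sigma_pts = config.gauss_width_da / spacing
    if spacing > config.gauss_width_da + 1e-12:
        raise ValidationError("grid spacing coarser than smoothing kernel")
    size = max(3, int(round(config.tophat_window_da / spacing)))

    # vectorized across pixels: filter along the m/z axis; float32 input
    # stays float32 to keep large studies within memory
    arr = np.asarray(dataset.intensities)
    out = arr.astype(arr.dtype if arr.dtype == np.float32 else np.float64)
    for _ in range(config.gauss_cycles):
        out = ndimage.gaussian_filter1d(out, sigma_pts, axis=1, mode="nearest", truncate=8.0)
    opened = ndimage.grey_opening(out, size=(1, size), mode="nearest")
    out = np.maximum(out - opened, 0.0)

    tic = out.sum(axis=1)
    keep = tic > 0
    excluded = dataset.coords[~keep].tolist()
    out = out[keep]
    if normalize:
        out = out / tic[keep, None]
    meta = dict(dataset.meta)
    meta["excluded_pixels"] = excluded
    meta["preprocessed"] = True
    return MSIDataset(coords=dataset.coords[keep], mz_axis=mz.copy(),
                      intensities=out, meta=meta).validate()


def resample_dataset(dataset: MSIDataset, grid) -> MSIDataset:
    """Linear-interpolate every pixel's spectrum onto a common m/z grid
    (used after recalibration so datasets share one axis again)."""
    if dataset.centroided:
        raise ValidationError("resampling operates on profile-mode spectra")
    grid = np.asarray(grid, dtype=float)
    src = np.asarray(dataset.mz_axis, dtype=float)
    inten = np.asarray(dataset.intensities)
    out = np.empty((inten.shape[0], grid.size),
                   dtype=inten.dtype if inten.dtype == np.float32 else np.float64)
    for i in range(inten.shape[0]):
        out[i] = np.interp(grid, src, inten[i], left=0.0, right=0.0)
    return MSIDataset(coords=dataset.coords, mz_axis=grid.copy(),
                      intensities=out, meta=dict(dataset.meta)).validate()


# ---------------------------------------------------------------------------
# Cross-sample alignment


@dataclass
class AlignmentModel:
    """Per-sample linear m/z recalibration fitted on common anchor peaks."""

    anchor_mzs: list[float]
    coeffs: dict[str, tuple[float, float]] = field(default_factory=dict)  # id -> (slope, offset)
    presence_fraction: float = 0.85

    def apply(self, sample_id: str, mz_axis):
        slope, offset = self.coeffs[sample_id]
        return slope * np.asarray(mz_axis, dtype=float) + offset

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "anchor_mzs": self.anchor_mzs,
                    "presence_fraction": self.presence_fraction,
                    "coeffs": {k: list(v) for k, v in self.coeffs.items()},
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "AlignmentModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["anchor_mzs"], {k: tuple(v) for k, v in d["coeffs"].items()},
                   d["presence_fraction"])


def _mean_spectrum_peaks(dataset: MSIDataset, min_rel_height=0.02):
    mean = np.asarray(dataset.intensities).mean(axis=0)
    if mean.max() <= 0:
        return np.empty(0), np.empty(0)
    idx, _ = signal.find_peaks(mean, height=min_rel_height * mean.max())
    return dataset.mz_axis[idx], mean[idx]


def align_spectra(datasets: list[MSIDataset], presence_fraction: float = 0.85,
                  match_tol_da: float | None = None):
    """Fit and apply per-sample linear m/z recalibrations.

    Per-sample mean spectra are peak-picked; peaks are clustered across
    samples within ``match_tol_da``; clusters present in at least
    ``presence_fraction`` of samples become anchors; each sample's
    (slope, offset) is least-squares fitted so its anchor positions map to
    the cluster medians.  Returns ``(model, recalibrated datasets)``.
    """
    if len(datasets) < 2:
        raise ValidationError("alignment needs at least 2 datasets")
    classes = {d.meta.get("molecular_class") for d in datasets}
    if len(classes) > 1:
        raise ValidationError(f"alignment across molecular classes: {classes}")
    if match_tol_da is None:
        match_tol_da = CLASS_MATCH_TOL.get(classes.pop() or "metabolite", 0.1)

    sample_ids = []
    peaks = []
    for i, ds in enumerate(datasets):
        sid = str(ds.meta.get("section_id") or ds.meta.get("animal_id") or i)
        sample_ids.append(sid)
        mzs, heights = _mean_spectrum_peaks(ds)
        peaks.append((mzs, heights))

    # greedy 1-D clustering of all sample peaks
    flat = []
    for si, (mzs, hs) in enumerate(peaks):
        flat.extend((mz, h, si) for mz, h in zip(mzs, hs))
    flat.sort()
    clusters: list[list[tuple]] = []
    for mz, h, si in flat:
        if clusters and mz - clusters[-1][0][0] <= match_tol_da:
            clusters[-1].append((mz, h, si))
        else:
            clusters.append([(mz, h, si)])

    n = len(datasets)
    anchors = []  # (median_mz, {sample: mz})
    for cl in clusters:
        per_sample: dict[int, tuple] = {}
        for mz, h, si in cl:
            # two peaks of one sample in a window: keep the more intense
            if si not in per_sample or h > per_sample[si][1]:
                per_sample[si] = (mz, h)
        if len(per_sample) / n >= presence_fraction:
            med = float(np.median([v[0] for v in per_sample.values()]))
            anchors.append((med, {si: v[0] for si, v in per_sample.items()}))

    if len(anchors) < 3:
        raise ValidationError(
            f"alignment refused: only {len(anchors)} anchor peaks found "
            f"(need >=3 for a stable linear recalibration)"
        )

    model = AlignmentModel(anchor_mzs=[a[0] for a in anchors],
                           presence_fraction=presence_fraction)
    recal = []
    for si, (ds, sid) in enumerate(zip(datasets, sample_ids)):
        obs, ref = [], []
        for med, per_sample in anchors:
            if si in per_sample:
                obs.append(per_sample[si])
                ref.append(med)
        obs, ref = np.asarray(obs), np.asarray(ref)
        # corrected = slope * observed + offset, least squares to medians
        A = np.vstack([obs, np.ones_like(obs)]).T
        (slope, offset), *_ = np.linalg.lstsq(A, ref, rcond=None)
        model.coeffs[sid] = (float(slope), float(offset))
        new_mz = model.apply(sid, ds.mz_axis)
        meta = dict(ds.meta)
        meta["recalibrated"] = True
        recal.append(
            MSIDataset(coords=ds.coords, mz_axis=new_mz,
                       intensities=np.asarray(ds.intensities), meta=meta).validate()
        )
    return model, recal
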