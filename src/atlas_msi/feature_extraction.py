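"""Global base-peak-spectrum feature extraction.

The base peak spectrum (per-bin maximum over every pixel of every sample)
is computed study-wide per molecular class, peaks are picked on it once,
and each section is distilled into a pixels x features image cube.
"""
from __future__ import annotations

import numpy as np
from scipy import signal
from scipy.stats import median_abs_deviation

from .core_model_io.model import DataCube, FeatureDef, MSIDataset, ValidationError

__all__ = [
    "BasePeakSpectrum",
    "compute_base_peak_spectrum",
    "pick_peaks",
    "extract_datacube",
    "variance_stabilize",
]


class BasePeakSpectrum:
    """Shared m/z grid plus the per-bin maximum over all contributing pixels."""

    def __init__(self, mz_axis, values):
        self.mz_axis = np.asarray(mz_axis, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.mz_axis.shape != self.values.shape:
            raise ValidationError("base peak spectrum axis/value length mismatch")


def compute_base_peak_spectrum(datasets: list[MSIDataset]) -> BasePeakSpectrum:
    """Per-bin maximum intensity over every pixel of every dataset."""
    if not datasets:
        raise ValidationError("no datasets")
    ref = np.asarray(datasets[0].mz_axis, dtype=float)
    values = np.zeros_like(ref)
    for ds in datasets:
        if ds.centroided:
            raise ValidationError("base peak spectrum requires profile-mode data")
        mz = np.asarray(ds.mz_axis, dtype=float)
        if mz.shape != ref.shape or not np.allclose(mz, ref, atol=1e-6):
            raise ValidationError("datasets must share a common (resampled) m/z grid")
        values = np.maximum(values, np.asarray(ds.intensities).max(axis=0))
    return BasePeakSpectrum(ref, values)


def pick_peaks(bps: BasePeakSpectrum, snr_min: float = 3.0,
               min_separation_da: float | None = None,
               gauss_width_da: float = 0.02) -> list[FeatureDef]:
    """Pick local maxima on the base peak spectrum.

    Noise is estimated as 1.4826 x MAD of the detrended spectrum; windows
    are the contiguous bins above half-maximum, clipped so neighbouring
    windows stay disjoint.
    """
    v = bps.values
    mz = bps.mz_axis
    if v.max() <= 0:
        return []
    if min_separation_da is None:
        min_separation_da = 4.0 * gauss_width_da
    spacing = float(np.diff(mz).mean())
    min_sep_pts = max(1, int(round(min_separation_da / spacing)))

    detrended = v - signal.medfilt(v, kernel_size=min(len(v) // 2 * 2 - 1, 201))
    noise = 1.4826 * median_abs_deviation(detrended)
    if noise <= 0:
        noise = max(1e-12, 1.4826 * median_abs_deviation(v[v > 0]) or v.max() * 1e-6)

    # SNR gate on the *detrended* spectrum: the per-bin max over many noisy
    # pixels rides on a smooth envelope that must not count as signal
    idx, props = signal.find_peaks(detrended, height=snr_min * noise,
                                   prominence=snr_min * noise, distance=min_sep_pts)
    if len(idx) == 0:
        return []

    feats = []
    half = min_sep_pts / 2.0
    for k, i in enumerate(idx):
        apex = v[i]
        # walk out to half-maximum
        lo_i = i
        while lo_i > 0 and v[lo_i - 1] >= apex / 2 and i - (lo_i - 1) <= min_sep_pts:
            lo_i -= 1
        hi_i = i
        while hi_i < len(v) - 1 and v[hi_i + 1] >= apex / 2 and (hi_i + 1) - i <= min_sep_pts:
            hi_i += 1
        lo = max(mz[lo_i] - spacing / 2, mz[i] - half * spacing)
        hi = min(mz[hi_i] + spacing / 2, mz[i] + half * spacing)
        # enforce disjoint windows against previous feature
        if feats and lo < feats[-1].hi:
            mid = (mz[idx[k - 1]] + mz[i]) / 2
            prev = feats[-1]
            feats[-1] = FeatureDef(prev.center_mz, prev.lo, min(prev.hi, mid), prev.snr)
            lo = max(lo, mid)
        feats.append(FeatureDef(float(mz[i]), float(lo), float(hi), float(apex / noise)))
    return feats


def extract_datacube(dataset: MSIDataset, features: list[FeatureDef]) -> DataCube:
    """Sum each pixel's intensities inside every feature window."""
    n = dataset.n_pixels
    values = np.zeros((n, len(features)))
    if dataset.centroided:
        for fi, f in enumerate(features):
            for pi in range(n):
                mz = np.asarray(dataset.mz_axis[pi])
                sel = (mz >= f.lo) & (mz <= f.hi)
                values[pi, fi] = np.asarray(dataset.intensities[pi])[sel].sum()
    else:
        mz = dataset.mz_axis
        lo_mz, hi_mz = float(mz[0]), float(mz[-1])
        inten = np.asarray(dataset.intensities)
        for fi, f in enumerate(features):
            if f.hi < lo_mz or f.lo > hi_mz:
                raise ValidationError(
                    f"feature window ({f.lo:.4f}, {f.hi:.4f}) outside dataset "
                    f"mass range ({lo_mz:.4f}, {hi_mz:.4f})"
                )
            sel = (mz >= f.lo) & (mz <= f.hi)
            values[:, fi] = inten[:, sel].sum(axis=1)
    cube = DataCube(coords=dataset.coords.copy(), features=list(features),
                    values=values, meta=dict(dataset.meta))
    cube.log(
        "extract_datacube: windows="
        + ";".join(f"{f.lo:.4f}-{f.hi:.4f}" for f in features)
    )
    return cube.validate()


def variance_stabilize(cube: DataCube, molecular_class: str | None = None,
                       c: float = 1.0, variant: str = "log2p1") -> DataCube:
    """Variance-stabilizing transform for Poisson-like intensities.

    Metabolite cubes get ``log2(1 + c*x)`` (or the configured variant);
    peptide/protein cubes are returned unchanged apart from a provenance
    note (the log transform is appropriate only for the high-count
    metabolite data).
    """
    molecular_class = molecular_class or cube.meta.get("molecular_class", "metabolite")
    if np.nanmin(cube.values) < 0:
        raise ValidationError("negative values: variance stabilization expects counts")
    if molecular_class in ("peptide", "protein"):
        out = DataCube(cube.coords, cube.features, cube.values.copy(), cube.valid,
                       cube.transform_applied, list(cube.provenance), dict(cube.meta))
        out.log(f"variance_stabilize: skipped for class {molecular_class}")
        return out
    x = cube.values
    if variant == "log2p1":
        v = np.log2(1.0 + c * x)
    elif variant == "log10p1":
        v = np.log10(1.0 + c * x)
    elif variant == "glog":
        v = np.log2(c * x + np.sqrt((c * x) ** 2 + 1.0))
    else:
        raise ValidationError(f"unknown variance-stabilization variant {variant!r}")
    meta = dict(cube.meta)
    meta["variance_stabilized"] = variant
    out = DataCube(cube.coords, cube.features, v, cube.valid,
                   cube.transform_applied, list(cube.provenance), meta)
    out.log(f"variance_stabilize: {variant}, c={c}")
    return out
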