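"""Shared data model for the MSI analysis pipeline.

All spatial conventions: pixel grids are 0-based, ``x`` is the column index
(increases rightward), ``y`` is the row index (increases downward); image
arrays are indexed ``[row, col]``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_MASS_RANGES",
    "MOLECULAR_CLASSES",
    "ValidationError",
    "MSIDataset",
    "FeatureDef",
    "DataCube",
    "AtlasSection",
    "StudyDesign",
    "REQUIRED_ROIS",
]

#: Default mass ranges (Da) per molecular class.
CLASS_MASS_RANGES: dict[str, tuple[float, float]] = {
    "metabolite": (50.0, 1000.0),
    "peptide": (600.0, 2000.0),
    "protein": (3000.0, 20000.0),
}
MOLECULAR_CLASSES = tuple(CLASS_MASS_RANGES)

REQUIRED_ROIS = ("cortex", "striatum", "hippocampus", "thalamus")


class ValidationError(ValueError):
    """Raised when an object violates a documented invariant."""


@dataclass
class MSIDataset:
    """One tissue section's grid of mass spectra.

    Parameters
    ----------
    coords
        ``(n_pixels, 2)`` integer array of ``(x, y)`` grid coordinates.
    mz_axis
        Shared strictly-increasing m/z grid (profile mode) as a 1-D array,
        or a list of per-pixel centroid m/z arrays (centroid mode).
    intensities
        ``(n_pixels, n_bins)`` nonnegative array aligned to ``mz_axis``
        (profile mode) or a list of per-pixel intensity arrays.
    meta
        Acquisition metadata; see :meth:`validate` for required keys.
    """

    coords: np.ndarray
    mz_axis: np.ndarray | list[np.ndarray]
    intensities: np.ndarray | list[np.ndarray]
    meta: dict = field(default_factory=dict)

    @property
    def centroided(self) -> bool:
        return isinstance(self.mz_axis, list)

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    def validate(self) -> "MSIDataset":
        self.coords = np.asarray(self.coords, dtype=int)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValidationError("coords must be an (n, 2) array of (x, y)")
        if self.coords.shape[0] == 0:
            raise ValidationError("dataset has no pixels")
        if len(np.unique(self.coords, axis=0)) != len(self.coords):
            raise ValidationError("pixel coordinates must be unique")

        if self.centroided:
            if len(self.mz_axis) != len(self.coords):
                raise ValidationError("one centroid list per pixel required")
            for mz, it in zip(self.mz_axis, self.intensities):
                if np.any(np.diff(mz) <= 0):
                    raise ValidationError("centroid m/z values must be strictly increasing")
                if np.any(np.asarray(it) < 0):
                    raise ValidationError("intensities must be nonnegative")
        else:
            self.mz_axis = np.asarray(self.mz_axis, dtype=float)
            self.intensities = np.asarray(self.intensities)
            if np.any(np.diff(self.mz_axis) <= 0):
                raise ValidationError("mz_axis must be strictly increasing")
            if self.intensities.shape != (len(self.coords), len(self.mz_axis)):
                raise ValidationError(
                    f"intensities shape {self.intensities.shape} does not match "
                    f"({len(self.coords)}, {len(self.mz_axis)})"
                )
            if np.any(self.intensities < 0):
                raise ValidationError("intensities must be nonnegative")

        mclass = self.meta.get("molecular_class")
        if mclass is not None:
            if mclass not in CLASS_MASS_RANGES:
                raise ValidationError(f"unknown molecular_class {mclass!r}")
            lo_d, hi_d = CLASS_MASS_RANGES[mclass]
            lo, hi = self.meta.get("mass_range", (lo_d, hi_d))
            # mass_range must stay inside the class default window
            if lo < lo_d - 1e-9 or hi > hi_d + 1e-9 or lo >= hi:
                raise ValidationError(
                    f"mass_range ({lo}, {hi}) inconsistent with class "
                    f"{mclass!r} default ({lo_d}, {hi_d})"
                )
            self.meta.setdefault("mass_range", (lo, hi))
        pol = self.meta.get("polarity")
        if pol is not None and pol not in ("+", "-"):
            raise ValidationError(f"polarity must be '+' or '-', got {pol!r}")
        return self


@dataclass(frozen=True)
class FeatureDef:
    """A picked peak: integration window ``[lo, hi]`` around ``center_mz``."""

    center_mz: float
    lo: float
    hi: float
    snr: float = float("nan")

    def __post_init__(self):
        if not (self.lo < self.center_mz < self.hi):
            raise ValidationError(
                f"feature window ({self.lo}, {self.hi}) must bracket center {self.center_mz}"
            )


@dataclass
class DataCube:
    """Pixels x picked-features intensity matrix for one section.

    ``valid`` marks pixels retained for statistics; pixels mapped out of
    frame by a transform, or with zero TIC, are flagged invalid rather than
    zero-filled.
    """

    coords: np.ndarray
    features: list[FeatureDef]
    values: np.ndarray
    valid: np.ndarray | None = None
    transform_applied: bool = False
    provenance: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def validate(self) -> "DataCube":
        self.coords = np.asarray(self.coords, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.coords), len(self.features)):
            raise ValidationError("values must be (n_pixels, n_features)")
        if self.valid is None:
            self.valid = np.ones(len(self.coords), dtype=bool)
        vals = self.values[self.valid]
        if not self.meta.get("variance_stabilized") and vals.size and np.nanmin(vals) < 0:
            raise ValidationError("cube values must be nonnegative before variance stabilization")
        mzs = [f.center_mz for f in self.features]
        if sorted(mzs) == mzs:
            for a, b in zip(self.features[:-1], self.features[1:]):
                if b.lo < a.hi - 1e-12:
                    raise ValidationError("feature windows must be disjoint")
        return self

    def log(self, entry: str) -> None:
        self.provenance.append(entry)

    def feature_image(self, j: int, shape: tuple[int, int]) -> np.ndarray:
        """Render feature column ``j`` as a 2-D image (NaN where no pixel)."""
        img = np.full(shape, np.nan)
        ok = self.valid
        img[self.coords[ok, 1], self.coords[ok, 0]] = self.values[ok, j]
        return img


@dataclass
class AtlasSection:
    """Reference grayscale image plus integer label map and legend."""

    image: np.ndarray
    labels: np.ndarray
    legend: dict[int, str]
    ap_mm: float = 0.0
    midline_col: int | None = None
    section_id: str = ""

    def validate(self) -> "AtlasSection":
        self.image = np.asarray(self.image, dtype=float)
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("label map must be integer-valued")
        if self.image.shape != self.labels.shape:
            raise ValidationError("image and label map must share a shape")
        present = set(np.unique(self.labels)) - {0}
        missing = sorted(present - set(self.legend))
        if missing:
            raise ValidationError(f"labels present in image but absent from legend: {missing}")
        if self.midline_col is None:
            self.midline_col = self.labels.shape[1] // 2
        return self

    def roi_mask(self, roi: str) -> np.ndarray:
        ids = [k for k, v in self.legend.items() if v == roi]
        if not ids:
            raise ValidationError(f"ROI {roi!r} not in legend")
        return np.isin(self.labels, ids)

    def hemisphere_mask(self, hemisphere: str) -> np.ndarray:
        """Left = columns strictly left of the midline column."""
        cols = np.arange(self.labels.shape[1])
        if hemisphere == "L":
            m = cols < self.midline_col
        elif hemisphere == "R":
            m = cols >= self.midline_col
        else:
            raise ValidationError(f"hemisphere must be 'L' or 'R', got {hemisphere!r}")
        return np.broadcast_to(m, self.labels.shape)


GENOTYPES = ("WT", "R192Q")
CONDITIONS = ("Naive", "Sham", "CSD")

#: Group sizes of the study being emulated (genotype, condition) -> n animals.
DEFAULT_GROUP_SIZES = {
    ("WT", "Naive"): 5,
    ("WT", "Sham"): 6,
    ("WT", "CSD"): 5,
    ("R192Q", "Naive"): 5,
    ("R192Q", "Sham"): 6,
    ("R192Q", "CSD"): 5,
}


@dataclass
class StudyDesign:
    """Animal-level design table (one row per animal)."""

    table: pd.DataFrame

    REQUIRED = ("animal_id", "genotype", "condition")
    OPTIONAL = ("slide_id", "slide_position", "acquisition_order", "postmortem_min")

    def validate(self) -> "StudyDesign":
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValidationError(f"design table missing column {col!r}")
        if t["animal_id"].duplicated().any():
            dup = t.loc[t["animal_id"].duplicated(), "animal_id"].tolist()
            raise ValidationError(f"duplicate animal_ids: {dup}")
        bad_g = set(t["genotype"]) - set(GENOTYPES)
        bad_c = set(t["condition"]) - set(CONDITIONS)
        if bad_g or bad_c:
            raise ValidationError(f"unknown genotype/condition values: {bad_g | bad_c}")
        return self

    @property
    def groups(self) -> pd.Series:
        return self.table["genotype"] + "-" + self.table["condition"]

    @classmethod
    def default(cls, sizes: dict | None = None) -> "StudyDesign":
        """The emulated 32-animal / 6-group design."""
        sizes = sizes or DEFAULT_GROUP_SIZES
        rows = []
        i = 0
        for (gt, cond), n in sizes.items():
            for _ in range(n):
                i += 1
                rows.append({"animal_id": f"m{i:02d}", "genotype": gt, "condition": cond})
        return cls(pd.DataFrame(rows)).validate()

    @classmethod
    def from_csv(cls, path) -> "StudyDesign":
        return cls(pd.read_csv(path)).validate()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)
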