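"""Label-map (PNG/TIFF + JSON legend) reading and writing."""
from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .model import AtlasSection, ValidationError


def read_labelmap(image_path, legend_path) -> AtlasSection:
    """Load an integer label image plus its JSON legend into an AtlasSection.

    The legend JSON maps label value -> region name and may carry optional
    ``_ap_mm``, ``_midline_col``, ``_section_id`` and ``_image`` (grayscale
    companion path, relative to the legend file) entries.
    """
    image_path, legend_path = Path(image_path), Path(legend_path)
    if not image_path.exists():
        raise IOError(f"no such label image: {image_path}")
    labels = np.asarray(iio.imread(image_path))
    if labels.ndim == 3:  # palette/RGB PNGs of identical channels
        if not (labels[..., 0] == labels[..., 1]).all():
            raise ValidationError(f"{image_path}: label image must be single-channel")
        labels = labels[..., 0]
    if not np.issubdtype(labels.dtype, np.integer):
        if np.any(labels != np.round(labels)):
            raise ValidationError(f"{image_path}: label image must be integer-valued")
        labels = labels.astype(int)
    labels = labels.astype(int)

    raw = json.loads(Path(legend_path).read_text())
    legend = {int(k): v for k, v in raw.items() if not k.startswith("_")}
    image = labels.astype(float)
    if "_image" in raw:
        image = np.asarray(iio.imread(legend_path.parent / raw["_image"]), dtype=float)
        image *= float(raw.get("_image_scale", 1.0)) / 65535.0
    sec = AtlasSection(
        image=image,
        labels=labels,
        legend=legend,
        ap_mm=float(raw.get("_ap_mm", 0.0)),
        midline_col=raw.get("_midline_col"),
        section_id=raw.get("_section_id", image_path.stem),
    )
    return sec.validate()


def write_labelmap(section: AtlasSection, image_path, legend_path) -> None:
    """Write label PNG (16-bit), grayscale companion PNG, and legend JSON."""
    image_path, legend_path = Path(image_path), Path(legend_path)
    iio.imwrite(image_path, section.labels.astype(np.uint16))
    gray_path = image_path.with_name(image_path.stem + "_gray.png")
    img = section.image
    scale = img.max() if img.max() > 0 else 1.0
    iio.imwrite(gray_path, np.round(img / scale * 65535).astype(np.uint16))
    raw = {str(k): v for k, v in section.legend.items()}
    raw["_ap_mm"] = section.ap_mm
    raw["_midline_col"] = int(section.midline_col)
    raw["_section_id"] = section.section_id
    raw["_image"] = gray_path.name
    raw["_image_scale"] = float(scale)
    legend_path.write_text(json.dumps(raw, indent=1))
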