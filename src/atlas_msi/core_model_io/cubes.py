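"""HDF5 serialization of image cubes (pixels, features, values, provenance)."""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .model import DataCube, FeatureDef


def write_cube_h5(cube: DataCube, path) -> Path:
    path = Path(path)
    cube.validate()
    with h5py.File(path, "w") as f:
        f.create_dataset("coords", data=cube.coords)
        f.create_dataset("values", data=cube.values)
        f.create_dataset("valid", data=cube.valid.astype(np.uint8))
        feats = np.array([(fd.center_mz, fd.lo, fd.hi, fd.snr) for fd in cube.features])
        f.create_dataset("features", data=feats.reshape(-1, 4))
        f.attrs["transform_applied"] = cube.transform_applied
        f.attrs["provenance"] = json.dumps(cube.provenance)
        f.attrs["meta"] = json.dumps({k: v for k, v in cube.meta.items()
                                      if isinstance(v, (str, int, float, bool))})
    return path


def read_cube_h5(path) -> DataCube:
    with h5py.File(Path(path), "r") as f:
        feats = [FeatureDef(*row) for row in f["features"][()]]
        cube = DataCube(
            coords=f["coords"][()],
            features=feats,
            values=f["values"][()],
            valid=f["valid"][()].astype(bool),
            transform_applied=bool(f.attrs["transform_applied"]),
            provenance=json.loads(f.attrs["provenance"]),
            meta=json.loads(f.attrs["meta"]),
        )
    return cube.validate()
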