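"""Minimal imzML 1.1 reader/writer (continuous and processed binary modes).

The writer emits a standards-shaped ``.imzML`` XML document plus the external
``.ibd`` binary (16-byte UUID header followed by the referenced arrays) and an
optional ``<stem>.meta.yaml`` sidecar for metadata the format cannot carry
(molecular class, animal id, post-mortem time).  The reader accepts the same
subset: singly-referenced external binary arrays, no compression, 32/64-bit
floats.
"""
from __future__ import annotations

import struct
import uuid
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np
import yaml

from .model import MSIDataset, ValidationError

_NS = "http://psi.hupo.org/ms/mzml"

# CV accessions we read/write
_ACC_CONTINUOUS = "IMS:1000030"
_ACC_PROCESSED = "IMS:1000031"
_ACC_UUID = "IMS:1000080"
_ACC_X = "IMS:1000050"
_ACC_Y = "IMS:1000051"
_ACC_OFFSET = "IMS:1000102"
_ACC_ARRLEN = "IMS:1000103"
_ACC_ENCLEN = "IMS:1000104"
_ACC_MZ = "MS:1000514"
_ACC_INT = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_NOCOMP = "MS:1000576"
_ACC_POS = "MS:1000130"
_ACC_NEG = "MS:1000129"

_DTYPES = {_ACC_F64: np.dtype("<f8"), _ACC_F32: np.dtype("<f4")}


def _cv(parent, accession, name, value=""):
    ET.SubElement(
        parent,
        "cvParam",
        cvRef=accession.split(":")[0],
        accession=accession,
        name=name,
        value=str(value),
    )


def write_imzml(dataset: MSIDataset, path, intensity_dtype="f8",
                ibd_uuid: uuid.UUID | None = None) -> Path:
    """Write *dataset* as an imzML/ibd pair; returns the ``.imzML`` path.

    Centroid data is always written in processed mode (lossless, 64-bit);
    profile data in continuous mode with one shared m/z array.  Pass a
    fixed *ibd_uuid* for byte-reproducible output.
    """
    dataset.validate()
    path = Path(path)
    if path.suffix.lower() != ".imzml":
        path = path.with_suffix(".imzML")
    ibd_path = path.with_suffix(".ibd")

    processed = dataset.centroided
    if ibd_uuid is None:
        ibd_uuid = uuid.uuid4()
    int_dtype = np.dtype("<f8") if processed else np.dtype("<" + intensity_dtype)

    offsets = []  # per spectrum: (mz_off, mz_len, int_off, int_len)
    try:
        f = open(ibd_path, "wb")
    except OSError as e:
        raise IOError(f"cannot write ibd file {ibd_path}: {e}") from e
    with f:
        f.write(ibd_uuid.bytes)
        pos = 16
        shared_mz_off = None
        if not processed:
            mz = np.ascontiguousarray(dataset.mz_axis, dtype="<f8")
            f.write(mz.tobytes())
            shared_mz_off = (pos, len(mz))
            pos += mz.nbytes
        for i in range(dataset.n_pixels):
            if processed:
                mz = np.ascontiguousarray(dataset.mz_axis[i], dtype="<f8")
                f.write(mz.tobytes())
                mz_off = (pos, len(mz))
                pos += mz.nbytes
                inten = np.ascontiguousarray(dataset.intensities[i], dtype=int_dtype)
            else:
                mz_off = shared_mz_off
                inten = np.ascontiguousarray(dataset.intensities[i], dtype=int_dtype)
            f.write(inten.tobytes())
            offsets.append((*mz_off, pos, len(inten)))
            pos += inten.nbytes

    root = ET.Element("mzML", xmlns=_NS, version="1.1")
    fdesc = ET.SubElement(root, "fileDescription")
    fcontent = ET.SubElement(fdesc, "fileContent")
    _cv(fcontent, _ACC_PROCESSED if processed else _ACC_CONTINUOUS,
        "processed" if processed else "continuous")
    _cv(fcontent, _ACC_UUID, "universally unique identifier", f"{{{ibd_uuid}}}")

    groups = ET.SubElement(root, "referenceableParamGroupList", count="2")
    g_mz = ET.SubElement(groups, "referenceableParamGroup", id="mzArray")
    _cv(g_mz, _ACC_MZ, "m/z array")
    _cv(g_mz, _ACC_F64, "64-bit float")
    _cv(g_mz, _ACC_NOCOMP, "no compression")
    g_it = ET.SubElement(groups, "referenceableParamGroup", id="intensityArray")
    _cv(g_it, _ACC_INT, "intensity array")
    _cv(g_it, _ACC_F64 if int_dtype.itemsize == 8 else _ACC_F32,
        "64-bit float" if int_dtype.itemsize == 8 else "32-bit float")
    _cv(g_it, _ACC_NOCOMP, "no compression")

    run = ET.SubElement(root, "run", id="run0")
    slist = ET.SubElement(run, "spectrumList", count=str(dataset.n_pixels))
    polarity = dataset.meta.get("polarity")
    for i, (x, y) in enumerate(np.asarray(dataset.coords)):
        spec = ET.SubElement(slist, "spectrum", index=str(i),
                             id=f"spectrum={i}", defaultArrayLength="0")
        if polarity == "+":
            _cv(spec, _ACC_POS, "positive scan")
        elif polarity == "-":
            _cv(spec, _ACC_NEG, "negative scan")
        scan_list = ET.SubElement(spec, "scanList", count="1")
        scan = ET.SubElement(scan_list, "scan")
        # imzML position indices are 1-based
        _cv(scan, _ACC_X, "position x", int(x) + 1)
        _cv(scan, _ACC_Y, "position y", int(y) + 1)
        bal = ET.SubElement(spec, "binaryDataArrayList", count="2")
        mz_off, mz_len, int_off, int_len = offsets[i]
        for ref, off, n, width in (
            ("mzArray", mz_off, mz_len, 8),
            ("intensityArray", int_off, int_len, int_dtype.itemsize),
        ):
            bda = ET.SubElement(bal, "binaryDataArray", encodedLength="0")
            ET.SubElement(bda, "referenceableParamGroupRef", ref=ref)
            _cv(bda, _ACC_OFFSET, "external offset", off)
            _cv(bda, _ACC_ARRLEN, "external array length", n)
            _cv(bda, _ACC_ENCLEN, "external encoded length", n * width)
            ET.SubElement(bda, "binary")

    tree = ET.ElementTree(root)
    ET.indent(tree)
    try:
        tree.write(path, xml_declaration=True, encoding="utf-8")
    except OSError as e:
        raise IOError(f"cannot write imzML file {path}: {e}") from e

    sidecar = {
        k: dataset.meta[k]
        for k in ("molecular_class", "animal_id", "section_id", "raster_um",
                  "mass_range", "postmortem_min", "polarity")
        if k in dataset.meta
    }
    if sidecar:
        if "mass_range" in sidecar:
            sidecar["mass_range"] = [float(v) for v in sidecar["mass_range"]]
        path.with_suffix(".meta.yaml").write_text(yaml.safe_dump(sidecar))
    return path


def _spectrum_records(root):
    for spec in root.iter(f"{{{_NS}}}spectrum"):
        rec = {"polarity": None, "x": None, "y": None, "arrays": {}}
        for cv in spec.iter(f"{{{_NS}}}cvParam"):
            acc = cv.get("accession")
            if acc == _ACC_POS:
                rec["polarity"] = "+"
            elif acc == _ACC_NEG:
                rec["polarity"] = "-"
            elif acc == _ACC_X:
                rec["x"] = int(cv.get("value")) - 1
            elif acc == _ACC_Y:
                rec["y"] = int(cv.get("value")) - 1
        for bda in spec.iter(f"{{{_NS}}}binaryDataArray"):
            ref = bda.find(f"{{{_NS}}}referenceableParamGroupRef")
            kind = ref.get("ref") if ref is not None else None
            info = {}
            for cv in bda.iter(f"{{{_NS}}}cvParam"):
                acc = cv.get("accession")
                if acc == _ACC_OFFSET:
                    info["offset"] = int(cv.get("value"))
                elif acc == _ACC_ARRLEN:
                    info["length"] = int(cv.get("value"))
                elif acc in (_ACC_MZ,):
                    kind = "mzArray"
                elif acc in (_ACC_INT,):
                    kind = "intensityArray"
            rec["arrays"][kind] = info
        yield rec


def read_imzml(path) -> MSIDataset:
    """Read an imzML/ibd pair into an :class:`MSIDataset`.

    Sidecar metadata from ``<stem>.meta.yaml`` is merged in when present.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such imzML file: {path}")
    ibd_path = path.with_suffix(".ibd")
    if not ibd_path.exists():
        raise IOError(f"missing ibd companion for {path}")
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as e:
        raise IOError(f"corrupt imzML file {path}: {e}") from e

    mode = None
    group_dtypes = {}
    for g in root.iter(f"{{{_NS}}}referenceableParamGroup"):
        for cv in g.iter(f"{{{_NS}}}cvParam"):
            if cv.get("accession") in _DTYPES:
                group_dtypes[g.get("id")] = _DTYPES[cv.get("accession")]
    for cv in root.iter(f"{{{_NS}}}cvParam"):
        if cv.get("accession") == _ACC_CONTINUOUS:
            mode = "continuous"
        elif cv.get("accession") == _ACC_PROCESSED:
            mode = "processed"
    if mode is None:
        raise IOError(f"{path}: binary mode (continuous/processed) not declared")

    raw = ibd_path.read_bytes()
    mz_dtype = group_dtypes.get("mzArray", np.dtype("<f8"))
    int_dtype = group_dtypes.get("intensityArray", np.dtype("<f8"))

    def fetch(info, dtype):
        off, n = info["offset"], info["length"]
        return np.frombuffer(raw, dtype=dtype, count=n, offset=off)

    coords, mzs, intens, polarities = [], [], [], set()
    for rec in _spectrum_records(root):
        coords.append((rec["x"], rec["y"]))
        polarities.add(rec["polarity"])
        mzs.append(fetch(rec["arrays"]["mzArray"], mz_dtype))
        intens.append(fetch(rec["arrays"]["intensityArray"], int_dtype).astype(float))
    if not coords:
        raise IOError(f"{path}: no spectra found")
    polarities.discard(None)
    if len(polarities) > 1:
        raise ValidationError(f"{path}: mixed polarity within one file")

    meta = {}
    sidecar = path.with_suffix(".meta.yaml")
    if sidecar.exists():
        meta.update(yaml.safe_load(sidecar.read_text()) or {})
        if "mass_range" in meta:
            meta["mass_range"] = tuple(meta["mass_range"])
    if polarities:
        meta["polarity"] = polarities.pop()

    coords = np.asarray(coords, dtype=int)
    if mode == "continuous":
        ds = MSIDataset(coords=coords, mz_axis=mzs[0].astype(float),
                        intensities=np.vstack(intens), meta=meta)
    else:
        ds = MSIDataset(coords=coords, mz_axis=[m.astype(float) for m in mzs],
                        intensities=intens, meta=meta)
    return ds.validate()
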