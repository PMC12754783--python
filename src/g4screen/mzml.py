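"""Minimal mzML subset: one MS1 spectrum per file, 64-bit uncompressed
binary arrays. Enough to round-trip the synthetic generator's output
bit-identically and to ingest simple single-spectrum exports.

Not a general mzML implementation: chromatograms, multiple spectra,
numpress and indexed wrappers are out of scope.
"""

from __future__ import annotations

import base64
import struct
import zlib
import xml.etree.ElementTree as ET

import numpy as np

_NS = "http://psi.hupo.org/ms/mzml"

_ACC_MZ = "MS:1000514"
_ACC_INT = "MS:1000515"
_ACC_64 = "MS:1000523"
_ACC_32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NONE = "MS:1000576"


def _encode(arr: np.ndarray) -> str:
    raw = np.asarray(arr, dtype="<f8").tobytes()
    return base64.b64encode(raw).decode("ascii")


def write_mzml(path, mz, intensity, sample_id: str = "synthetic") -> None:
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.shape != intensity.shape:
        raise ValueError("mz and intensity must have equal length")
    root = ET.Element("mzML", xmlns=_NS, version="1.1.0")
    run = ET.SubElement(root, "run", id=sample_id)
    sl = ET.SubElement(run, "spectrumList", count="1")
    sp = ET.SubElement(
        sl, "spectrum", index="0", id=f"scan=1", defaultArrayLength=str(mz.size)
    )
    ET.SubElement(
        sp, "cvParam", accession="MS:1000129", name="negative scan", value=""
    )
    bal = ET.SubElement(sp, "binaryDataArrayList", count="2")
    for acc, name, arr in (
        (_ACC_MZ, "m/z array", mz),
        (_ACC_INT, "intensity array", intensity),
    ):
        bda = ET.SubElement(bal, "binaryDataArray")
        ET.SubElement(bda, "cvParam", accession=_ACC_64, name="64-bit float", value="")
        ET.SubElement(
            bda, "cvParam", accession=_ACC_NONE, name="no compression", value=""
        )
        ET.SubElement(bda, "cvParam", accession=acc, name=name, value="")
        ET.SubElement(bda, "binary").text = _encode(arr)
    ET.ElementTree(root).write(path, xml_declaration=True, encoding="utf-8")


def _decode(bda) -> np.ndarray:
    accs = {cv.get("accession") for cv in bda.iter(f"{{{_NS}}}cvParam")}
    text = bda.find(f"{{{_NS}}}binary").text or ""
    raw = base64.b64decode(text)
    if _ACC_ZLIB in accs:
        raw = zlib.decompress(raw)
    dtype = "<f4" if _ACC_32 in accs else "<f8"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path):
    """Return (mz, intensity) of the first spectrum in the file."""
    tree = ET.parse(path)
    spectrum = tree.getroot().find(f".//{{{_NS}}}spectrum")
    if spectrum is None:
        raise ValueError(f"{path}: no spectrum element found")
    mz = intensity = None
    for bda in spectrum.iter(f"{{{_NS}}}binaryDataArray"):
        accs = {cv.get("accession") for cv in bda.iter(f"{{{_NS}}}cvParam")}
        if _ACC_MZ in accs:
            mz = _decode(bda)
        elif _ACC_INT in accs:
            intensity = _decode(bda)
    if mz is None or intensity is None:
        raise ValueError(f"{path}: missing m/z or intensity array")
    return mz, intensity
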