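"""Reading and writing centroided runs (mzML and MGF).

MGF reading and writing go through pyteomics.  MGF can only carry MS2
scans, so simulated runs that need MS1 traces for XIC work are written as
plain (non-indexed) mzML with uncompressed 64-bit arrays.  mzML parsing
uses the standard-library XML parser (pyteomics' mzML reader needs the
optional ``psims`` package, which is not assumed to be present); the
parser understands the usual cvParam vocabulary — ms level, scan start
time in seconds or minutes, selected ion m/z and charge, 32/64-bit float
arrays, zlib or no compression — not just this module's own output.
"""

from __future__ import annotations

import base64
import struct
import zlib
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Iterable, Optional, Sequence
from xml.sax.saxutils import escape

import numpy as np
from pyteomics import mgf as _mgf

from .spectra import SpectrumRecord

__all__ = ["read_mzml", "read_mgf", "write_mzml", "write_mgf", "read_run"]


def _encode(arr: Sequence[float]) -> str:
    raw = struct.pack(f"<{len(arr)}d", *arr)
    return base64.b64encode(raw).decode("ascii")


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <run id="{run_id}">
    <spectrumList count="{count}">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _binary_block(name: str, accession: str, data: str, unit: str = "") -> str:
    return f"""          <binaryDataArray encodedLength="{len(data)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="{accession}" name="{name}" value=""{unit}/>
            <binary>{data}</binary>
          </binaryDataArray>
"""


def write_mzml(spectra: Iterable[SpectrumRecord], path) -> None:
    """Write spectra as minimal centroided mzML (sorted by retention time)."""
    spectra = sorted(spectra, key=lambda s: (s.rt, s.scan_id))
    run_id = spectra[0].run_id if spectra else "run"
    parts = [_MZML_HEADER.format(run_id=escape(str(run_id)), count=len(spectra))]
    for idx, s in enumerate(spectra):
        level_param = (
            '<cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>'
            if s.ms_level == 1
            else '<cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>'
        )
        precursor = ""
        if s.ms_level >= 2 and s.precursor_mz is not None:
            precursor = f"""        <precursorList count="1">
          <precursor>
            <selectedIonList count="1">
              <selectedIon>
                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{float(s.precursor_mz)!r}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
                <cvParam cvRef="MS" accession="MS:1000041" name="charge state" value="{s.precursor_charge}"/>
              </selectedIon>
            </selectedIonList>
          </precursor>
        </precursorList>
"""
        mz_b = _encode(np.asarray(s.mz, dtype=float))
        it_b = _encode(np.asarray(s.intensity, dtype=float))
        parts.append(
            f"""      <spectrum index="{idx}" id="scan={s.scan_id}" defaultArrayLength="{len(s.mz)}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{s.ms_level}"/>
        {level_param}
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{float(s.rt)!r}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>
          </scan>
        </scanList>
{precursor}        <binaryDataArrayList count="2">
{_binary_block("m/z array", "MS:1000514", mz_b, ' unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"')}{_binary_block("intensity array", "MS:1000515", it_b)}        </binaryDataArrayList>
      </spectrum>
"""
        )
    parts.append(_MZML_FOOTER)
    Path(path).write_text("".join(parts))


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _cvparams(elem) -> dict[str, dict[str, str]]:
    """name -> attribute dict of the element's direct cvParam children."""
    return {
        child.get("name", ""): child.attrib
        for child in elem
        if _localname(child.tag) == "cvParam"
    }


def _decode_binary_array(bda) -> tuple[Optional[str], np.ndarray]:
    """One <binaryDataArray>: returns (array kind, decoded values)."""
    params = _cvparams(bda)
    text = ""
    for child in bda:
        if _localname(child.tag) == "binary":
            text = child.text or ""
    raw = base64.b64decode(text)
    if "zlib compression" in params:
        raw = zlib.decompress(raw)
    dtype = "<f4" if "32-bit float" in params else "<f8"
    values = np.frombuffer(raw, dtype=dtype).astype(float)
    kind = None
    if "m/z array" in params:
        kind = "mz"
    elif "intensity array" in params:
        kind = "intensity"
    return kind, values


def _parse_spectrum(elem, run_id: str, index: int) -> SpectrumRecord:
    params = _cvparams(elem)
    ms_level = int(params.get("ms level", {}).get("value", 1))
    rt = 0.0
    prec_mz = None
    prec_z = None
    arrays: dict[str, np.ndarray] = {}
    for sub in elem.iter():
        name = _localname(sub.tag)
        if name == "scan":
            sp = _cvparams(sub)
            t = sp.get("scan start time")
            if t is not None:
                rt = float(t["value"])
                if t.get("unitName", "") == "minute":
                    rt *= 60.0
        elif name == "selectedIon":
            sp = _cvparams(sub)
            if "selected ion m/z" in sp:
                prec_mz = float(sp["selected ion m/z"]["value"])
            if "charge state" in sp:
                prec_z = int(sp["charge state"]["value"])
        elif name == "binaryDataArray":
            kind, values = _decode_binary_array(sub)
            if kind is not None:
                arrays[kind] = values
    scan_id = elem.get("id", f"index={index}")
    if "scan=" in scan_id:
        scan_id = scan_id.split("scan=")[-1]
    return SpectrumRecord(
        run_id=run_id,
        scan_id=str(scan_id),
        ms_level=ms_level,
        rt=rt,
        precursor_mz=prec_mz,
        precursor_charge=prec_z,
        mz=arrays.get("mz", np.array([])),
        intensity=arrays.get("intensity", np.array([])),
    )


def read_mzml(path) -> list[SpectrumRecord]:
    """Read a centroided mzML file; the run id is the file stem."""
    run_id = Path(path).stem
    out: list[SpectrumRecord] = []
    index = 0
    for _, elem in ET.iterparse(str(path), events=("end",)):
        if _localname(elem.tag) == "spectrum":
            out.append(_parse_spectrum(elem, run_id, index))
            index += 1
            elem.clear()
    out.sort(key=lambda s: (s.rt, s.scan_id))
    return out


def write_mgf(spectra: Iterable[SpectrumRecord], path) -> None:
    """Write MS2 spectra as MGF (MS1 scans are silently skipped)."""
    entries = []
    for s in spectra:
        if s.ms_level != 2:
            continue
        entries.append(
            {
                "m/z array": np.asarray(s.mz, dtype=float),
                "intensity array": np.asarray(s.intensity, dtype=float),
                "params": {
                    "title": f"{s.run_id}.scan={s.scan_id}",
                    "pepmass": (s.precursor_mz,),
                    "charge": f"{s.precursor_charge}+",
                    "rtinseconds": s.rt,
                },
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def read_mgf(path) -> list[SpectrumRecord]:
    """Read MS2 spectra from MGF; the run id is the file stem."""
    run_id = Path(path).stem
    out: list[SpectrumRecord] = []
    with _mgf.read(str(path)) as reader:
        for i, spec in enumerate(reader):
            params = spec["params"]
            charge = params.get("charge")
            z = int(charge[0]) if charge else None
            title = str(params.get("title", f"index={i}"))
            scan_id = title.split("scan=")[-1] if "scan=" in title else str(i)
            out.append(
                SpectrumRecord(
                    run_id=run_id,
                    scan_id=scan_id,
                    ms_level=2,
                    rt=float(params.get("rtinseconds", 0.0)),
                    precursor_mz=float(params["pepmass"][0]),
                    precursor_charge=z,
                    mz=np.asarray(spec["m/z array"], dtype=float),
                    intensity=np.asarray(spec["intensity array"], dtype=float),
                )
            )
    return out


def read_run(path) -> list[SpectrumRecord]:
    """Dispatch on extension: .mzML or .mgf."""
    p = Path(path)
    suffix = p.suffix.lower()
    if suffix == ".mzml":
        return read_mzml(p)
    if suffix == ".mgf":
        return read_mgf(p)
    raise ValueError(f"unsupported run format {suffix!r} (expected .mzML or .mgf)")
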