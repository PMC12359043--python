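"""Minimal mzML 1.1 reader/writer for centroided MS2 spectra.

The writer emits 64-bit float, zlib-compressed, base64 binary arrays with
the MS-level / selected-precursor / scan-time CV params; the reader parses
those plus the common variations (32-bit floats, uncompressed arrays,
minute-valued scan times).  Together they round-trip peak lists bit-exactly.
Not a general-purpose mzML toolkit — raw vendor conversions with exotic
encodings are out of scope.
"""

from __future__ import annotations

import base64
import zlib
from typing import Iterable, Iterator, Sequence
from xml.sax.saxutils import escape

import numpy as np
from lxml import etree

from .spectra import MsnSpectrum

_CV = 'cvRef="MS" accession="{acc}" name="{name}"'


def _b64(arr: np.ndarray) -> str:
    raw = np.asarray(arr, dtype="<f8").tobytes()
    return base64.b64encode(zlib.compress(raw)).decode("ascii")


def _binary_array(arr: np.ndarray, acc: str, name: str, unit: str) -> str:
    data = _b64(arr)
    return (
        f'<binaryDataArray encodedLength="{len(data)}">'
        f'<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float"/>'
        f'<cvParam cvRef="MS" accession="MS:1000574" name="zlib compression"/>'
        f'<cvParam cvRef="MS" accession="{acc}" name="{name}" {unit}/>'
        f"<binary>{data}</binary></binaryDataArray>"
    )


def _spectrum_xml(index: int, s: MsnSpectrum) -> str:
    charge = (
        f'<cvParam cvRef="MS" accession="MS:1000041" name="charge state" value="{s.precursor_charge}"/>'
        if s.precursor_charge
        else ""
    )
    mz_arr = _binary_array(
        s.mz, "MS:1000514", "m/z array", 'unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"'
    )
    int_arr = _binary_array(
        s.intensity,
        "MS:1000515",
        "intensity array",
        'unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"',
    )
    return (
        f'<spectrum index="{index}" id="{escape(s.native_id)}" defaultArrayLength="{s.n_peaks}">'
        f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>'
        f'<cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum"/>'
        f'<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum"/>'
        f"<scanList count=\"1\"><scan>"
        f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{s.retention_time}" '
        f'unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>'
        f"</scan></scanList>"
        f'<precursorList count="1"><precursor><selectedIonList count="1"><selectedIon>'
        f'<cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{s.precursor_mz!r}"/>'
        f"{charge}"
        f"</selectedIon></selectedIonList><activation>"
        f'<cvParam cvRef="MS" accession="MS:1000422" name="beam-type collision-induced dissociation"/>'
        f"</activation></precursor></precursorList>"
        f'<binaryDataArrayList count="2">{mz_arr}{int_arr}</binaryDataArrayList>'
        f"</spectrum>"
    )


def write_mzml(path: str, spectra: Sequence[MsnSpectrum]) -> None:
    """Write centroided MS2 spectra to a minimal standalone mzML file."""
    parts = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '<cvList count="2">'
        '<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" '
        'URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>'
        '<cv id="UO" fullName="Unit Ontology" URI="http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"/>'
        "</cvList>",
        '<fileDescription><fileContent>'
        '<cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum"/>'
        "</fileContent></fileDescription>",
        '<softwareList count="1"><software id="nuclink" version="0.1.0"/></softwareList>',
        '<instrumentConfigurationList count="1">'
        '<instrumentConfiguration id="IC1"/></instrumentConfigurationList>',
        '<dataProcessingList count="1"><dataProcessing id="dp1">'
        '<processingMethod order="1" softwareRef="nuclink"/>'
        "</dataProcessing></dataProcessingList>",
        '<run id="run1" defaultInstrumentConfigurationRef="IC1">',
        f'<spectrumList count="{len(spectra)}" defaultDataProcessingRef="dp1">',
    ]
    for i, s in enumerate(spectra):
        parts.append(_spectrum_xml(i, s))
    parts.extend(["</spectrumList>", "</run>", "</mzML>"])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(parts))


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

class MzmlParseError(RuntimeError):
    """Malformed mzML; the message names the offending spectrum."""


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary(bda: etree._Element, n_expected: int) -> np.ndarray:
    dtype = "<f8"
    compressed = False
    payload = None
    for child in bda:
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            if acc == "MS:1000521":
                dtype = "<f4"
            elif acc == "MS:1000523":
                dtype = "<f8"
            elif acc == "MS:1000574":
                compressed = True
        elif name == "binary":
            payload = child.text or ""
    raw = base64.b64decode(payload) if payload else b""
    if compressed and raw:
        raw = zlib.decompress(raw)
    arr = np.frombuffer(raw, dtype=dtype).astype(np.float64)
    if n_expected and arr.size != n_expected:
        raise ValueError(f"array length {arr.size} != defaultArrayLength {n_expected}")
    return arr


def _cv_value(elem: etree._Element, accession: str):
    for cv in elem.iter():
        if _local(cv.tag) == "cvParam" and cv.get("accession") == accession:
            return cv
    return None


def iter_spectra(path: str) -> Iterator[MsnSpectrum]:
    """Stream MS2 spectra from an mzML file (see :func:`nuclink.spectra.read_ms2`)."""
    import warnings

    for _, elem in etree.iterparse(path, events=("end",), tag="{*}spectrum"):
        sid = elem.get("id", "?")
        try:
            level = _cv_value(elem, "MS:1000511")
            if level is None or int(level.get("value", 0)) != 2:
                continue
            if _cv_value(elem, "MS:1000128") is not None:  # profile spectrum
                warnings.warn(f"skipping profile-mode spectrum {sid}")
                continue
            ion = None
            for child in elem.iter():
                if _local(child.tag) == "selectedIon":
                    ion = child
                    break
            if ion is None:
                continue
            pmz_param = _cv_value(ion, "MS:1000744")
            if pmz_param is None:
                continue
            pmz = float(pmz_param.get("value"))
            charge_param = _cv_value(ion, "MS:1000041")
            charge = int(charge_param.get("value")) if charge_param is not None else None
            if charge == 0:
                charge = None
            rt = 0.0
            rt_param = _cv_value(elem, "MS:1000016")
            if rt_param is not None:
                rt = float(rt_param.get("value", 0.0))
                if rt_param.get("unitName") == "minute":
                    rt *= 60.0
            n = int(elem.get("defaultArrayLength", 0))
            mz_arr = inten_arr = None
            for child in elem.iter():
                if _local(child.tag) == "binaryDataArray":
                    if _cv_value(child, "MS:1000514") is not None:
                        mz_arr = _decode_binary(child, n)
                    elif _cv_value(child, "MS:1000515") is not None:
                        inten_arr = _decode_binary(child, n)
            if mz_arr is None or inten_arr is None:
                raise ValueError("missing m/z or intensity array")
            yield MsnSpectrum(sid, pmz, charge, rt, mz_arr, inten_arr)
        except (TypeError, ValueError) as exc:
            raise MzmlParseError(f"malformed mzML spectrum {sid!r} in {path}: {exc}") from exc
        finally:
            elem.clear()
            parent = elem.getparent()
            while parent is not None and elem.getprevious() is not None:
                del parent[0]
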