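"""mzML 1.1 I/O for centroided MS1 runs.

Both directions are built on lxml: writing emits 64-bit, uncompressed,
base64-encoded binary arrays; the reader streams ``<spectrum>`` elements
with ``iterparse`` and understands 32/64-bit floats with or without zlib
compression. Spectra are modelled as flat centroid lists per scan — enough
for targeted peak-height extraction, with no profile mode or MS2 support.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree

MZML_NS = "http://psi.hupo.org/ms/mzml"


@dataclass
class Spectrum:
    """One centroided MS1 scan: retention time, polarity and sorted peaks."""

    rt: float  # seconds
    polarity: str  # 'positive' | 'negative'
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]


@dataclass
class Run:
    """An RT-ordered sequence of centroided scans plus sample metadata."""

    sample_id: str
    spectra: list[Spectrum]
    role: str = "sample"  # 'sample' | 'blank'
    group: str | None = None
    donor: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ("sample", "blank"):
            raise ValueError(f"unknown run role {self.role!r}")
        rts = [s.rt for s in self.spectra]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError("scan RTs must be strictly increasing")


def _encode(array: np.ndarray) -> str:
    return base64.b64encode(
        struct.pack(f"<{array.size}d", *np.asarray(array, dtype=float))
    ).decode("ascii")


def _cv(parent, accession: str, name: str, value: str = "", **attrs) -> None:
    etree.SubElement(
        parent,
        "cvParam",
        cvRef="MS",
        accession=accession,
        name=name,
        value=value,
        **attrs,
    )


def write_mzml(run: Run, path: str | Path) -> None:
    """Serialize a centroided MS1 run as mzML 1.1."""
    root = etree.Element(
        "mzML",
        nsmap={None: MZML_NS},
        version="1.1.0",
        id=run.sample_id,
    )
    cv_list = etree.SubElement(root, "cvList", count="1")
    etree.SubElement(
        cv_list,
        "cv",
        id="MS",
        fullName="Proteomics Standards Initiative Mass Spectrometry Ontology",
        URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo",
    )
    fdl = etree.SubElement(root, "fileDescription")
    fc = etree.SubElement(fdl, "fileContent")
    _cv(fc, "MS:1000579", "MS1 spectrum")
    _cv(fc, "MS:1000127", "centroid spectrum")

    sw_list = etree.SubElement(root, "softwareList", count="1")
    etree.SubElement(sw_list, "software", id="enviromics", version="0.1.0")
    ic_list = etree.SubElement(root, "instrumentConfigurationList", count="1")
    etree.SubElement(ic_list, "instrumentConfiguration", id="IC1")
    dp_list = etree.SubElement(root, "dataProcessingList", count="1")
    dp = etree.SubElement(dp_list, "dataProcessing", id="DP1")
    pm = etree.SubElement(dp, "processingMethod", order="1", softwareRef="enviromics")
    _cv(pm, "MS:1000544", "Conversion to mzML")

    mzrun = etree.SubElement(
        root, "run", id=run.sample_id, defaultInstrumentConfigurationRef="IC1"
    )
    spec_list = etree.SubElement(
        mzrun,
        "spectrumList",
        count=str(len(run.spectra)),
        defaultDataProcessingRef="DP1",
    )
    for i, s in enumerate(run.spectra):
        spec = etree.SubElement(
            spec_list,
            "spectrum",
            index=str(i),
            id=f"scan={i + 1}",
            defaultArrayLength=str(s.mz.size),
        )
        _cv(spec, "MS:1000579", "MS1 spectrum")
        _cv(spec, "MS:1000511", "ms level", "1")
        _cv(spec, "MS:1000127", "centroid spectrum")
        if s.polarity == "positive":
            _cv(spec, "MS:1000130", "positive scan")
        else:
            _cv(spec, "MS:1000129", "negative scan")
        scan_list = etree.SubElement(spec, "scanList", count="1")
        _cv(scan_list, "MS:1000795", "no combination")
        scan = etree.SubElement(scan_list, "scan")
        _cv(
            scan,
            "MS:1000016",
            "scan start time",
            repr(s.rt),
            unitCvRef="UO",
            unitAccession="UO:0000010",
            unitName="second",
        )
        bdal = etree.SubElement(spec, "binaryDataArrayList", count="2")
        for accession, name, arr in (
            ("MS:1000514", "m/z array", s.mz),
            ("MS:1000515", "intensity array", s.intensity),
        ):
            payload = _encode(arr)
            bda = etree.SubElement(
                bdal, "binaryDataArray", encodedLength=str(len(payload))
            )
            _cv(bda, "MS:1000523", "64-bit float")
            _cv(bda, "MS:1000576", "no compression")
            _cv(bda, accession, name)
            etree.SubElement(bda, "binary").text = payload

    tree = etree.ElementTree(root)
    tree.write(
        str(path), xml_declaration=True, encoding="utf-8", pretty_print=True
    )


def _decode_binary_array(bda) -> np.ndarray:
    """Decode one <binaryDataArray>: base64, optional zlib, 32/64-bit float."""
    dtype = "<f8"
    compressed = False
    for cv in bda.findall(f"{{{MZML_NS}}}cvParam"):
        acc = cv.get("accession")
        if acc == "MS:1000521":
            dtype = "<f4"
        elif acc == "MS:1000523":
            dtype = "<f8"
        elif acc == "MS:1000574":
            compressed = True
    binary = bda.find(f"{{{MZML_NS}}}binary")
    raw = base64.b64decode(binary.text or "")
    if compressed:
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(elem) -> Spectrum | None:
    ms_level = 1
    polarity = "positive"
    for cv in elem.findall(f"{{{MZML_NS}}}cvParam"):
        acc = cv.get("accession")
        if acc == "MS:1000511":
            ms_level = int(cv.get("value"))
        elif acc == "MS:1000129":
            polarity = "negative"
    if ms_level != 1:
        return None
    rt = None
    for cv in elem.iterfind(
        f"{{{MZML_NS}}}scanList/{{{MZML_NS}}}scan/{{{MZML_NS}}}cvParam"
    ):
        if cv.get("accession") == "MS:1000016":
            rt = float(cv.get("value"))
            if cv.get("unitName") in ("minute", "min"):
                rt *= 60.0
    if rt is None:
        raise ValueError("spectrum without a scan start time")
    arrays: dict[str, np.ndarray] = {}
    for bda in elem.iterfind(
        f"{{{MZML_NS}}}binaryDataArrayList/{{{MZML_NS}}}binaryDataArray"
    ):
        accs = {cv.get("accession") for cv in bda.findall(f"{{{MZML_NS}}}cvParam")}
        if "MS:1000514" in accs:
            arrays["mz"] = _decode_binary_array(bda)
        elif "MS:1000515" in accs:
            arrays["intensity"] = _decode_binary_array(bda)
    if "mz" not in arrays or "intensity" not in arrays:
        raise ValueError("spectrum lacks m/z or intensity array")
    return Spectrum(
        rt=rt, polarity=polarity, mz=arrays["mz"], intensity=arrays["intensity"]
    )


def read_mzml(
    path: str | Path,
    sample_id: str | None = None,
    role: str = "sample",
    group: str | None = None,
    donor: str | None = None,
) -> Run:
    """Load a centroided MS1 mzML file into a :class:`Run`.

    Metadata (role/group/donor) is not part of mzML; it is supplied by the
    caller, typically from a sample sheet.
    """
    path = Path(path)
    spectra: list[Spectrum] = []
    for _, elem in etree.iterparse(str(path), tag=f"{{{MZML_NS}}}spectrum"):
        s = _parse_spectrum(elem)
        if s is not None:
            spectra.append(s)
        elem.clear(keep_tail=True)
    spectra.sort(key=lambda s: s.rt)
    return Run(
        sample_id=sample_id or path.stem,
        spectra=spectra,
        role=role,
        group=group,
        donor=donor,
    )
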