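"""Reading, writing and preprocessing MS data.

Spectra are centroided peak lists.  MGF is read and written through
pyteomics; mzML is read through pyteomics and written with a minimal
lxml serializer (enough metadata for lossless round-tripping of
synthetic runs: ms level, retention time, precursor selection and
isolation windows, 64-bit uncompressed peak arrays).

The only glycopeptide-specific operation here is the oxonium filter:
MS/MS scans are retained when they contain the HexNAc oxonium ion at
m/z 204.0867 (configurable), the standard diagnostic that a scan comes
from a glycopeptide.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from lxml import etree
from pyteomics import mgf as _mgf

from .glycan_model import PROTON_MASS

HEXNAC_OXONIUM_MZ = 204.08667


class SpectrumError(ValueError):
    """Malformed spectral record."""


@dataclass
class Spectrum:
    """A centroided spectrum with sorted peak arrays.

    ``retention_time`` is in minutes.  ``precursor_charge`` is None
    when unknown (common in MGF exports).  MS2 scans from DIA runs
    carry the isolation window bounds instead of a meaningful selected
    precursor.
    """

    scan_id: str
    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray
    precursor_charge: Optional[int] = None
    retention_time: float = 0.0
    ms_level: int = 2
    isolation_window: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise SpectrumError(f"scan {self.scan_id}: peak array shape mismatch")
        if np.any(self.intensity < 0):
            raise SpectrumError(f"scan {self.scan_id}: negative intensity")
        if self.ms_level == 2 and self.precursor_mz <= 0:
            raise SpectrumError(f"scan {self.scan_id}: non-positive precursor m/z")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if self.intensity.size else 0.0

    def has_peak(self, target_mz: float, tol_da: float, min_relative_intensity: float = 0.0) -> bool:
        lo = np.searchsorted(self.mz, target_mz - tol_da, side="left")
        hi = np.searchsorted(self.mz, target_mz + tol_da, side="right")
        if lo == hi:
            return False
        threshold = min_relative_intensity * self.base_peak_intensity
        return bool(np.any(self.intensity[lo:hi] >= threshold))

    def intensity_near(self, target_mz: float, tol_da: float) -> float:
        lo = np.searchsorted(self.mz, target_mz - tol_da, side="left")
        hi = np.searchsorted(self.mz, target_mz + tol_da, side="right")
        return float(self.intensity[lo:hi].sum())


@dataclass
class Run:
    """An ordered acquisition: MS1 + MS2 spectra with a mode tag."""

    spectra: List[Spectrum]
    mode: str = "DDA"  # DDA | DIA
    dia_windows: Tuple[Tuple[float, float], ...] = ()

    def __post_init__(self):
        if self.mode not in ("DDA", "DIA"):
            raise ValueError(f"unknown acquisition mode {self.mode!r}")
        if self.mode == "DIA" and not self.dia_windows:
            raise ValueError("DIA run requires a non-empty window scheme")

    def ms1(self) -> List[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    def ms2(self) -> List[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 2]


# ---------------------------------------------------------------------------
# MGF

def read_mgf(path) -> List[Spectrum]:
    """Read an MGF peak-list file. RTINSECONDS is converted to minutes."""
    out = []
    with _mgf.MGF(str(path)) as reader:
        for i, rec in enumerate(reader):
            params = rec["params"]
            pepmass = params.get("pepmass", (0.0,))
            charge = params.get("charge")
            if charge:
                charge = int(charge[0])
            rt = params.get("rtinseconds")
            rt_min = float(rt) / 60.0 if rt is not None else 0.0
            out.append(
                Spectrum(
                    scan_id=str(params.get("title", f"index={i}")),
                    precursor_mz=float(pepmass[0]),
                    precursor_charge=charge,
                    retention_time=rt_min,
                    mz=rec["m/z array"],
                    intensity=rec["intensity array"],
                )
            )
    return out


def write_mgf(spectra: Sequence[Spectrum], path) -> None:
    records = []
    for s in spectra:
        params = {
            "title": s.scan_id,
            "pepmass": s.precursor_mz,
            "rtinseconds": s.retention_time * 60.0,
        }
        if s.precursor_charge is not None:
            params["charge"] = s.precursor_charge
        records.append(
            {"params": params, "m/z array": s.mz, "intensity array": s.intensity}
        )
    _mgf.write(records, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# mzML

_DIA_MIN_WIDTH = 5.0  # Da; isolation windows at least this wide are called DIA


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def _cv_params(elem) -> Dict[str, str]:
    out = {}
    for cv in elem.iterchildren(f"{_MZML_NS}cvParam"):
        out[cv.get("accession")] = cv.get("value", "")
    return out


def _decode_binary_array(ba) -> np.ndarray:
    params = _cv_params(ba)
    binary = ba.find(f"{_MZML_NS}binary")
    raw = base64.b64decode(binary.text or "")
    if "MS:1000574" in params:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in params else "<f8"  # 32- vs 64-bit float
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path) -> Run:
    """Read an mzML run (lxml-based, PSI-MS cvParam subset).

    Handles centroided spectra with 32/64-bit, optionally
    zlib-compressed peak arrays.  The DIA window scheme is inferred
    from isolation window metadata when the MS2 isolation widths
    exceed a DDA-typical width (5 Da).
    """
    tree = etree.parse(str(path))
    spectra = []
    windows = set()
    wide = 0
    ms2 = 0
    for sp in tree.iter(f"{_MZML_NS}spectrum"):
        params = _cv_params(sp)
        level = int(params.get("MS:1000511", 1))
        rt = 0.0
        for scan in sp.iter(f"{_MZML_NS}scan"):
            for cv in scan.iterchildren(f"{_MZML_NS}cvParam"):
                if cv.get("accession") == "MS:1000016":
                    rt = float(cv.get("value"))
                    if "second" in (cv.get("unitName") or "minute"):
                        rt /= 60.0
            break
        prec_mz, charge, iso = 0.0, None, None
        if level >= 2:
            ms2 += 1
            prec = sp.find(f"{_MZML_NS}precursorList/{_MZML_NS}precursor")
            if prec is None:
                raise SpectrumError(f"scan {sp.get('id')}: MS2 record lacks precursor metadata")
            iw = prec.find(f"{_MZML_NS}isolationWindow")
            if iw is not None:
                p = _cv_params(iw)
                target = float(p.get("MS:1000827", 0.0))
                if target:
                    lo_off = float(p.get("MS:1000828", 0.0))
                    hi_off = float(p.get("MS:1000829", 0.0))
                    iso = (target - lo_off, target + hi_off)
                    prec_mz = target
            si = prec.find(f"{_MZML_NS}selectedIonList/{_MZML_NS}selectedIon")
            if si is not None:
                p = _cv_params(si)
                if "MS:1000744" in p:
                    prec_mz = float(p["MS:1000744"])
                if p.get("MS:1000041"):
                    charge = int(p["MS:1000041"])
            if prec_mz <= 0:
                raise SpectrumError(f"scan {sp.get('id')}: no precursor m/z")
            if iso is not None and iso[1] - iso[0] >= _DIA_MIN_WIDTH:
                wide += 1
                windows.add((round(iso[0], 4), round(iso[1], 4)))
        arrays: Dict[str, np.ndarray] = {}
        for ba in sp.iter(f"{_MZML_NS}binaryDataArray"):
            p = _cv_params(ba)
            if "MS:1000514" in p:
                arrays["mz"] = _decode_binary_array(ba)
            elif "MS:1000515" in p:
                arrays["intensity"] = _decode_binary_array(ba)
        if "mz" not in arrays or "intensity" not in arrays:
            raise SpectrumError(f"scan {sp.get('id')}: missing peak arrays")
        spectra.append(
            Spectrum(
                scan_id=str(sp.get("id")),
                precursor_mz=prec_mz,
                precursor_charge=charge,
                retention_time=rt,
                ms_level=level,
                isolation_window=iso,
                mz=arrays["mz"],
                intensity=arrays["intensity"],
            )
        )
    if ms2 and wide >= ms2 * 0.9 and windows:
        return Run(spectra, mode="DIA", dia_windows=tuple(sorted(windows)))
    return Run(spectra, mode="DDA")


def _b64_array(a: np.ndarray) -> str:
    return base64.b64encode(struct.pack(f"<{a.size}d", *a.astype(float))).decode()


def _cv(parent, accession, name, value="", **extra):
    attrs = {"cvRef": "MS", "accession": accession, "name": name, "value": str(value)}
    attrs.update(extra)
    etree.SubElement(parent, "cvParam", **attrs)


def write_mzml(run: Run, path) -> None:
    """Serialize a Run to plain (unindexed, uncompressed) mzML 1.1."""
    NS = "http://psi.hupo.org/ms/mzml"
    root = etree.Element("mzML", xmlns=NS, version="1.1.0")
    cvlist = etree.SubElement(root, "cvList", count="2")
    etree.SubElement(cvlist, "cv", id="MS", fullName="PSI-MS", URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo")
    etree.SubElement(cvlist, "cv", id="UO", fullName="UNIT-ONTOLOGY", URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo")
    fdesc = etree.SubElement(root, "fileDescription")
    fcontent = etree.SubElement(fdesc, "fileContent")
    _cv(fcontent, "MS:1000294", "mass spectrum")
    slist_parent = etree.SubElement(root, "run", id="run1")
    slist = etree.SubElement(
        slist_parent, "spectrumList", count=str(len(run.spectra)), defaultDataProcessingRef="dp"
    )
    for i, s in enumerate(run.spectra):
        sp = etree.SubElement(
            slist, "spectrum", index=str(i), id=str(s.scan_id), defaultArrayLength=str(s.n_peaks)
        )
        _cv(sp, "MS:1000511", "ms level", s.ms_level)
        _cv(sp, "MS:1000127", "centroid spectrum")
        scan_list = etree.SubElement(sp, "scanList", count="1")
        _cv(scan_list, "MS:1000795", "no combination")
        scan = etree.SubElement(scan_list, "scan")
        _cv(
            scan, "MS:1000016", "scan start time", f"{s.retention_time:.6f}",
            unitCvRef="UO", unitAccession="UO:0000031", unitName="minute",
        )
        if s.ms_level >= 2:
            plist = etree.SubElement(sp, "precursorList", count="1")
            prec = etree.SubElement(plist, "precursor")
            if s.isolation_window is not None:
                lo, hi = s.isolation_window
                target = 0.5 * (lo + hi)
                iw = etree.SubElement(prec, "isolationWindow")
                _cv(iw, "MS:1000827", "isolation window target m/z", f"{target:.6f}")
                _cv(iw, "MS:1000828", "isolation window lower offset", f"{target - lo:.6f}")
                _cv(iw, "MS:1000829", "isolation window upper offset", f"{hi - target:.6f}")
            silist = etree.SubElement(prec, "selectedIonList", count="1")
            si = etree.SubElement(silist, "selectedIon")
            _cv(si, "MS:1000744", "selected ion m/z", f"{s.precursor_mz:.6f}")
            if s.precursor_charge is not None:
                _cv(si, "MS:1000041", "charge state", s.precursor_charge)
        balist = etree.SubElement(sp, "binaryDataArrayList", count="2")
        for accession, name, arr in (
            ("MS:1000514", "m/z array", s.mz),
            ("MS:1000515", "intensity array", s.intensity),
        ):
            encoded = _b64_array(arr)
            ba = etree.SubElement(balist, "binaryDataArray", encodedLength=str(len(encoded)))
            _cv(ba, "MS:1000523", "64-bit float")
            _cv(ba, "MS:1000576", "no compression")
            _cv(ba, accession, name)
            etree.SubElement(ba, "binary").text = encoded
    tree = etree.ElementTree(root)
    tree.write(str(path), xml_declaration=True, encoding="utf-8", pretty_print=True)


# ---------------------------------------------------------------------------
# Filtering and preprocessing

def oxonium_filter(
    spectra: Sequence[Spectrum],
    targets: Sequence[float] = (HEXNAC_OXONIUM_MZ,),
    tol_da: float = 0.02,
    min_relative_intensity: float = 0.0,
) -> List[Spectrum]:
    """Retain spectra containing at least one diagnostic oxonium peak.

    A spectrum passes when any target m/z has a peak within ``tol_da``
    whose intensity is at least ``min_relative_intensity`` of the base
    peak.  Order is preserved; the operation is idempotent.
    """
    if tol_da <= 0:
        raise ValueError("tol_da must be positive")
    return [
        s
        for s in spectra
        if any(s.has_peak(t, tol_da, min_relative_intensity) for t in targets)
    ]


def preprocess_peaks(
    spectrum: Spectrum,
    precursor_exclusion: float = 17.0,
    top_k: int = 6,
    window: float = 50.0,
) -> Spectrum:
    """Standard molecular-networking peak cleanup.

    Removes peaks within +/- ``precursor_exclusion`` Th of the precursor
    (unfragmented precursor and its losses dominate cosine scores
    otherwise) and keeps the ``top_k`` most intense peaks per ``window``
    Th bin.
    """
    mz, inten = spectrum.mz, spectrum.intensity
    keep = np.abs(mz - spectrum.precursor_mz) > precursor_exclusion
    mz, inten = mz[keep], inten[keep]
    if mz.size and top_k > 0:
        bins = (mz // window).astype(int)
        mask = np.zeros(mz.size, dtype=bool)
        for b in np.unique(bins):
            idx = np.nonzero(bins == b)[0]
            if idx.size > top_k:
                idx = idx[np.argsort(inten[idx], kind="stable")[-top_k:]]
            mask[idx] = True
        mz, inten = mz[mask], inten[mask]
    return replace(spectrum, mz=mz, intensity=inten)
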