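"""Reading, writing and filtering LC-MS runs (mzML / mzXML).

A :class:`Run` is an RT-ordered list of :class:`Spectrum` objects with
per-scan centroid arrays.  mzXML reading goes through pyteomics; mzML is
read by a compact lxml-based reader covering the spectrum / cvParam /
binaryDataArray subset that converters such as msConvert emit (32/64-bit
float arrays, zlib or uncompressed).  Writing emits a minimal mzML 1.1.0
document that reads back bit-faithfully.

Retention time is minutes everywhere; files recorded in seconds are
converted at parse time.
"""

from __future__ import annotations

import base64
import logging
import struct
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape, quoteattr

import numpy as np
from lxml import etree
from pyteomics import mzxml as _mzxml_reader

__all__ = ["Spectrum", "Run", "load_run", "filter_scans", "write_run"]

log = logging.getLogger(__name__)

#: PRM precursor match tolerance in m/z; half the 2.0 m/z isolation window.
PRM_PRECURSOR_TOL = 1.0


@dataclass
class Spectrum:
    """One scan: centroid m/z and intensity arrays at a retention time."""

    rt: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray
    ms_level: int = 1
    precursor_mz: float | None = None  # PRM precursor, if MS2
    scan_window: tuple[float, float] | None = None  # SIM segment m/z range

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if self.mz.size > 1 and np.any(np.diff(self.mz) <= 0):
            raise ValueError("m/z array must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.rt < 0:
            raise ValueError("retention time must be >= 0")


@dataclass
class Run:
    """An ordered LC-MS run."""

    spectra: list[Spectrum] = field(default_factory=list)
    source: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        rts = [s.rt for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("spectra must be ordered by non-decreasing RT")

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def rt_span(self) -> tuple[float, float]:
        if not self.spectra:
            return (0.0, 0.0)
        return (self.spectra[0].rt, self.spectra[-1].rt)


def load_run(path: str | Path, format: str = "auto") -> Run:
    """Load an mzML or mzXML file into a :class:`Run`.

    ``format`` may be ``"auto"`` (by extension), ``"mzML"`` or ``"mzXML"``.
    Profile-mode spectra are accepted but flagged in ``run.metadata`` since
    quantification assumes centroided data.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    if fmt == "auto":
        suffix = path.suffix.lower()
        if suffix == ".mzml":
            fmt = "mzml"
        elif suffix == ".mzxml":
            fmt = "mzxml"
        else:
            raise ValueError(f"cannot infer format from extension {suffix!r}")
    if fmt not in ("mzml", "mzxml"):
        raise ValueError(f"unsupported format {format!r}")
    if path.stat().st_size == 0:
        raise ValueError(f"empty file: {path}")

    spectra: list[Spectrum] = []
    profile_seen = False
    try:
        if fmt == "mzml":
            for spec, is_profile in _iter_mzml(path):
                spectra.append(spec)
                profile_seen |= is_profile
        else:
            with _mzxml_reader.MzXML(str(path)) as reader:
                for entry in reader:
                    spectra.append(_spectrum_from_mzxml(entry))
                    profile_seen |= entry.get("centroided") is False
    except Exception as exc:  # noqa: BLE001 - surfaced with context
        if isinstance(exc, (ValueError, FileNotFoundError)):
            raise
        raise ValueError(f"failed to parse {path} as {fmt}: {exc}") from exc

    spectra.sort(key=lambda s: s.rt)
    meta = {"format": fmt, "profile": profile_seen}
    if profile_seen:
        warnings.warn(
            f"{path.name}: profile spectra present; quantification assumes centroids",
            stacklevel=2,
        )
    log.info("loaded %d spectra from %s", len(spectra), path.name)
    return Run(spectra=spectra, source=str(path), metadata=meta)


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _decode_binary_array(bda: etree._Element) -> np.ndarray:
    dtype = "<f8"
    compressed = False
    payload = b""
    for child in bda.iter():
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
            payload = base64.b64decode(child.text or "")
    if compressed:
        payload = zlib.decompress(payload)
    return np.frombuffer(payload, dtype=dtype).astype(float)


def _parse_mzml_spectrum(elem: etree._Element) -> tuple[Spectrum, bool]:
    ms_level = 1
    profile = False
    rt = 0.0
    window = None
    precursor = None
    mz = np.array([])
    intensity = np.array([])
    win_lo = win_hi = None
    for child in elem.iter():
        name = _local(child.tag)
        if name == "cvParam":
            acc = child.get("accession", "")
            val = child.get("value", "")
            if acc == "MS:1000511":
                ms_level = int(val)
            elif acc == "MS:1000128":
                profile = True
            elif acc == "MS:1000016":
                rt = float(val)
                if "second" in (child.get("unitName") or "").lower():
                    rt /= 60.0
            elif acc == "MS:1000501":
                win_lo = float(val)
            elif acc == "MS:1000500":
                win_hi = float(val)
            elif acc == "MS:1000744":
                precursor = float(val)
        elif name == "binaryDataArray":
            arr = _decode_binary_array(child)
            role = {
                c.get("accession")
                for c in child
                if _local(c.tag) == "cvParam"
            }
            if "MS:1000514" in role:
                mz = arr
            elif "MS:1000515" in role:
                intensity = arr
    if win_lo is not None and win_hi is not None:
        window = (win_lo, win_hi)
    spec = Spectrum(
        rt=rt,
        mz=mz,
        intensity=intensity,
        ms_level=ms_level,
        precursor_mz=precursor,
        scan_window=window,
    )
    return spec, profile


def _iter_mzml(path: Path):
    """Yield (Spectrum, is_profile) from an mzML file via incremental parse."""
    seen = 0
    for _, elem in etree.iterparse(str(path), events=("end",)):
        if _local(elem.tag) == "spectrum":
            seen += 1
            yield _parse_mzml_spectrum(elem)
            elem.clear()
    if seen == 0:
        # distinguish "no spectra" from "not an mzML document"
        root = etree.parse(str(path)).getroot()
        if _local(root.tag) not in ("mzML", "indexedmzML"):
            raise ValueError(f"{path}: root element {root.tag!r} is not mzML")


def _spectrum_from_mzxml(entry: dict) -> Spectrum:
    rt = entry.get("retentionTime", 0.0)  # pyteomics converts to minutes
    window = None
    if "lowMz" in entry and "highMz" in entry:
        window = (float(entry["lowMz"]), float(entry["highMz"]))
    precursor = None
    if entry.get("precursorMz"):
        precursor = float(entry["precursorMz"][0]["precursorMz"])
    return Spectrum(
        rt=float(rt),
        mz=entry["m/z array"],
        intensity=entry["intensity array"],
        ms_level=int(entry.get("msLevel", 1)),
        precursor_mz=precursor,
        scan_window=window,
    )


def filter_scans(
    run: Run,
    ms_level: int | None = None,
    rt_range: tuple[float, float] | None = None,
    sim_mz: float | None = None,
    prm_precursor: float | None = None,
    precursor_tol: float = PRM_PRECURSOR_TOL,
) -> Run:
    """Subset a run by conjunctive criteria, preserving scan order.

    ``sim_mz`` keeps scans whose SIM scan window contains the queried m/z
    (combined with ``rt_range`` this selects one acquisition segment);
    ``prm_precursor`` keeps MS2 scans whose precursor lies within
    ``precursor_tol``.  An empty result is not an error.
    """
    out = []
    for s in run.spectra:
        if ms_level is not None and s.ms_level != ms_level:
            continue
        if rt_range is not None and not (rt_range[0] <= s.rt <= rt_range[1]):
            continue
        if sim_mz is not None:
            if s.scan_window is None or not (
                s.scan_window[0] <= sim_mz <= s.scan_window[1]
            ):
                continue
        if prm_precursor is not None:
            if s.precursor_mz is None or abs(s.precursor_mz - prm_precursor) > precursor_tol:
                continue
        out.append(s)
    log.debug("filter_scans: %d of %d scans kept", len(out), len(run))
    return Run(spectra=out, source=run.source, metadata=dict(run.metadata))


# ---------------------------------------------------------------------------
# mzML writing


def _encode_array(values: np.ndarray, compress: bool) -> str:
    raw = np.asarray(values, dtype="<f8").tobytes()
    if compress:
        raw = zlib.compress(raw)
    return base64.b64encode(raw).decode("ascii")


_CV = 'cvRef="MS"'


def _cv(accession: str, name: str, value: str = "", unit: str = "") -> str:
    s = f'<cvParam {_CV} accession={quoteattr(accession)} name={quoteattr(name)} value={quoteattr(value)}'
    return s + (unit + "/>" if unit else "/>")


_MIN_UNIT = ' unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"'
_MZ_UNIT = ' unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"'


def write_run(run: Run, path: str | Path, compress: bool = False) -> Path:
    """Write a run as mzML 1.1.0 readable by :func:`load_run`.

    Arrays are 64-bit little-endian, base64; ``compress=True`` applies zlib.
    Centroid spectra are assumed.  The run must be non-empty.
    """
    if not run.spectra:
        raise ValueError("refusing to write an empty run")
    path = Path(path)
    n = len(run.spectra)
    parts = [
        '<?xml version="1.0" encoding="utf-8"?>',
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">',
        '<cvList count="2">',
        '<cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>',
        '<cv id="UO" fullName="UNIT-ONTOLOGY" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>',
        "</cvList>",
        '<fileDescription><fileContent>',
        _cv("MS:1000579", "MS1 spectrum"),
        _cv("MS:1000127", "centroid spectrum"),
        "</fileContent></fileDescription>",
        '<softwareList count="1"><software id="silkms" version="0.1.0"/></softwareList>',
        '<instrumentConfigurationList count="1">'
        '<instrumentConfiguration id="IC1"/></instrumentConfigurationList>',
        '<dataProcessingList count="1"><dataProcessing id="DP1">'
        '<processingMethod order="1" softwareRef="silkms"/>'
        "</dataProcessing></dataProcessingList>",
        f'<run id={quoteattr(run.metadata.get("run_id", "run"))} defaultInstrumentConfigurationRef="IC1">',
        f'<spectrumList count="{n}" defaultDataProcessingRef="DP1">',
    ]
    for i, s in enumerate(run.spectra):
        npk = s.mz.size
        parts.append(
            f'<spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{npk}">'
        )
        parts.append(_cv("MS:1000511", "ms level", str(s.ms_level)))
        parts.append(_cv("MS:1000127", "centroid spectrum"))
        parts.append(
            _cv("MS:1000579", "MS1 spectrum")
            if s.ms_level == 1
            else _cv("MS:1000580", "MSn spectrum")
        )
        parts.append('<scanList count="1">')
        parts.append(_cv("MS:1000795", "no combination"))
        parts.append("<scan>")
        parts.append(
            _cv("MS:1000016", "scan start time", repr(float(s.rt)), _MIN_UNIT)
        )
        if s.scan_window is not None:
            parts.append('<scanWindowList count="1"><scanWindow>')
            parts.append(
                _cv("MS:1000501", "scan window lower limit", repr(float(s.scan_window[0])), _MZ_UNIT)
            )
            parts.append(
                _cv("MS:1000500", "scan window upper limit", repr(float(s.scan_window[1])), _MZ_UNIT)
            )
            parts.append("</scanWindow></scanWindowList>")
        parts.append("</scan></scanList>")
        if s.precursor_mz is not None:
            parts.append(
                '<precursorList count="1"><precursor>'
                '<selectedIonList count="1"><selectedIon>'
            )
            parts.append(
                _cv("MS:1000744", "selected ion m/z", repr(float(s.precursor_mz)), _MZ_UNIT)
            )
            parts.append("</selectedIon></selectedIonList></precursor></precursorList>")
        parts.append('<binaryDataArrayList count="2">')
        for arr, acc, name in (
            (s.mz, "MS:1000514", "m/z array"),
            (s.intensity, "MS:1000515", "intensity array"),
        ):
            payload = _encode_array(arr, compress)
            parts.append(f'<binaryDataArray encodedLength="{len(payload)}">')
            parts.append(_cv("MS:1000523", "64-bit float"))
            parts.append(
                _cv("MS:1000574", "zlib compression")
                if compress
                else _cv("MS:1000576", "no compression")
            )
            parts.append(_cv(acc, name))
            parts.append(f"<binary>{payload}</binary>")
            parts.append("</binaryDataArray>")
        parts.append("</binaryDataArrayList></spectrum>")
    parts.append("</spectrumList></run></mzML>")
    path.write_text("\n".join(parts))
    return path
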