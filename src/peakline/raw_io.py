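"""mzML reading and ROI-bounded ion-chromatogram extraction.

The reader is deliberately minimal: it understands plain or gzipped mzML,
MS1 spectra, 32/64-bit little-endian binary arrays with optional zlib
compression, and scan start times in seconds or minutes (auto-converted to
seconds).  Nothing is resampled — extraction works on the native scan grid.
"""

from __future__ import annotations

import base64
import gzip
import struct
import xml.etree.ElementTree as ET
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .errors import EmptyRunError, MzMLReadError
from .target_registry import ROI, ROISet

__all__ = ["Spectrum", "RawRun", "EIC", "read_mzml", "extract_eic", "extract_all"]

# PSI-MS / UO controlled-vocabulary accessions used by the reader
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SCAN_START = "MS:1000016"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_NOCOMP = "MS:1000576"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_POSITIVE = "MS:1000130"
_ACC_NEGATIVE = "MS:1000129"
_ACC_MINUTE = "UO:0000031"
_ACC_SECOND = "UO:0000010"


@dataclass
class Spectrum:
    """One mass spectrum: parallel m/z and intensity vectors at a scan time."""

    scan_index: int
    rt: float                      # seconds
    mz_values: np.ndarray          # ascending, Da
    intensities: np.ndarray        # non-negative, same length
    ms_level: int = 1
    centroided: bool = True

    def __post_init__(self) -> None:
        self.mz_values = np.asarray(self.mz_values, dtype=np.float64)
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.mz_values.shape != self.intensities.shape:
            raise ValueError("mz_values and intensities must have equal length")
        if self.mz_values.size > 1 and not np.all(np.diff(self.mz_values) > 0):
            raise ValueError("mz_values must be strictly ascending")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class RawRun:
    """An ordered collection of MS1 spectra for one sample."""

    sample_id: str
    spectra: list[Spectrum]
    polarity: str = "unknown"      # positive | negative | unknown

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.spectra]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("spectra must be ordered by non-decreasing rt")

    @property
    def rt_range(self) -> tuple[float, float]:
        return (self.spectra[0].rt, self.spectra[-1].rt)

    def __len__(self) -> int:
        return len(self.spectra)


@dataclass
class EIC:
    """Extracted ion chromatogram for one (sample, compound) pair.

    ``mz`` holds the intensity-weighted mean m/z inside the extraction
    window at each scan (NaN where the summed intensity is zero).
    """

    sample_id: str
    cpd_id: str
    rt: np.ndarray
    intensity: np.ndarray
    mz: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_scans: int = 0

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz is None:
            self.mz = np.full_like(self.rt, np.nan)
        else:
            self.mz = np.asarray(self.mz, dtype=np.float64)
        if self.rt.shape != self.intensity.shape:
            raise ValueError("rt and intensity must have equal length")
        if self.rt.size > 1 and not np.all(np.diff(self.rt) > 0):
            raise ValueError("rt must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")
        self.n_scans = int(self.rt.size)

    @property
    def is_empty(self) -> bool:
        return self.n_scans == 0

    @property
    def scan_interval(self) -> float:
        """Median spacing of the scan grid (0 for <2 points)."""
        if self.n_scans < 2:
            return 0.0
        return float(np.median(np.diff(self.rt)))


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _open_maybe_gzip(path: Path):
    fh = open(path, "rb")
    magic = fh.read(2)
    fh.seek(0)
    if magic == b"\x1f\x8b":
        fh.close()
        return gzip.open(path, "rb")
    return fh


def _decode_binary(text: str | None, dtype: str, compressed: bool, n: int) -> np.ndarray:
    if not text or not text.strip():
        return np.zeros(0, dtype=np.float64)
    raw = base64.b64decode(text.strip().encode("ascii"))
    if compressed:
        raw = zlib.decompress(raw)
    arr = np.frombuffer(raw, dtype="<f8" if dtype == "f64" else "<f4")
    if n and arr.size != n:
        raise MzMLReadError(
            f"binary array length {arr.size} does not match defaultArrayLength {n}"
        )
    return arr.astype(np.float64)


def _parse_spectrum_elem(elem: ET.Element, index: int) -> tuple[Spectrum | None, str]:
    """Build a Spectrum from a <spectrum> element; returns (spectrum, polarity)."""
    ms_level = 1
    centroided = True
    have_mode = False
    rt = None
    polarity = "unknown"
    arrays: dict[str, np.ndarray] = {}
    n_default = int(elem.get("defaultArrayLength", "0"))

    for child in elem.iter():
        tag = _local(child.tag)
        if tag == "cvParam":
            acc = child.get("accession", "")
            if acc == _ACC_MS_LEVEL:
                ms_level = int(child.get("value", "1"))
            elif acc == _ACC_CENTROID:
                centroided, have_mode = True, True
            elif acc == _ACC_PROFILE:
                centroided, have_mode = False, True
            elif acc == _ACC_POSITIVE:
                polarity = "positive"
            elif acc == _ACC_NEGATIVE:
                polarity = "negative"
            elif acc == _ACC_SCAN_START:
                value = float(child.get("value", "nan"))
                unit = child.get("unitAccession", "") or child.get("unitName", "")
                if unit in (_ACC_MINUTE, "minute"):
                    value *= 60.0
                rt = value

    for bda in elem.iter():
        if _local(bda.tag) != "binaryDataArray":
            continue
        dtype, compressed, kind, text = "f64", False, None, None
        for child in bda:
            tag = _local(child.tag)
            if tag == "cvParam":
                acc = child.get("accession", "")
                if acc == _ACC_F64:
                    dtype = "f64"
                elif acc == _ACC_F32:
                    dtype = "f32"
                elif acc == _ACC_ZLIB:
                    compressed = True
                elif acc == _ACC_NOCOMP:
                    compressed = False
                elif acc == _ACC_MZ_ARRAY:
                    kind = "mz"
                elif acc == _ACC_INT_ARRAY:
                    kind = "intensity"
            elif tag == "binary":
                text = child.text
        if kind is not None:
            arrays[kind] = _decode_binary(text, dtype, compressed, n_default)

    if ms_level != 1:
        return None, polarity
    if rt is None:
        raise MzMLReadError(f"spectrum {index} lacks a scan start time")
    mz = arrays.get("mz", np.zeros(0))
    inten = arrays.get("intensity", np.zeros(0))
    spec = Spectrum(
        scan_index=index,
        rt=rt,
        mz_values=mz,
        intensities=np.maximum(inten, 0.0),
        ms_level=1,
        centroided=centroided if have_mode else True,
    )
    return spec, polarity


def read_mzml(path: str | Path) -> RawRun:
    """Read an mzML file (plain or gzipped) into a :class:`RawRun`.

    Only MS-level-1 spectra are kept, ordered by retention time.  Scan start
    times given in minutes are converted to seconds.  The centroided flag is
    read from file metadata when present, otherwise assumed true.

    Raises
    ------
    MzMLReadError
        If the file is absent, unreadable or not well-formed XML.
    EmptyRunError
        If the file contains no MS1 spectra.
    """
    path = Path(path)
    if not path.exists():
        raise MzMLReadError(f"mzML file not found: {path}")

    spectra: list[Spectrum] = []
    polarity = "unknown"
    try:
        with _open_maybe_gzip(path) as fh:
            index = 0
            for _event, elem in ET.iterparse(fh, events=("end",)):
                if _local(elem.tag) == "spectrum":
                    spec, pol = _parse_spectrum_elem(elem, index)
                    index += 1
                    if pol != "unknown" and polarity == "unknown":
                        polarity = pol
                    if spec is not None:
                        spectra.append(spec)
                    elem.clear()
    except ET.ParseError as exc:
        raise MzMLReadError(f"malformed mzML in {path}: {exc}") from exc
    except (OSError, zlib.error, ValueError) as exc:
        if isinstance(exc, MzMLReadError):
            raise
        raise MzMLReadError(f"cannot read mzML {path}: {exc}") from exc

    if not spectra:
        raise EmptyRunError(f"no MS1 spectra in {path}")
    spectra.sort(key=lambda s: s.rt)
    for i, spec in enumerate(spectra):
        spec.scan_index = i
    return RawRun(sample_id=path.name.split(".")[0], spectra=spectra, polarity=polarity)


def extract_eic(run: RawRun, roi: ROI) -> EIC:
    """Extract the ion chromatogram of ``roi`` from ``run``.

    One point per MS1 spectrum with rt in the closed interval
    ``[roi.rt_min, roi.rt_max]``; the point's intensity is the sum of all
    ion intensities with m/z in the closed interval
    ``[roi.mz_min, roi.mz_max]``.  Scans with no matching ions contribute
    zero, so the rt grid is always the scan grid.  An ROI whose rt window
    misses the run entirely yields an empty (flagged) EIC, not an error.
    """
    rts, sums, mz_means = [], [], []
    for spec in run.spectra:
        if spec.rt < roi.rt_min or spec.rt > roi.rt_max:
            continue
        lo = np.searchsorted(spec.mz_values, roi.mz_min, side="left")
        hi = np.searchsorted(spec.mz_values, roi.mz_max, side="right")
        inten = spec.intensities[lo:hi]
        total = float(inten.sum())
        rts.append(spec.rt)
        sums.append(total)
        if total > 0:
            mz_means.append(float(np.dot(spec.mz_values[lo:hi], inten) / total))
        else:
            mz_means.append(np.nan)
    return EIC(
        sample_id=run.sample_id,
        cpd_id=roi.cpd_id,
        rt=np.asarray(rts),
        intensity=np.asarray(sums),
        mz=np.asarray(mz_means),
    )


def extract_all(run: RawRun, rois: ROISet | Sequence[ROI]) -> list[EIC]:
    """Extract one EIC per ROI, in ROI order; identical to per-ROI calls."""
    roi_list = list(rois)
    if not roi_list:
        raise ValueError("extract_all requires at least one ROI")
    return [extract_eic(run, roi) for roi in roi_list]
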