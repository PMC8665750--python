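"""Compound target (ROI) files and calibrant tables.

The CSV schema follows the convention widely used for targeted-extraction
target lists: columns ``cpdID, cpdName, rtMin, rt, rtMax, mzMin, mz, mzMax``
(``rt`` and ``mz`` optional).  Unknown extra columns are carried through as
opaque per-row metadata so annotated files survive a round trip.

Retention times in these files are always seconds; unit conversion is an
explicit caller decision (``--rt-unit`` on the CLI), never guessed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd

from .errors import RowValidationError, SchemaError

__all__ = [
    "ROI",
    "ROISet",
    "CalibrantTable",
    "read_roi_csv",
    "write_roi_csv",
    "read_calibrant_csv",
]

_REQUIRED_COLUMNS = ("cpdID", "cpdName", "rtMin", "rtMax", "mzMin", "mzMax")
_OPTIONAL_COLUMNS = ("rt", "mz")
_ALL_COLUMNS = ("cpdID", "cpdName", "rtMin", "rt", "rtMax", "mzMin", "mz", "mzMax")


@dataclass
class ROI:
    """One compound's targeted search window in rt x m/z.

    ``rt`` (expected apex retention time) and ``mz`` (expected ion m/z)
    may be None when unknown.
    """

    cpd_id: str
    cpd_name: str
    rt_min: float
    rt_max: float
    mz_min: float
    mz_max: float
    rt: float | None = None
    mz: float | None = None
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        def _bad(fieldname: str, msg: str) -> RowValidationError:
            return RowValidationError(self.cpd_id, fieldname, msg)

        for name in ("rt_min", "rt_max", "mz_min", "mz_max"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise _bad(name, "must be a finite number")
        if not self.rt_min < self.rt_max:
            raise _bad("rt_min", f"rt_min ({self.rt_min}) must be < rt_max ({self.rt_max})")
        if not self.mz_min < self.mz_max:
            raise _bad("mz_min", f"mz_min ({self.mz_min}) must be < mz_max ({self.mz_max})")
        if self.rt is not None and not (self.rt_min <= self.rt <= self.rt_max):
            raise _bad("rt", f"expected rt {self.rt} outside [{self.rt_min}, {self.rt_max}]")
        if self.mz is not None and not (self.mz_min <= self.mz <= self.mz_max):
            raise _bad("mz", f"expected mz {self.mz} outside [{self.mz_min}, {self.mz_max}]")

    @property
    def rt_span(self) -> float:
        return self.rt_max - self.rt_min


@dataclass
class ROISet:
    """An ordered, cpd_id-unique collection of ROIs."""

    rois: list[ROI]
    source_path: str = ""

    def __post_init__(self) -> None:
        if not self.rois:
            raise SchemaError("ROISet must not be empty")
        seen: set[str] = set()
        for roi in self.rois:
            if roi.cpd_id in seen:
                raise RowValidationError(roi.cpd_id, "cpd_id", "duplicate cpd_id")
            seen.add(roi.cpd_id)

    def __iter__(self) -> Iterator[ROI]:
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    def __getitem__(self, key: int | str) -> ROI:
        if isinstance(key, str):
            for roi in self.rois:
                if roi.cpd_id == key:
                    return roi
            raise KeyError(key)
        return self.rois[key]

    @property
    def cpd_ids(self) -> list[str]:
        return [r.cpd_id for r in self.rois]


@dataclass
class CalibrantTable:
    """Expected retention times (seconds) for calibrant compounds."""

    cpd_ids: list[str]
    expected_rt: list[float]
    observed_rt: list[float] | None = None

    def __post_init__(self) -> None:
        if len(self.cpd_ids) != len(self.expected_rt):
            raise SchemaError("calibrant table: cpd_ids and expected_rt lengths differ")
        if any(rt <= 0 for rt in self.expected_rt):
            raise SchemaError("calibrant expected_rt values must be > 0")
        if self.observed_rt is not None and len(self.observed_rt) != len(self.cpd_ids):
            raise SchemaError("calibrant table: observed_rt length mismatch")

    def __len__(self) -> int:
        return len(self.cpd_ids)

    def validate_against(self, rois: ROISet) -> None:
        known = set(rois.cpd_ids)
        missing = [c for c in self.cpd_ids if c not in known]
        if missing:
            raise SchemaError(f"calibrant cpd_ids not in ROI set: {missing}")


def _parse_optional(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def read_roi_csv(path: str | Path, rt_unit: str = "sec") -> ROISet:
    """Read and validate an ROI target CSV.

    Parameters
    ----------
    path : file path
    rt_unit : {'sec', 'min'}
        Unit of the rt columns in the file; 'min' multiplies by 60.
        No auto-detection is performed.
    """
    path = Path(path)
    if rt_unit not in ("sec", "min"):
        raise ValueError(f"rt_unit must be 'sec' or 'min', got {rt_unit!r}")
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise SchemaError(f"cannot parse ROI CSV {path}: {exc}") from exc

    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"ROI CSV {path} missing required columns: {missing}")

    scale = 60.0 if rt_unit == "min" else 1.0
    extra_cols = [c for c in df.columns if c not in _ALL_COLUMNS]
    rois: list[ROI] = []
    for _, row in df.iterrows():
        cpd_id = str(row["cpdID"])
        try:
            rt = _parse_optional(row["rt"]) if "rt" in df.columns else None
            mz = _parse_optional(row["mz"]) if "mz" in df.columns else None
            roi = ROI(
                cpd_id=cpd_id,
                cpd_name=str(row["cpdName"]),
                rt_min=float(row["rtMin"]) * scale,
                rt_max=float(row["rtMax"]) * scale,
                mz_min=float(row["mzMin"]),
                mz_max=float(row["mzMax"]),
                rt=rt * scale if rt is not None else None,
                mz=mz,
                extra={c: str(row[c]) for c in extra_cols},
            )
        except RowValidationError:
            raise
        except (TypeError, ValueError) as exc:
            raise RowValidationError(cpd_id, "numeric", str(exc)) from exc
        rois.append(roi)
    return ROISet(rois=rois, source_path=str(path))


def write_roi_csv(rois: ROISet, path: str | Path) -> Path:
    """Write an ROI set to CSV; round-trips losslessly through read_roi_csv."""
    path = Path(path)
    extra_cols: list[str] = []
    for roi in rois:
        for c in roi.extra:
            if c not in extra_cols:
                extra_cols.append(c)
    rows = []
    for roi in rois:
        row = {
            "cpdID": roi.cpd_id,
            "cpdName": roi.cpd_name,
            "rtMin": repr(roi.rt_min),
            "rt": repr(roi.rt) if roi.rt is not None else "",
            "rtMax": repr(roi.rt_max),
            "mzMin": repr(roi.mz_min),
            "mz": repr(roi.mz) if roi.mz is not None else "",
            "mzMax": repr(roi.mz_max),
        }
        for c in extra_cols:
            row[c] = roi.extra.get(c, "")
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(_ALL_COLUMNS) + extra_cols)
    df.to_csv(path, index=False)
    return path


def read_calibrant_csv(path: str | Path) -> CalibrantTable:
    """Read a calibrant CSV with columns cpdID, expectedRt [, observedRt]."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ("cpdID", "expectedRt") if c not in df.columns]
    if missing:
        raise SchemaError(f"calibrant CSV {path} missing columns: {missing}")
    observed = None
    if "observedRt" in df.columns:
        observed = [float(v) for v in df["observedRt"]]
    return CalibrantTable(
        cpd_ids=[str(v) for v in df["cpdID"]],
        expected_rt=[float(v) for v in df["expectedRt"]],
        observed_rt=observed,
    )
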