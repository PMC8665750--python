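"""Dataset-level orchestration: samples x compounds extraction and fitting,
summaries, and consensus window refinement.

Per-file work is independent, so the batch can run on any number of worker
processes; results are always assembled in file order, making the output
bit-identical regardless of worker count or completion order.  A file that
fails to read yields a flagged all-not-found row instead of aborting the
batch.
"""

from __future__ import annotations

import concurrent.futures
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import BatchError, PeaklineError
from .peak_fit import FitConfig, PeakMeasurement, fallback_area, measure_peak
from .raw_io import extract_all, read_mzml
from .target_registry import ROI, ROISet, write_roi_csv

__all__ = ["AnnotationState", "CompoundSummary", "RefinementConfig",
           "run_annotation", "summarize", "propose_refinement", "export_tables",
           "load_state_tables"]


@dataclass
class AnnotationState:
    """The samples x compounds grid of peak measurements plus window sets."""

    sample_ids: list[str]
    rois: ROISet
    measurements: list[list[PeakMeasurement]]   # [sample][compound]
    u_rois: Optional[ROISet] = None
    firs: Optional[ROISet] = None
    use_uroi: bool = False
    use_fir: bool = False
    errors: dict[str, str] = field(default_factory=dict)  # sample_id -> message

    def __post_init__(self) -> None:
        if len(self.measurements) != len(self.sample_ids):
            raise ValueError("measurement grid row count != number of samples")
        for row in self.measurements:
            if len(row) != len(self.rois):
                raise ValueError("measurement grid column count != number of ROIs")
        for windows in (self.u_rois, self.firs):
            if windows is not None and windows.cpd_ids != self.rois.cpd_ids:
                raise ValueError("refined window sets must share the ROI cpd_ids")

    def column(self, cpd_id: str) -> list[PeakMeasurement]:
        j = self.rois.cpd_ids.index(cpd_id)
        return [row[j] for row in self.measurements]


@dataclass
class CompoundSummary:
    cpd_id: str
    found_fraction: float
    rt_dev_median: float        # median(apex_rt - roi.rt) over found; NaN if unavailable
    rt_dev_iqr: float
    area_rsd: float             # percent
    fallback_fraction: float    # fraction of found measurements using fallback
    ppm_error_median: float


@dataclass
class RefinementConfig:
    min_found: int = 3
    mz_pad: float = 0.005       # Da
    rt_pad_fwhm: float = 1.0    # pad = this many median FWHMs


def _measure_file(path: str, rois_list: list[ROI], config: FitConfig,
                  fir_list: list[ROI] | None) -> list[PeakMeasurement]:
    """Worker: read one file and measure every compound (picklable top-level)."""
    run = read_mzml(path)
    roiset = ROISet(rois=rois_list)
    eics = extract_all(run, roiset)
    out = []
    for eic, roi in zip(eics, roiset):
        m = measure_peak(eic, roi, config)
        out.append(m)
    if fir_list is not None:
        # fallback-integration regions rescue cells the fit pass missed
        for j, (m, fir) in enumerate(zip(out, fir_list)):
            if m.found:
                continue
            from .raw_io import extract_eic
            feic = extract_eic(run, fir)
            if feic.is_empty:
                continue
            area, apex_rt, apex_h = fallback_area(feic, fir.rt_min, fir.rt_max)
            if area is None or apex_h is None or apex_h <= 0:
                continue
            out[j] = replace(m, found=True, area=area, apex_rt=apex_rt,
                             apex_height=apex_h, fallback_used=True,
                             rt_min_obs=fir.rt_min, rt_max_obs=fir.rt_max,
                             note="integrated over fallback region")
    return out


def _empty_row(sample_id: str, rois: ROISet, note: str) -> list[PeakMeasurement]:
    return [PeakMeasurement(cpd_id=r.cpd_id, sample_id=sample_id, found=False,
                            note=note) for r in rois]


def run_annotation(files: Sequence[str | Path], rois: ROISet,
                   config: FitConfig | None = None, workers: int = 1,
                   firs: ROISet | None = None, use_fir: bool = False) -> AnnotationState:
    """Extract and measure every (file, compound) cell.

    Output is identical for any ``workers`` value.  Failed files are
    recorded per sample (all-not-found row + error note); only a batch
    where every file fails raises :class:`BatchError`.
    """
    if not files:
        raise ValueError("run_annotation requires at least one file")
    config = config or FitConfig()
    paths = [str(p) for p in files]
    fir_list = list(firs) if (use_fir and firs is not None) else None

    results: list[list[PeakMeasurement] | Exception] = [None] * len(paths)  # type: ignore
    if workers <= 1:
        for i, p in enumerate(paths):
            try:
                results[i] = _measure_file(p, list(rois), config, fir_list)
            except Exception as exc:  # noqa: BLE001 - isolation contract
                results[i] = exc
    else:
        with concurrent.futures.ProcessPoolExecutor(max_workers=workers) as pool:
            futures = [pool.submit(_measure_file, p, list(rois), config, fir_list)
                       for p in paths]
            for i, fut in enumerate(futures):
                try:
                    results[i] = fut.result()
                except Exception as exc:  # noqa: BLE001
                    results[i] = exc

    sample_ids, grid, errors = [], [], {}
    n_failed = 0
    for path, res in zip(paths, results):
        sid = Path(path).name.split(".")[0]
        sample_ids.append(sid)
        if isinstance(res, Exception):
            n_failed += 1
            errors[sid] = f"{type(res).__name__}: {res}"
            grid.append(_empty_row(sid, rois, f"file failed: {res}"))
        else:
            grid.append(res)
    if n_failed == len(paths):
        raise BatchError("all files failed: " + "; ".join(
            f"{k}: {v}" for k, v in errors.items()))
    return AnnotationState(sample_ids=sample_ids, rois=rois, measurements=grid,
                           firs=firs, use_fir=use_fir, errors=errors)


def _nan_median(values: list[float]) -> float:
    return float(np.median(values)) if values else float("nan")


def summarize(state: AnnotationState) -> list[CompoundSummary]:
    """Per-compound dataset statistics over found measurements only."""
    out = []
    n_samples = len(state.sample_ids)
    for roi in state.rois:
        col = state.column(roi.cpd_id)
        found = [m for m in col if m.found]
        found_fraction = len(found) / n_samples if n_samples else 0.0
        areas = [m.area for m in found if m.area is not None]
        if len(areas) >= 2 and np.mean(areas) > 0:
            area_rsd = 100.0 * float(np.std(areas, ddof=1) / np.mean(areas))
        elif len(areas) == 1:
            area_rsd = 0.0
        else:
            area_rsd = float("nan")
        if roi.rt is not None:
            devs = [m.apex_rt - roi.rt for m in found if m.apex_rt is not None]
        else:
            devs = []
        rt_dev_median = _nan_median(devs)
        if len(devs) >= 2:
            q75, q25 = np.percentile(devs, [75, 25])
            rt_dev_iqr = float(q75 - q25)
        else:
            rt_dev_iqr = float("nan") if not devs else 0.0
        fallback_fraction = (sum(m.fallback_used for m in found) / len(found)
                             if found else float("nan"))
        ppms = [m.ppm_error for m in found if m.ppm_error is not None]
        out.append(CompoundSummary(
            cpd_id=roi.cpd_id, found_fraction=found_fraction,
            rt_dev_median=rt_dev_median, rt_dev_iqr=rt_dev_iqr,
            area_rsd=area_rsd, fallback_fraction=fallback_fraction,
            ppm_error_median=_nan_median(ppms),
        ))
    return out


def propose_refinement(state: AnnotationState,
                       config: RefinementConfig | None = None
                       ) -> tuple[ROISet, ROISet]:
    """Consensus-refined ROI (uROI) and fallback-integration (FIR) windows.

    Per compound, over its found measurements: the uROI rt window spans the
    observed peak extents padded by one median FWHM; the uROI m/z window is
    the observed m/z range padded by ``mz_pad`` but never wider than the
    original window; the FIR rt window is the median observed extent.
    Compounds found in fewer than ``min_found`` samples keep their original
    windows, flagged ``refined=0`` in the row metadata.
    """
    config = config or RefinementConfig()
    u_list, fir_list = [], []
    for roi in state.rois:
        col = state.column(roi.cpd_id)
        found = [m for m in col
                 if m.found and m.rt_min_obs is not None and m.rt_max_obs is not None]
        if len(found) < config.min_found:
            u_list.append(replace(roi, extra={**roi.extra, "refined": "0"}))
            fir_list.append(replace(roi, extra={**roi.extra, "refined": "0"}))
            continue
        fwhms = [m.fwhm for m in found if m.fwhm is not None]
        pad = config.rt_pad_fwhm * (float(np.median(fwhms)) if fwhms
                                    else roi.rt_span / 4.0)
        lo = min(m.rt_min_obs for m in found) - pad
        hi = max(m.rt_max_obs for m in found) + pad
        if hi <= lo:  # degenerate; keep original
            lo, hi = roi.rt_min, roi.rt_max
        apex_med = float(np.median([m.apex_rt for m in found]))
        lo = min(lo, apex_med - 1e-9)
        hi = max(hi, apex_med + 1e-9)

        mzs = [m.mz_obs for m in found if m.mz_obs is not None]
        if mzs:
            mz_lo = max(min(mzs) - config.mz_pad, roi.mz_min)
            mz_hi = min(max(mzs) + config.mz_pad, roi.mz_max)
            if mz_hi <= mz_lo:
                mz_lo, mz_hi = roi.mz_min, roi.mz_max
        else:
            mz_lo, mz_hi = roi.mz_min, roi.mz_max
        mz_expect = roi.mz
        if mz_expect is not None:
            mz_expect = float(np.clip(mz_expect, mz_lo, mz_hi))

        u_list.append(ROI(
            cpd_id=roi.cpd_id, cpd_name=roi.cpd_name, rt_min=lo, rt_max=hi,
            mz_min=mz_lo, mz_max=mz_hi, rt=apex_med, mz=mz_expect,
            extra={**roi.extra, "refined": "1"},
        ))
        fir_lo = float(np.median([m.rt_min_obs for m in found]))
        fir_hi = float(np.median([m.rt_max_obs for m in found]))
        if fir_hi <= fir_lo:
            fir_lo, fir_hi = lo, hi
        fir_rt = apex_med if fir_lo <= apex_med <= fir_hi else None
        fir_list.append(ROI(
            cpd_id=roi.cpd_id, cpd_name=roi.cpd_name, rt_min=fir_lo,
            rt_max=fir_hi, mz_min=mz_lo, mz_max=mz_hi, rt=fir_rt,
            mz=mz_expect, extra={**roi.extra, "refined": "1"},
        ))
    return ROISet(rois=u_list), ROISet(rois=fir_list)


_MATRIX_FIELDS = ("area", "apex_rt", "apex_height", "fwhm", "tailing_factor",
                  "rt_min_obs", "rt_max_obs", "mz_obs", "ppm_error")


def export_tables(state: AnnotationState, out_dir: str | Path) -> dict[str, Path]:
    """Write the samples x compounds matrices and summary tables as CSV.

    Not-found cells are written as empty cells (missing, not zero).
    Returns a mapping of table name to file path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cpd_ids = state.rois.cpd_ids
    paths: dict[str, Path] = {}

    def _matrix(getter) -> pd.DataFrame:
        data = [[getter(m) for m in row] for row in state.measurements]
        return pd.DataFrame(data, index=state.sample_ids, columns=cpd_ids)

    for fieldname in _MATRIX_FIELDS:
        df = _matrix(lambda m, f=fieldname: getattr(m, f) if m.found else None)
        p = out_dir / f"{fieldname}.csv"
        df.to_csv(p, index_label="sample_id", float_format="%.12g")
        paths[fieldname] = p
    for flag in ("found", "fallback_used"):
        df = _matrix(lambda m, f=flag: int(getattr(m, f)))
        p = out_dir / f"{flag}.csv"
        df.to_csv(p, index_label="sample_id")
        paths[flag] = p

    summary_rows = [vars(s) for s in summarize(state)]
    p = out_dir / "compound_summary.csv"
    pd.DataFrame(summary_rows).to_csv(p, index=False, float_format="%.12g")
    paths["compound_summary"] = p

    if state.u_rois is not None:
        paths["uroi"] = write_roi_csv(state.u_rois, out_dir / "uroi.csv")
    if state.firs is not None:
        paths["fir"] = write_roi_csv(state.firs, out_dir / "fir.csv")
    if state.errors:
        p = out_dir / "file_errors.csv"
        pd.DataFrame(sorted(state.errors.items()),
                     columns=["sample_id", "error"]).to_csv(p, index=False)
        paths["file_errors"] = p
    return paths


def load_state_tables(state_dir: str | Path, rois: ROISet) -> AnnotationState:
    """Rebuild a minimal AnnotationState from export_tables output.

    Only the fields needed by :func:`propose_refinement` and
    :func:`summarize` are restored; fit objects are not.
    """
    state_dir = Path(state_dir)
    tables = {}
    for name in _MATRIX_FIELDS + ("found", "fallback_used"):
        path = state_dir / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing state table: {path}")
        tables[name] = pd.read_csv(path, index_col="sample_id")
    sample_ids = [str(s) for s in tables["found"].index]
    grid = []
    for sid in sample_ids:
        row = []
        for roi in rois:
            found = bool(tables["found"].loc[sid, roi.cpd_id])

            def _get(name: str):
                v = tables[name].loc[sid, roi.cpd_id]
                return None if pd.isna(v) else float(v)

            row.append(PeakMeasurement(
                cpd_id=roi.cpd_id, sample_id=sid, found=found,
                area=_get("area"), apex_rt=_get("apex_rt"),
                apex_height=_get("apex_height"), fwhm=_get("fwhm"),
                tailing_factor=_get("tailing_factor"),
                rt_min_obs=_get("rt_min_obs"), rt_max_obs=_get("rt_max_obs"),
                mz_obs=_get("mz_obs"), ppm_error=_get("ppm_error"),
                fallback_used=bool(tables["fallback_used"].loc[sid, roi.cpd_id]),
            ))
        grid.append(row)
    return AnnotationState(sample_ids=sample_ids, rois=rois, measurements=grid)
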