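"""Synthetic LC-MS runs with known ground truth, written as minimal mzML.

Every run is fully determined by its recipe (including the seed): per scan
and per planted peak one centroid is emitted at ``mz + jitter`` with
intensity ``shape(rt) + baseline + noise`` clipped at zero.  The truth
ledger records, per peak, the (drift-shifted) apex retention time and the
true baseline-free area obtained by quadrature at generation time, so
downstream fitting and integration can be checked against it offline.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence
from xml.sax.saxutils import escape

import numpy as np
import pandas as pd
from scipy import integrate, optimize

from .errors import MzMLWriteError
from .peak_fit import ShapeParams, model_eval
from .raw_io import RawRun, Spectrum
from .target_registry import ROI, ROISet, write_roi_csv

__all__ = ["PeakSpec", "RunRecipe", "simulate_run", "write_mzml", "make_dataset"]


@dataclass
class PeakSpec:
    """Ground-truth parameters of one planted chromatographic peak.

    ``tau == 0`` plants a pure gaussian; ``tau > 0`` an exponentially
    modified gaussian with that time constant.
    """

    cpd_id: str
    mz: float
    mu: float
    sigma: float
    amplitude: float
    tau: float = 0.0
    true_area: float | None = None  # filled in at generation time

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")

    def shape_params(self, baseline: float = 0.0) -> ShapeParams:
        if self.tau > 0:
            return ShapeParams(model="emg", amplitude=self.amplitude, mu=self.mu,
                               sigma=self.sigma, shape=self.tau, baseline=baseline)
        return ShapeParams(model="gaussian", amplitude=self.amplitude, mu=self.mu,
                           sigma=self.sigma, baseline=baseline)


@dataclass
class RunRecipe:
    """Everything needed to deterministically simulate one run."""

    n_scans: int
    rt_start: float
    scan_interval: float
    peaks: list[PeakSpec]
    noise_sd: float = 0.0
    baseline: float = 0.0
    mz_jitter_sd: float = 0.0
    rt_drift: tuple | None = None   # None | ("offset", d) | ("linear", a, b)
    seed: int = 0
    sample_id: str = "sample"

    def __post_init__(self) -> None:
        if self.n_scans < 10:
            raise ValueError("n_scans must be >= 10")
        if self.scan_interval <= 0:
            raise ValueError("scan_interval must be > 0")

    @property
    def rt_end(self) -> float:
        return self.rt_start + (self.n_scans - 1) * self.scan_interval

    def scan_times(self) -> np.ndarray:
        return self.rt_start + self.scan_interval * np.arange(self.n_scans)


def _drift_mu(mu: float, drift: tuple | None) -> float:
    if drift is None:
        return mu
    kind = drift[0]
    if kind == "none":
        return mu
    if kind == "offset":
        return mu + float(drift[1])
    if kind == "linear":
        return float(drift[1]) * mu + float(drift[2])
    raise ValueError(f"unknown drift model {drift!r}")


def _true_area(spec: PeakSpec, mu: float) -> float:
    """Baseline-free area of the planted shape over its full support."""
    p = replace(spec, mu=mu).shape_params(baseline=0.0)

    def f(t: float) -> float:
        return float(model_eval(p, np.array([t]))[0])

    lo = mu - 12.0 * spec.sigma
    hi = mu + 12.0 * spec.sigma + 20.0 * spec.tau
    val, err = integrate.quad(f, lo, hi, points=[mu], limit=400)
    if abs(err) > 1e-8 * max(abs(val), 1.0):
        val2, _ = integrate.quad(f, lo, hi, limit=800)
        val = val2
    return float(val)


def _apex_rt(spec: PeakSpec, mu: float) -> float:
    """Retention time of the (possibly tailed) shape maximum."""
    if spec.tau == 0:
        return mu
    p = replace(spec, mu=mu).shape_params(baseline=0.0)
    res = optimize.minimize_scalar(
        lambda t: -float(model_eval(p, np.array([t]))[0]),
        bounds=(mu - spec.sigma, mu + spec.sigma + 3.0 * spec.tau),
        method="bounded", options={"xatol": 1e-10},
    )
    return float(res.x)


def simulate_run(recipe: RunRecipe) -> tuple[RawRun, dict]:
    """Simulate one run; returns the RawRun and its truth ledger.

    The ledger dict holds:

    * ``peaks``: DataFrame with cpd_id, mz, mu (drifted), apex_rt, sigma,
      tau, amplitude, true_area
    * ``scan_rt``: the scan-time grid
    * ``intensities``: (n_scans x n_peaks) matrix of the exact centroid
      intensities emitted (noise and clipping included)
    * ``noiseless``: same matrix without noise/baseline (pure shape values)
    """
    rng = np.random.default_rng(recipe.seed)
    times = recipe.scan_times()
    n_peaks = len(recipe.peaks)

    drifted = [replace(p, mu=_drift_mu(p.mu, recipe.rt_drift)) for p in recipe.peaks]
    shapes = [p.shape_params(baseline=0.0) for p in drifted]
    noiseless = np.zeros((recipe.n_scans, n_peaks))
    for j, sp in enumerate(shapes):
        noiseless[:, j] = model_eval(sp, times)

    # rng draw order is fixed (scan-major, then peak) so seeds reproduce
    jitter = rng.normal(0.0, recipe.mz_jitter_sd, size=(recipe.n_scans, n_peaks)) \
        if recipe.mz_jitter_sd > 0 else np.zeros((recipe.n_scans, n_peaks))
    noise = rng.normal(0.0, recipe.noise_sd, size=(recipe.n_scans, n_peaks)) \
        if recipe.noise_sd > 0 else np.zeros((recipe.n_scans, n_peaks))

    final = np.clip(noiseless + recipe.baseline + noise, 0.0, None)

    spectra: list[Spectrum] = []
    for i, t in enumerate(times):
        mzs = np.array([p.mz for p in drifted]) + jitter[i]
        order = np.argsort(mzs, kind="stable")
        mz_sorted = mzs[order]
        int_sorted = final[i][order]
        # enforce strictly ascending m/z (centroid collisions are merged)
        keep_mz, keep_int = [], []
        for m, v in zip(mz_sorted, int_sorted):
            if keep_mz and m <= keep_mz[-1]:
                keep_int[-1] += v
            else:
                keep_mz.append(m)
                keep_int.append(v)
        spectra.append(Spectrum(scan_index=i, rt=float(t),
                                mz_values=np.array(keep_mz),
                                intensities=np.array(keep_int)))

    truth_rows = []
    for spec, dspec in zip(recipe.peaks, drifted):
        area = _true_area(spec, dspec.mu)
        truth_rows.append({
            "cpd_id": spec.cpd_id, "mz": spec.mz, "mu": dspec.mu,
            "apex_rt": _apex_rt(spec, dspec.mu), "sigma": spec.sigma,
            "tau": spec.tau, "amplitude": spec.amplitude, "true_area": area,
        })
    ledger = {
        "peaks": pd.DataFrame(truth_rows),
        "scan_rt": times,
        "intensities": final,
        "noiseless": noiseless,
    }
    run = RawRun(sample_id=recipe.sample_id, spectra=spectra, polarity="positive")
    return run, ledger


# ---------------------------------------------------------------------------
# mzML writing

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="https://raw.githubusercontent.com/bio-ontology-research-group/unit-ontology/master/unit.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="{run_id}">
    <spectrumList count="{count}" defaultDataProcessingRef="dp">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _encode_array(values: np.ndarray, compression: str, dtype: str) -> str:
    arr = np.asarray(values, dtype="<f8" if dtype == "f64" else "<f4")
    raw = arr.tobytes()
    if compression == "zlib":
        raw = zlib.compress(raw, 6)
    return base64.b64encode(raw).decode("ascii")


def write_mzml(run: RawRun, path: str | Path, compression: str = "zlib",
               dtype: str = "f64") -> Path:
    """Write a RawRun as minimal standards-conformant mzML (MS1, centroid).

    Retention times are written in seconds; binary arrays are little-endian
    64-bit (or 32-bit) floats, zlib-compressed by default.
    """
    if compression not in ("zlib", "none"):
        raise ValueError("compression must be 'zlib' or 'none'")
    if dtype not in ("f64", "f32"):
        raise ValueError("dtype must be 'f64' or 'f32'")
    path = Path(path)
    dtype_acc = ('MS:1000523', '64-bit float') if dtype == "f64" else ('MS:1000521', '32-bit float')
    comp_acc = ('MS:1000574', 'zlib compression') if compression == "zlib" else ('MS:1000576', 'no compression')
    pol_acc = {
        "positive": ('MS:1000130', 'positive scan'),
        "negative": ('MS:1000129', 'negative scan'),
    }.get(run.polarity)

    try:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(_MZML_HEADER.format(run_id=escape(run.sample_id, {'"': "&quot;"}),
                                         count=len(run.spectra)))
            for i, spec in enumerate(run.spectra):
                mode_acc = ('MS:1000127', 'centroid spectrum') if spec.centroided \
                    else ('MS:1000128', 'profile spectrum')
                b64_mz = _encode_array(spec.mz_values, compression, dtype)
                b64_int = _encode_array(spec.intensities, compression, dtype)
                fh.write(f'      <spectrum index="{i}" id="scan={i}" defaultArrayLength="{spec.mz_values.size}">\n')
                fh.write(f'        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{spec.ms_level}"/>\n')
                fh.write('        <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>\n')
                fh.write(f'        <cvParam cvRef="MS" accession="{mode_acc[0]}" name="{mode_acc[1]}" value=""/>\n')
                if pol_acc:
                    fh.write(f'        <cvParam cvRef="MS" accession="{pol_acc[0]}" name="{pol_acc[1]}" value=""/>\n')
                fh.write('        <scanList count="1">\n          <scan>\n')
                fh.write(f'            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{spec.rt!r}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>\n')
                fh.write('          </scan>\n        </scanList>\n')
                fh.write('        <binaryDataArrayList count="2">\n')
                for kind_acc, kind_name, b64 in (
                    ("MS:1000514", "m/z array", b64_mz),
                    ("MS:1000515", "intensity array", b64_int),
                ):
                    fh.write('          <binaryDataArray>\n')
                    fh.write(f'            <cvParam cvRef="MS" accession="{dtype_acc[0]}" name="{dtype_acc[1]}" value=""/>\n')
                    fh.write(f'            <cvParam cvRef="MS" accession="{comp_acc[0]}" name="{comp_acc[1]}" value=""/>\n')
                    fh.write(f'            <cvParam cvRef="MS" accession="{kind_acc}" name="{kind_name}" value=""/>\n')
                    fh.write(f'            <binary>{b64}</binary>\n')
                    fh.write('          </binaryDataArray>\n')
                fh.write('        </binaryDataArrayList>\n      </spectrum>\n')
            fh.write(_MZML_FOOTER)
    except OSError as exc:
        raise MzMLWriteError(f"cannot write mzML to {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# end-to-end fixture datasets

def default_peaks(n_compounds: int, rt_start: float = 30.0, rt_end: float = 570.0,
                  seed: int = 0) -> list[PeakSpec]:
    """A reproducible panel of EMG peaks spread over the rt range."""
    rng = np.random.default_rng(seed)
    mus = np.linspace(rt_start + 30.0, rt_end - 30.0, n_compounds)
    peaks = []
    for i, mu in enumerate(mus):
        sigma = float(rng.uniform(2.0, 5.0))
        tau = float(rng.uniform(0.5, 1.0) * sigma)
        amp = float(rng.uniform(5e4, 5e5))
        mz = 120.0 + 17.0 * i + float(rng.uniform(-0.2, 0.2))
        peaks.append(PeakSpec(cpd_id=f"C{i+1:03d}", mz=mz, mu=float(mu),
                              sigma=sigma, amplitude=amp, tau=tau))
    return peaks


def rois_for_peaks(peaks: Sequence[PeakSpec], rt_pad_sigmas: float = 4.0,
                   mz_pad: float = 0.01) -> ROISet:
    """ROI windows around the planted peaks (mu +/- 4 sigma, tail-padded)."""
    rois = []
    for p in peaks:
        rois.append(ROI(
            cpd_id=p.cpd_id, cpd_name=f"compound {p.cpd_id}",
            rt_min=p.mu - rt_pad_sigmas * p.sigma,
            rt_max=p.mu + rt_pad_sigmas * p.sigma + 5.0 * p.tau,
            mz_min=p.mz - mz_pad, mz_max=p.mz + mz_pad,
            rt=_apex_rt(p, p.mu), mz=p.mz,
        ))
    return ROISet(rois=rois)


def make_dataset(n_samples: int, out_dir: str | Path, seed: int = 0,
                 n_compounds: int = 10, n_scans: int = 300,
                 rt_start: float = 0.0, scan_interval: float = 1.0,
                 noise_sd: float = 500.0, baseline: float = 1000.0,
                 mz_jitter_sd: float = 0.001,
                 drift: tuple | None = None,
                 peaks: Sequence[PeakSpec] | None = None) -> dict:
    """Generate a full fixture dataset: mzML files + ROI/calibrant/truth CSVs.

    ``drift`` options:

    * ``None`` — all samples share the nominal retention times
    * ``("offset_jitter", sd)`` — each sample gets an rt offset ~ N(0, sd)
    * ``("offset", d)`` / ``("linear", a, b)`` — same systematic drift for
      every sample
    * ``("per_sample", [drift0, drift1, ...])`` — explicit per-sample drifts

    Returns a dict with ``mzml_paths``, ``roi_csv``, ``calibrant_csv``,
    ``truth_csv``, ``truth`` (DataFrame) and ``roiset``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    master_rng = np.random.default_rng(seed)
    rt_end = rt_start + (n_scans - 1) * scan_interval
    if peaks is None:
        peaks = default_peaks(n_compounds, rt_start=rt_start, rt_end=rt_end,
                              seed=seed)
    peaks = list(peaks)

    sample_drifts: list[tuple | None] = []
    for i in range(n_samples):
        if drift is None:
            sample_drifts.append(None)
        elif drift[0] == "offset_jitter":
            sample_drifts.append(("offset", float(master_rng.normal(0.0, drift[1]))))
        elif drift[0] == "per_sample":
            sample_drifts.append(drift[1][i])
        else:
            sample_drifts.append(drift)

    mzml_paths, truth_frames = [], []
    for i, sdrift in enumerate(sample_drifts):
        recipe = RunRecipe(
            n_scans=n_scans, rt_start=rt_start, scan_interval=scan_interval,
            peaks=peaks, noise_sd=noise_sd, baseline=baseline,
            mz_jitter_sd=mz_jitter_sd, rt_drift=sdrift,
            seed=int(master_rng.integers(0, 2**31 - 1)),
            sample_id=f"sample_{i:03d}",
        )
        run, ledger = simulate_run(recipe)
        path = out_dir / f"sample_{i:03d}.mzML"
        write_mzml(run, path)
        mzml_paths.append(path)
        frame = ledger["peaks"].copy()
        frame.insert(0, "sample_id", run.sample_id)
        truth_frames.append(frame)

    truth = pd.concat(truth_frames, ignore_index=True)
    truth_csv = out_dir / "truth.csv"
    truth.to_csv(truth_csv, index=False)

    roiset = rois_for_peaks(peaks)
    roi_csv = write_roi_csv(roiset, out_dir / "roi.csv")

    # calibrants: every other compound, expected rt = undrifted apex
    cal_rows = [{"cpdID": p.cpd_id, "expectedRt": _apex_rt(p, p.mu)}
                for p in peaks[::2]]
    calibrant_csv = out_dir / "calibrants.csv"
    pd.DataFrame(cal_rows).to_csv(calibrant_csv, index=False)

    return {"mzml_paths": mzml_paths, "roi_csv": roi_csv,
            "calibrant_csv": calibrant_csv, "truth_csv": truth_csv,
            "truth": truth, "roiset": roiset}
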