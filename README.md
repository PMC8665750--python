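# peakline

Targeted extraction and integration of annotated compounds from LC–MS
profiling runs. Given raw runs in mzML and a CSV of per-compound
regions of interest (ROI: retention-time and m/z boundaries), peakline

- extracts ROI-bounded ion chromatograms (EIC) by per-scan summation over
  the m/z window,
- fits chromatographic line shapes — exponentially modified Gaussian
  (EMG), skew-normal Gaussian, or plain Gaussian — by bounded nonlinear
  least squares, deriving peak area, FWHM and the USP tailing factor from
  the fitted curve,
- falls back to direct trapezoidal integration of the data points when no
  model fits acceptably,
- aggregates a samples × compounds measurement grid with per-compound
  diagnostics, and proposes consensus-refined ROI (uROI) and fallback
  integration region (FIR) windows for a second pass,
- re-calibrates retention time from calibrant compounds with a seeded
  RANSAC fit (offset / linear / polynomial), moving the target windows —
  never the data,
- ships a synthetic-run generator that writes minimal valid mzML with a
  fully known ground-truth ledger, so the whole pipeline is testable
  offline.

## CLI

One binary, four subcommands. Every command accepts `--config config.yaml`
(keys mirror the flags; unknown keys are rejected) and echoes the fully
resolved configuration next to its outputs.

```sh
# make a reproducible synthetic dataset (mzML + ROI/calibrant/truth CSVs)
peakline simulate --out data/ --n-samples 5 --n-compounds 10 --seed 1

# first pass: extract + fit + export samples x compounds tables
peakline extract data/*.mzML --roi data/roi.csv --out pass1/ --workers 4

# propose consensus-refined windows from the first pass
peakline refine --state-dir pass1/ --roi data/roi.csv --out refined/

# second pass using the refined windows and fallback regions
peakline extract data/*.mzML --roi refined/uroi.csv \
    --fir refined/fir.csv --use-fir --out pass2/

# retention-time re-calibration (RANSAC), writing corrected ROI windows
peakline correct-rt --roi data/roi.csv --calibrants cal.csv \
    --out roi_corrected.csv --kind linear --seed 1
```

`extract` writes one CSV matrix per quantity (`area`, `apex_rt`, `fwhm`,
`tailing_factor`, `found`, `fallback_used`, …) with samples as rows and
compounds as columns; not-found cells are empty, never zero. Outputs are
byte-identical for any `--workers` value given the same inputs and seed.

The ROI CSV uses columns `cpdID, cpdName, rtMin, rt, rtMax, mzMin, mz,
mzMax` (`rt`/`mz` optional, extra columns preserved); retention times are
seconds unless `--rt-unit min` is given. Calibrant CSVs use
`cpdID, expectedRt[, observedRt]`.

## Library

```python
import peakline as pl

run = pl.read_mzml("sample.mzML")
rois = pl.read_roi_csv("roi.csv")
eic = pl.extract_eic(run, rois["cpd1"])
m = pl.measure_peak(eic, rois["cpd1"])          # PeakMeasurement
state = pl.run_annotation(files, rois, pl.FitConfig(), workers=4)
u_rois, firs = pl.propose_refinement(state)
```
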