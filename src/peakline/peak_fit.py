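"""Chromatographic line-shape models, fitting and peak measurement.

Three line shapes are supported:

* ``gaussian``          : ``b + A exp(-(t-mu)^2 / (2 sigma^2))``
* ``skewed_gaussian``   : gaussian scaled by ``1 + erf(alpha (t-mu) / (sigma sqrt 2))``
  (skew-normal shape; ``alpha = 0`` recovers the gaussian exactly)
* ``emg``               : exponentially modified gaussian,
  ``b + A (sigma/tau) sqrt(pi/2) exp(sigma^2/(2 tau^2) - (t-mu)/tau)
  erfc((sigma/tau - (t-mu)/sigma)/sqrt 2)``,
  evaluated through the scaled complementary error function (erfcx) so it
  stays finite for every finite ``t`` — the naive form overflows as soon as
  ``sigma/tau`` is large.

When a model fits acceptably, the peak integral, width (FWHM) and USP
tailing factor are derived from the fitted curve; otherwise a fallback
trapezoidal integration of the raw EIC points handles extreme shape
deviations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import integrate, optimize, special

from .errors import (
    InsufficientDataError,
    NoSignalError,
    UndefinedMetricsError,
)
from .raw_io import EIC
from .target_registry import ROI

__all__ = [
    "ShapeParams",
    "FitConfig",
    "FitResult",
    "PeakMeasurement",
    "model_eval",
    "guess_initial",
    "fit_curve",
    "model_area",
    "fallback_area",
    "peak_metrics",
    "measure_peak",
]

_MODELS = ("gaussian", "skewed_gaussian", "emg")
_SQRT2 = math.sqrt(2.0)
_FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


@dataclass
class ShapeParams:
    """Parameters of one line-shape model.

    ``shape`` is the skew alpha for ``skewed_gaussian`` and the exponential
    time constant tau (seconds) for ``emg``; unused for ``gaussian``.
    """

    model: str
    amplitude: float
    mu: float
    sigma: float
    shape: float = 0.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {_MODELS}")
        for name in ("amplitude", "mu", "sigma", "shape", "baseline"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite parameter {name}")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.model == "emg" and self.shape <= 0:
            raise ValueError("emg requires tau > 0")


@dataclass
class FitConfig:
    """Knobs for fitting, acceptance and detection.

    Defaults are deliberately permissive: the acceptance rule is a relative
    residual RMSE threshold and the detection rule is apex height above
    ``min_height_k`` times the estimated baseline noise sd.
    """

    model: str = "emg"
    fallback_model: str = "skewed_gaussian"
    max_residual: float = 0.35          # accept fit iff rel. residual RMSE <= this
    min_height_k: float = 3.0           # found iff apex >= k * noise sd
    max_nfev: int = 400
    extent_frac: float = 0.05           # peak extent measured at this height fraction

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.fallback_model not in _MODELS:
            raise ValueError(f"unknown fallback model {self.fallback_model!r}")


@dataclass
class FitResult:
    params: ShapeParams
    converged: bool
    residual_rel_rmse: float
    n_points: int


@dataclass
class PeakMeasurement:
    """Measured peak for one (sample, compound) cell.

    Absent fields are None.  ``found=False`` implies all apex/area fields
    are None.
    """

    cpd_id: str
    sample_id: str
    found: bool
    area: Optional[float] = None
    apex_rt: Optional[float] = None
    apex_height: Optional[float] = None
    fwhm: Optional[float] = None
    tailing_factor: Optional[float] = None
    rt_min_obs: Optional[float] = None
    rt_max_obs: Optional[float] = None
    mz_obs: Optional[float] = None
    ppm_error: Optional[float] = None
    fallback_used: bool = False
    fit: Optional[FitResult] = None
    note: str = ""


# ---------------------------------------------------------------------------
# model evaluation

def _gaussian(t: np.ndarray, A: float, mu: float, sigma: float) -> np.ndarray:
    z = (t - mu) / sigma
    return A * np.exp(-0.5 * z * z)


def _skewed_gaussian(t: np.ndarray, A: float, mu: float, sigma: float, alpha: float) -> np.ndarray:
    z = (t - mu) / sigma
    return A * np.exp(-0.5 * z * z) * (1.0 + special.erf(alpha * z / _SQRT2))


def _emg(t: np.ndarray, A: float, mu: float, sigma: float, tau: float) -> np.ndarray:
    # erfcx form: A (sigma/tau) sqrt(pi/2) erfcx(z) exp(-(t-mu)^2/(2 sigma^2))
    # with z = (sigma/tau - (t-mu)/sigma)/sqrt(2); algebraically identical to
    # the erfc form but overflow-free.
    u = (t - mu) / sigma
    z = (sigma / tau - u) / _SQRT2
    pref = A * (sigma / tau) * math.sqrt(math.pi / 2.0)
    out = np.empty_like(u, dtype=np.float64)
    pos = z >= 0
    out[pos] = pref * special.erfcx(z[pos]) * np.exp(-0.5 * u[pos] * u[pos])
    # for z<0 erfcx(z) explodes; use erfc directly (its argument is then
    # comfortably in range because the exp factor compensates)
    neg = ~pos
    if np.any(neg):
        un = u[neg]
        expo = 0.5 * (sigma / tau) ** 2 - un * (sigma / tau)
        out[neg] = pref * special.erfc(z[neg]) * np.exp(np.minimum(expo, 700.0))
    return out


def model_eval(params: ShapeParams, t: np.ndarray) -> np.ndarray:
    """Evaluate the model at times ``t`` (seconds), baseline included."""
    t = np.asarray(t, dtype=np.float64)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    A, mu, sigma, b = params.amplitude, params.mu, params.sigma, params.baseline
    if params.model == "gaussian":
        y = _gaussian(t, A, mu, sigma)
    elif params.model == "skewed_gaussian":
        y = _skewed_gaussian(t, A, mu, sigma, params.shape)
    else:
        y = _emg(t, A, mu, sigma, params.shape)
    y = y + b
    return float(y[0]) if scalar else y


# ---------------------------------------------------------------------------
# initialization and fitting

def estimate_noise_sd(intensity: np.ndarray) -> float:
    """Robust noise sd from scan-to-scan first differences (MAD-scaled)."""
    intensity = np.asarray(intensity, dtype=np.float64)
    if intensity.size < 3:
        return 0.0
    d = np.diff(intensity)
    mad = np.median(np.abs(d - np.median(d)))
    return float(1.4826 * mad / _SQRT2)


def guess_initial(eic: EIC, model: str = "emg") -> ShapeParams:
    """Heuristic starting parameters from the EIC itself.

    mu sits at the intensity argmax, the baseline is the mean of the lowest
    decile, amplitude is apex minus baseline, and sigma comes from the width
    at half apex (clipped to [scan interval, rt window width]).
    """
    if eic.n_scans < 5:
        raise InsufficientDataError(f"EIC has {eic.n_scans} points; need >= 5")
    inten = eic.intensity
    if float(inten.max()) <= 0:
        raise NoSignalError("EIC carries no signal (all intensities zero)")
    i_max = int(np.argmax(inten))
    n_low = max(1, inten.size // 10)
    baseline = float(np.sort(inten)[:n_low].mean())
    amplitude = max(float(inten[i_max]) - baseline, 1e-12)
    half = baseline + 0.5 * amplitude
    j = i_max
    while j > 0 and inten[j] > half:
        j -= 1
    k = i_max
    while k < inten.size - 1 and inten[k] > half:
        k += 1
    width = max(eic.rt[k] - eic.rt[j], eic.scan_interval)
    span = float(eic.rt[-1] - eic.rt[0])
    sigma = float(np.clip(width / _FWHM_FACTOR, eic.scan_interval, max(span, eic.scan_interval)))
    if model == "emg":
        shape = max(sigma / 3.0, 1e-3)
    elif model == "skewed_gaussian":
        shape = 0.1
    else:
        shape = 0.0
    return ShapeParams(
        model=model, amplitude=amplitude, mu=float(eic.rt[i_max]),
        sigma=sigma, shape=shape, baseline=baseline,
    )


def _pack(p: ShapeParams) -> np.ndarray:
    return np.array([p.amplitude, p.mu, p.sigma, p.shape, p.baseline])


def _unpack(model: str, x: np.ndarray) -> ShapeParams:
    return ShapeParams(model=model, amplitude=float(x[0]), mu=float(x[1]),
                       sigma=float(x[2]), shape=float(x[3]), baseline=float(x[4]))


def fit_curve(eic: EIC, model: str | None = None, config: FitConfig | None = None) -> FitResult:
    """Bounded nonlinear least-squares fit of a line shape to the EIC.

    Never raises on optimizer trouble: failure to converge (or a solution
    pinned against a meaningful bound) is recorded as ``converged=False``.
    """
    config = config or FitConfig()
    model = model or config.model
    if eic.n_scans < 5:
        raise InsufficientDataError(f"EIC has {eic.n_scans} points; need >= 5")
    t, y = eic.rt, eic.intensity
    try:
        p0 = guess_initial(eic, model)
    except NoSignalError:
        dummy = ShapeParams(model=model, amplitude=1e-12 + 1e-15, mu=float(t[0]),
                            sigma=max(eic.scan_interval, 1e-6),
                            shape=1e-3 if model == "emg" else 0.0)
        return FitResult(params=dummy, converged=False, residual_rel_rmse=np.inf,
                         n_points=eic.n_scans)

    span = float(t[-1] - t[0])
    y_max = float(y.max())
    dt = max(eic.scan_interval, 1e-9)
    lower = np.array([1e-12, t[0], dt / 2.0, -30.0 if model == "skewed_gaussian" else 1e-6, 0.0])
    upper = np.array([2.0 * y_max, t[-1], max(span, dt), 30.0 if model == "skewed_gaussian" else max(span, dt), y_max])
    free = np.ones(5, dtype=bool)
    if model == "gaussian":
        free[3] = False  # shape slot unused; a near-degenerate bound stalls trf
    x0 = np.clip(_pack(p0), lower + 1e-15, upper - 1e-15)

    def _expand(xf: np.ndarray) -> np.ndarray:
        full = x0.copy()
        full[free] = xf
        return full

    def residuals(xf: np.ndarray) -> np.ndarray:
        return model_eval(_unpack(model, _expand(xf)), t) - y

    try:
        res = optimize.least_squares(
            residuals, x0[free], bounds=(lower[free], upper[free]),
            method="trf", max_nfev=config.max_nfev,
        )
        x = _expand(res.x)
        success = bool(res.success) and np.all(np.isfinite(x))
    except Exception:
        x, success = x0, False

    params = _unpack(model, np.where(np.isfinite(x), x, x0))
    # a solution jammed against a bound that matters is not a trusted fit
    pinned = False
    if success:
        scale = np.maximum(np.abs(upper - lower), 1e-12)
        at_lo = (x - lower) / scale < 1e-6
        at_hi = (upper - x) / scale < 1e-6
        # amplitude hi, mu both, sigma both, shape hi (runaway skew/tau);
        # the gaussian's shape slot is fixed at zero, never a real bound
        pinned = bool(at_hi[0] or at_lo[1] or at_hi[1] or at_lo[2] or at_hi[2])
        if model != "gaussian":
            pinned = pinned or bool(at_hi[3])
    r = model_eval(params, t) - y
    apex_h = max(y_max - params.baseline, 1e-12)
    rel_rmse = float(np.sqrt(np.mean(r * r)) / apex_h)
    return FitResult(params=params, converged=success and not pinned,
                     residual_rel_rmse=rel_rmse, n_points=eic.n_scans)


# ---------------------------------------------------------------------------
# areas and metrics

def model_area(params: ShapeParams, rt_lo: float, rt_hi: float) -> float:
    """Baseline-subtracted integral of the model over [rt_lo, rt_hi]."""
    if rt_hi <= rt_lo:
        return 0.0
    bare = replace(params, baseline=0.0)

    def f(t: float) -> float:
        return model_eval(bare, np.array([t]))[0]

    pts = [params.mu] if rt_lo < params.mu < rt_hi else None
    val, _err = integrate.quad(f, rt_lo, rt_hi, points=pts, limit=200)
    return float(val)


def fallback_area(eic: EIC, rt_lo: float, rt_hi: float):
    """Direct trapezoidal integration of EIC points inside [rt_lo, rt_hi].

    The baseline is the straight segment joining the window-edge
    intensities; baseline-subtracted values are clipped at zero before
    integration.  Returns ``(area, apex_rt, apex_height)`` or
    ``(None, None, None)`` when no points fall in the window.
    """
    mask = (eic.rt >= rt_lo) & (eic.rt <= rt_hi)
    if not np.any(mask):
        return None, None, None
    t = eic.rt[mask]
    y = eic.intensity[mask]
    if t.size == 1:
        return 0.0, float(t[0]), float(y[0])
    base = np.interp(t, [t[0], t[-1]], [y[0], y[-1]])
    net = np.clip(y - base, 0.0, None)
    area = float(np.trapezoid(net, t))
    i = int(np.argmax(y))
    return area, float(t[i]), float(y[i] - base[i])


def _model_apex(params: ShapeParams) -> tuple[float, float]:
    """Locate the model apex (rt, baseline-subtracted height) numerically."""
    tail = params.shape if params.model == "emg" else 0.0
    lo = params.mu - 2.0 * params.sigma
    hi = params.mu + 2.0 * params.sigma + 4.0 * tail
    grid = np.linspace(lo, hi, 801)
    vals = model_eval(params, grid)
    i = int(np.argmax(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda t: -model_eval(params, np.array([t]))[0], bounds=(a, b), method="bounded",
        options={"xatol": 1e-10},
    )
    apex_t = float(res.x)
    apex_h = float(-res.fun - params.baseline)
    return apex_t, apex_h


def _crossing(params: ShapeParams, level: float, apex_t: float, direction: int) -> float:
    """Find where the model falls to ``level`` on one side of the apex."""
    tail = params.shape if params.model == "emg" else 0.0
    step = max(params.sigma, 1e-9) / 2.0
    t0 = apex_t
    limit = 60.0 * (params.sigma + tail)
    travelled = 0.0
    while travelled < limit:
        t1 = t0 + direction * step
        if model_eval(params, np.array([t1]))[0] < level:
            lo, hi = (t1, t0) if direction < 0 else (t0, t1)
            return float(optimize.brentq(
                lambda t: model_eval(params, np.array([t]))[0] - level, lo, hi,
                xtol=1e-10))
        t0 = t1
        travelled += step
        step *= 1.5  # expand the search geometrically for long tails
    raise UndefinedMetricsError("model never falls below the requested level")


def peak_metrics(fit: FitResult, extent_frac: float = 0.05):
    """FWHM, USP tailing factor and 5 %-height extent of a converged fit.

    Tailing factor is the USP definition at ``extent_frac`` of apex height:
    ``(a + b) / (2 a)`` with ``a`` the apex-to-left and ``b`` the
    apex-to-right distances at that height.
    """
    if not fit.converged:
        raise UndefinedMetricsError("metrics undefined for a non-converged fit")
    p = fit.params
    apex_t, apex_h = _model_apex(p)
    if apex_h <= 0:
        raise UndefinedMetricsError("fitted apex height is not positive")
    half = p.baseline + 0.5 * apex_h
    low = p.baseline + extent_frac * apex_h
    t_left_h = _crossing(p, half, apex_t, -1)
    t_right_h = _crossing(p, half, apex_t, +1)
    t_left_l = _crossing(p, low, apex_t, -1)
    t_right_l = _crossing(p, low, apex_t, +1)
    fwhm = abs(t_right_h - t_left_h)
    a = apex_t - t_left_l
    b = t_right_l - apex_t
    tailing = (a + b) / (2.0 * a) if a > 0 else np.inf
    return fwhm, float(tailing), t_left_l, t_right_l


# ---------------------------------------------------------------------------
# top-level measurement

def _not_found(eic: EIC, roi: ROI, note: str, fallback_used: bool = False) -> PeakMeasurement:
    return PeakMeasurement(cpd_id=roi.cpd_id, sample_id=eic.sample_id,
                           found=False, fallback_used=fallback_used, note=note)


def _mz_at_apex(eic: EIC, apex_rt: float) -> float | None:
    if eic.n_scans == 0 or np.all(np.isnan(eic.mz)):
        return None
    i = int(np.argmin(np.abs(eic.rt - apex_rt)))
    if np.isnan(eic.mz[i]):  # zero-intensity scan: use the strongest scan instead
        i = int(np.argmax(eic.intensity))
        if np.isnan(eic.mz[i]):
            return None
    return float(eic.mz[i])


def _data_extent(eic: EIC, apex_idx: int, level: float) -> tuple[float, float]:
    """Contiguous region around the apex staying at/above ``level``."""
    j = apex_idx
    while j > 0 and eic.intensity[j - 1] >= level:
        j -= 1
    k = apex_idx
    while k < eic.n_scans - 1 and eic.intensity[k + 1] >= level:
        k += 1
    half_dt = eic.scan_interval / 2.0 or 1e-9
    return float(eic.rt[j] - half_dt), float(eic.rt[k] + half_dt)


def measure_peak(eic: EIC, roi: ROI, config: FitConfig | None = None) -> PeakMeasurement:
    """Fit-then-fallback measurement of one (sample, compound) cell.

    Tries the configured model, then the fallback model; a fit is accepted
    iff it converged, its relative residual RMSE is within
    ``config.max_residual``, the fitted apex lies inside the ROI rt window
    and the FWHM does not exceed the window span.  On rejection the raw
    data points are integrated instead (``fallback_used=True``).  A cell is
    ``found=False`` when the apex height is below ``min_height_k`` times
    the estimated baseline noise sd.
    """
    config = config or FitConfig()
    if eic.is_empty:
        return _not_found(eic, roi, "empty EIC (no scans in rt window)")
    if float(eic.intensity.max()) <= 0.0:
        return _not_found(eic, roi, "no signal in window")

    noise_sd = estimate_noise_sd(eic.intensity)
    min_height = config.min_height_k * noise_sd

    accepted: FitResult | None = None
    metrics = None
    last_fit: FitResult | None = None
    if eic.n_scans >= 5:
        for model in dict.fromkeys([config.model, config.fallback_model]):
            fit = fit_curve(eic, model, config)
            last_fit = fit
            if not fit.converged or fit.residual_rel_rmse > config.max_residual:
                continue
            try:
                fwhm, tailing, lo5, hi5 = peak_metrics(fit, config.extent_frac)
            except UndefinedMetricsError:
                continue
            apex_t, apex_h = _model_apex(fit.params)
            if not (roi.rt_min <= apex_t <= roi.rt_max):
                continue
            if fwhm > roi.rt_span:
                continue
            accepted = fit
            metrics = (fwhm, tailing, lo5, hi5, apex_t, apex_h)
            break

    if accepted is not None and metrics is not None:
        fwhm, tailing, lo5, hi5, apex_t, apex_h = metrics
        if apex_h < min_height:
            return _not_found(eic, roi, "apex below detection threshold")
        area = model_area(accepted.params, lo5, hi5)
        mz_obs = _mz_at_apex(eic, apex_t)
        ppm = None
        if mz_obs is not None and roi.mz is not None:
            ppm = (mz_obs - roi.mz) / roi.mz * 1e6
        return PeakMeasurement(
            cpd_id=roi.cpd_id, sample_id=eic.sample_id, found=True,
            area=area, apex_rt=apex_t, apex_height=apex_h,
            fwhm=fwhm, tailing_factor=tailing,
            rt_min_obs=lo5, rt_max_obs=hi5, mz_obs=mz_obs, ppm_error=ppm,
            fallback_used=False, fit=accepted,
        )

    # fallback: direct data-point integration over the ROI rt window
    area, apex_rt, apex_h = fallback_area(eic, roi.rt_min, roi.rt_max)
    if area is None:
        return _not_found(eic, roi, "no data points in window", fallback_used=True)
    if apex_h is None or apex_h < min_height or apex_h <= 0:
        return _not_found(eic, roi, "apex below detection threshold", fallback_used=True)
    apex_idx = int(np.argmax(eic.intensity))
    lo_obs, hi_obs = _data_extent(eic, apex_idx, config.extent_frac * eic.intensity[apex_idx])
    mz_obs = _mz_at_apex(eic, apex_rt)
    ppm = None
    if mz_obs is not None and roi.mz is not None:
        ppm = (mz_obs - roi.mz) / roi.mz * 1e6
    return PeakMeasurement(
        cpd_id=roi.cpd_id, sample_id=eic.sample_id, found=True,
        area=area, apex_rt=apex_rt, apex_height=apex_h,
        fwhm=None, tailing_factor=None,
        rt_min_obs=min(lo_obs, apex_rt - 1e-9), rt_max_obs=max(hi_obs, apex_rt + 1e-9),
        mz_obs=mz_obs, ppm_error=ppm,
        fallback_used=True, fit=last_fit,
    )
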