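"""Retention-time re-calibration from calibrant compounds.

The mapping is fitted in the direction ``expected_rt = f(observed_rt)``
(calibrants are measured in the new run's frame) with a seeded, classic
RANSAC loop, then target windows are corrected by the inverse mapping —
windows move, the raw data never does.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from .errors import CalibrationError, InversionError
from .target_registry import ROI, ROISet

__all__ = ["RtObservationSet", "RansacConfig", "RtModel", "fit_rt_ransac",
           "apply_rt_model"]

_MIN_SAMPLES = {"offset": 1, "linear": 2, "poly2": 3, "poly3": 4}


def _degree(kind: str) -> int:
    if kind == "offset":
        return 0
    if kind == "linear":
        return 1
    if kind in ("poly2", "poly3"):
        return int(kind[-1])
    raise ValueError(f"unknown model kind {kind!r}; expected offset|linear|poly2|poly3")


@dataclass
class RtObservationSet:
    """Paired expected/observed retention times for calibrant compounds."""

    cpd_ids: list[str]
    expected_rt: np.ndarray
    observed_rt: np.ndarray

    def __post_init__(self) -> None:
        self.expected_rt = np.asarray(self.expected_rt, dtype=np.float64)
        self.observed_rt = np.asarray(self.observed_rt, dtype=np.float64)
        if not (len(self.cpd_ids) == self.expected_rt.size == self.observed_rt.size):
            raise ValueError("cpd_ids, expected_rt and observed_rt must align")
        if np.any(self.expected_rt <= 0) or np.any(self.observed_rt <= 0):
            raise ValueError("retention times must be > 0")

    def __len__(self) -> int:
        return len(self.cpd_ids)


@dataclass
class RansacConfig:
    n_iter: int = 500
    threshold: float = 5.0            # seconds; inlier residual bound
    min_inlier_fraction: float = 0.5
    seed: int = 0


@dataclass
class RtModel:
    """A fitted rt mapping expected = f(observed).

    ``coefficients`` are highest-degree-first (numpy polyval convention);
    an offset model stores ``[1.0, c]`` so prediction is uniform.
    """

    kind: str
    coefficients: np.ndarray
    inlier_mask: np.ndarray
    inlier_threshold: float
    seed: int

    def predict(self, observed_rt: np.ndarray | float) -> np.ndarray | float:
        return np.polyval(self.coefficients, observed_rt)

    def invert(self, expected_rt: float, rt_range: tuple[float, float] | None = None) -> float:
        """Map an expected-frame rt back to the observed frame."""
        c = self.coefficients
        deg = len(c) - 1
        if deg == 1:
            a, b = float(c[0]), float(c[1])
            if a == 0:
                raise InversionError("degenerate linear model (zero slope)")
            return (expected_rt - b) / a
        if rt_range is None:
            raise InversionError("polynomial inversion needs an rt_range")
        lo, hi = rt_range
        grid = np.linspace(lo, hi, 512)
        deriv = np.polyval(np.polyder(c), grid)
        if not (np.all(deriv > 0) or np.all(deriv < 0)):
            raise InversionError(
                "rt mapping is not monotone on the requested range; use a lower degree")
        f_lo, f_hi = np.polyval(c, lo), np.polyval(c, hi)
        a, b = (f_lo, f_hi) if f_lo < f_hi else (f_hi, f_lo)
        if not (a <= expected_rt <= b):
            # extrapolate linearly beyond the calibrated range
            edge = lo if (expected_rt < a) == (f_lo < f_hi) else hi
            slope = float(np.polyval(np.polyder(c), edge))
            return edge + (expected_rt - float(np.polyval(c, edge))) / slope
        return float(optimize.brentq(
            lambda t: np.polyval(c, t) - expected_rt, lo, hi, xtol=1e-10))


def _fit_ls(kind: str, obs: np.ndarray, exp: np.ndarray) -> np.ndarray:
    if kind == "offset":
        return np.array([1.0, float(np.mean(exp - obs))])
    return np.polyfit(obs, exp, _degree(kind))


def fit_rt_ransac(observations: RtObservationSet, kind: str = "linear",
                  config: RansacConfig | None = None) -> RtModel:
    """Classic seeded RANSAC fit of expected = f(observed).

    For ``n_iter`` iterations a minimal subset is drawn and fitted exactly;
    the consensus set is every point with |residual| <= threshold.  The
    largest consensus wins (ties: lower inlier RMSE, then earlier
    iteration) and is refitted by least squares on its inliers.

    Raises :class:`CalibrationError` when no candidate reaches
    ``min_inlier_fraction``.
    """
    config = config or RansacConfig()
    m = _MIN_SAMPLES[kind]
    n = len(observations)
    if n < m:
        raise CalibrationError(f"{kind} model needs >= {m} calibrants, got {n}")
    obs = observations.observed_rt
    exp = observations.expected_rt
    rng = np.random.default_rng(config.seed)

    best = None  # (count, -neg rmse used via tuple compare) tracked manually
    best_key = None
    for it in range(config.n_iter):
        idx = rng.choice(n, size=m, replace=False)
        o, e = obs[idx], exp[idx]
        if m > 1 and np.unique(o).size < m:
            continue  # degenerate subset
        try:
            coeffs = _fit_ls(kind, o, e)
        except np.linalg.LinAlgError:
            continue
        resid = exp - np.polyval(coeffs, obs)
        mask = np.abs(resid) <= config.threshold
        count = int(mask.sum())
        if count < m:
            continue
        rmse = float(np.sqrt(np.mean(resid[mask] ** 2)))
        key = (-count, rmse, it)
        if best_key is None or key < best_key:
            best_key = key
            best = (mask, coeffs)

    if best is None:
        raise CalibrationError(
            f"RANSAC found no consensus (n={n}, threshold={config.threshold}s)")
    mask, _ = best
    min_inliers = max(m, int(np.ceil(config.min_inlier_fraction * n)))
    if int(mask.sum()) < min_inliers:
        raise CalibrationError(
            f"RANSAC consensus too small: {int(mask.sum())}/{n} inliers "
            f"(need {min_inliers}); residual threshold {config.threshold}s")
    coeffs = _fit_ls(kind, obs[mask], exp[mask])
    # refreshed mask after the least-squares refit
    final_mask = np.abs(exp - np.polyval(coeffs, obs)) <= config.threshold
    return RtModel(kind=kind, coefficients=np.asarray(coeffs, dtype=np.float64),
                   inlier_mask=final_mask, inlier_threshold=config.threshold,
                   seed=config.seed)


def apply_rt_model(rois: ROISet, model: RtModel,
                   rt_range: tuple[float, float] | None = None) -> ROISet:
    """Correct ROI rt windows into the observed frame of a new run.

    Each rt field (rt_min, rt, rt_max) is passed through the inverse
    mapping f^-1; m/z boundaries are untouched.  For polynomial models an
    ``rt_range`` covering the run is required for monotone inversion.
    """
    corrected: list[ROI] = []
    for roi in rois:
        new_min = model.invert(roi.rt_min, rt_range)
        new_max = model.invert(roi.rt_max, rt_range)
        new_rt = model.invert(roi.rt, rt_range) if roi.rt is not None else None
        if new_min >= new_max:
            raise InversionError(
                f"rt correction inverted the window of {roi.cpd_id}")
        corrected.append(replace(roi, rt_min=new_min, rt_max=new_max, rt=new_rt))
    return ROISet(rois=corrected, source_path=rois.source_path)
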