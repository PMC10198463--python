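"""Spectral standardization before quantification: crop, smooth, de-baseline.

The pipeline mirrors what vendor acquisition software does automatically:
Savitzky-Golay smoothing and a slowly-varying-background subtraction.  The
default background estimator is asymmetric least squares (ALS): minimize

    sum_i w_i (y_i - b_i)^2 + lam * sum_i (d2 b)_i^2,

with asymmetric weights w_i = p where y > b and 1 - p otherwise, so the
estimate hugs the valleys between peaks.  The penalized system is
pentadiagonal and solved with a banded Cholesky factorization.

Every applied step is appended to ``spectrum.meta['preprocessing']`` so a
processed spectrum carries its own provenance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter

from .errors import ParameterError, RamanCodeError
from .spectrum import Spectrum

__all__ = ["PreprocessParams", "smooth", "correct_baseline", "asls_baseline", "preprocess"]


@dataclass(frozen=True)
class PreprocessParams:
    """Smoothing, baseline, and crop settings.

    Defaults: Savitzky-Golay window 7 points (14 cm^-1 at 2 cm^-1 steps),
    cubic; ALS with lam=1e5, p=0.01; crop to 900-2400 cm^-1, which covers
    the three code regions plus the polystyrene internal standard.
    """

    smoothing_window: int = 7
    smoothing_polyorder: int = 3
    baseline_method: str = "asymmetric_least_squares"  # | "polynomial" | "none"
    baseline_lam: float = 1e5
    baseline_p: float = 0.01
    baseline_niter: int = 10
    baseline_poly_degree: int = 3
    crop_range: tuple[float, float] | None = (900.0, 2400.0)

    def __post_init__(self) -> None:
        if self.smoothing_window % 2 == 0:
            raise ParameterError("smoothing_window must be odd")
        if self.smoothing_window <= self.smoothing_polyorder:
            raise ParameterError("smoothing_window must exceed smoothing_polyorder")
        if self.baseline_method not in ("asymmetric_least_squares", "polynomial", "none"):
            raise ParameterError(f"unknown baseline_method {self.baseline_method!r}")
        if not 0 < self.baseline_p < 1:
            raise ParameterError("baseline_p must be in (0, 1)")


def smooth(spectrum: Spectrum, params: PreprocessParams) -> Spectrum:
    """Savitzky-Golay local-polynomial smoothing; the grid is unchanged."""
    n = spectrum.intensities.size
    if params.smoothing_window >= n:
        raise ParameterError(
            f"smoothing_window {params.smoothing_window} >= spectrum length {n}"
        )
    y = savgol_filter(
        spectrum.intensities, params.smoothing_window, params.smoothing_polyorder
    )
    out = Spectrum(spectrum.wavenumbers.copy(), y, dict(spectrum.meta))
    _log_step(out, "smooth", window=params.smoothing_window, polyorder=params.smoothing_polyorder)
    return out


def asls_baseline(
    y: np.ndarray, lam: float = 1e5, p: float = 0.01, niter: int = 10
) -> np.ndarray:
    """Asymmetric-least-squares background estimate of *y*.

    Banded (pentadiagonal) formulation of the Eilers-Boelens smoother;
    O(n) per iteration.
    """
    n = y.size
    if n < 3:
        raise ParameterError("ALS needs at least 3 points")
    # upper-banded form of lam * D2' D2 (rows: 2nd superdiag, 1st, main)
    ab0 = np.full(n, lam)
    ab0[:2] = 0.0  # second superdiagonal, padded
    ab1 = np.full(n, -4.0 * lam)
    ab1[0] = 0.0  # padding
    ab1[1] = -2.0 * lam
    ab1[-1] = -2.0 * lam
    main = np.full(n, 6.0 * lam)
    main[0] = main[-1] = lam
    main[1] = main[-2] = 5.0 * lam
    w = np.ones(n)
    baseline = y.copy()
    for _ in range(niter):
        ab = np.vstack([ab0, ab1, main + w])
        baseline = solveh_banded(ab, w * y, lower=False)
        w_new = np.where(y > baseline, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    if not np.all(np.isfinite(baseline)):
        raise RamanCodeError(
            f"ALS baseline failed to converge (lam={lam}, p={p}): non-finite values"
        )
    return baseline


def _polynomial_baseline(x: np.ndarray, y: np.ndarray, degree: int, niter: int) -> np.ndarray:
    """Iterative clipped polynomial fit (modified-polyfit background)."""
    t = (x - x.mean()) / (np.ptp(x) / 2.0)
    work = y.copy()
    baseline = np.zeros_like(y)
    for _ in range(max(niter, 1)):
        coeffs = np.polynomial.polynomial.polyfit(t, work, degree)
        baseline = np.polynomial.polynomial.polyval(t, coeffs)
        work = np.minimum(work, baseline)
    return baseline


def correct_baseline(spectrum: Spectrum, params: PreprocessParams) -> Spectrum:
    """Subtract the estimated slowly varying background."""
    if params.baseline_method == "none":
        out = spectrum.copy()
        _log_step(out, "baseline", method="none")
        return out
    if params.baseline_method == "asymmetric_least_squares":
        baseline = asls_baseline(
            spectrum.intensities, params.baseline_lam, params.baseline_p, params.baseline_niter
        )
    else:
        baseline = _polynomial_baseline(
            spectrum.wavenumbers,
            spectrum.intensities,
            params.baseline_poly_degree,
            params.baseline_niter,
        )
    out = Spectrum(spectrum.wavenumbers.copy(), spectrum.intensities - baseline, dict(spectrum.meta))
    _log_step(
        out,
        "baseline",
        method=params.baseline_method,
        lam=params.baseline_lam,
        p=params.baseline_p,
    )
    return out


def preprocess(spectrum: Spectrum, params: PreprocessParams | None = None) -> Spectrum:
    """Crop, smooth, then baseline-correct with the given (or default) params.

    The pipeline is provenance-aware: a spectrum whose ``meta`` records an
    earlier smoothing or baseline pass does not get that step again
    (repeated local-polynomial filtering progressively broadens narrow
    bands, and every ALS pass shaves a little more off each peak), so
    re-running ``preprocess`` on its own output is an identity apart from
    the harmless crop.  Call :func:`smooth` or :func:`correct_baseline`
    directly to force a re-run.
    """
    if params is None:
        params = PreprocessParams()
    done = {step.get("step") for step in spectrum.meta.get("preprocessing", [])}
    out = spectrum
    if params.crop_range is not None:
        out = out.crop(*params.crop_range)
        _log_step(out, "crop", range=list(params.crop_range))
    if "smooth" not in done:
        out = smooth(out, params)
    if "baseline" not in done:
        out = correct_baseline(out, params)
    return out


def _log_step(spectrum: Spectrum, step: str, **parameters) -> None:
    spectrum.meta.setdefault("preprocessing", []).append({"step": step, **parameters})
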