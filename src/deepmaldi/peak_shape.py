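"""Instrument peak-shape model for MALDI-TOF profile spectra.

Isolated peaks in Deep-MALDI averaged spectra are well described by an
asymmetric Gaussian with independent left/right half-widths at half maximum
(HWHM):

    s(m) = A0 * exp(-(m - m0)^2 ln2 / sigma_L^2)   for m <  m0
    s(m) = A0 * exp(-(m - m0)^2 ln2 / sigma_R^2)   for m >= m0

The widths vary systematically with m/z: approximately linearly at low mass
(instrument response dominated) and quadratically at high mass (isotope
envelope dominated).  Each side's HWHM therefore follows a piecewise trend

    sigma(m) = a0 + a1*m            for m <  m_int
    sigma(m) = c0 + c1*m + c2*m^2   for m >= m_int

with FWHM(m) = sigma_L(m) + sigma_R(m).  :func:`calibrate_peak_shape` fits
these trends from a set of prominent isolated peaks spanning the acquisition
range, the way the shape model is established on a real instrument from
reference-sample preparations.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .spectra_io import Spectrum

__all__ = [
    "AsymmetricGaussian",
    "WidthTrend",
    "PeakShapeModel",
    "PeakFitResult",
    "eval_asym_gaussian",
    "width_at",
    "fit_isolated_peak",
    "calibrate_peak_shape",
    "default_shape_model",
]

_LN2 = math.log(2.0)


@dataclass
class AsymmetricGaussian:
    """Asymmetric-Gaussian peak: amplitude, center (Da), left/right HWHM (Da)."""

    amplitude: float
    center: float
    sigma_l: float
    sigma_r: float

    def __post_init__(self) -> None:
        if self.sigma_l <= 0 or self.sigma_r <= 0:
            raise ValueError("HWHMs must be positive")

    @property
    def fwhm(self) -> float:
        return self.sigma_l + self.sigma_r

    def __call__(self, m) -> np.ndarray:
        return eval_asym_gaussian(self, m)


def eval_asym_gaussian(g: AsymmetricGaussian, m) -> np.ndarray:
    """Evaluate the two-half-width Gaussian; exactly A0/2 at m0 -/+ HWHM."""
    m = np.asarray(m, dtype=float)
    d2 = (m - g.center) ** 2
    sig2 = np.where(m < g.center, g.sigma_l**2, g.sigma_r**2)
    return g.amplitude * np.exp(-d2 * _LN2 / sig2)


@dataclass
class WidthTrend:
    """Piecewise linear/quadratic width-vs-m/z trend for one side (or the FWHM).

    ``m_int`` is the crossover mass; below it the linear branch applies, at and
    above it the quadratic branch.  ``m_int = 0`` gives a pure quadratic (the
    convention for instruments whose trend has no linear regime), and
    ``m_int = inf`` a pure linear trend.
    """

    a0: float
    a1: float
    c0: float
    c1: float
    c2: float
    m_int: float
    side: str = "fwhm"  # {"left", "right", "fwhm"}

    def __call__(self, m) -> np.ndarray:
        m = np.asarray(m, dtype=float)
        lin = self.a0 + self.a1 * m
        quad = self.c0 + self.c1 * m + self.c2 * m**2
        return np.where(m < self.m_int, lin, quad)


@dataclass
class PeakShapeModel:
    """Calibrated width trends for sigma_L, sigma_R and the FWHM."""

    left: WidthTrend
    right: WidthTrend
    fwhm: WidthTrend
    mz_range: tuple = (3000.0, 30000.0)

    def width(self, m, side: str = "fwhm") -> np.ndarray:
        return width_at(self, m, side)

    def to_json(self, path=None) -> str:
        payload = {
            "mz_range": list(self.mz_range),
            "left": asdict(self.left),
            "right": asdict(self.right),
            "fwhm": asdict(self.fwhm),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "PeakShapeModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        trends = {k: WidthTrend(**payload[k]) for k in ("left", "right", "fwhm")}
        return cls(mz_range=tuple(payload["mz_range"]), **trends)


def width_at(model: PeakShapeModel, m, side: str = "fwhm"):
    """Evaluate a calibrated width trend; errors on non-positive widths."""
    trend = {"left": model.left, "right": model.right, "fwhm": model.fwhm}[side]
    w = trend(m)
    if np.any(np.asarray(w) <= 0):
        raise ValueError(f"{side} width trend evaluates non-positive at m={m}")
    return w


@dataclass
class PeakFitResult:
    """An isolated-peak fit: parameters plus the sum of absolute residuals."""

    gaussian: AsymmetricGaussian
    abs_residual: float
    n_points: int


def _initial_guess(mz: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Deterministic start: apex location/height and the empirical HWHM."""
    i = int(np.argmax(y))
    a0, m0 = float(y[i]), float(mz[i])
    half = a0 / 2.0
    above = y >= half
    sig = max((mz[above][-1] - mz[above][0]) / 2.0, 2 * np.median(np.diff(mz)))
    return a0, m0, float(sig)


def fit_isolated_peak(
    s: Spectrum,
    window: tuple[float, float],
    threshold_frac: float = 0.25,
    symmetric: bool = False,
) -> PeakFitResult:
    """Least-squares fit of one asymmetric Gaussian to an isolated peak.

    Only points with intensity above ``threshold_frac`` times the window
    maximum enter the fit (the top 75% of the peak by default), which keeps the
    estimate insensitive to the local background under the peak tails.
    ``symmetric=True`` constrains sigma_L == sigma_R, which is the classical
    single-width Gaussian model used for comparison.
    """
    sub = s.slice(*window)
    ymax = float(sub.intensity.max())
    keep = sub.intensity > threshold_frac * ymax
    if int(keep.sum()) < 5:
        raise ValueError(
            f"window {window}: only {int(keep.sum())} points above "
            f"{threshold_frac} x max; need at least 5"
        )
    mz, y = sub.mz[keep], sub.intensity[keep]
    a0, m0, sig = _initial_guess(mz, y)

    if symmetric:
        def resid(theta):
            a, c, sg = theta
            g = AsymmetricGaussian(max(a, 0.0), c, sg, sg)
            return eval_asym_gaussian(g, mz) - y

        x0 = [a0, m0, sig]
        lb = [0.0, mz[0] - sig, 1e-6]
        ub = [np.inf, mz[-1] + sig, np.inf]
    else:
        def resid(theta):
            a, c, sl, sr = theta
            g = AsymmetricGaussian(max(a, 0.0), c, sl, sr)
            return eval_asym_gaussian(g, mz) - y

        x0 = [a0, m0, sig, sig]
        lb = [0.0, mz[0] - sig, 1e-6, 1e-6]
        ub = [np.inf, mz[-1] + sig, np.inf, np.inf]

    sol = least_squares(resid, x0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise RuntimeError(f"peak fit in window {window} did not converge: {sol.message}")
    if symmetric:
        a, c, sg = sol.x
        g = AsymmetricGaussian(a, c, sg, sg)
    else:
        a, c, sl, sr = sol.x
        g = AsymmetricGaussian(a, c, sl, sr)
    return PeakFitResult(g, abs_residual=float(np.abs(resid(sol.x)).sum()), n_points=len(y))


def _fit_trend_branches(
    masses: np.ndarray,
    widths: np.ndarray,
    linear_range: tuple[float, float],
    quad_range: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray]:
    """OLS linear fit on the low-mass window, quadratic on the (overlapping) high-mass window."""
    lin_sel = (masses >= linear_range[0]) & (masses <= linear_range[1])
    quad_sel = (masses >= quad_range[0]) & (masses <= quad_range[1])
    if lin_sel.sum() < 2:
        raise ValueError(f"need >=2 seed peaks in the linear range {linear_range}")
    if quad_sel.sum() < 3:
        raise ValueError(
            f"need >=3 seed peaks in the quadratic range {quad_range}; "
            f"got {int(quad_sel.sum())} (seed peaks must extend above "
            f"{quad_range[0]/1000:g} kDa)"
        )
    a1, a0 = np.polyfit(masses[lin_sel], widths[lin_sel], 1)
    c2, c1, c0 = np.polyfit(masses[quad_sel], widths[quad_sel], 2)
    return np.array([a0, a1]), np.array([c0, c1, c2])


def _branch_intersection(
    lin: np.ndarray, quad: np.ndarray, lo: float, hi: float
) -> float | None:
    """Root of quad(m) - lin(m) inside [lo, hi], if any (closest to the middle)."""
    a0, a1 = lin
    c0, c1, c2 = quad
    roots = np.roots([c2, c1 - a1, c0 - a0])
    real = roots[np.abs(roots.imag) < 1e-9].real
    inside = real[(real >= lo) & (real <= hi)]
    if len(inside) == 0:
        return None
    mid = 0.5 * (lo + hi)
    return float(inside[np.argmin(np.abs(inside - mid))])


def calibrate_peak_shape(
    spectra: Sequence[Spectrum] | Spectrum,
    seed_peaks: Sequence[tuple[float, float]],
    threshold_frac: float = 0.25,
    linear_range: tuple[float, float] = (3000.0, 17000.0),
    quad_range: tuple[float, float] = (13000.0, 30000.0),
    intersection_range: tuple[float, float] = (13000.0, 17000.0),
    fallback_m_int: float = 15000.0,
    mz_range: tuple[float, float] = (3000.0, 30000.0),
) -> PeakShapeModel:
    """Calibrate the width-trend model from isolated seed peaks.

    Each seed window is fitted per :func:`fit_isolated_peak` in each replicate
    spectrum; per-spectrum linear and quadratic branches are fitted for
    sigma_L, sigma_R and the FWHM (the two branches deliberately overlap in
    mass), trend coefficients are averaged arithmetically across replicate
    preparations, and a single crossover ``m_int`` is taken from the
    intersection of the averaged FWHM branches so that all three trends switch
    branch at the same mass (no width discontinuities between sides).  If the
    branches do not intersect inside ``intersection_range`` the crossover falls
    back to ``fallback_m_int`` with a warning.
    """
    if isinstance(spectra, Spectrum):
        spectra = [spectra]
    if len(seed_peaks) < 8:
        raise ValueError(f"need >=8 seed peaks spanning the range, got {len(seed_peaks)}")

    per_spectrum: list[dict[str, np.ndarray]] = []
    for spec in spectra:
        masses, sl, sr = [], [], []
        for window in seed_peaks:
            fit = fit_isolated_peak(spec, window, threshold_frac=threshold_frac)
            masses.append(fit.gaussian.center)
            sl.append(fit.gaussian.sigma_l)
            sr.append(fit.gaussian.sigma_r)
        masses = np.asarray(masses)
        sl, sr = np.asarray(sl), np.asarray(sr)
        coeffs = {}
        for name, w in (("left", sl), ("right", sr), ("fwhm", sl + sr)):
            lin, quad = _fit_trend_branches(masses, w, linear_range, quad_range)
            coeffs[name] = np.concatenate([lin, quad])
        per_spectrum.append(coeffs)

    avg = {
        name: np.mean([c[name] for c in per_spectrum], axis=0)
        for name in ("left", "right", "fwhm")
    }
    m_int = _branch_intersection(
        avg["fwhm"][:2], avg["fwhm"][2:], *intersection_range
    )
    if m_int is None:
        warnings.warn(
            f"FWHM linear/quadratic branches do not intersect inside "
            f"{intersection_range}; falling back to m_int={fallback_m_int}",
            stacklevel=2,
        )
        m_int = fallback_m_int

    trends = {
        name: WidthTrend(
            a0=float(avg[name][0]), a1=float(avg[name][1]),
            c0=float(avg[name][2]), c1=float(avg[name][3]), c2=float(avg[name][4]),
            m_int=float(m_int), side=name,
        )
        for name in ("left", "right", "fwhm")
    }
    model = PeakShapeModel(left=trends["left"], right=trends["right"],
                           fwhm=trends["fwhm"], mz_range=mz_range)
    _check_model(model)
    return model


def _check_model(model: PeakShapeModel) -> None:
    m = np.linspace(*model.mz_range, 200)
    for side in ("left", "right", "fwhm"):
        w = model.width(m, side)  # raises on non-positive widths
        del w
    mismatch = np.max(
        np.abs(model.width(m, "left") + model.width(m, "right") - model.width(m, "fwhm"))
        / model.width(m, "fwhm")
    )
    if mismatch > 0.05:
        warnings.warn(
            f"sigma_L + sigma_R deviates from the FWHM trend by up to "
            f"{mismatch:.1%} (>5%); trends are mutually inconsistent",
            stacklevel=2,
        )


def _tangent_quadratic(a0: float, a1: float, c2: float, slope: float, m_int: float):
    """Quadratic branch crossing the linear branch at m_int with the given slope."""
    c1 = slope - 2.0 * c2 * m_int
    c0 = (a0 + a1 * m_int) - c1 * m_int - c2 * m_int**2
    return c0, c1, c2


def default_shape_model(mz_range: tuple[float, float] = (3000.0, 30000.0)) -> PeakShapeModel:
    """A synthetic default width-trend model (not an instrument calibration).

    Linear HWHM trends below 15 kDa (right side wider than left, as observed on
    real TOF instruments), transversally crossing quadratic branches above.
    Used by the synthetic-spectrum generator and as a stand-in where no
    calibrated model is supplied; real analyses should calibrate with
    :func:`calibrate_peak_shape`.
    """
    m_int = 15000.0
    specs = {
        # side: (a0, a1, c2, quadratic slope at m_int)
        "left": (0.45, 1.8e-4, 0.9e-8, 2.3e-4),
        "right": (0.75, 2.6e-4, 1.1e-8, 3.2e-4),
        "fwhm": (1.20, 4.4e-4, 2.0e-8, 5.5e-4),
    }
    trends = {}
    for side, (a0, a1, c2, slope) in specs.items():
        c0, c1, c2 = _tangent_quadratic(a0, a1, c2, slope, m_int)
        trends[side] = WidthTrend(a0=a0, a1=a1, c0=c0, c1=c1, c2=c2, m_int=m_int, side=side)
    return PeakShapeModel(left=trends["left"], right=trends["right"],
                          fwhm=trends["fwhm"], mz_range=mz_range)
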