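"""Raster-spectrum alignment and Deep-MALDI averaging.

A raster spectrum is a single 800-laser-shot average from one position on a
MALDI spot; it is noisy and only its strongest peaks are resolvable.  Each
raster is aligned to a set of internal alignment points via a second-order
polynomial in m/z (peaks detected at SNR > 3, matched within a ppm tolerance)
and must pass quality control — enough detected peaks, enough matched points,
and a bounded shift at the lowest alignment point — before it can contribute.
Averaging 500 aligned rasters yields the 400,000-shot analysis spectrum with
greatly improved signal-to-noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra_io import Spectrum
from .peak_shape import PeakShapeModel
from .baseline import EilersParams, STIFF, RELAXED, decompose
from .peak_detect import find_candidates

__all__ = [
    "AlignmentPointSet",
    "RasterQC",
    "DEFAULT_ALIGNMENT_POINTS",
    "align_raster",
    "average_rasters",
]

#: External calibration masses (Da) used on both instruments; the default
#: alignment-point set when no instrument-specific list is supplied.
DEFAULT_ALIGNMENT_POINTS = (
    3320.0,
    4158.7338,
    6636.7971,
    9429.302,
    13890.4398,
    15877.5801,
    28093.951,
)


@dataclass
class AlignmentPointSet:
    """Reference m/z positions with a matching tolerance (ppm) and shift bound."""

    mz_points: np.ndarray = field(
        default_factory=lambda: np.asarray(DEFAULT_ALIGNMENT_POINTS)
    )
    tolerance_ppm: float = 1500.0
    max_shift_lowest: float = 15.0  # Da, at the lowest alignment point

    def __post_init__(self) -> None:
        self.mz_points = np.asarray(self.mz_points, dtype=float)
        if np.any(np.diff(self.mz_points) <= 0):
            raise ValueError("alignment points must be strictly increasing")
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance_ppm must be positive")


@dataclass
class RasterQC:
    n_detected: int
    n_usable: int
    passed: bool
    poly_coeffs: tuple = (0.0, 1.0, 0.0)  # (b0, b1, b2): m' = b0 + b1 m + b2 m^2


def align_raster(
    r: Spectrum,
    pts: AlignmentPointSet,
    shape: PeakShapeModel,
    snr_min: float = 3.0,
    min_detected: int = 20,
    min_usable: int = 13,
    stiff: EilersParams = STIFF,
    relaxed: EilersParams = RELAXED,
) -> tuple[Spectrum, RasterQC]:
    """Align one raster spectrum to the reference alignment points.

    Peaks are detected on the raster's fine structure at a relaxed SNR
    threshold and matched to the nearest alignment point within the ppm
    tolerance.  If at least ``min_detected`` peaks are found and at least
    ``min_usable`` of them match, a quadratic m/z transform is fitted by least
    squares on the matched pairs and applied to the axis.  The fitted shift at
    the lowest alignment point must not exceed the point set's bound.  QC
    failure returns the unchanged spectrum with ``passed=False`` rather than
    raising.
    """
    dec = decompose(r, stiff, relaxed)
    cands = find_candidates(dec.fine, dec.mz, shape, snr_min=snr_min)
    n_detected = len(cands)
    observed = np.array([c.m0 for c in cands])

    matched_obs, matched_ref = [], []
    for ref in pts.mz_points:
        if len(observed) == 0:
            break
        tol = pts.tolerance_ppm * 1e-6 * ref
        k = int(np.argmin(np.abs(observed - ref)))
        if abs(observed[k] - ref) <= tol:
            matched_obs.append(observed[k])
            matched_ref.append(ref)
    n_usable = len(matched_obs)

    fail = RasterQC(n_detected=n_detected, n_usable=n_usable, passed=False)
    if n_detected < min_detected or n_usable < min_usable:
        return r, fail

    b2, b1, b0 = np.polyfit(matched_obs, matched_ref, 2)
    lowest = pts.mz_points[0]
    shift = abs((b0 + b1 * lowest + b2 * lowest**2) - lowest)
    if shift > pts.max_shift_lowest:
        return r, fail

    new_mz = b0 + b1 * r.mz + b2 * r.mz**2
    if np.any(np.diff(new_mz) <= 0):  # degenerate transform
        return r, fail
    qc = RasterQC(n_detected=n_detected, n_usable=n_usable, passed=True,
                  poly_coeffs=(float(b0), float(b1), float(b2)))
    aligned = Spectrum(new_mz, r.intensity.copy(),
                       {**r.meta, "raster_alignment": qc.poly_coeffs})
    return aligned, qc


def average_rasters(
    rasters: list[Spectrum],
    n_select: int,
    seed: int,
    grid: np.ndarray | None = None,
) -> Spectrum:
    """Average a random without-replacement selection of aligned rasters.

    Intensities are linearly interpolated onto a common grid (the first
    raster's axis unless ``grid`` is given) and averaged pointwise.  The
    selection is reproducible from ``seed``.
    """
    if n_select > len(rasters):
        raise ValueError(
            f"cannot select {n_select} rasters from only {len(rasters)} available"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(rasters), size=n_select, replace=False)
    grid = rasters[0].mz if grid is None else np.asarray(grid, float)
    acc = np.zeros_like(grid)
    for k in chosen:
        r = rasters[k]
        acc += np.interp(grid, r.mz, r.intensity)
    shots = sum(rasters[k].meta.get("shots", 800) for k in chosen)
    return Spectrum(grid.copy(), acc / n_select,
                    {"n_averaged": int(n_select), "shots": int(shots), "seed": int(seed)})
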