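"""Spectral alignment to a common m/z axis and master peak-list merging.

Averaged spectra from different preparations carry small residual m/z
miscalibrations.  Each spectrum's fitted peak list is aligned to a set of
reference alignment points with a second-order polynomial: only high-SNR peaks
(at or above the 80th SNR percentile among SNR > 10 peaks) participate, a peak
is "alignable" when it falls within half a local peak width of its nearest
alignment point, every one of four m/z sub-ranges must contribute at least
five alignable peaks, and the least-squares fit weights peaks inversely to
their m/z (so the abundant high-mass points do not dominate).  Spectra that
fail these checks are excluded from further analysis.

Aligned per-sample peak lists are merged into a master list of unique peaks:
an incoming peak further than half a peak width from every master entry is
appended; otherwise its position is folded into the existing entry by a
running (count-weighted) mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra_io import Spectrum
from .peak_shape import PeakShapeModel
from .peak_detect import FittedPeak
from .raster import AlignmentPointSet

__all__ = [
    "AlignmentConfig",
    "AlignmentResult",
    "MasterPeakList",
    "align_spectrum",
    "apply_alignment",
    "merge_peak_lists",
]

_DEFAULT_SUBRANGES = ((3000.0, 7500.0), (7500.0, 12000.0),
                      (12000.0, 18000.0), (18000.0, 30000.0))


@dataclass
class AlignmentConfig:
    """Alignment policy: sub-ranges, per-region minimum, SNR percentile, order."""

    sub_ranges: tuple = _DEFAULT_SUBRANGES
    min_alignable_per_region: int = 5
    snr_percentile: float = 0.80
    poly_order: int = 2
    snr_min: float = 10.0  # peaks below this never participate in alignment

    def __post_init__(self) -> None:
        rs = self.sub_ranges
        for (a, b), (c, d) in zip(rs[:-1], rs[1:]):
            if b != c:
                raise ValueError("sub-ranges must be contiguous and non-overlapping")


@dataclass
class AlignmentResult:
    passed: bool
    coeffs: tuple = (0.0, 1.0, 0.0)  # (b0, b1, b2)
    n_alignable: tuple = ()
    reason: str = ""


def align_spectrum(
    peaks: list[FittedPeak],
    pts: AlignmentPointSet,
    cfg: AlignmentConfig,
    shape: PeakShapeModel,
) -> AlignmentResult:
    """Fit the quadratic m/z correction for one spectrum's fitted peak list.

    Returns the polynomial mapping observed m/z to the reference axis, or a QC
    failure naming the deficient sub-range.
    """
    eligible = [p for p in peaks if p.snr > cfg.snr_min]
    if not eligible:
        return AlignmentResult(False, reason="no peaks above the SNR threshold")
    snrs = np.array([p.snr for p in eligible])
    cut = np.quantile(snrs, cfg.snr_percentile)
    strong = [p for p in eligible if p.snr >= cut]

    obs, ref = [], []
    for p in strong:
        m = p.gaussian.center
        k = int(np.argmin(np.abs(pts.mz_points - m)))
        if abs(pts.mz_points[k] - m) <= 0.5 * float(shape.width(m, "fwhm")):
            obs.append(m)
            ref.append(float(pts.mz_points[k]))
    obs_arr, ref_arr = np.asarray(obs), np.asarray(ref)

    counts = []
    for lo, hi in cfg.sub_ranges:
        c = int(np.sum((obs_arr >= lo) & (obs_arr < hi)))
        counts.append(c)
        if c < cfg.min_alignable_per_region:
            return AlignmentResult(
                False, n_alignable=tuple(counts),
                reason=f"only {c} alignable peaks in [{lo:g}, {hi:g}) Da "
                       f"(need {cfg.min_alignable_per_region})",
            )

    # least squares with weights w_i = 1/m_i (polyfit squares its w argument)
    w = 1.0 / np.sqrt(obs_arr)
    coeffs = np.polyfit(obs_arr, ref_arr, cfg.poly_order, w=w)
    b0, b1, b2 = coeffs[::-1] if cfg.poly_order == 2 else (coeffs[-1], coeffs[-2], 0.0)
    return AlignmentResult(True, coeffs=(float(b0), float(b1), float(b2)),
                           n_alignable=tuple(counts))


def apply_alignment(s: Spectrum, coeffs: tuple[float, float, float]) -> Spectrum:
    """Rewrite the m/z axis through the fitted polynomial (no resampling)."""
    b0, b1, b2 = coeffs
    new_mz = b0 + b1 * s.mz + b2 * s.mz**2
    return Spectrum(new_mz, s.intensity.copy(), {**s.meta, "alignment": coeffs})


@dataclass
class MasterPeakList:
    """Unique peak positions merged across samples, with contributor counts."""

    mz: np.ndarray
    provenance: np.ndarray  # number of source lists contributing to each entry

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.provenance = np.asarray(self.provenance, dtype=int)

    def __len__(self) -> int:
        return len(self.mz)


def merge_peak_lists(
    lists: list[np.ndarray],
    shape: PeakShapeModel,
    merge_frac: float = 0.5,
) -> MasterPeakList:
    """Merge per-sample peak positions into a master list of unique peaks.

    Iterative rule: an incoming peak at m with no master entry closer than
    ``merge_frac`` x FWHM(m) is appended; otherwise the nearest entry's
    position is updated by a running mean weighted by its contributor count
    (order-robust).  A final pass enforces the minimum-separation invariant on
    the merged list itself.
    """
    positions: list[float] = []
    counts: list[int] = []
    for lst in lists:
        for m in np.sort(np.asarray(lst, dtype=float)):
            tol = merge_frac * float(shape.width(m, "fwhm"))
            if positions:
                j = int(np.searchsorted(positions, m))
                best, dist = None, np.inf
                for k in (j - 1, j):
                    if 0 <= k < len(positions) and abs(positions[k] - m) < dist:
                        best, dist = k, abs(positions[k] - m)
                if best is not None and dist < tol:
                    c = counts[best]
                    positions[best] = (positions[best] * c + m) / (c + 1)
                    counts[best] = c + 1
                    continue
            j = int(np.searchsorted(positions, m))
            positions.insert(j, m)
            counts.insert(j, 1)

    # final pass: collapse any adjacent entries that drifted within tolerance
    pos = np.asarray(positions)
    cnt = np.asarray(counts)
    merged_pos, merged_cnt = [], []
    for m, c in zip(pos, cnt):
        if merged_pos:
            tol = merge_frac * float(shape.width(m, "fwhm"))
            if m - merged_pos[-1] < tol:
                tot = merged_cnt[-1] + c
                merged_pos[-1] = (merged_pos[-1] * merged_cnt[-1] + m * c) / tot
                merged_cnt[-1] = tot
                continue
        merged_pos.append(float(m))
        merged_cnt.append(int(c))
    return MasterPeakList(np.asarray(merged_pos), np.asarray(merged_cnt))
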