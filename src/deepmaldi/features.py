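"""Standard and enhanced feature values, normalization and replicate CV statistics.

For every master-list peak the standard feature value FV_S is the fitted
asymmetric-Gaussian amplitude A0, obtained by amplitude-only (non-negative)
fits with centers and widths held fixed — isolated peaks singly, influence
clusters jointly.  The enhanced feature value adds the slowly varying bump
intensity under the peak:

    FV_E(m) = FV_S(m) + Bumps(m)

with negative bump excursions (decomposition artifacts) contributing zero.
Because the bumps pool many unresolved proteins they are more stable across
replicate preparations than weak individual peak amplitudes, so enhanced
values are typically more reproducible.

Reproducibility is quantified per feature by the coefficient of variation
CV = sd/mean over replicate preparations (sample standard deviation), and
summarized by the cumulative distribution N_CV(x) = fraction of features with
CV <= x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra_io import FeatureTable
from .peak_shape import PeakShapeModel
from .baseline import SpectrumDecomposition
from .align import MasterPeakList
from .peak_detect import (
    PeakCandidate,
    assign_clusters,
    convolve_with_shape,
    estimate_noise,
    fit_peaks,
)

__all__ = [
    "FeatureValue",
    "extract_features",
    "build_feature_table",
    "normalize_total",
    "replicate_cv",
    "cv_cumulative",
]


@dataclass
class FeatureValue:
    mz: float
    fv_standard: float
    fv_enhanced: float
    bumps_at_mz: float
    missing: bool = False


def extract_features(
    dec: SpectrumDecomposition,
    master: MasterPeakList,
    shape: PeakShapeModel,
) -> list[FeatureValue]:
    """Amplitude-only extraction of every master-list feature from one spectrum.

    Master positions are grouped by the influence rule (amplitude estimates
    from the convolved fine-structure response), all amplitudes are fitted with
    non-negativity, and the enhanced value adds the (linearly interpolated,
    clipped-at-zero) bump intensity at the master m/z.  Master positions
    outside the spectrum's m/z range are flagged missing rather than zero.
    """
    mz, fine = dec.mz, dec.fine
    in_range = (master.mz >= mz[0]) & (master.mz <= mz[-1])
    conv = convolve_with_shape(fine, mz, shape)
    noise = estimate_noise(fine, mz, shape)

    cands = []
    for m in master.mz[in_range]:
        i = int(np.searchsorted(mz, m))
        i = min(max(i, 0), len(mz) - 1)
        cands.append(PeakCandidate(m0=float(m), snr=float(fine[i] / noise[i]),
                                   index=i, amplitude=float(conv[i])))
    clusters, isolated = assign_clusters(cands, shape)
    fitted = fit_peaks(fine, mz, clusters, isolated, shape, fit_positions=False)
    amp_by_m = {p.gaussian.center: p.gaussian.amplitude for p in fitted}

    out: list[FeatureValue] = []
    for m, ok in zip(master.mz, in_range):
        if not ok:
            out.append(FeatureValue(float(m), np.nan, np.nan, np.nan, missing=True))
            continue
        a0 = float(amp_by_m[float(m)])
        bump = float(np.interp(m, mz, dec.bumps))
        out.append(FeatureValue(float(m), a0, a0 + max(bump, 0.0), bump))
    return out


def build_feature_table(
    per_sample: list[tuple[str, list[FeatureValue]]],
    kind: str = "standard",
) -> FeatureTable:
    """Stack per-sample feature values into a samples x features table."""
    if not per_sample:
        raise ValueError("no samples")
    mzs = np.asarray([fv.mz for fv in per_sample[0][1]])
    attr = {"standard": "fv_standard", "enhanced": "fv_enhanced"}[kind]
    values = np.array([[getattr(fv, attr) for fv in fvs] for _, fvs in per_sample])
    return FeatureTable(feature_mz=mzs, sample_ids=[sid for sid, _ in per_sample],
                        values=values, value_kind=kind)


def normalize_total(table: FeatureTable) -> FeatureTable:
    """Divide each sample's values by its total feature-value intensity."""
    if not np.all(np.isfinite(table.values)):
        raise ValueError("cannot normalize a table with non-finite values")
    totals = table.values.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if len(zero):
        raise ValueError(
            f"zero total feature value for sample(s) "
            f"{[table.sample_ids[i] for i in zero]}"
        )
    return FeatureTable(
        feature_mz=table.feature_mz.copy(),
        sample_ids=list(table.sample_ids),
        values=table.values / totals[:, None],
        value_kind="normalized",
    )


def replicate_cv(
    table: FeatureTable,
    replicate_ids: list | None = None,
) -> pd.DataFrame:
    """Per-feature mean, sample standard deviation (n-1) and CV over replicates.

    ``replicate_ids`` restricts to a subset of sample ids; by default every row
    of the table is treated as a replicate of the same preparation.  Features
    with zero mean get a NaN CV (flagged, not an error).
    """
    if replicate_ids is not None:
        idx = [table.sample_ids.index(r) for r in replicate_ids]
        values = table.values[idx]
    else:
        values = table.values
    if values.shape[0] < 2:
        raise ValueError("need at least 2 replicates")
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    return pd.DataFrame({"mz": table.feature_mz, "mean": mean, "sd": sd, "cv": cv})


def cv_cumulative(cv_values: np.ndarray, x: np.ndarray | float) -> np.ndarray:
    """N_CV(x): fraction of features with CV <= x (NaNs excluded)."""
    cv = np.asarray(cv_values, float)
    cv = cv[np.isfinite(cv)]
    if len(cv) == 0:
        raise ValueError("no finite CV values")
    x = np.asarray(x, float)
    return np.searchsorted(np.sort(cv), x, side="right") / len(cv)
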