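"""End-to-end orchestration: spectra -> decompose -> detect -> align -> merge -> extract.

The pipeline consumes averaged analysis spectra (raster averaging is available
separately in :mod:`deepmaldi.raster`), decomposes each into background, bumps
and fine structure, detects and fits peaks, aligns every spectrum's peak list
to the reference alignment points (spectra failing alignment QC are excluded
and reported), merges the per-sample peak lists into a master list, and
extracts standard and enhanced feature values for every sample at every master
position.  A single resolved :class:`PipelineConfig` is logged with the
outputs so any run is reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .spectra_io import Spectrum, FeatureTable
from .peak_shape import PeakShapeModel, default_shape_model
from .baseline import EilersParams, STIFF, RELAXED, decompose
from .peak_detect import detect_peaks
from .raster import AlignmentPointSet
from .align import (
    AlignmentConfig,
    align_spectrum,
    apply_alignment,
    merge_peak_lists,
    MasterPeakList,
)
from .features import extract_features, build_feature_table

logger = logging.getLogger("deepmaldi")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their standard defaults."""

    stiff: EilersParams = field(default_factory=lambda: STIFF)
    relaxed: EilersParams = field(default_factory=lambda: RELAXED)
    snr_min: float = 10.0
    alignment_points: AlignmentPointSet = field(default_factory=AlignmentPointSet)
    alignment: AlignmentConfig = field(default_factory=AlignmentConfig)
    align_spectra: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["alignment_points"]["mz_points"] = list(
            np.asarray(d["alignment_points"]["mz_points"], float)
        )
        return d


@dataclass
class PipelineResult:
    standard: FeatureTable
    enhanced: FeatureTable
    master: MasterPeakList
    qc: dict  # per-sample alignment QC; excluded samples listed
    config: dict


def run_pipeline(
    spectra: list[tuple[str, Spectrum]],
    shape: PeakShapeModel | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full analysis on named averaged spectra.

    Raises on an empty input or a stage failure (naming the sample); alignment
    QC failures are not errors — those spectra are excluded and listed in the
    QC report.
    """
    if not spectra:
        raise ValueError("no input spectra")
    config = config or PipelineConfig()
    shape = shape or default_shape_model()
    logger.info("pipeline config: %s", json.dumps(config.to_dict(), default=str))

    decomposed, peak_lists, qc = {}, {}, {}
    for sid, spec in spectra:
        try:
            dec = decompose(spec, config.stiff, config.relaxed)
            peaks = detect_peaks(dec.fine, dec.mz, shape, snr_min=config.snr_min)
        except Exception as exc:
            raise RuntimeError(f"stage decompose/detect failed for sample {sid!r}: {exc}") from exc
        decomposed[sid] = (spec, dec)
        peak_lists[sid] = peaks

    kept: list[str] = []
    for sid, peaks in peak_lists.items():
        if config.align_spectra:
            res = align_spectrum(peaks, config.alignment_points, config.alignment, shape)
            qc[sid] = {"aligned": res.passed, "coeffs": res.coeffs, "reason": res.reason}
            if not res.passed:
                logger.warning("sample %s failed alignment QC: %s", sid, res.reason)
                continue
            spec, _ = decomposed[sid]
            aligned = apply_alignment(spec, res.coeffs)
            dec = decompose(aligned, config.stiff, config.relaxed)
            b0, b1, b2 = res.coeffs
            for p in peaks:
                m = p.gaussian.center
                p.gaussian.center = b0 + b1 * m + b2 * m**2
            decomposed[sid] = (aligned, dec)
        else:
            qc[sid] = {"aligned": True, "coeffs": (0.0, 1.0, 0.0), "reason": "alignment disabled"}
        kept.append(sid)

    if not kept:
        raise RuntimeError("every spectrum failed alignment QC")

    master = merge_peak_lists(
        [np.array([p.gaussian.center for p in peak_lists[sid]]) for sid in kept], shape
    )
    per_sample = []
    for sid in kept:
        _, dec = decomposed[sid]
        per_sample.append((sid, extract_features(dec, master, shape)))
    return PipelineResult(
        standard=build_feature_table(per_sample, "standard"),
        enhanced=build_feature_table(per_sample, "enhanced"),
        master=master,
        qc={"samples": qc, "excluded": [s for s in peak_lists if s not in kept]},
        config=config.to_dict(),
    )
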