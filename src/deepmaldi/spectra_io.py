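"""Core containers and plain-text I/O for spectra, peak lists and feature tables.

A :class:`Spectrum` is an (m/z, intensity) pair on a possibly non-uniform grid;
m/z is always in Da and never rescaled internally.  Text spectra are two-column
CSV/TSV files (delimiter auto-detected, ``#`` comments skipped); mzML reading is
optional and delegated to :mod:`pyteomics` when available.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "FeatureTable",
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum",
    "read_feature_table",
    "write_feature_table",
    "read_peak_list",
    "write_peak_list",
]


class SpectrumParseError(ValueError):
    """Raised for malformed spectrum files; carries the offending line number."""


@dataclass
class Spectrum:
    """A profile-mode mass spectrum.

    Attributes
    ----------
    mz : ndarray
        Strictly increasing m/z axis in Da.
    intensity : ndarray
        Intensities (arbitrary units), same length as ``mz``, all finite.
    meta : dict
        Free-form provenance (sample id, raster index, number of shots, ...).
    """

    mz: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("mz and intensity must be one-dimensional")
        if len(self.mz) != len(self.intensity):
            raise ValueError(
                f"length mismatch: {len(self.mz)} m/z values vs "
                f"{len(self.intensity)} intensities"
            )
        if len(self.mz) < 2:
            raise ValueError("a spectrum needs at least 2 points")
        if not np.all(np.isfinite(self.mz)) or not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite values in spectrum")
        dmz = np.diff(self.mz)
        if np.any(dmz <= 0):
            if np.any(dmz == 0):
                dups = np.unique(self.mz[1:][dmz == 0])
                raise ValueError(f"duplicated m/z values: {dups[:10].tolist()}")
            raise ValueError("m/z axis must be strictly increasing")

    def __len__(self) -> int:
        return len(self.mz)

    def slice(self, lo: float, hi: float) -> "Spectrum":
        """Return the sub-spectrum with lo <= m/z <= hi."""
        i0, i1 = np.searchsorted(self.mz, [lo, hi], side="left")
        i1 = int(np.searchsorted(self.mz, hi, side="right"))
        if i1 - i0 < 2:
            raise ValueError(f"window [{lo}, {hi}] contains fewer than 2 points")
        return Spectrum(self.mz[i0:i1].copy(), self.intensity[i0:i1].copy(), dict(self.meta))

    def copy(self) -> "Spectrum":
        return Spectrum(self.mz.copy(), self.intensity.copy(), dict(self.meta))


@dataclass
class FeatureTable:
    """Samples x master-list features.

    ``values[i, j]`` is the feature value of sample ``sample_ids[i]`` at master
    peak ``feature_mz[j]``.  ``value_kind`` records which definition produced
    the numbers (``standard``, ``enhanced`` or ``normalized``).
    """

    feature_mz: np.ndarray
    sample_ids: list
    values: np.ndarray
    value_kind: str = "standard"

    def __post_init__(self) -> None:
        self.feature_mz = np.asarray(self.feature_mz, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.feature_mz.ndim != 1:
            raise ValueError("feature_mz must be 1-D")
        if len(self.feature_mz) == 0:
            raise ValueError("feature table needs at least one feature")
        if np.any(np.diff(self.feature_mz) <= 0):
            raise ValueError("feature_mz must be strictly increasing")
        if self.values.shape != (len(self.sample_ids), len(self.feature_mz)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.sample_ids)} samples, {len(self.feature_mz)} features)"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_mz)

    def to_dataframe(self) -> pd.DataFrame:
        cols = [_format_mz(m) for m in self.feature_mz]
        return pd.DataFrame(self.values, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=cols)


def _format_mz(m: float) -> str:
    return format(float(m), ".12g")


_DELIMS = [",", "\t", ";", None]  # None => whitespace


def _parse_two_columns(path: Path) -> tuple[np.ndarray, np.ndarray]:
    mz, inten = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            for delim in _DELIMS:
                parts = [p for p in line.split(delim) if p != ""]
                if len(parts) >= 2:
                    break
            if len(parts) < 2:
                raise SpectrumParseError(f"{path}:{lineno}: expected two columns, got {line!r}")
            # skip a single header line of non-numeric labels
            try:
                m, y = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1 or (not mz and not inten):
                    continue
                raise SpectrumParseError(
                    f"{path}:{lineno}: non-numeric value in {parts[:2]!r}"
                ) from None
            mz.append(m)
            inten.append(y)
    if len(mz) < 2:
        raise SpectrumParseError(f"{path}: fewer than 2 data rows")
    return np.asarray(mz), np.asarray(inten)


def read_spectrum(path, format: str | None = None) -> Spectrum:
    """Read a spectrum from a two-column text file or an mzML file.

    Text dialect (comma / tab / semicolon / whitespace) is auto-detected and
    ``#`` comment lines are skipped.  Rows are sorted by m/z if needed, in
    which case ``meta['sorted_on_read']`` is set.  Duplicated m/z values are an
    error.  ``format`` may force ``"tsv"``, ``"csv"`` or ``"mzml"``; by default
    it is inferred from the file suffix.
    """
    path = Path(path)
    if format is None:
        format = "mzml" if path.suffix.lower() == ".mzml" else "text"
    if format == "mzml":
        return _read_mzml(path)
    mz, inten = _parse_two_columns(path)
    meta = {"source": str(path)}
    order = np.argsort(mz, kind="stable")
    if np.any(order != np.arange(len(mz))):
        mz, inten = mz[order], inten[order]
        meta["sorted_on_read"] = True
    if np.any(np.diff(mz) == 0):
        dups = np.unique(mz[1:][np.diff(mz) == 0])
        raise SpectrumParseError(f"{path}: duplicated m/z values: {dups[:10].tolist()}")
    return Spectrum(mz, inten, meta)


def _read_mzml(path: Path) -> Spectrum:
    try:
        from pyteomics import mzml as _mzml
    except ImportError as exc:  # soft failure with a clear message
        raise RuntimeError(
            "mzML support requires the 'pyteomics' package "
            "(install deepmaldi[mzml])"
        ) from exc
    with _mzml.read(str(path)) as reader:
        for scan in reader:
            if scan.get("ms level", 1) == 1:
                mz = np.asarray(scan["m/z array"], dtype=float)
                inten = np.asarray(scan["intensity array"], dtype=float)
                meta = {"source": str(path), "scan_id": scan.get("id")}
                return Spectrum(mz, inten, meta)
    raise SpectrumParseError(f"{path}: no MS1 profile spectrum found")


def write_spectrum(spectrum: Spectrum, path, header: bool = True) -> None:
    """Write a spectrum as two-column CSV (12 significant digits)."""
    path = Path(path)
    with open(path, "w") as fh:
        if header:
            fh.write("# mz,intensity\n")
        for m, y in zip(spectrum.mz, spectrum.intensity):
            fh.write(f"{m:.12g},{y:.12g}\n")


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table as CSV: header ``sample_id,<mz_1>,...``.

    Numeric content round-trips at 12 significant digits.
    """
    if table.n_features == 0:
        raise ValueError("refusing to write an empty feature table")
    df = table.to_dataframe()
    df.to_csv(path, float_format="%.12g")


def read_feature_table(path, value_kind: str = "standard") -> FeatureTable:
    df = pd.read_csv(path, index_col=0)
    feature_mz = np.asarray([float(c) for c in df.columns])
    return FeatureTable(feature_mz=feature_mz, sample_ids=list(df.index),
                        values=df.to_numpy(dtype=float), value_kind=value_kind)


_PEAK_COLUMNS = ["mz", "amplitude", "sigma_l", "sigma_r", "snr", "cluster_id"]


def write_peak_list(peaks: Iterable, path) -> None:
    """Write fitted peaks as CSV with columns (mz, amplitude, sigma_L, sigma_R, snr, cluster_id)."""
    rows = []
    for p in peaks:
        g = p.gaussian
        rows.append(
            {
                "mz": g.center,
                "amplitude": g.amplitude,
                "sigma_l": g.sigma_l,
                "sigma_r": g.sigma_r,
                "snr": p.snr,
                "cluster_id": -1 if p.cluster_id is None else p.cluster_id,
            }
        )
    pd.DataFrame(rows, columns=_PEAK_COLUMNS).to_csv(path, index=False, float_format="%.12g")


def read_peak_list(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_PEAK_COLUMNS) - set(df.columns)
    if missing:
        raise SpectrumParseError(f"{path}: peak list missing columns {sorted(missing)}")
    return df
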