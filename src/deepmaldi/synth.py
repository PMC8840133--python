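"""Ground-truth synthetic Deep-MALDI spectra, replicate sets and PSEA panels.

The generator emulates the structure of real averaged serum spectra: several
hundred sharp asymmetric-Gaussian peaks whose widths follow the instrument
width trend and whose amplitudes span ~3.5 orders of magnitude, sitting on
broad Gaussian "bumps" (unresolved biological signal, hundreds of Da wide),
a smooth slowly decaying instrument background, and additive Gaussian noise.
The m/z grid is TOF-like: sampling is uniform in flight time, so grid spacing
grows proportionally to sqrt(m).  Replicates share the truth but draw
per-replicate amplitude jitter, fresh noise and small polynomial m/z
miscalibrations.  Every generator is reproducible from (parameters, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .spectra_io import Spectrum, FeatureTable
from .peak_shape import (
    AsymmetricGaussian,
    PeakShapeModel,
    default_shape_model,
    eval_asym_gaussian,
)

__all__ = [
    "SyntheticTruth",
    "tof_grid",
    "make_truth",
    "make_spectrum",
    "make_replicates",
    "make_psea_panel",
]


def tof_grid(mz_range: tuple[float, float] = (3000.0, 30000.0), n_points: int = 60000) -> np.ndarray:
    """m/z grid with spacing proportional to sqrt(m) (uniform flight-time sampling)."""
    t = np.linspace(np.sqrt(mz_range[0]), np.sqrt(mz_range[1]), n_points)
    return t**2


@dataclass
class SyntheticTruth:
    """Complete description of a synthetic spectrum; the oracle for every stage.

    ``baseline_params = (amplitude, decay_scale_da, offset)`` describes the
    smooth instrument background a*exp(-((m - m_lo)/scale)^2) + offset — a
    matrix hump that peaks at the low-mass cutoff and rolls off smoothly (zero
    slope at the cutoff, as on real TOF instruments).
    ``bump_components`` is a list of (center, fwhm, height) broad Gaussians.
    """

    peak_positions: np.ndarray
    amplitudes: np.ndarray
    shape: PeakShapeModel
    bump_components: list = field(default_factory=list)
    baseline_params: tuple = (2000.0, 8000.0, 200.0)
    noise_sd: float = 10.0
    mz_range: tuple = (3000.0, 30000.0)
    n_points: int = 60000
    seed: int = 0

    def __post_init__(self) -> None:
        self.peak_positions = np.asarray(self.peak_positions, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if len(self.peak_positions) != len(self.amplitudes):
            raise ValueError("positions and amplitudes must have equal length")

    def baseline(self, mz: np.ndarray) -> np.ndarray:
        amp, scale, offset = self.baseline_params
        return amp * np.exp(-(((mz - self.mz_range[0]) / scale) ** 2)) + offset

    def bumps(self, mz: np.ndarray) -> np.ndarray:
        total = np.zeros_like(mz)
        for center, fwhm, height in self.bump_components:
            # symmetric Gaussian parameterized by its FWHM
            total += height * np.exp(-((mz - center) ** 2) * np.log(2.0) / (fwhm / 2.0) ** 2)
        return total

    def peaks(self, mz: np.ndarray, amplitudes: np.ndarray | None = None,
              positions: np.ndarray | None = None) -> np.ndarray:
        amps = self.amplitudes if amplitudes is None else amplitudes
        pos = self.peak_positions if positions is None else positions
        total = np.zeros_like(mz)
        for m0, a0 in zip(pos, amps):
            sl = float(self.shape.width(m0, "left"))
            sr = float(self.shape.width(m0, "right"))
            g = AsymmetricGaussian(a0, m0, sl, sr)
            lo, hi = m0 - 6 * sl, m0 + 6 * sr
            i0, i1 = np.searchsorted(mz, [lo, hi])
            total[i0:i1] += eval_asym_gaussian(g, mz[i0:i1])
        return total

    def true_snr(self) -> np.ndarray:
        """Amplitude over generator noise s.d. — the reference detectability."""
        if self.noise_sd <= 0:
            return np.full(len(self.amplitudes), np.inf)
        return self.amplitudes / self.noise_sd

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["peak_positions"] = self.peak_positions.tolist()
        payload["amplitudes"] = self.amplitudes.tolist()
        payload["shape"] = json.loads(self.shape.to_json())
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _default_bumps(mz_range: tuple[float, float], rng: np.random.Generator, n_bumps: int):
    lo, hi = mz_range
    centers = np.linspace(lo + 0.05 * (hi - lo), hi - 0.05 * (hi - lo), n_bumps)
    centers = centers + rng.uniform(-0.3, 0.3, n_bumps) * (hi - lo) / n_bumps
    fwhms = rng.uniform(700.0, 1400.0, n_bumps)
    heights = rng.uniform(300.0, 1200.0, n_bumps)
    return [(float(c), float(w), float(h)) for c, w, h in zip(centers, fwhms, heights)]


def make_truth(
    n_peaks: int = 500,
    seed: int = 0,
    shape: PeakShapeModel | None = None,
    mz_range: tuple[float, float] = (3000.0, 30000.0),
    n_points: int = 60000,
    dynamic_range_decades: float = 3.5,
    min_amplitude: float = 30.0,
    noise_sd: float = 10.0,
    n_bumps: int = 14,
    min_separation_fwhm: float = 3.0,
) -> SyntheticTruth:
    """Draw a random but reproducible synthetic truth.

    Amplitudes are log-uniform over ``dynamic_range_decades`` decades starting
    at ``min_amplitude`` (default 3.5 decades, the dynamic range of real
    averaged spectra).  Peak positions are uniform over the acquisition range
    with a minimum separation of ``min_separation_fwhm`` local FWHMs, mimicking
    the typical density of resolvable serum peaks.
    """
    rng = np.random.default_rng(seed)
    shape = shape or default_shape_model(mz_range)
    lo, hi = mz_range
    margin = 0.01 * (hi - lo)
    positions: list[float] = []
    # rejection-sample positions with a local minimum-separation constraint
    for _ in range(n_peaks * 60):
        if len(positions) >= n_peaks:
            break
        m = float(rng.uniform(lo + margin, hi - margin))
        fw = float(shape.width(m, "fwhm"))
        if all(abs(m - q) >= min_separation_fwhm * fw for q in positions
               if abs(m - q) < 30 * fw):
            positions.append(m)
    positions = np.sort(np.asarray(positions[:n_peaks]))
    amplitudes = min_amplitude * 10 ** rng.uniform(0.0, dynamic_range_decades, len(positions))
    bumps = _default_bumps(mz_range, rng, n_bumps) if n_bumps else []
    return SyntheticTruth(
        peak_positions=positions,
        amplitudes=amplitudes,
        shape=shape,
        bump_components=bumps,
        noise_sd=noise_sd,
        mz_range=mz_range,
        n_points=n_points,
        seed=seed,
    )


def make_spectrum(
    truth: SyntheticTruth,
    rng: np.random.Generator | None = None,
    amplitudes: np.ndarray | None = None,
    bump_scale: np.ndarray | float = 1.0,
) -> Spectrum:
    """Render the truth on its TOF-like grid: peaks + bumps + baseline + noise.

    Deterministic given the truth's seed (a fresh generator seeded from
    ``truth.seed`` is used when ``rng`` is not supplied).
    """
    rng = np.random.default_rng(truth.seed) if rng is None else rng
    mz = tof_grid(truth.mz_range, truth.n_points)
    y = truth.baseline(mz) + bump_scale * truth.bumps(mz) + truth.peaks(mz, amplitudes)
    if truth.noise_sd > 0:
        y = y + rng.normal(0.0, truth.noise_sd, len(mz))
    return Spectrum(mz, y, {"synthetic": True, "seed": truth.seed})


def _warp_axis(mz: np.ndarray, coeffs: tuple[float, float, float]) -> np.ndarray:
    b0, b1, b2 = coeffs
    return b0 + b1 * mz + b2 * mz**2


def make_replicates(
    truth: SyntheticTruth,
    n: int,
    amp_cv: float = 0.1,
    bump_cv: float = 0.02,
    warp_scale: float = 0.0,
    seed: int | None = None,
) -> list[Spectrum]:
    """Replicate preparations: shared truth, per-replicate jitter.

    Peak amplitudes draw independent lognormal multipliers with coefficient of
    variation ``amp_cv``; bump heights likewise with ``bump_cv`` (bumps pool
    many unresolved proteins, so their total is more stable than individual
    peak amplitudes — the regime in which enhanced feature values help).
    ``warp_scale`` scales a small random quadratic m/z miscalibration
    (``warp_scale = 1`` gives shifts of a few tenths of a Da across the range).
    """
    if n < 2:
        raise ValueError("need at least 2 replicates")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    out = []
    for k in range(n):
        if amp_cv > 0:
            sig = np.sqrt(np.log(1.0 + amp_cv**2))
            mult = rng.lognormal(-sig**2 / 2.0, sig, len(truth.amplitudes))
        else:
            mult = np.ones(len(truth.amplitudes))
        if bump_cv > 0:
            sigb = np.sqrt(np.log(1.0 + bump_cv**2))
            bump_mult = rng.lognormal(-sigb**2 / 2.0, sigb)
        else:
            bump_mult = 1.0
        spec = make_spectrum(truth, rng=rng, amplitudes=truth.amplitudes * mult,
                             bump_scale=bump_mult)
        if warp_scale > 0:
            b0 = rng.normal(0.0, 0.3) * warp_scale
            b1 = 1.0 + rng.normal(0.0, 2e-5) * warp_scale
            b2 = rng.normal(0.0, 5e-10) * warp_scale
            spec = Spectrum(_warp_axis(spec.mz, (b0, b1, b2)), spec.intensity,
                            {**spec.meta, "warp": (b0, b1, b2)})
        spec.meta["replicate"] = k
        out.append(spec)
    return out


def make_psea_panel(
    n_samples: int = 100,
    n_proteins: int = 200,
    processes: dict[str, list[str]] | int = 5,
    n_features: int = 50,
    planted: list[tuple[int, str, float]] | None = None,
    seed: int = 0,
):
    """Synthetic protein panel plus feature table for enrichment testing.

    Protein abundances are i.i.d. lognormal.  ``processes`` is either a
    membership map or a count of disjoint sets (size 12 each) to generate.
    ``planted`` lists (feature_index, process_name, noise_fraction): those
    features are the mean of the process's member-protein abundances plus
    ``noise_fraction`` relative Gaussian noise; all other features are
    independent lognormal draws (null features).

    Returns ``(FeatureTable, ProteinPanel)``.
    """
    from .psea import ProteinPanel
    rng = np.random.default_rng(seed)
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    protein_ids = [f"P{j:04d}" for j in range(n_proteins)]
    abundance = pd.DataFrame(
        rng.lognormal(0.0, 1.0, (n_samples, n_proteins)),
        index=sample_ids, columns=protein_ids,
    )
    if isinstance(processes, int):
        set_size = 12
        if processes * set_size > n_proteins:
            raise ValueError("not enough proteins for the requested process sets")
        perm = rng.permutation(n_proteins)
        process_sets = {
            f"process_{k}": [protein_ids[j] for j in perm[k * set_size:(k + 1) * set_size]]
            for k in range(processes)
        }
    else:
        process_sets = {k: list(v) for k, v in processes.items()}
        for name, members in process_sets.items():
            if not members or not set(members) <= set(protein_ids):
                raise ValueError(f"process {name!r} has invalid membership")

    values = rng.lognormal(0.0, 1.0, (n_samples, n_features))
    for feat_idx, process, noise_frac in planted or []:
        if process not in process_sets:
            raise ValueError(f"planted feature references unknown process {process!r}")
        members = process_sets[process]
        signal = abundance[members].mean(axis=1).to_numpy()
        values[:, feat_idx] = signal + noise_frac * signal.std() * rng.normal(size=n_samples)
    feature_mz = 4000.0 + 50.0 * np.arange(n_features)
    table = FeatureTable(feature_mz=feature_mz, sample_ids=sample_ids,
                         values=values, value_kind="standard")
    return table, ProteinPanel(abundance=abundance, process_sets=process_sets)
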