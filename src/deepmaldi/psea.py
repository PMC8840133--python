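"""Protein set enrichment analysis (PSEA) for mass-spectral features.

Associates each feature with biological processes via a protein panel measured
on the same samples: Spearman correlations between the feature and every panel
protein are computed, proteins are ranked by correlation, and a weighted
Kolmogorov-Smirnov running-sum statistic measures whether the process's member
proteins concentrate at either end of the ranking.  For power, the enrichment
score averages the statistic over random half-splits of the sample set
(correlations recomputed per split).  Significance comes from a permutation
null — feature values shuffled across samples, the whole score recomputed —
with Benjamini-Hochberg control of the false discovery rate across processes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .spectra_io import FeatureTable

__all__ = [
    "ProteinPanel",
    "EnrichmentResult",
    "feature_protein_correlations",
    "ks_enrichment_statistic",
    "enrichment_score",
    "association_test",
]


@dataclass
class ProteinPanel:
    """Protein abundances (samples x proteins) plus process membership sets."""

    abundance: pd.DataFrame
    process_sets: dict

    def __post_init__(self) -> None:
        ids = set(self.abundance.columns)
        for name, members in self.process_sets.items():
            if not members:
                raise ValueError(f"process {name!r} has no members")
            unknown = set(members) - ids
            if unknown:
                raise ValueError(f"process {name!r} references unknown proteins "
                                 f"{sorted(unknown)[:5]}")

    @property
    def protein_ids(self) -> list:
        return list(self.abundance.columns)


@dataclass
class EnrichmentResult:
    feature_mz: float
    process: str
    score: float
    p_value: float
    fdr_significant: bool


def _shared_samples(features: FeatureTable, panel: ProteinPanel) -> list:
    shared = [s for s in features.sample_ids if s in set(panel.abundance.index)]
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared samples; need at least 10")
    return shared


def _rank_normalize(a: np.ndarray, axis: int) -> np.ndarray:
    """Mid-ranked, centered, unit-norm along ``axis``; constant slices -> 0."""
    r = rankdata(a, axis=axis)
    r = r - r.mean(axis=axis, keepdims=True)
    norm = np.sqrt((r**2).sum(axis=axis, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norm > 0, r / np.where(norm == 0, 1.0, norm), 0.0)
    return out


def feature_protein_correlations(features: FeatureTable, panel: ProteinPanel) -> pd.DataFrame:
    """Spearman correlation of every feature with every panel protein.

    Computed over the shared samples with mid-ranked ties; constant features or
    proteins give NaN (undefined, excluded downstream).
    """
    shared = _shared_samples(features, panel)
    fi = [features.sample_ids.index(s) for s in shared]
    F = features.values[fi]  # samples x features
    A = panel.abundance.loc[shared].to_numpy(dtype=float)

    Fr = _rank_normalize(F, axis=0)
    Ar = _rank_normalize(A, axis=0)
    corr = Fr.T @ Ar
    const_f = F.std(axis=0) == 0
    const_p = A.std(axis=0) == 0
    corr[const_f, :] = np.nan
    corr[:, const_p] = np.nan
    return pd.DataFrame(corr, index=[f"{m:.12g}" for m in features.feature_mz],
                        columns=panel.protein_ids)


def ks_enrichment_statistic(
    corrs: np.ndarray,
    member_mask: np.ndarray,
    weight: float = 1.0,
) -> float:
    """Weighted KS running-sum enrichment statistic for one correlation vector.

    Proteins are ranked by decreasing correlation; member proteins advance the
    running sum by |r|^weight (normalized over members), non-members retreat it
    by 1/(N - N_members); the statistic is the signed maximum deviation.  With
    all members at the top of the ranking the statistic attains its maximum
    value of 1.
    """
    corrs = np.asarray(corrs, float)
    member_mask = np.asarray(member_mask, bool)
    if member_mask.sum() == 0:
        raise ValueError("member set does not intersect the ranked proteins")
    scores = _batch_ks(corrs[None, :], member_mask, weight)
    return float(scores[0])


def _batch_ks(C: np.ndarray, mask: np.ndarray, weight: float) -> np.ndarray:
    """Vectorized running-sum statistic for rows of a correlation matrix."""
    finite = np.isfinite(C).all(axis=0)
    C = C[:, finite]
    mask = mask[finite]
    n_members = int(mask.sum())
    if n_members == 0:
        raise ValueError("member set does not intersect the ranked proteins")
    n = C.shape[1]
    if n == n_members:
        raise ValueError("member set covers the whole panel")
    order = np.argsort(-C, axis=1)
    sortedC = np.take_along_axis(C, order, axis=1)
    member_sorted = mask[order]
    w = np.abs(sortedC) ** weight * member_sorted
    denom = w.sum(axis=1, keepdims=True)
    denom = np.where(denom == 0, 1.0, denom)
    p_hit = np.cumsum(w, axis=1) / denom
    p_miss = np.cumsum(~member_sorted, axis=1) / (n - n_members)
    dev = p_hit - p_miss
    best = np.argmax(np.abs(dev), axis=1)
    return dev[np.arange(len(dev)), best]


def _split_indices(n: int, n_splits: int, split_fraction: float,
                   rng: np.random.Generator) -> list[np.ndarray]:
    k = max(2, int(round(split_fraction * n)))
    return [rng.choice(n, size=k, replace=False) for _ in range(n_splits)]


def enrichment_score(
    feature_values: np.ndarray,
    abundance: np.ndarray | pd.DataFrame,
    set_members: np.ndarray,
    n_splits: int = 25,
    split_fraction: float = 0.5,
    seed: int = 0,
    weight: float = 1.0,
) -> float:
    """Split-averaged enrichment score of one feature against one protein set.

    For each of ``n_splits`` random sample subsets (fraction ``split_fraction``
    of the samples, without replacement) the Spearman correlations of the
    feature with every protein are recomputed and the running-sum statistic is
    evaluated; the score is the average over splits.  Deterministic given
    ``seed``.  ``set_members`` is a boolean mask over the abundance columns.
    """
    x = np.asarray(feature_values, float)
    A = abundance.to_numpy(dtype=float) if isinstance(abundance, pd.DataFrame) else np.asarray(abundance, float)
    mask = np.asarray(set_members, bool)
    if mask.sum() < 3:
        raise ValueError("need at least 3 member proteins")
    rng = np.random.default_rng(seed)
    total = 0.0
    for idx in _split_indices(len(x), n_splits, split_fraction, rng):
        xr = _rank_normalize(x[idx][None, :], axis=1)
        ar = _rank_normalize(A[idx], axis=0)
        corr = (xr @ ar)[0]
        total += float(_batch_ks(corr[None, :], mask, weight)[0])
    return total / n_splits


def association_test(
    features: FeatureTable,
    panel: ProteinPanel,
    n_perm: int = 1000,
    alpha: float = 0.01,
    fdr: float = 0.05,
    seed: int = 0,
    n_splits: int = 25,
    split_fraction: float = 0.5,
    weight: float = 1.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Permutation test of feature-process association with BH FDR control.

    For every (feature, process) pair the split-averaged enrichment score is
    compared against a null distribution obtained by recomputing the score on
    ``n_perm`` random permutations of the feature's values across samples
    (two-sided, on the score magnitude); p = (1 + #{|null| >= |observed|}) /
    (1 + n_perm), so p-values are never zero.  A pair is significant when
    p < ``alpha`` and its Benjamini-Hochberg adjusted FDR across the processes
    tested for that feature is at most ``fdr``.

    Returns the per-pair results and the per-process count of associated
    features.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be at least 100, got {n_perm}")
    shared = _shared_samples(features, panel)
    fi = [features.sample_ids.index(s) for s in shared]
    A = panel.abundance.loc[shared].to_numpy(dtype=float)
    n = len(shared)
    rng = np.random.default_rng(seed)
    splits = _split_indices(n, n_splits, split_fraction, rng)

    masks = {
        name: np.isin(panel.protein_ids, list(members))
        for name, members in panel.process_sets.items()
    }
    for name, mask in masks.items():
        if mask.sum() == 0:
            raise ValueError(f"process {name!r} has no proteins in the panel")

    # protein ranks per split, shared by all features and permutations
    Ar = [_rank_normalize(A[idx], axis=0) for idx in splits]

    rows = []
    process_names = list(panel.process_sets)
    for j, mz in enumerate(features.feature_mz):
        x = features.values[fi, j]
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])
        X = np.vstack([x[None, :], x[perms]])  # (1 + n_perm, n)
        scores = {name: np.zeros(1 + n_perm) for name in process_names}
        for idx, ar in zip(splits, Ar):
            xr = _rank_normalize(X[:, idx], axis=1)
            corr = xr @ ar  # (1 + n_perm, n_proteins)
            order = np.argsort(-corr, axis=1)
            sortedC = np.take_along_axis(corr, order, axis=1)
            absw = np.abs(sortedC) ** weight
            for name in process_names:
                member_sorted = masks[name][order]
                w = absw * member_sorted
                denom = w.sum(axis=1, keepdims=True)
                denom = np.where(denom == 0, 1.0, denom)
                p_hit = np.cumsum(w, axis=1) / denom
                p_miss = np.cumsum(~member_sorted, axis=1) / (
                    corr.shape[1] - masks[name].sum()
                )
                dev = p_hit - p_miss
                best = np.argmax(np.abs(dev), axis=1)
                scores[name] += dev[np.arange(len(dev)), best]
        pvals = {}
        for name in process_names:
            s = scores[name] / n_splits
            obs, null = s[0], s[1:]
            pvals[name] = (1.0 + np.sum(np.abs(null) >= abs(obs))) / (1.0 + n_perm)
            scores[name] = obs
        reject = multipletests(
            [pvals[name] for name in process_names], alpha=fdr, method="fdr_bh"
        )[0]
        for name, rej in zip(process_names, reject):
            rows.append(
                EnrichmentResult(
                    feature_mz=float(mz),
                    process=name,
                    score=float(scores[name]),
                    p_value=float(pvals[name]),
                    fdr_significant=bool(rej and pvals[name] < alpha),
                )
            )

    results = pd.DataFrame([r.__dict__ for r in rows])
    counts = (
        results[results.fdr_significant]
        .groupby("process")["feature_mz"]
        .count()
        .reindex(process_names, fill_value=0)
        .rename("n_associated")
    )
    return results, counts
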