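import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from deepmaldi.psea import (
    ProteinPanel,
    association_test,
    enrichment_score,
    feature_protein_correlations,
    ks_enrichment_statistic,
)
from deepmaldi.spectra_io import FeatureTable
from deepmaldi.synth import make_psea_panel


def _table(values, mz=None):
    values = np.asarray(values, float)
    mz = np.arange(1.0, values.shape[1] + 1) * 1000 if mz is None else mz
    return FeatureTable(mz, [f"S{i:03d}" for i in range(values.shape[0])], values)


class TestCorrelations:
    def test_identical_series_has_rho_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        panel = ProteinPanel(
            pd.DataFrame({"P0": x, "P1": rng.normal(size=30)},
                         index=[f"S{i:03d}" for i in range(30)]),
            {"proc": ["P0"]},
        )
        corr = feature_protein_correlations(_table(x[:, None]), panel)
        assert corr.iloc[0, 0] == pytest.approx(1.0)

    def test_monotone_decreasing_transform_has_rho_minus_one(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(1.0, 2.0, 40)
        panel = ProteinPanel(
            pd.DataFrame({"P0": np.exp(-x)}, index=[f"S{i:03d}" for i in range(40)]),
            {"proc": ["P0"]},
        )
        corr = feature_protein_correlations(_table(x[:, None]), panel)
        assert corr.iloc[0, 0] == pytest.approx(-1.0)

    def test_matches_scipy_spearman(self):
        rng = np.random.default_rng(2)
        F = rng.normal(size=(50, 4))
        A = rng.normal(size=(50, 6))
        ids = [f"S{i:03d}" for i in range(50)]
        panel = ProteinPanel(
            pd.DataFrame(A, index=ids, columns=[f"P{j}" for j in range(6)]),
            {"proc": ["P0", "P1", "P2"]},
        )
        corr = feature_protein_correlations(_table(F), panel)
        for i in range(4):
            for j in range(6):
                want = spearmanr(F[:, i], A[:, j]).statistic
                assert corr.iloc[i, j] == pytest.approx(want, abs=1e-12)

    def test_null_correlation_scale(self):
        rng = np.random.default_rng(3)
        n = 100
        F = rng.normal(size=(n, 10))
        A = rng.normal(size=(n, 100))
        ids = [f"S{i:03d}" for i in range(n)]
        panel = ProteinPanel(
            pd.DataFrame(A, index=ids, columns=[f"P{j:03d}" for j in range(100)]),
            {"proc": ["P000", "P001", "P002"]},
        )
        corr = feature_protein_correlations(_table(F), panel).to_numpy().ravel()
        assert abs(corr.mean()) < 0.01
        assert corr.std() == pytest.approx(1 / np.sqrt(n - 1), rel=0.2)

    def test_constant_series_flagged_nan(self):
        ids = [f"S{i:03d}" for i in range(20)]
        rng = np.random.default_rng(4)
        panel = ProteinPanel(
            pd.DataFrame({"P0": np.ones(20), "P1": rng.normal(size=20)}, index=ids),
            {"proc": ["P0", "P1"]},
        )
        corr = feature_protein_correlations(_table(rng.normal(size=(20, 1))), panel)
        assert np.isnan(corr.iloc[0, 0])
        assert np.isfinite(corr.iloc[0, 1])


class TestKsStatistic:
    def test_members_at_top_attain_maximum(self):
        corrs = np.linspace(1.0, -1.0, 100)
        mask = np.zeros(100, bool)
        mask[:10] = True
        assert ks_enrichment_statistic(corrs, mask) == pytest.approx(1.0)

    def test_interspersed_members_score_near_zero(self):
        corrs = np.linspace(1.0, -1.0, 100)
        mask = np.zeros(100, bool)
        mask[4::10] = True  # mid-decile placement; |score| ~ 1/(2 n_members)
        assert abs(ks_enrichment_statistic(corrs, mask, weight=0.0)) < 0.1

    def test_empty_intersection_is_error(self):
        with pytest.raises(ValueError, match="intersect"):
            ks_enrichment_statistic(np.ones(10), np.zeros(10, bool))

    def test_null_scores_symmetric_about_zero(self):
        rng = np.random.default_rng(5)
        scores = []
        for _ in range(200):
            corrs = rng.normal(0.0, 0.1, 80)
            mask = np.zeros(80, bool)
            mask[rng.choice(80, 8, replace=False)] = True
            scores.append(ks_enrichment_statistic(corrs, mask))
        scores = np.array(scores)
        assert abs(np.mean(scores)) < 3 * np.std(scores) / np.sqrt(len(scores)) + 0.05


class TestEnrichmentScore:
    def test_deterministic_given_seed(self):
        table, panel = make_psea_panel(n_samples=60, n_proteins=60, processes=3,
                                       n_features=4, seed=6)
        mask = np.isin(panel.protein_ids, panel.process_sets["process_0"])
        a = enrichment_score(table.values[:, 0], panel.abundance, mask, n_splits=5, seed=9)
        b = enrichment_score(table.values[:, 0], panel.abundance, mask, n_splits=5, seed=9)
        assert a == b

    def test_planted_feature_scores_high(self):
        table, panel = make_psea_panel(n_samples=80, n_proteins=100, processes=4,
                                       n_features=6, planted=[(0, "process_1", 0.1)],
                                       seed=7)
        mask = np.isin(panel.protein_ids, panel.process_sets["process_1"])
        planted = enrichment_score(table.values[:, 0], panel.abundance, mask, seed=1)
        null = enrichment_score(table.values[:, 1], panel.abundance, mask, seed=1)
        assert planted > 0.4
        assert planted > abs(null) * 2

    def test_small_member_set_rejected(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError, match="at least 3"):
            enrichment_score(rng.normal(size=20), rng.normal(size=(20, 10)),
                             np.array([True] + [False] * 9))


class TestAssociationTest:
    def test_planted_pair_significant(self):
        table, panel = make_psea_panel(n_samples=100, n_proteins=120, processes=4,
                                       n_features=8, planted=[(2, "process_3", 0.1)],
                                       seed=10)
        res, counts = association_test(table, panel, n_perm=200, seed=3)
        row = res[(res.process == "process_3")
                  & (res.feature_mz == table.feature_mz[2])].iloc[0]
        assert row.p_value < 0.01
        assert row.fdr_significant
        assert counts["process_3"] >= 1

    def test_null_pairs_rarely_significant(self):
        table, panel = make_psea_panel(n_samples=80, n_proteins=100, processes=4,
                                       n_features=10, seed=11)
        res, counts = association_test(table, panel, n_perm=200, seed=4)
        assert (res.p_value < 0.01).mean() < 0.1
        assert counts.sum() <= 2

    def test_permutation_pvalues_never_zero(self):
        table, panel = make_psea_panel(n_samples=60, n_proteins=60, processes=3,
                                       n_features=3, planted=[(0, "process_0", 0.05)],
                                       seed=12)
        res, _ = association_test(table, panel, n_perm=150, seed=5)
        assert (res.p_value > 0).all()
        assert res.p_value.min() >= 1.0 / 151

    def test_too_few_permutations_rejected(self):
        table, panel = make_psea_panel(n_samples=60, n_proteins=60, processes=2,
                                       n_features=2, seed=13)
        with pytest.raises(ValueError, match="at least 100"):
            association_test(table, panel, n_perm=0)
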