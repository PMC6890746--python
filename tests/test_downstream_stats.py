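"""TPM, z-scores, hypergeometric enrichment and ddCt arithmetic."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ccmlnc import downstream_stats as ds
from ccmlnc.errors import AnalysisError
from ccmlnc.io import GeneSet


class TestTpm:
    def test_two_gene_worked_example(self):
        counts = pd.DataFrame({"s1": [10, 20]}, index=["G1", "G2"])
        lengths = pd.Series([1000, 2000], index=["G1", "G2"])
        tpm = ds.tpm_normalize(counts, lengths)
        np.testing.assert_allclose(tpm["s1"], [500000.0, 500000.0])

    def test_columns_sum_to_one_million(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(0, 1000, size=(50, 6)), index=[f"G{i}" for i in range(50)]
        )
        lengths = pd.Series(rng.integers(500, 5000, size=50), index=counts.index)
        tpm = ds.tpm_normalize(counts, lengths)
        np.testing.assert_allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_all_zero_column_rejected(self):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]}, index=["G1", "G2"])
        lengths = pd.Series([1000, 1000], index=["G1", "G2"])
        with pytest.raises(AnalysisError, match="s2"):
            ds.tpm_normalize(counts, lengths)

    def test_missing_length_rejected(self):
        counts = pd.DataFrame({"s1": [1, 2]}, index=["G1", "G2"])
        with pytest.raises(AnalysisError, match="length"):
            ds.tpm_normalize(counts, pd.Series([1000], index=["G1"]))


class TestZscore:
    def test_hand_vector(self):
        panel = pd.DataFrame([[1.0, 2.0, 3.0]], index=["G1"])
        np.testing.assert_allclose(ds.zscore_by_gene(panel).iloc[0], [-1.0, 0.0, 1.0])

    def test_rows_standardised(self):
        rng = np.random.default_rng(1)
        panel = pd.DataFrame(rng.uniform(0, 100, size=(20, 8)))
        z = ds.zscore_by_gene(panel)
        np.testing.assert_allclose(z.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_constant_row_becomes_zero(self, caplog):
        panel = pd.DataFrame([[5.0, 5.0, 5.0]], index=["G1"])
        with caplog.at_level("WARNING"):
            z = ds.zscore_by_gene(panel)
        np.testing.assert_allclose(z.iloc[0], 0.0)
        assert any("constant" in rec.message for rec in caplog.records)

    def test_tpm_then_zscore_invariant_to_library_rescaling(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(
            rng.integers(1, 500, size=(30, 5)), index=[f"G{i}" for i in range(30)]
        )
        lengths = pd.Series(rng.integers(500, 3000, size=30), index=counts.index)
        z1 = ds.zscore_by_gene(ds.tpm_normalize(counts, lengths))
        scaled = counts.copy()
        scaled.iloc[:, 2] *= 7  # uniform depth rescaling of one column
        z2 = ds.zscore_by_gene(ds.tpm_normalize(scaled, lengths))
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-9)


class TestBrainContrast:
    @pytest.fixture()
    def z(self):
        cols = pd.MultiIndex.from_product(
            [["brain", "liver"], ["1", "2"]], names=("tissue", "replicate")
        )
        return pd.DataFrame(
            [[-2.0, -1.0, 1.0, 2.0], [1.5, 2.5, -1.0, -3.0], [0.0, 0.0, 0.0, 0.0]],
            index=["up1", "down1", "flat"],
            columns=cols,
        )

    def test_planted_direction(self, z):
        up_z, down_z = ds.brain_contrast(z, ["up1"], ["down1"])
        assert up_z < down_z
        assert up_z == pytest.approx(-1.5)

    def test_equal_sets_equal_means(self, z):
        a, b = ds.brain_contrast(z, ["up1", "down1"], ["up1", "down1"])
        assert a == b

    def test_empty_set_undefined(self, z):
        up_z, _ = ds.brain_contrast(z, [], ["down1"])
        assert math.isnan(up_z)

    def test_single_brain_replicate(self):
        cols = pd.MultiIndex.from_tuples(
            [("brain", "1"), ("liver", "1")], names=("tissue", "replicate")
        )
        z = pd.DataFrame([[-1.0, 1.0]], index=["g"], columns=cols)
        up_z, _ = ds.brain_contrast(z, ["g"], [])
        assert up_z == pytest.approx(-1.0)


def _enumeration_p(universe_size, set_size, query_size, overlap):
    """Exhaustively enumerate all query draws, counting overlap >= observed."""
    universe = range(universe_size)
    members = set(range(set_size))
    hits = total = 0
    for draw in itertools.combinations(universe, query_size):
        total += 1
        hits += len(members & set(draw)) >= overlap
    return hits / total


class TestEnrichment:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            n = int(rng.integers(8, 26))
            k = int(rng.integers(1, n))
            q = int(rng.integers(1, min(n, 6)))
            universe = [f"g{i}" for i in range(n)]
            members = frozenset(universe[:k])
            query = list(rng.choice(universe, size=q, replace=False))
            res = ds.hypergeometric_enrichment(
                query, [GeneSet("T", "t", "GO_BP", members)], universe
            )
            overlap = res.loc[0, "overlap_count"]
            assert res.loc[0, "p"] == pytest.approx(
                _enumeration_p(n, k, q, overlap), abs=1e-12
            )

    def test_term_equal_to_universe_has_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        res = ds.hypergeometric_enrichment(
            universe[:5], [GeneSet("ALL", "a", "KEGG", frozenset(universe))], universe
        )
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_equals_one_sided_fisher(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(20, 200))
            k = int(rng.integers(1, n))
            q = int(rng.integers(1, n))
            universe = [f"g{i}" for i in range(n)]
            members = frozenset(rng.choice(universe, size=k, replace=False))
            query = set(rng.choice(universe, size=q, replace=False))
            res = ds.hypergeometric_enrichment(
                query, [GeneSet("T", "t", "GO_BP", members)], universe
            )
            overlap = res.loc[0, "overlap_count"]
            table = [
                [overlap, len(query) - overlap],
                [k - overlap, n - k - (len(query) - overlap)],
            ]
            fisher = stats.fisher_exact(table, alternative="greater").pvalue
            assert res.loc[0, "p"] == pytest.approx(fisher, abs=1e-12)

    def test_p_monotone_decreasing_in_overlap(self):
        ps = [
            float(stats.hypergeom.sf(k - 1, 100, 20, 10)) for k in range(0, 11)
        ]
        universe = [f"g{i}" for i in range(100)]
        # same quantity through the module surface for two overlaps
        res = []
        for overlap in (2, 5):
            members = frozenset(universe[:20])
            query = universe[:overlap] + universe[50 : 50 + (10 - overlap)]
            out = ds.hypergeometric_enrichment(
                query, [GeneSet("T", "t", "GO_BP", members)], universe
            )
            res.append(out.loc[0, "p"])
        assert res[1] < res[0]
        assert all(b <= a for a, b in zip(ps, ps[1:]))

    def test_strict_significance_threshold(self):
        universe = [f"g{i}" for i in range(40)]
        members = frozenset(universe[:10])
        res = ds.hypergeometric_enrichment(
            universe[:8], [GeneSet("T", "t", "GO_BP", members)], universe
        )
        assert bool(res.loc[0, "significant"]) == (res.loc[0, "p"] < 0.05)

    def test_empty_universe_rejected(self):
        with pytest.raises(AnalysisError, match="universe"):
            ds.hypergeometric_enrichment(["a"], [], [])


class TestDdct:
    @staticmethod
    def _table(case_dct, control_dct):
        rows = []
        for i, d in enumerate(case_dct):
            rows.append(dict(sample=f"c{i}", group="case", ct_target=20 + d, ct_reference=20.0))
        for i, d in enumerate(control_dct):
            rows.append(dict(sample=f"n{i}", group="control", ct_target=20 + d, ct_reference=20.0))
        return pd.DataFrame(rows)

    def test_equal_dct_gives_fold_change_one(self):
        res = ds.ddct_fold_change(self._table([5, 5, 5], [5, 5]))
        assert res.fold_change == pytest.approx(1.0)

    def test_ddct_minus_one_gives_fold_change_two(self):
        res = ds.ddct_fold_change(self._table([4, 4, 4], [5, 5]))
        assert res.fold_change == pytest.approx(2.0)
        assert res.ddct == pytest.approx(-1.0)

    def test_small_group_fold_change_defined_p_undefined(self):
        res = ds.ddct_fold_change(self._table([4, 4], [5]))
        assert res.fold_change == pytest.approx(2.0)
        assert math.isnan(res.p)

    def test_welch_p_matches_scipy(self):
        rng = np.random.default_rng(6)
        case = rng.normal(4, 0.3, size=10)
        control = rng.normal(5, 0.3, size=4)
        res = ds.ddct_fold_change(self._table(case, control))
        expected = stats.ttest_ind(case, control, equal_var=False).pvalue
        assert res.p == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_ct_rejected(self):
        bad = self._table([4], [5])
        bad.loc[0, "ct_reference"] = -1.0
        with pytest.raises(AnalysisError, match="positive"):
            ds.ddct_fold_change(bad)
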