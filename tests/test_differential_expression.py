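"""NB Wald test calibration, BH adjustment, thresholds, cohort merging."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ccmlnc import differential_expression as de
from ccmlnc import synthetic_data as sim
from ccmlnc.errors import AnalysisError
from ccmlnc.io import CountMatrix


def _matrix(values, groups=None):
    values = np.asarray(values)
    samples = [f"s{i}" for i in range(values.shape[1])]
    if groups is None:
        half = values.shape[1] // 2
        groups = {s: ("case" if i < half else "control") for i, s in enumerate(samples)}
    data = pd.DataFrame(values, index=[f"G{i}" for i in range(values.shape[0])], columns=samples)
    return CountMatrix(data.astype(np.int64), groups)


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        cm = _matrix(np.tile([[10], [40], [7]], (1, 4)))
        np.testing.assert_allclose(de.size_factors(cm), 1.0)

    def test_doubled_column_doubles_factor(self):
        rng = np.random.default_rng(0)
        base = rng.integers(5, 200, size=(30, 1))
        cols = np.hstack([base, 2 * base, base])
        cm = _matrix(cols)
        f = de.size_factors(cm)
        assert f.iloc[1] / f.iloc[0] == pytest.approx(2.0, rel=1e-12)

    def test_zero_in_every_gene_advises_fallback(self):
        values = np.array([[0, 5, 5, 5], [5, 0, 5, 5], [5, 5, 0, 5]])
        cm = _matrix(values)
        with pytest.raises(AnalysisError, match="pseudo_reference"):
            de.size_factors(cm)
        f = de.size_factors(cm, allow_pseudo_reference=True)
        assert (f > 0).all()


class TestNbWaldTest:
    def test_null_type_one_error_close_to_nominal(self):
        # 200 independent null cohorts of 20 genes each, 10 vs 4
        rng = np.random.default_rng(42)
        pvals = []
        for _ in range(200):
            mu = rng.uniform(50, 2000, size=(20, 1))
            lam = rng.gamma(1 / 0.05, mu * 0.05, size=(20, 14))
            counts = rng.poisson(lam)
            cm = _matrix(counts, groups={f"s{i}": ("case" if i < 10 else "control") for i in range(14)})
            det = de.nb_wald_test(cm, pd.Series(1.0, index=cm.samples))
            pvals.append(det["p"].to_numpy())
        rate = (np.concatenate(pvals) < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_all_zero_gene_is_untested(self):
        values = np.vstack([np.zeros(6, dtype=int), np.full(6, 50)])
        cm = _matrix(values)
        det = de.nb_wald_test(cm)
        assert det.loc["G0", "status"] == "untested"
        assert np.isnan(det.loc["G0", "p"])
        assert not np.isnan(det.loc["G1", "p"])

    def test_power_at_planted_lfc3(self):
        # |log2FC| = 3 at mean 500, dispersion 0.05: called DE in >= 95% of
        # sims; null genes present so median-of-ratios has an anchor
        called = 0
        total = 0
        for seed in range(25):
            cfg = sim.SimConfig(
                n_lncRNA=0, n_PCG=100, partners_per_hub=10,
                baseline_mean_log_range=(np.log(500.0), np.log(500.0)),
                dispersion=0.05, de_fraction_pcg=0.25,
                planted_log2fc_range=(3.0, 3.0),
                library_size_sd=0.0, rng_seed=seed,
            )
            cm, _, truth = sim.generate_counts(cfg)
            det = de.filter_de(de.nb_wald_test(cm))
            for g in truth.de_genes:
                total += 1
                called += det.loc[g, "status"] in ("up", "down")
        assert called / total >= 0.95

    def test_group_swap_negates_lfc_and_keeps_p(self, small_cohort):
        _, cm, _, _ = small_cohort
        det = de.nb_wald_test(cm)
        flipped = {s: ("case" if g == "control" else "control") for s, g in cm.groups.items()}
        cm2 = CountMatrix(cm.data, flipped, dict(cm.cohorts))
        det2 = de.nb_wald_test(cm2)
        np.testing.assert_allclose(det2["log2fc"], -det["log2fc"], atol=1e-10)
        np.testing.assert_allclose(det2["p"], det["p"], atol=1e-12, equal_nan=True)

    def test_single_sample_group_rejected(self):
        cm = _matrix(np.full((3, 4), 10), groups={"s0": "case", "s1": "control",
                                                  "s2": "control", "s3": "control"})
        with pytest.raises(AnalysisError, match=">=2"):
            de.nb_wald_test(cm)

    def test_false_discovery_proportion_controlled_on_null(self):
        # reduced version of the all-null FDR property (full size in acceptance)
        fdps = []
        for seed in range(15):
            cfg = sim.SimConfig(n_lncRNA=100, n_PCG=400, de_fraction_lnc=0,
                                de_fraction_pcg=0, rng_seed=seed)
            cm, _, _ = sim.generate_counts(cfg)
            det = de.nb_wald_test(cm)
            n_disc = int((det["padj"] < 0.01).sum())
            fdps.append(1.0 if n_disc else 0.0)
        assert np.mean(fdps) <= 0.05


class TestBhAdjust:
    @staticmethod
    def _oracle(p):
        # step-up formula: padj_i = min over k >= rank(i) of p_(k) * m / k
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        out = np.empty(m)
        ranked = p[order]
        for i in range(m):
            out[order[i]] = min(
                min(ranked[k] * m / (k + 1) for k in range(i, m)), 1.0
            )
        return out

    def test_single_p_unchanged(self):
        assert de.bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_textbook_vector(self):
        np.testing.assert_allclose(
            de.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04], atol=1e-12
        )

    def test_matches_step_up_oracle_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            p = rng.uniform(0, 1, size=rng.integers(1, 21))
            np.testing.assert_allclose(de.bh_adjust(p), self._oracle(p), atol=1e-12)

    def test_nan_passthrough_and_range_check(self):
        out = de.bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(out[1]) and not np.isnan(out[0])
        with pytest.raises(AnalysisError, match="outside"):
            de.bh_adjust([1.2])

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=15))
    def test_monotone_in_p_order(self, p):
        padj = de.bh_adjust(p)
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(padj[order]) >= -1e-12).all()
        assert (padj >= np.asarray(p) - 1e-12).all()


class TestFilterDe:
    @pytest.fixture()
    def table(self):
        return pd.DataFrame(
            {
                "base_mean": [10.0] * 4,
                "log2fc": [2.0, 1.5, -2.0, 0.5],
                "se_log2fc": [0.1] * 4,
                "p": [0.001, 0.0005, 0.001, np.nan],
                "padj": [0.005, 0.001, 0.005, np.nan],
                "status": ["ns", "ns", "ns", "untested"],
            },
            index=["up_gene", "boundary", "down_gene", "zero"],
        )

    def test_paper_thresholds(self, table):
        out = de.filter_de(table)
        assert out.loc["up_gene", "status"] == "up"
        assert out.loc["down_gene", "status"] == "down"

    def test_boundary_lfc_is_strictly_excluded(self, table):
        assert de.filter_de(table).loc["boundary", "status"] == "ns"

    def test_untested_stays_untested(self, table):
        assert de.filter_de(table).loc["zero", "status"] == "untested"


class TestMergeCohorts:
    @staticmethod
    def _cohort(n_case, n_control, genes, prefix, cohort):
        rng = np.random.default_rng(hash(prefix) % 2**31)
        samples = [f"{prefix}c{i}" for i in range(n_case)] + [
            f"{prefix}n{i}" for i in range(n_control)
        ]
        groups = {s: ("case" if "c" in s[len(prefix):] else "control") for s in samples}
        data = pd.DataFrame(
            rng.integers(0, 100, size=(len(genes), len(samples))),
            index=genes, columns=samples,
        )
        return CountMatrix(data.astype(np.int64), groups, cohort)

    def test_ten_four_plus_five_three_gives_22_samples(self):
        genes = [f"G{i}" for i in range(30)]
        a = self._cohort(10, 4, genes, "a", "ours")
        b = self._cohort(5, 3, genes, "b", "public")
        merged = de.merge_cohorts(a, b)
        assert len(merged.samples) == 22
        assert len(merged.samples_in_group("case")) == 15
        assert len(merged.samples_in_group("control")) == 7
        assert merged.cohorts[a.samples[0]] == "ours"
        assert merged.cohorts[b.samples[0]] == "public"

    def test_disjoint_gene_sets_rejected(self):
        a = self._cohort(2, 2, ["G1", "G2"], "a", "x")
        b = self._cohort(2, 2, ["H1", "H2"], "b", "y")
        with pytest.raises(AnalysisError, match="no gene ids"):
            de.merge_cohorts(a, b)

    def test_overlapping_samples_rejected(self):
        a = self._cohort(2, 2, ["G1"], "a", "x")
        with pytest.raises(AnalysisError, match="overlapping sample"):
            de.merge_cohorts(a, a)

    def test_shared_gene_set_preserved(self):
        genes = ["G1", "G2", "G3"]
        a = self._cohort(2, 2, genes, "a", "x")
        b = self._cohort(2, 2, genes, "b", "y")
        assert de.merge_cohorts(a, b).genes == genes


class TestOverlapFraction:
    def test_paper_cohort_overlap_is_789_percent(self):
        combined = {f"L{i}" for i in range(190)}
        reference = {f"L{i}" for i in range(150)} | {f"X{i}" for i in range(40)}
        count, frac = de.overlap_fraction(combined, reference)
        assert count == 150
        assert round(100 * frac, 1) == 78.9

    def test_identical_and_disjoint_sets(self):
        s = {"a", "b"}
        assert de.overlap_fraction(s, s) == (2, 1.0)
        assert de.overlap_fraction(s, {"c"}) == (0, 0.0)

    def test_empty_combined_set_is_undefined(self):
        count, frac = de.overlap_fraction(set(), {"a"})
        assert count == 0 and frac is None
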