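"""DEG filtering, TWCS, 2^-ddCT, and platform concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hormsense import DegTable, PathwayAnnotation
from hormsense.errors import UndefinedCorrelationError
from hormsense.pathway import (
    DegThresholds,
    compute_relative_expression,
    compute_twcs,
    compute_twcs_table,
    critical_pearson_r,
    filter_degs,
    platform_concordance,
)


def deg_table_from_log2fc(log2fcs, p=0.01, tissue="root", dose=20.0, prefix="g"):
    return DegTable(
        rows=pd.DataFrame(
            {
                "gene_id": [f"{prefix}{i}" for i in range(len(log2fcs))],
                "tissue": tissue,
                "dose_mg_L": dose,
                "fold_change": [2.0**x for x in log2fcs],
                "p_value": p,
            }
        )
    )


class TestFilter:
    def test_toy_table_keeps_exactly_two(self, toy_deg_table):
        kept = filter_degs(toy_deg_table)
        assert len(kept) == 2
        assert sorted(kept.rows["gene_id"]) == ["g0", "g2"]
        directions = kept.rows.set_index("gene_id")["direction"]
        assert directions["g0"] == "up"  # FC = 3.0
        assert directions["g2"] == "down"  # FC = 0.4

    def test_boundaries_excluded(self, toy_deg_table):
        kept = filter_degs(toy_deg_table)
        assert "g1" not in set(kept.rows["gene_id"])  # FC exactly 2.0
        assert "g4" not in set(kept.rows["gene_id"])  # FC exactly 0.5

    def test_idempotent(self, toy_deg_table):
        once = filter_degs(toy_deg_table)
        twice = filter_degs(once)
        assert twice.rows["gene_id"].tolist() == once.rows["gene_id"].tolist()

    def test_count_conservation(self, toy_deg_table):
        kept = filter_degs(toy_deg_table)
        fc = toy_deg_table.rows["fold_change"]
        p = toy_deg_table.rows["p_value"]
        removed = (~(((fc < 0.5) | (fc > 2.0)) & (p < 0.05))).sum()
        assert len(kept) + removed == len(toy_deg_table)


class TestTwcs:
    def test_single_direct_gene(self, toy_annotation):
        filtered = deg_table_from_log2fc([1.0])  # gene g0: direct ET, log2FC = 1
        rec = compute_twcs(filtered, toy_annotation, "ET")
        assert rec.score == pytest.approx(1.0, abs=1e-10)
        assert (rec.n_direct, rec.m_indirect) == (1, 0)

    def test_hand_summed_mixed_classes(self, toy_annotation):
        # ET direct genes g0, g1 with log2FC {2, -1}; indirect g2 with {2}
        filtered = deg_table_from_log2fc([2.0, -1.0, 2.0])
        rec = compute_twcs(filtered, toy_annotation, "ET")
        # (1/2)(2-1)(1.0) + (1/1)(2)(0.5) = 1.5
        assert rec.score == pytest.approx(1.5, abs=1e-10)
        assert (rec.n_direct, rec.m_indirect) == (2, 1)

    def test_empty_pathway_scores_zero(self, toy_annotation):
        filtered = deg_table_from_log2fc([2.0])
        rec = compute_twcs(filtered, toy_annotation, "GA")
        assert rec.score == 0.0
        assert (rec.n_direct, rec.m_indirect) == (0, 0)

    def test_linearity_in_log2fc(self, toy_annotation):
        rng = np.random.default_rng(0)
        for _ in range(10):
            lfc = rng.normal(0, 2, 5)
            c = rng.uniform(0.5, 3)
            s1 = compute_twcs(deg_table_from_log2fc(lfc), toy_annotation, "ET").score
            s2 = compute_twcs(deg_table_from_log2fc(c * lfc), toy_annotation, "ET").score
            assert s2 == pytest.approx(c * s1, rel=1e-9, abs=1e-12)

    def test_weight_contract(self, toy_annotation):
        lfc = [2.0, -1.0, 2.0]
        filtered = deg_table_from_log2fc(lfc)
        # with zero indirect weight the score is the direct-class mean log2FC
        rec = compute_twcs(filtered, toy_annotation, "ET", w_indirect=0.0)
        assert rec.score == pytest.approx(0.5, abs=1e-12)
        # equal FCs in both classes with n == m gives 1.5 x the mean log2FC
        ann = PathwayAnnotation(
            rows=pd.DataFrame(
                {
                    "gene_id": ["a", "b"],
                    "pathway": "ET",
                    "effect_class": ["direct", "indirect"],
                }
            )
        )
        same = DegTable(
            rows=pd.DataFrame(
                {
                    "gene_id": ["a", "b"],
                    "tissue": "root",
                    "dose_mg_L": 20.0,
                    "fold_change": 2.0**3.0,
                    "p_value": 0.01,
                }
            )
        )
        assert compute_twcs(same, ann, "ET").score == pytest.approx(1.5 * 3.0, abs=1e-10)

    def test_multi_pathway_gene_counts_in_both(self, toy_annotation):
        extra = pd.DataFrame([{"gene_id": "g0", "pathway": "JA", "effect_class": "direct"}])
        ann = PathwayAnnotation(rows=pd.concat([toy_annotation.rows, extra]))
        filtered = deg_table_from_log2fc([2.0])
        assert compute_twcs(filtered, ann, "ET").score == pytest.approx(2.0)
        assert compute_twcs(filtered, ann, "JA").score == pytest.approx(2.0)

    def test_table_covers_all_contrasts(self, toy_deg_table, toy_annotation):
        table = compute_twcs_table(toy_deg_table, toy_annotation)
        assert set(table["pathway"]) == {
            "ET", "JA", "CK", "GA", "BR", "ABA", "SA", "IAA",
        }
        assert (table[table["pathway"] == "BR"]["twcs"] == 0).all()


class TestRelativeExpression:
    @pytest.mark.parametrize(
        "ddct, expected, tol",
        [(0.0, 1.0, 1e-12), (-1.0, 2.0, 1e-12), (3.3219, 0.1, 1e-4), (1.0, 0.5, 1e-12)],
    )
    def test_two_power_minus_ddct(self, ddct, expected, tol):
        assert compute_relative_expression(0.0, ddct) == pytest.approx(expected, abs=tol)

    def test_invariant_to_common_offset(self):
        assert compute_relative_expression(5.0, 4.0) == pytest.approx(
            compute_relative_expression(10.0, 9.0), abs=1e-12
        )


class TestConcordance:
    def test_identical_vectors(self):
        v = np.array([1.0, -2.0, 0.5, 3.0, -1.0])
        r, r_crit, sig = platform_concordance(v, v)
        assert r == pytest.approx(1.0)
        assert sig

    def test_anticorrelated_vectors(self):
        v = np.array([1.0, -2.0, 0.5, 3.0, -1.0])
        r, _, _ = platform_concordance(v, -v)
        assert r == pytest.approx(-1.0)

    def test_critical_r_closed_form(self):
        t_crit = stats.t.ppf(0.975, 18)
        expected = t_crit / np.sqrt(t_crit**2 + 18)
        assert critical_pearson_r(20, 0.05) == pytest.approx(expected, abs=1e-6)

    def test_critical_r_matches_pvalue_boundary(self):
        """At r = r_crit the two-sided Pearson test p equals alpha."""
        n, alpha = 12, 0.05
        r_crit = critical_pearson_r(n, alpha)
        t = r_crit * np.sqrt((n - 2) / (1 - r_crit**2))
        p = 2 * stats.t.sf(t, n - 2)
        assert p == pytest.approx(alpha, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            platform_concordance(np.ones(5), np.arange(5.0))

    def test_noisy_concordance_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 2, 20)
        b = a + rng.normal(0, 0.5, 20)
        r, r_crit, sig = platform_concordance(a, b)
        assert sig and r > r_crit
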