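import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gasnet.datatypes import DriverTable, ExpressionMatrix, PhenotypeLabels, ValidationError
from gasnet.selection import (
    differential_expression,
    filter_drivers,
    filter_unexpressed_by_count,
    filter_unexpressed_by_fpkm,
    select_invasive_specific,
)

from .conftest import bh_oracle


def _expr_with_counts(counts: dict) -> ExpressionMatrix:
    cdf = pd.DataFrame(counts, index=["s1", "s2", "s3"]).T.astype(float)
    return ExpressionMatrix(cdf + 0.5, cdf)


class TestCountFilter:
    def test_median_zero_removed_positive_retained(self):
        expr = _expr_with_counts({"G1": [0, 0, 1], "G2": [2, 3, 4]})
        out = filter_unexpressed_by_count(expr)
        assert out.gene_ids == ["G2"]

    def test_all_zero_gives_empty_matrix(self, caplog):
        expr = _expr_with_counts({"G1": [0, 0, 0], "G2": [0, 0, 1]})
        with caplog.at_level("WARNING"):
            out = filter_unexpressed_by_count(expr)
        assert out.n_genes == 0
        assert any("median raw count 0" in r.message for r in caplog.records)

    def test_missing_counts_points_to_fpkm_filter(self, tiny_expr):
        with pytest.raises(ValidationError, match="fpkm"):
            filter_unexpressed_by_count(tiny_expr)


class TestFpkmFilter:
    @pytest.mark.parametrize(
        "values,threshold,expected",
        [
            ([0.2, 0.5, 0.9], 1.0, False),   # median 0.5 -> excluded
            ([1.0, 1.0, 1.0], 1.0, True),    # boundary: median exactly 1 kept
            ([0.2, 0.5, 0.9], 0.0, True),    # threshold 0 keeps everything
        ],
    )
    def test_median_boundary(self, values, threshold, expected):
        expr = ExpressionMatrix(
            pd.DataFrame([values], index=["G"], columns=["s1", "s2", "s3"])
        )
        assert ("G" in filter_unexpressed_by_fpkm(expr, threshold)) is expected


class TestDifferentialExpression:
    def _dataset(self, control, case):
        genes = list(control)
        values = pd.DataFrame(
            {f"c{i}": [control[g][i] for g in genes] for i in range(3)}
            | {f"t{i}": [case[g][i] for g in genes] for i in range(3)},
            index=genes,
        )
        labels = PhenotypeLabels(
            pd.Series(["ctl"] * 3 + ["tum"] * 3, index=values.columns),
            ("ctl", "tum"),
        )
        return ExpressionMatrix(values), labels

    def test_identical_groups_fold_change_zero(self):
        expr, labels = self._dataset({"G": [4, 4, 4]}, {"G": [4, 4, 4]})
        de = differential_expression(expr, labels)
        assert de.loc[0, "log2_fc"] == 0.0
        assert de.loc[0, "p_value"] == 1.0  # zero variance in both groups

    def test_fourfold_case_gives_log2fc_two(self):
        expr, labels = self._dataset({"G": [10, 11, 12]}, {"G": [40, 44, 48]})
        de = differential_expression(expr, labels, epsilon=1e-9)
        assert de.loc[0, "log2_fc"] == pytest.approx(2.0, abs=1e-9)

    def test_small_class_rejected(self):
        expr, _ = self._dataset({"G": [1, 2, 3]}, {"G": [1, 2, 3]})
        with pytest.raises(ValidationError, match=">= 2 samples"):
            PhenotypeLabels(
                pd.Series(["ctl", "tum", "tum", "tum", "tum", "tum"],
                          index=expr.sample_ids),
                ("ctl", "tum"),
            )

    def test_fdr_matches_brute_force_bh(self):
        rng = np.random.default_rng(7)
        n = 100
        values = pd.DataFrame(
            rng.lognormal(1, 1, size=(n, 10)),
            index=[f"G{i:03d}" for i in range(n)],
            columns=[f"s{i}" for i in range(10)],
        )
        expr = ExpressionMatrix(values)
        labels = PhenotypeLabels(
            pd.Series(["a"] * 5 + ["b"] * 5, index=values.columns), ("a", "b")
        )
        de = differential_expression(expr, labels)
        np.testing.assert_allclose(
            de["fdr"].to_numpy(), bh_oracle(de["p_value"].to_numpy()),
            atol=1e-12,
        )

    def test_count_filter_commutes_with_de(self):
        rng = np.random.default_rng(11)
        genes = [f"G{i}" for i in range(20)]
        counts = pd.DataFrame(
            rng.poisson(3, size=(20, 8)).astype(float), index=genes,
            columns=[f"s{i}" for i in range(8)],
        )
        counts.iloc[:5] = 0
        values = counts + rng.uniform(0.1, 1, size=counts.shape)
        expr = ExpressionMatrix(values, counts)
        labels = PhenotypeLabels(
            pd.Series(["a"] * 4 + ["b"] * 4, index=values.columns), ("a", "b")
        )
        de_filtered = differential_expression(
            filter_unexpressed_by_count(expr), labels
        )
        kept = filter_unexpressed_by_count(expr).gene_ids
        de_restricted = differential_expression(expr.subset_genes(kept), labels)
        pd.testing.assert_frame_equal(de_filtered, de_restricted)


def _de_frame(entries):
    return pd.DataFrame(
        [
            {"gene": g, "log2_fc": fc, "p_value": p, "fdr": p}
            for g, fc, p in entries
        ]
    )


class TestInvasiveSpecific:
    def test_single_comparison_hit_excluded(self):
        a = _de_frame([("G", 1.5, 0.001)])
        b = _de_frame([("G", 0.5, 0.001)])   # |log2FC| <= 1 in second
        assert select_invasive_specific(a, b).empty

    def test_hit_in_both_is_up(self):
        a = _de_frame([("G", 2.0, 0.01)])
        b = _de_frame([("G", 2.0, 0.01)])
        out = select_invasive_specific(a, b)
        assert out.loc[0, "gene"] == "G"
        assert out.loc[0, "direction"] == "up"

    def test_discordant_sign_dropped(self, caplog):
        a = _de_frame([("G", 2.0, 0.01)])
        b = _de_frame([("G", -2.0, 0.01)])
        with caplog.at_level("WARNING"):
            out = select_invasive_specific(a, b)
        assert out.empty
        assert any("discordant" in r.message for r in caplog.records)

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValidationError):
            select_invasive_specific(
                _de_frame([("G1", 2, 0.01)]), _de_frame([("G2", 2, 0.01)])
            )

    def test_nested_pass_counts(self):
        """98 genes pass the first comparison, 61 of them also pass the
        second; the intersection has exactly 61 genes."""
        genes = [f"G{i:03d}" for i in range(200)]
        a = _de_frame(
            [(g, 2.0 if i < 98 else 0.1, 0.001 if i < 98 else 0.9)
             for i, g in enumerate(genes)]
        )
        b = _de_frame(
            [(g, 1.8 if i < 61 else 0.2, 0.002 if i < 61 else 0.8)
             for i, g in enumerate(genes)]
        )
        out = select_invasive_specific(a, b)
        assert len(out) == 61

    @given(
        fc=st.floats(min_value=2.0, max_value=8.0),
        fdr=st.floats(min_value=0.001, max_value=0.05),
    )
    @settings(max_examples=25, deadline=None)
    def test_threshold_monotonicity(self, fc, fdr):
        """Tightening either threshold never adds genes."""
        rng = np.random.default_rng(5)
        genes = [f"G{i}" for i in range(50)]
        a = _de_frame(
            [(g, rng.normal(0, 2), rng.uniform(0, 0.2)) for g in genes]
        )
        b = _de_frame(
            [(g, rng.normal(0, 2), rng.uniform(0, 0.2)) for g in genes]
        )
        loose = set(select_invasive_specific(a, b, 2.0, 0.05).gene)
        tight = set(select_invasive_specific(a, b, fc, fdr).gene)
        assert tight <= loose


class TestDriverFilter:
    @pytest.fixture
    def table(self):
        return DriverTable(
            pd.DataFrame(
                {
                    "score": [0.824, 0.8, 0.9, 0.85],
                    "p_value": [0.0044, 0.01, 0.10, 0.04],
                },
                index=pd.Index(["ADGRL3", "Gboundary", "Gbigp", "Gok"],
                               name="gene"),
            )
        )

    def test_strict_threshold_default(self, table):
        assert filter_drivers(table) == {"ADGRL3", "Gok"}

    def test_boundary_score_excluded_when_strict(self, table):
        assert "Gboundary" not in filter_drivers(table)
        assert "Gboundary" in filter_drivers(table, strict=False)

    def test_large_p_excluded(self, table):
        assert "Gbigp" not in filter_drivers(table)
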