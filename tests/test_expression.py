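"""Fold-change computation, the significance rule, threshold tables and the
Fra2-dependence fraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings, strategies as st

from regulonprint.expression import (ExpressionMatrix, apply_significance,
                                     compute_rpkm, fold_changes,
                                     fra2_fraction, signed_to_linear,
                                     threshold_table)

from conftest import make_matrix

REF = ("wt", "untreated")
TEST = ("wt", "cubpq")


def fc_of(ref_reps, test_reps, **kw):
    matrix = make_matrix({"G1": {REF: ref_reps, TEST: test_reps}})
    return fold_changes(matrix, REF, TEST, **kw).loc["G1"]


class TestRPKM:
    def make_counts(self, counts, lengths, totals):
        samples = pd.DataFrame(
            {"genotype": ["wt"] * len(totals), "condition": ["untreated"] * len(totals),
             "replicate": range(1, len(totals) + 1)},
            index=[f"s{i}" for i in range(len(totals))])
        values = pd.DataFrame(counts, index=[f"g{i}" for i in range(len(counts))],
                              columns=samples.index)
        return ExpressionMatrix(
            values=values, samples=samples, unit="counts",
            gene_lengths=pd.Series(lengths, index=values.index),
            total_reads=pd.Series(totals, index=samples.index))

    def test_formula_and_zero(self):
        m = self.make_counts([[10], [0]], [1000, 500], [1_000_000])
        rpkm = compute_rpkm(m)
        assert rpkm.values.iloc[0, 0] == pytest.approx(10.0)
        assert rpkm.values.iloc[1, 0] == 0.0
        assert rpkm.unit == "RPKM"

    def test_depth_scale_invariance(self):
        m1 = self.make_counts([[10], [7]], [1000, 500], [1_000_000])
        m2 = self.make_counts([[20], [14]], [1000, 500], [2_000_000])
        assert np.allclose(compute_rpkm(m1).values, compute_rpkm(m2).values)

    def test_requires_lengths_and_totals(self):
        m = self.make_counts([[10]], [1000], [1_000_000])
        m.gene_lengths = None
        with pytest.raises(ValueError):
            compute_rpkm(m)


class TestFoldChanges:
    def test_hand_computed_up(self):
        # replicate ratios 3.0, 3.3, 2.7 -> mean 3.0, sample SD 0.3
        row = fc_of([10, 10, 10], [30, 33, 27])
        assert row["mean_fc"] == pytest.approx(3.0)
        assert row["sd_fc"] == pytest.approx(0.3)
        assert row["direction"] == "up"
        assert row["signed_fold"] == pytest.approx(3.0)

    def test_down_on_reciprocal_scale(self):
        row = fc_of([10, 10, 10], [2, 2, 2])
        assert row["direction"] == "down"
        assert row["fold"] == pytest.approx(5.0)
        assert row["fold_sd"] == 0.0
        assert row["signed_fold"] == pytest.approx(-5.0)

    def test_identity(self):
        row = fc_of([10, 10, 10], [10, 10, 10])
        assert row["mean_fc"] == pytest.approx(1.0)
        assert row["direction"] == "none"
        assert row["signed_fold"] == pytest.approx(1.0)
        assert not row["significant"]

    def test_low_reference_floor(self):
        row = fc_of([0.0, 0.0, 0.0], [1.0, 1.0, 1.0], floor=0.1)
        assert row["low_reference"]
        assert row["mean_fc"] == pytest.approx(10.0)

    def test_reciprocity(self):
        """Swapping reference and test preserves the direction-scale fold of
        symmetric (zero-spread) data and flips the direction."""
        fwd = fc_of([10, 10, 10], [2, 2, 2])
        matrix = make_matrix({"G1": {REF: [10, 10, 10], TEST: [2, 2, 2]}})
        rev = fold_changes(matrix, TEST, REF).loc["G1"]
        assert rev["direction"] == "up"
        assert rev["fold"] == pytest.approx(fwd["fold"])

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3),
           ref=st.lists(st.floats(min_value=0.5, max_value=100), min_size=3,
                        max_size=3),
           test=st.lists(st.floats(min_value=0.5, max_value=100), min_size=3,
                         max_size=3))
    def test_scale_invariance(self, scale, ref, test):
        # tiny floor so the low-reference rule never engages
        a = fc_of(ref, test, floor=1e-12)
        # direction is discontinuous at mean ratio exactly 1; stay off it
        assume(abs(a["mean_fc"] - 1.0) > 1e-6)
        b = fc_of([scale * v for v in ref], [scale * v for v in test],
                  floor=1e-12)
        assert a["mean_fc"] == pytest.approx(b["mean_fc"], rel=1e-9)
        assert a["fold"] == pytest.approx(b["fold"], rel=1e-9)
        assert a["direction"] == b["direction"]


class TestSignificance:
    def make_table(self, fold, sd, direction="up"):
        signed = fold if direction == "up" else -fold
        return pd.DataFrame({"mean_fc": [fold], "sd_fc": [sd],
                             "direction": [direction], "fold": [fold],
                             "fold_sd": [sd], "signed_fold": [signed],
                             "significant": [False],
                             "low_reference": [False]}, index=["G"])

    @pytest.mark.parametrize("fold,sd,expected", [
        (3.0, 0.3, True),      # 2.7 > 2
        (6.22, 3.8, True),     # 2.42 > 2: large-SD strong responder passes
        (2.0, 0.0, False),     # boundary: 2.0 > 2 is false
        (10.0, 8.5, False),    # 1.5 > 2 is false
    ])
    def test_fold_minus_sd_rule(self, fold, sd, expected):
        out = apply_significance(self.make_table(fold, sd), threshold=2.0)
        assert bool(out["significant"].iloc[0]) is expected

    def test_direction_none_never_significant(self):
        out = apply_significance(self.make_table(1.0, 0.0, direction="none"))
        assert not out["significant"].any()

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ValueError):
            apply_significance(self.make_table(3.0, 0.1), threshold=0.5)


class TestThresholdTable:
    def make_table(self, rows):
        df = pd.DataFrame(
            [{"mean_fc": f if d == "up" else 1 / f, "sd_fc": s, "direction": d,
              "fold": f, "fold_sd": s,
              "signed_fold": f if d == "up" else -f,
              "significant": True, "low_reference": False}
             for _, f, s, d in rows],
            index=[g for g, *_ in rows])
        return df

    def test_strong_upregulated_table(self):
        # mirrors the printed strong-responder values
        table = self.make_table([("FIT1", 26.8, 3.1, "up"),
                                 ("FET3", 4.65, 0.95, "up"),
                                 ("CRS5", 4.58, 0.84, "up"),
                                 ("X", 4.4, 0.1, "up")])
        out = threshold_table(table, cutoff=4.5, direction="up")
        assert list(out.index) == ["FIT1", "FET3", "CRS5"]

    def test_downregulated_direction(self):
        table = self.make_table([("LEU1", 4.71, 0.39, "down")])
        out = threshold_table(table, cutoff=4.5, direction="down")
        assert list(out.index) == ["LEU1"]

    def test_empty_and_monotone(self):
        table = self.make_table([("A", 5.0, 0.1, "up"), ("B", 4.6, 0.1, "up")])
        assert threshold_table(table.iloc[0:0]).empty
        lo = set(threshold_table(table, cutoff=4.5).index)
        hi = set(threshold_table(table, cutoff=5.0).index)
        assert hi <= lo


class TestFra2Fraction:
    def make_pair(self, signed_untreated, signed_treated):
        def tab(signed):
            return pd.DataFrame({"signed_fold": [signed]}, index=["G"])
        return tab(signed_untreated), tab(signed_treated)

    def test_no_derepression_gives_zero(self):
        unt, trt = self.make_pair(1.0, 9.0)
        assert fra2_fraction(unt, trt)["f_dep"].iloc[0] == pytest.approx(0.0)

    def test_full_dependence_gives_one(self):
        unt, trt = self.make_pair(9.0, 9.0)
        assert fra2_fraction(unt, trt)["f_dep"].iloc[0] == pytest.approx(1.0)

    def test_partial_dependence_down_gene(self):
        # 0.3-fold repression, half already present untreated: S_u = 0.65
        unt, trt = self.make_pair(-1 / 0.65, -1 / 0.3)
        assert fra2_fraction(unt, trt)["f_dep"].iloc[0] == pytest.approx(0.5)

    def test_flat_treated_is_flagged_not_divided(self):
        unt, trt = self.make_pair(2.0, 1.0)
        out = fra2_fraction(unt, trt, tolerance=0.1)
        assert out["undefined"].iloc[0]
        assert np.isnan(out["f_dep"].iloc[0])

    def test_mismatched_gene_sets_rejected(self):
        unt, _ = self.make_pair(2.0, 3.0)
        other = pd.DataFrame({"signed_fold": [3.0]}, index=["H"])
        with pytest.raises(ValueError):
            fra2_fraction(unt, other)


def test_signed_to_linear_convention():
    assert np.allclose(signed_to_linear(np.array([5.0, -5.0, 1.0])),
                       [5.0, 0.2, 1.0])
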