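import math

import numpy as np
import pandas as pd
import pytest

from scntkit.io import ExpressionMatrix, GeneSet, GeneSetCollection, SampleSheet
from scntkit.rescue import (
    DOWN,
    UP,
    benjamini_hochberg,
    call_degs,
    classify_rescue,
    classify_rescue_table,
    summarize_rescue,
)
from scntkit.simulate import SimConfig, simulate_dataset
from tests.conftest import SMALL

GRID = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)


def bh_oracle(p):
    """Brute-force step-up: sort, scale by n/rank, enforce monotonicity
    from the largest rank down, cap at 1."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(n)
    running_min = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, p[i] * n / rank)
        adjusted[i] = running_min
    return np.minimum(adjusted, 1.0)


def rescue_oracle(wt, nta, ntb, direction):
    """Independent evaluation of the raw inequalities."""
    w = math.log2(wt + 1)
    n = math.log2(nta + 1)
    b = math.log2(ntb + 1)
    mid = (w + n) / 2
    if direction == DOWN:
        if b > mid:
            return "highly"
        if n < b < mid:
            return "partially"
        return "unrescued"
    if b < mid:
        return "highly"
    if mid < b < n:
        return "partially"
    return "unrescued"


class TestBenjaminiHochberg:
    @pytest.mark.parametrize(
        "p,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.3], [0.3]),
            ([0.005, 0.1], [0.01, 0.1]),
        ],
    )
    def test_frozen_examples(self, p, expected):
        # expected values computed by the brute-force step-up oracle
        np.testing.assert_allclose(bh_oracle(p), expected, atol=1e-15)
        np.testing.assert_allclose(benjamini_hochberg(p), expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.2])

    def test_monotone_in_sorted_raw_p(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=200)
        adj = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_matches_oracle_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            p = rng.uniform(size=rng.integers(1, 60))
            np.testing.assert_allclose(benjamini_hochberg(p), bh_oracle(p),
                                       atol=1e-12)


class TestClassifyRescue:
    @pytest.mark.parametrize(
        "wt,nta,ntb,expected",
        [
            (15, 3, 10, "highly"),     # log 3.459 above midpoint 3.0
            (15, 3, 5, "partially"),   # log 2.585 inside (2.0, 3.0)
            (15, 3, 3, "unrescued"),   # log 2.0 not above the NTA boundary
            (15, 3, 7, "unrescued"),   # log exactly 3.0 = midpoint, strict
        ],
    )
    def test_down_regulated_examples(self, wt, nta, ntb, expected):
        assert classify_rescue(wt, nta, ntb, DOWN).category == expected

    def test_up_regulated_mirrors(self):
        # WT 3, NTA 15: rescue means NTB coming back down below the midpoint
        assert classify_rescue(3, 15, 3, UP).category == "highly"
        assert classify_rescue(3, 15, 10, UP).category == "partially"
        assert classify_rescue(3, 15, 15, UP).category == "unrescued"

    def test_literal_mode_ignores_direction(self):
        call = classify_rescue(3, 15, 3, UP, literal=True)
        assert call.category == "unrescued"  # down-form inequalities verbatim

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            classify_rescue(-1, 3, 3, DOWN)

    def test_midpoint_stored_consistently(self):
        call = classify_rescue(15, 3, 10, DOWN)
        assert call.midpoint == pytest.approx((call.wt_log + call.nta_log) / 2)

    def test_full_grid_matches_bruteforce_oracle(self):
        for wt in GRID:
            for nta in GRID:
                for ntb in GRID:
                    for direction in (DOWN, UP):
                        got = classify_rescue(wt, nta, ntb, direction).category
                        assert got == rescue_oracle(wt, nta, ntb, direction)


class TestCallDegs:
    def test_noiseless_planted_gene_called_down(self):
        cfg = SimConfig(**{**SMALL.__dict__, "noise_sd": 0.0})
        expr, sheet, _, _, truth = simulate_dataset(cfg)
        degs = call_degs(expr, sheet, "NTA2", "WT2").set_index("gene_id")
        down_genes = truth.deg_table.loc[
            truth.deg_table["direction"] == DOWN, "gene"
        ]
        sub = degs.loc[down_genes]
        assert sub["is_deg"].all()
        assert (sub["direction"] == DOWN).all()

    def test_identical_groups_yield_zero_degs(self):
        cfg = SimConfig(**{**SMALL.__dict__, "noise_sd": 0.0})
        expr, sheet, _, _, _ = simulate_dataset(cfg)
        relabelled = sheet.data.copy()
        relabelled.loc[relabelled["group"] == "NTA2", "group"] = "COPY"
        relabelled.loc[relabelled["group"] == "WT2", "group"] = "NTA2"
        relabelled.loc[relabelled["group"] == "COPY", "group"] = "WT2X"
        degs = call_degs(expr, SampleSheet(relabelled), "NTA2", "NTA2")
        assert not degs["is_deg"].any()

    def test_all_zero_rows_by_convention(self):
        expr = ExpressionMatrix(
            pd.DataFrame(np.zeros((2, 4)), index=["g1", "g2"],
                         columns=["a1", "a2", "b1", "b2"])
        )
        sheet = SampleSheet(pd.DataFrame(
            [{"sample_id": s, "group": g, "stage": "x", "embryo_type": "WT",
              "replicate": i + 1}
             for i, (s, g) in enumerate([("a1", "A"), ("a2", "A"),
                                         ("b1", "B"), ("b2", "B")])]
        ))
        degs = call_degs(expr, sheet, "A", "B")
        assert (degs["log2fc"] == 0).all()
        assert (degs["p_value"] == 1).all()

    def test_too_few_samples_rejected(self, small_bundle):
        expr, sheet, _, _, _ = small_bundle
        one = SampleSheet(sheet.data.drop_duplicates("group"))
        with pytest.raises(ValueError, match=">=2 samples"):
            call_degs(expr, one, "NTA2", "WT2")

    def test_planted_recall_at_default_noise(self, default_bundle):
        expr, sheet, _, _, truth = default_bundle
        degs = call_degs(expr, sheet, "NTA2", "WT2")
        called = set(degs.loc[degs["is_deg"], "gene_id"])
        planted = set(truth.deg_genes)
        recall = len(called & planted) / len(planted)
        assert recall >= 0.95


class TestSummarizeRescue:
    CALLS = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(10)],
            "category": ["highly"] * 2 + ["partially"] * 3 + ["unrescued"] * 5,
        }
    )
    SETS = GeneSetCollection(
        (GeneSet("pw", "", tuple(f"g{i}" for i in range(20))),)
    )

    def test_fractions_over_abnormal_genes(self):
        out = summarize_rescue(self.CALLS, self.SETS).table.set_index("pathway")
        row = out.loc["pw"]
        assert (row["frac_highly"], row["frac_partially"], row["frac_unrescued"]) == (
            pytest.approx(0.2), pytest.approx(0.3), pytest.approx(0.5))

    def test_fractions_over_all_pathway_genes(self):
        out = summarize_rescue(
            self.CALLS, self.SETS, denominator_mode="all_pathway_genes"
        ).table.set_index("pathway")
        row = out.loc["pw"]
        assert (row["frac_highly"], row["frac_partially"], row["frac_unrescued"]) == (
            pytest.approx(0.1), pytest.approx(0.15), pytest.approx(0.25))

    def test_counts_conserve_classified_genes(self):
        out = summarize_rescue(self.CALLS, self.SETS).table
        for _, row in out.iterrows():
            assert row["n_highly"] + row["n_partially"] + row["n_unrescued"] == \
                row["n_classified"]

    def test_empty_calls_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_rescue(self.CALLS.iloc[:0], self.SETS)


class TestClassifyRescueTable:
    def test_planted_categories_recovered(self, small_bundle):
        expr, sheet, _, _, truth = small_bundle
        degs = call_degs(expr, sheet, "NTA2", "WT2")
        calls = classify_rescue_table(degs, expr, sheet, "WT2", "NTA2", "NTB2")
        merged = calls.merge(truth.deg_table, left_on="gene_id", right_on="gene")
        agreement = (merged["category"] == merged["rescue_category"]).mean()
        assert agreement > 0.95

    def test_every_gene_exactly_one_category(self, small_bundle):
        expr, sheet, _, _, _ = small_bundle
        degs = call_degs(expr, sheet, "NTA2", "WT2")
        calls = classify_rescue_table(degs, expr, sheet, "WT2", "NTA2", "NTB2")
        assert calls["category"].isin(["highly", "partially", "unrescued"]).all()
        assert len(calls) == int(degs["is_deg"].sum())
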