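import numpy as np
import pandas as pd
import pytest

from scntkit.grn import (
    extract_subnetwork,
    fold_change_filter,
    select_core_tfs,
    select_core_tfs_all,
    subnetwork_to_graph,
    target_union,
    venn_partition,
)
from scntkit.io import ExpressionMatrix, GeneSet, RegulonSet, SampleSheet


def regulon_set(rows):
    df = pd.DataFrame(rows, columns=["condition", "tf", "target"])
    df["weight"] = 1.0
    return RegulonSet(df)


BASIC = regulon_set(
    [("WT2", "T1", "a"), ("WT2", "T1", "b"), ("WT2", "T2", "b"), ("WT2", "T2", "c"),
     ("NTA2", "T1", "a")]
)


class TestTargetUnion:
    def test_union_over_tfs(self):
        assert target_union(BASIC, "WT2") == {"a", "b", "c"}

    def test_tf_filter(self):
        assert target_union(BASIC, "WT2", tfs=["T1"]) == {"a", "b"}

    def test_empty_after_filter_warns(self):
        with pytest.warns(UserWarning, match="no regulon edges"):
            assert target_union(BASIC, "WT2", tfs=["T9"]) == set()

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            target_union(BASIC, "WT9")


class TestVennPartition:
    def test_counts(self):
        rows = [("A", "T", g) for g in "12345"] + [("B", "T", g) for g in "34567"]
        part = venn_partition(regulon_set(rows), "A", "B")
        assert (len(part.shared), len(part.a_specific), len(part.b_specific)) == (3, 2, 2)

    def test_identical_conditions_all_shared(self):
        rows = [("A", "T", g) for g in "123"] + [("B", "T", g) for g in "123"]
        part = venn_partition(regulon_set(rows), "A", "B")
        assert len(part.shared) == 3 and not part.a_specific and not part.b_specific

    def test_disjoint_conditions(self):
        rows = [("A", "T", "1"), ("B", "T", "2")]
        part = venn_partition(regulon_set(rows), "A", "B")
        assert not part.shared

    def test_conservation_on_random_regulon_sets(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            rows = {
                (rng.choice(["A", "B"]), f"T{rng.integers(5)}", f"g{rng.integers(40)}")
                for _ in range(rng.integers(5, 120))
            }
            regs = regulon_set(sorted(rows))
            if not {"A", "B"} <= set(regs.conditions()):
                continue
            part = venn_partition(regs, "A", "B")
            assert part.targets_a == target_union(regs, "A")
            assert part.targets_b == target_union(regs, "B")
            assert not part.shared & (part.a_specific | part.b_specific)


def expression_pair(mean_a, mean_b):
    expr = ExpressionMatrix(
        pd.DataFrame({"sa": [mean_a], "sb": [mean_b]}, index=["g"])
    )
    sheet = SampleSheet(pd.DataFrame(
        [{"sample_id": "sa", "group": "A", "stage": "x", "embryo_type": "WT",
          "replicate": 1},
         {"sample_id": "sb", "group": "B", "stage": "x", "embryo_type": "WT",
          "replicate": 1}]
    ))
    return expr, sheet


class TestFoldChangeFilter:
    @pytest.mark.parametrize(
        "ma,mb,expected",
        [(10, 4, "A_over_B"), (4, 10, "B_over_A"), (7, 7, "neither")],
    )
    def test_classes(self, ma, mb, expected):
        expr, sheet = expression_pair(ma, mb)
        out = fold_change_filter(["g"], expr, sheet, "A", "B")
        assert out["class"].tolist() == [expected]
        assert out["ratio"].iloc[0] == pytest.approx((ma + 1) / (mb + 1))

    def test_mirrored_under_group_swap(self):
        expr, sheet = expression_pair(10, 4)
        ab = fold_change_filter(["g"], expr, sheet, "A", "B")
        ba = fold_change_filter(["g"], expr, sheet, "B", "A")
        assert ab["class"].tolist() == ["A_over_B"]
        assert ba["class"].tolist() == ["B_over_A"]
        assert ab["ratio"].iloc[0] == pytest.approx(1 / ba["ratio"].iloc[0])

    def test_empty_gene_list_rejected(self):
        expr, sheet = expression_pair(1, 1)
        with pytest.raises(ValueError, match="empty"):
            fold_change_filter([], expr, sheet, "A", "B")


PW = GeneSet("pw", "", ("T1", "T2", "T3"))


def ranking_fixture(wt2_counts, wt4_counts):
    rows = []
    for cond, counts in (("WT2", wt2_counts), ("WT4", wt4_counts)):
        for tf, n in counts.items():
            rows += [(cond, tf, f"{cond}_{tf}_{i}") for i in range(n)]
    return regulon_set(rows)


class TestSelectCoreTfs:
    def test_top_k_in_every_condition(self):
        regs = ranking_fixture({"T1": 100, "T2": 80, "T3": 10},
                               {"T1": 90, "T2": 95, "T3": 5})
        sel = select_core_tfs(regs, PW, ("WT2", "WT4"), k=2)
        assert sel.selected == ("T1", "T2")

    def test_tie_broken_lexicographically(self):
        regs = ranking_fixture({"T1": 50, "T2": 50, "T3": 50}, {"T1": 50, "T2": 50})
        sel = select_core_tfs(regs, PW, ("WT2",), k=1)
        assert sel.selected == ("T1",)

    def test_disjoint_tops_give_empty_selection(self):
        regs = ranking_fixture({"T1": 100, "T2": 10}, {"T1": 10, "T2": 100})
        with pytest.warns(UserWarning, match="top 1"):
            sel = select_core_tfs(regs, PW, ("WT2", "WT4"), k=1)
        assert sel.selected == ()

    def test_row_order_invariant(self):
        regs = ranking_fixture({"T1": 30, "T2": 20, "T3": 25}, {"T1": 9, "T3": 8})
        shuffled = RegulonSet(
            regs.edges.sample(frac=1, random_state=4).reset_index(drop=True)
        )
        a = select_core_tfs(regs, PW, ("WT2", "WT4"), k=2)
        b = select_core_tfs(shuffled, PW, ("WT2", "WT4"), k=2)
        assert a.selected == b.selected
        assert a.rankings == b.rankings

    def test_default_k_screens_five_factors(self, small_bundle):
        _, _, genesets, regulons, truth = small_bundle
        sels = select_core_tfs_all(regulons, genesets, ("WT2", "WT4"))
        selected = sorted(tf for s in sels.values() for tf in s.selected)
        assert selected == sorted(truth.core_tfs)


class TestExtractSubnetwork:
    REGS = regulon_set(
        [("WT2", "T1", "a"), ("WT2", "T1", "b"), ("NTA2", "T1", "a")]
    )

    def test_contrast_removes_shared_edges(self):
        out = extract_subnetwork(self.REGS, "WT2", ["T1"],
                                 contrast_condition="NTA2")
        assert out[["tf", "target"]].to_numpy().tolist() == [["T1", "b"]]

    def test_key_gene_restriction(self):
        out = extract_subnetwork(self.REGS, "WT2", ["T1"], key_genes={"b"})
        assert out["target"].tolist() == ["b"]

    def test_no_contrast_keeps_all_focal_edges(self):
        out = extract_subnetwork(self.REGS, "WT2", ["T1"])
        assert sorted(out["target"]) == ["a", "b"]

    def test_missing_core_tf_kept_isolated(self):
        with pytest.warns(UserWarning, match="T9"):
            out = extract_subnetwork(self.REGS, "WT2", ["T1", "T9"])
        g = subnetwork_to_graph(out, ["T1", "T9"])
        assert g.nodes["T9"]["role"] == "core_tf"
        assert g.degree("T9") == 0

    def test_planted_wt_only_edges_recovered_exactly(self, small_bundle):
        """The WT2-vs-NTA2 specific subnetwork equals the planted WT-only
        edge set of the core TFs (edge space is noise-free)."""
        _, _, _, regulons, truth = small_bundle
        out = extract_subnetwork(regulons, "WT2", truth.core_tfs,
                                 contrast_condition="NTA2")
        got = set(map(tuple, out[["tf", "target"]].to_numpy()))
        wt = regulons.for_condition("WT2")
        nta = regulons.for_condition("NTA2")
        wt_pairs = {
            (r.tf, r.target) for r in wt.itertuples() if r.tf in truth.core_tfs
        }
        nta_pairs = {(r.tf, r.target) for r in nta.itertuples()}
        assert got == wt_pairs - nta_pairs
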