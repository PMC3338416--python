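import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from diviss.differential import (count_regulation_flagged, drug_profile_frame,
                                 enzyme_class_composition, family_composition,
                                 high_score_subset, oncoscore_cumulative,
                                 pathway_overlap, rank_drugs, venn_partition)
from diviss.io import ChemogenomicsDB, PathwaySet, TargetAnnotation


def make_sets(n_tumor, n_normal, n_shared):
    shared = {f"S{i}" for i in range(n_shared)}
    tumor = shared | {f"T{i}" for i in range(n_tumor - n_shared)}
    normal = shared | {f"N{i}" for i in range(n_normal - n_shared)}
    return tumor, normal


class TestVenn:
    def test_published_campaign_arithmetic(self):
        tumor, normal = make_sets(229, 160, 114)
        venn = venn_partition(tumor, normal)
        assert venn.sizes == (115, 114, 46)

    def test_disjoint(self):
        venn = venn_partition({"A"}, {"B"})
        assert venn.shared == frozenset()

    def test_identical_sets(self):
        venn = venn_partition({"A", "B"}, {"A", "B"})
        assert venn.sizes == (0, 2, 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(t=st.sets(st.integers(0, 60)), n=st.sets(st.integers(0, 60)))
    def test_conservation(self, t, n):
        venn = venn_partition(t, n)
        assert len(venn.tumor_unique) + len(venn.shared) == len(t)
        assert len(venn.normal_unique) + len(venn.shared) == len(n)
        assert not venn.tumor_unique & venn.normal_unique


def annotation(tid, family="enzyme", ec="transferase", score=None, reg="none"):
    return TargetAnnotation(tid, tid, family,
                            ec if family == "enzyme" else "none", score, reg)


class TestComposition:
    def test_enzyme_percentage_of_tumor_unique_list(self):
        anns = {}
        for i in range(67):
            anns[f"E{i}"] = annotation(f"E{i}", "enzyme")
        for i in range(48):
            anns[f"G{i}"] = annotation(f"G{i}", "GPCR")
        comp = family_composition(anns.keys(), anns)
        assert comp.loc[comp["family"] == "enzyme", "percent"].item() == 58

    def test_counts_sum_to_set_size(self):
        anns = {f"X{i}": annotation(f"X{i}", "GPCR") for i in range(7)}
        anns["Y"] = annotation("Y", "ion_channel")
        comp = family_composition(anns.keys(), anns)
        assert comp["count"].sum() == 8

    def test_unannotated_targets_count_as_other(self):
        comp = family_composition({"UNKNOWN"}, {})
        assert comp["family"].item() == "other"
        assert comp["unannotated"].item() == 1

    def test_empty_set(self):
        assert family_composition(set(), {}).empty

    def test_enzyme_class_split(self):
        anns = {}
        for i in range(29):
            anns[f"T{i}"] = annotation(f"T{i}", "enzyme", "transferase")
        for i in range(38):
            anns[f"H{i}"] = annotation(f"H{i}", "enzyme", "hydrolase")
        comp = enzyme_class_composition(anns.keys(), anns)
        assert comp.loc[comp["ec_class"] == "transferase", "percent"].item() == 43

    def test_enzyme_class_ignores_non_enzymes(self):
        anns = {"G": annotation("G", "GPCR")}
        assert enzyme_class_composition({"G"}, anns).empty


class TestOncoScore:
    def test_published_percentage_over_115_targets(self, target_panel_115):
        pct = oncoscore_cumulative(target_panel_115.keys(), target_panel_115, 0.7)
        assert pct == 36.5

    def test_cutoff_one_gives_zero(self, target_panel_115):
        assert oncoscore_cumulative(target_panel_115.keys(), target_panel_115,
                                    1.0) == 0.0

    def test_all_high_scores(self):
        anns = {f"T{i}": annotation(f"T{i}", score=1.0) for i in range(4)}
        assert oncoscore_cumulative(anns.keys(), anns, 0.7) == 100.0

    def test_non_increasing_in_cutoff(self, target_panel_115):
        values = [oncoscore_cumulative(target_panel_115.keys(),
                                       target_panel_115, c)
                  for c in np.linspace(0, 1, 21)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_reference_table_size_and_flags(self, oncoscore_reference,
                                            target_panel_115):
        table = high_score_subset(target_panel_115.keys(), target_panel_115, 0.7)
        assert len(table) == 42
        assert count_regulation_flagged(table) == 10

    def test_high_cutoff_is_a_subset(self, target_panel_115):
        t07 = high_score_subset(target_panel_115.keys(), target_panel_115, 0.7)
        t99 = high_score_subset(target_panel_115.keys(), target_panel_115, 0.9999)
        assert set(t99["gene"]) <= set(t07["gene"])
        assert (t99["oncoscore"] > 0.9999).all()

    def test_sorted_by_score_then_name(self, oncoscore_reference):
        table = high_score_subset(oncoscore_reference.keys(),
                                  oncoscore_reference, 0.7)
        assert list(table["oncoscore"]) == sorted(table["oncoscore"], reverse=True)
        top = table[table["oncoscore"] == 1.0]
        assert list(top["name"]) == sorted(top["name"])

    def test_empty_annotations(self):
        assert high_score_subset({"X"}, {}, 0.7).empty
        assert count_regulation_flagged(pd.DataFrame()) == 0


def drug_db(rows):
    return ChemogenomicsDB(pd.DataFrame(
        [(d, "CCO", t, p) for d, t, p in rows],
        columns=["ligand_id", "smiles", "target_id", "pact"]))


class TestDrugRanking:
    TUMOR_UNIQUE = {f"T{i}" for i in range(10)}

    def test_multi_target_drug_kept_and_binned(self):
        pacts = [6.5, 6.0, 6.9, 7.2, 8.1, 9.3]
        db = drug_db([("D1", f"T{i}", p) for i, p in enumerate(pacts)])
        rows = rank_drugs(db, self.TUMOR_UNIQUE)
        assert len(rows) == 1
        assert rows[0].n_targets == 6
        assert rows[0].bin_counts == (3, 1, 1, 1)

    def test_exactly_five_targets_excluded(self):
        db = drug_db([("D1", f"T{i}", 7.0) for i in range(5)])
        assert rank_drugs(db, self.TUMOR_UNIQUE) == []

    def test_bin_edges_are_half_open(self):
        db = drug_db([("D1", f"T{i}", 7.0) for i in range(6)])
        rows = rank_drugs(db, self.TUMOR_UNIQUE)
        assert rows[0].bin_counts == (0, 6, 0, 0)

    def test_off_list_and_weak_interactions_ignored(self):
        rows = [("D1", f"T{i}", 7.0) for i in range(6)]
        rows += [("D1", f"X{i}", 9.0) for i in range(5)]   # not tumor-unique
        rows += [("D2", f"T{i}", 5.9) for i in range(9)]   # below 1 uM
        ranked = rank_drugs(drug_db(rows), self.TUMOR_UNIQUE)
        assert [r.drug_id for r in ranked] == ["D1"]

    def test_row_order_invariance(self):
        rows = [("D1", f"T{i}", 6.0 + 0.3 * i) for i in range(8)]
        rows += [("D2", f"T{i}", 6.1) for i in range(7)]
        a = rank_drugs(drug_db(rows), self.TUMOR_UNIQUE)
        b = rank_drugs(drug_db(rows[::-1]), self.TUMOR_UNIQUE)
        assert drug_profile_frame(a).equals(drug_profile_frame(b))


class TestPathwayOverlap:
    def test_mapk_overlap_with_reference_genes(self, oncoscore_reference):
        pathway = PathwaySet("MAPK_SIGNALING", frozenset(
            {"BRAF", "MAP2K1", "MAP3K8", "MAPK10", "RAF1", "STAT1", "TGFBR1",
             "XTRA1", "XTRA2"}))
        genes = {a.gene for a in oncoscore_reference.values()}
        table, summary = pathway_overlap([pathway], genes)
        assert table["overlap"].item() == 7
        assert summary["ge5"] == 1

    def test_disjoint_pathway(self):
        table, _ = pathway_overlap(
            [PathwaySet("PW", frozenset({"AAA"}))], {"BBB"})
        assert table["overlap"].item() == 0

    def test_contained_pathway(self):
        p = PathwaySet("PW", frozenset({"A", "B", "C"}))
        table, _ = pathway_overlap([p], {"A", "B", "C", "D"})
        assert table["overlap"].item() == 3

    def test_case_insensitive_matching(self):
        p = PathwaySet("PW", frozenset({"BRAF"}))
        table, _ = pathway_overlap([p], {"braf"})
        assert table["overlap"].item() == 1
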