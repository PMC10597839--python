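from collections import Counter

import pytest

from clonoverge import (
    CellLabel,
    compartment_composition,
    detect_convergent_types,
    fisher_exact_2x2,
    rank_tcr_types,
    sharing_summary,
)
from clonoverge.clonotyping import Clonotype, TCRType
from oracles import fisher_two_sided_oracle


def _ct(cid, cells, tra_nt="TGTGCT", trb_nt="TGTTGG", **genes):
    return Clonotype(
        clonotype_id=cid,
        key=(tra_nt, trb_nt),
        tra_v=genes.get("tra_v", "TRAV1"),
        tra_j=genes.get("tra_j", "TRAJ1"),
        tra_junction_nt=tra_nt,
        trb_v=genes.get("trb_v", "TRBV1"),
        trb_d=genes.get("trb_d", "TRBD1"),
        trb_j=genes.get("trb_j", "TRBJ1"),
        trb_junction_nt=trb_nt,
        cells=cells,
    )


def _tt(tid, ct_ids, n_cells, rank=None):
    return TCRType(tid, "CA", "CW", ct_ids, n_cells, Counter(), rank=rank)


def _label(cell_id, **kw):
    sample, barcode = cell_id.split(":")
    return cell_id, CellLabel(barcode, sample, **kw)


class TestDetectConvergent:
    def test_single_clonotype_not_convergent(self):
        df = detect_convergent_types([_tt("T1", ["C1"], 2)], [_ct("C1", ["s1:a", "s1:b"])])
        assert not df["convergent"].iloc[0]

    def test_all_unique_repertoire_has_no_convergence(self):
        types = [_tt(f"T{i}", [f"C{i}"], 1) for i in range(5)]
        cts = [_ct(f"C{i}", [f"s1:c{i}"]) for i in range(5)]
        assert not detect_convergent_types(types, cts)["convergent"].any()

    def test_spiked_type_convergent_and_gene_concordant(self, pipeline_result):
        types = [t for t in pipeline_result["types"] if t.n_clonotypes >= 2]
        assert len(types) == 1
        df = detect_convergent_types(
            types, pipeline_result["clonotypes"], pipeline_result["labels"]
        )
        row = df.iloc[0]
        assert row["convergent"] and row["gene_concordant"]
        assert row["n_clonotypes"] == 5
        assert row["conditions"] == "HCC"

    def test_gene_discordance_reported(self):
        cts = [
            _ct("C1", ["s1:a"], trb_v="TRBV1"),
            _ct("C2", ["s1:b"], trb_nt="TGCTGG", trb_v="TRBV2"),
        ]
        df = detect_convergent_types([_tt("T1", ["C1", "C2"], 2)], cts)
        assert df["convergent"].iloc[0] and not df["gene_concordant"].iloc[0]


class TestSharing:
    def test_three_way_split(self):
        cts = [
            _ct("C1", ["s1:a"]),
            _ct("C2", ["s2:b"]),
            _ct("C3", ["s1:c", "s2:d"]),
        ]
        labels = dict(
            [
                _label("s1:a", condition="control"),
                _label("s2:b", condition="HCC"),
                _label("s1:c", condition="control"),
                _label("s2:d", condition="HCC"),
            ]
        )
        types = [
            _tt("T1", ["C1"], 1, rank=1),
            _tt("T2", ["C2"], 1, rank=2),
            _tt("T3", ["C3"], 2, rank=3),
        ]
        row = sharing_summary(types, cts, labels, n=30).iloc[0]
        assert (row["a_only"], row["b_only"], row["both"]) == (1, 1, 1)
        assert row["n_top"] == 3

    def test_unlabeled_cells_excluded(self):
        cts = [_ct("C1", ["s1:a", "s1:b"])]
        labels = dict([_label("s1:a", condition="HCC")])
        row = sharing_summary([_tt("T1", ["C1"], 2)], cts, labels).iloc[0]
        assert (row["a_only"], row["b_only"], row["both"]) == (0, 1, 0)

    def test_counts_sum_to_top_n(self, pipeline_result):
        ranked = rank_tcr_types(pipeline_result["types"], n=30)
        row = sharing_summary(
            ranked, pipeline_result["clonotypes"], pipeline_result["labels"], n=30
        ).iloc[0]
        assert row["a_only"] + row["b_only"] + row["both"] == row["n_top"] == 30

    def test_matches_enumeration_oracle(self, pipeline_result):
        ranked = rank_tcr_types(pipeline_result["types"], n=30)
        cts = {c.clonotype_id: c for c in pipeline_result["clonotypes"]}
        labels = pipeline_result["labels"]
        a_only = b_only = both = 0
        for t in ranked:  # brute-force presence re-derivation
            conds = set()
            for cid in t.clonotype_ids:
                for cell in cts[cid].cells:
                    if cell in labels and labels[cell].condition:
                        conds.add(labels[cell].condition)
            if conds == {"control", "HCC"}:
                both += 1
            elif conds == {"control"}:
                a_only += 1
            elif conds == {"HCC"}:
                b_only += 1
        row = sharing_summary(ranked, pipeline_result["clonotypes"], labels, n=30).iloc[0]
        assert (row["a_only"], row["b_only"], row["both"]) == (a_only, b_only, both)

    def test_spiked_type_present_only_in_tumor_condition(self, pipeline_result):
        spike_type = next(t for t in pipeline_result["types"] if t.n_clonotypes == 5)
        cts = pipeline_result["clonotypes"]
        labels = pipeline_result["labels"]
        from clonoverge.convergence import type_conditions

        by_id = {c.clonotype_id: c for c in cts}
        assert type_conditions(spike_type, by_id, labels) == {"HCC"}


class TestComposition:
    def test_single_cell_clonotype(self):
        labels = dict([_label("s1:a", gfp_status="GFP_pos", cluster="C3")])
        df = compartment_composition(_tt("T1", ["C1"], 1), [_ct("C1", ["s1:a"])], labels)
        assert len(df) == 1
        assert df.iloc[0].tolist() == ["T1", "C1", "GFP_pos", "C3", 1]

    def test_label_free_input_binned_unlabeled(self):
        df = compartment_composition(
            _tt("T1", ["C1"], 2), [_ct("C1", ["s1:a", "s1:b"])], {}
        )
        assert (df["gfp_status"] == "unlabeled").all()
        assert (df["cluster"] == "unlabeled").all()

    def test_matches_groupby_oracle_and_conserves_cells(self, pipeline_result):
        import pandas as pd

        types, cts = pipeline_result["types"], pipeline_result["clonotypes"]
        labels = pipeline_result["labels"]
        total = 0
        for t in types:
            df = compartment_composition(t, cts, labels)
            assert df["n_cells"].sum() == t.n_cells
            total += df["n_cells"].sum()
            # oracle: pandas groupby over the raw member-cell labels
            rows = []
            by_id = {c.clonotype_id: c for c in cts}
            for cid in t.clonotype_ids:
                for cell in by_id[cid].cells:
                    lab = labels.get(cell)
                    rows.append(
                        {
                            "clonotype_id": cid,
                            "gfp_status": lab.gfp_status if lab else "unlabeled",
                            "cluster": lab.cluster if lab else "unlabeled",
                        }
                    )
            oracle = (
                pd.DataFrame(rows)
                .groupby(["clonotype_id", "gfp_status", "cluster"])
                .size()
                .reset_index(name="n_cells")
            )
            merged = df.drop(columns="tcr_type_id").sort_values(
                ["clonotype_id", "gfp_status", "cluster"]
            )
            assert merged.reset_index(drop=True).equals(
                oracle.sort_values(["clonotype_id", "gfp_status", "cluster"]).reset_index(
                    drop=True
                )
            )
        assert total == sum(t.n_cells for t in types)


class TestFisher:
    def test_extreme_table_enumeration_value(self):
        # all 126 + 126 orderings; only the two extreme tables are as unlikely
        assert fisher_exact_2x2(5, 0, 0, 5) == pytest.approx(2 / 252, rel=1e-12)

    def test_symmetric_table_is_one(self):
        assert fisher_exact_2x2(1, 1, 1, 1) == 1.0

    def test_all_margins_up_to_eight_match_enumeration(self):
        for a in range(9):
            for b in range(9 - a):
                for c in range(9 - a):
                    for d in range(9 - b):
                        if a + b + c + d == 0:
                            continue
                        if a + b > 8 or c + d > 8 or a + c > 8 or b + d > 8:
                            continue
                        assert fisher_exact_2x2(a, b, c, d) == pytest.approx(
                            fisher_two_sided_oracle(a, b, c, d), rel=1e-9
                        )

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(0, 0, 0, 0)
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 1, 1, 1)
        with pytest.raises(ValueError):
            fisher_exact_2x2(1.5, 1, 1, 1)
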