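import random
from collections import defaultdict

import pytest

from clonoverge import (
    ContigRecord,
    assemble_cells,
    call_clonotypes,
    group_tcr_types,
    rank_tcr_types,
    translate_nt,
)
from oracles import translate_oracle


def _contig(barcode, chain, nt, *, sample="s1", umis=5, reads=50, productive=True, **kw):
    aa = translate_oracle(nt) if len(nt) % 3 == 0 else ""
    genes = {
        "v_gene": kw.get("v_gene", f"{chain}V1"),
        "j_gene": kw.get("j_gene", f"{chain}J1"),
        "d_gene": kw.get("d_gene", "TRBD1" if chain == "TRB" else None),
    }
    return ContigRecord(
        barcode, sample, chain, nt, aa, productive, umis=umis, reads=reads, **genes
    )


class TestTranslate:
    def test_codon_table(self):
        assert translate_nt("TGTGCTAGC") == "CAS"
        assert translate_nt("") == ""
        assert translate_nt("TGA") == "*"

    def test_random_sequence_matches_literal_table_oracle(self):
        rnd = random.Random(42)
        seq = "".join(rnd.choice("ACGT") for _ in range(900))
        assert translate_nt(seq) == translate_oracle(seq)

    def test_errors(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            translate_nt("TGTG")
        with pytest.raises(ValueError, match="non-ACGT"):
            translate_nt("TGN")


class TestAssemble:
    def test_simple_pairing(self):
        cells = assemble_cells(
            [_contig("A", "TRA", "TGTGCTTTT"), _contig("A", "TRB", "TGTGCTTGG")]
        )
        (cell,) = cells
        assert cell.paired and not cell.multi_tra and not cell.multi_trb

    def test_top_umi_retained_and_flagged(self):
        cells = assemble_cells(
            [
                _contig("A", "TRA", "TGTGCTTTT", umis=5),
                _contig("A", "TRA", "TGTGTTTTT", umis=9),
                _contig("A", "TRB", "TGTGCTTGG"),
            ]
        )
        (cell,) = cells
        assert cell.tra.umis == 9 and cell.multi_tra and not cell.multi_trb

    def test_umi_ties_break_by_reads_then_junction(self):
        cells = assemble_cells(
            [
                _contig("A", "TRA", "TGTGTTTTT", umis=5, reads=10),
                _contig("A", "TRA", "TGTGCTTTT", umis=5, reads=10),
                _contig("A", "TRB", "TGTGCTTGG"),
            ]
        )
        assert cells[0].tra.junction_nt == "TGTGCTTTT"  # lexicographically first

    def test_nonproductive_dropped_without_flag(self):
        cells = assemble_cells(
            [
                _contig("A", "TRA", "TGTGCTTTT"),
                _contig("A", "TRA", "TGTGATTTT", productive=False, umis=99),
                _contig("A", "TRB", "TGTGCTTGG"),
            ]
        )
        (cell,) = cells
        assert cell.tra.junction_nt == "TGTGCTTTT" and not cell.multi_tra

    def test_matches_simulator_truth_for_singlets(self, study_bundle, pipeline_result):
        cells = {c.cell_id: c for c in pipeline_result["cells"]}
        for sim_cell in study_bundle.cells:
            if sim_cell.is_doublet:
                continue
            cell = cells[sim_cell.cell_id]
            assert cell.tra.junction_nt == sim_cell.clone.tra.junction_nt
            assert cell.trb.junction_nt == sim_cell.clone.trb.junction_nt

    def test_doublets_resolve_to_primary_clone(self, study_bundle, pipeline_result):
        cells = {c.cell_id: c for c in pipeline_result["cells"]}
        doublets = [c for c in study_bundle.cells if c.is_doublet]
        assert doublets, "bundle should contain planted doublets"
        for sim_cell in doublets:
            cell = cells[sim_cell.cell_id]
            assert cell.trb.junction_nt == sim_cell.clone.trb.junction_nt


class TestClonotypes:
    def test_identical_pairs_group(self):
        contigs = []
        for bc in ("A", "B"):
            contigs += [_contig(bc, "TRA", "TGTGCTTTT"), _contig(bc, "TRB", "TGTGCTTGG")]
        (ct,) = call_clonotypes(assemble_cells(contigs))
        assert ct.size == 2

    def test_synonymous_variants_are_distinct_clonotypes(self):
        contigs = [
            _contig("A", "TRA", "TGTGCTTTT"),
            _contig("A", "TRB", "TGTGCATGG"),
            _contig("B", "TRA", "TGTGCTTTT"),
            _contig("B", "TRB", "TGCGCATGG"),  # synonymous TRB variant
        ]
        cts = call_clonotypes(assemble_cells(contigs))
        assert len(cts) == 2
        types = group_tcr_types(cts)
        assert len(types) == 1 and types[0].n_clonotypes == 2

    def test_partition_matches_groupby_oracle(self, pipeline_result):
        cells = [c for c in pipeline_result["cells"] if c.paired]
        oracle = defaultdict(set)
        for c in cells:
            key = (
                c.tra.v_gene, c.tra.j_gene, c.tra.junction_nt,
                c.trb.v_gene, c.trb.d_gene, c.trb.j_gene, c.trb.junction_nt,
            )
            oracle[key].add(c.cell_id)
        got = {frozenset(ct.cells) for ct in pipeline_result["clonotypes"]}
        assert got == {frozenset(v) for v in oracle.values()}

    def test_single_chain_cells_excluded(self):
        contigs = [
            _contig("A", "TRA", "TGTGCTTTT"),
            _contig("B", "TRA", "TGTGCTTTT"),
            _contig("B", "TRB", "TGTGCTTGG"),
        ]
        cts = call_clonotypes(assemble_cells(contigs))
        assert sum(ct.size for ct in cts) == 1


class TestTCRTypes:
    def test_counts_conserved_through_groupings(self, pipeline_result):
        cells = sum(1 for c in pipeline_result["cells"] if c.paired)
        cts, types = pipeline_result["clonotypes"], pipeline_result["types"]
        assert sum(ct.size for ct in cts) == cells
        assert sum(t.n_cells for t in types) == cells
        assert sum(t.n_clonotypes for t in types) == len(cts)

    def test_members_translate_to_type_key(self, pipeline_result):
        by_id = {ct.clonotype_id: ct for ct in pipeline_result["clonotypes"]}
        for t in pipeline_result["types"]:
            for cid in t.clonotype_ids:
                ct = by_id[cid]
                assert translate_oracle(ct.tra_junction_nt) == t.tra_junction_aa
                assert translate_oracle(ct.trb_junction_nt) == t.trb_junction_aa
                # synonymy forces equal nucleotide lengths
                assert len(ct.tra_junction_nt) == 3 * len(t.tra_junction_aa)
                assert len(ct.trb_junction_nt) == 3 * len(t.trb_junction_aa)

    def test_grouping_invariant_under_cell_permutation(self, pipeline_result):
        cells = list(pipeline_result["cells"])
        random.Random(0).shuffle(cells)
        cts = call_clonotypes(cells)
        types = group_tcr_types(cts)
        ref = {(t.tra_junction_aa, t.trb_junction_aa, t.n_cells, t.n_clonotypes)
               for t in pipeline_result["types"]}
        assert {(t.tra_junction_aa, t.trb_junction_aa, t.n_cells, t.n_clonotypes)
                for t in types} == ref


class TestRanking:
    def test_rank_order_and_tiebreaks(self):
        from clonoverge.clonotyping import TCRType
        from collections import Counter

        def t(aa, cells, ncts):
            return TCRType("TT" + aa, aa, "CAW", [f"{aa}{k}" for k in range(ncts)],
                           cells, Counter())

        types = [t("B", 7, 1), t("A", 7, 2), t("D", 2, 1), t("C", 10, 1)]
        ranked = rank_tcr_types(types, n=30)
        assert [x.tra_junction_aa for x in ranked] == ["C", "A", "B", "D"]
        assert [x.rank for x in ranked] == [1, 2, 3, 4]

    def test_rank_matches_sort_oracle(self, pipeline_result):
        types = pipeline_result["types"]
        ranked = rank_tcr_types(types, n=30)
        oracle = sorted(
            types,
            key=lambda t: (-t.n_cells, -t.n_clonotypes, t.tra_junction_aa, t.trb_junction_aa),
        )[:30]
        assert [t.tcr_type_id for t in ranked] == [t.tcr_type_id for t in oracle]

    def test_n_larger_than_type_count(self):
        from collections import Counter
        from clonoverge.clonotyping import TCRType

        types = [TCRType("TT1", "CAF", "CAW", ["x"], 3, Counter())]
        assert len(rank_tcr_types(types, n=30)) == 1
        with pytest.raises(ValueError):
            rank_tcr_types(types, n=0)
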