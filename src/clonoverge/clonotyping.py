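"""Paired-chain assembly, clonotype calling and TCR-type grouping.

Definitions used throughout:

* A **clonotype** is the set of cells sharing identical paired TRA+TRB
  junction *nucleotide* sequences (the mRNA-level unit). By default the key
  also includes the V/J (and TRB D) gene calls, matching upstream caller
  conventions; a nucleotide-only key policy is available.
* A **TCR type** is the set of clonotypes sharing identical paired TRA+TRB
  junction *amino-acid* sequences. Distinct clonotypes inside one TCR type
  are synonymous nucleotide variants — the signature of convergent
  recombination.

Cells enter clonotype calling with exactly one productive contig per chain:
per cell and chain, the highest-UMI productive contig is retained (ties
broken by read count, then lexicographically smallest junction), and a flag
records that competing productive contigs existed.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._seq import translate_nt
from .contigs import ContigRecord

logger = logging.getLogger(__name__)

KEY_POLICY_GENES_NT = "genes+nt"
KEY_POLICY_NT = "nt"


@dataclass
class CellVDJ:
    """Per-cell paired-chain unit after contig assembly."""

    cell_id: str
    sample_id: str
    barcode: str
    tra: ContigRecord | None = None
    trb: ContigRecord | None = None
    multi_tra: bool = False
    multi_trb: bool = False

    @property
    def paired(self) -> bool:
        return self.tra is not None and self.trb is not None


@dataclass
class Clonotype:
    """Cells sharing one exact paired nucleotide key."""

    clonotype_id: str
    key: tuple
    tra_v: str | None
    tra_j: str | None
    tra_junction_nt: str
    trb_v: str | None
    trb_d: str | None
    trb_j: str | None
    trb_junction_nt: str
    cells: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.cells)

    @property
    def size_by_sample(self) -> Counter:
        return Counter(c.split(":", 1)[0] for c in self.cells)

    @property
    def tra_junction_aa(self) -> str:
        return translate_nt(self.tra_junction_nt)

    @property
    def trb_junction_aa(self) -> str:
        return translate_nt(self.trb_junction_nt)

    @property
    def gene_combination(self) -> tuple:
        return (self.tra_v, self.tra_j, self.trb_v, self.trb_d, self.trb_j)


@dataclass
class TCRType:
    """Clonotypes sharing one paired amino-acid key."""

    tcr_type_id: str
    tra_junction_aa: str
    trb_junction_aa: str
    clonotype_ids: list[str]
    n_cells: int
    size_by_sample: Counter
    rank: int | None = None

    @property
    def n_clonotypes(self) -> int:
        return len(self.clonotype_ids)


def _contig_sort_key(record: ContigRecord) -> tuple:
    # highest UMIs first, then reads, then lexicographically smallest junction
    return (-record.umis, -record.reads, record.junction_nt)


def assemble_cells(contigs: Iterable[ContigRecord]) -> list[CellVDJ]:
    """Group contigs by cell and retain one productive contig per chain.

    Non-productive contigs are discarded; cells left with neither chain are
    dropped. ``multi_tra``/``multi_trb`` flag cells where more than one
    productive contig competed for a chain. Output is sorted by cell id.
    """
    by_cell: dict[str, dict[str, list[ContigRecord]]] = defaultdict(
        lambda: {"TRA": [], "TRB": []}
    )
    for rec in contigs:
        if rec.productive:
            by_cell[rec.cell_id][rec.chain].append(rec)
    cells = []
    for cid in sorted(by_cell):
        chains = by_cell[cid]
        tra_list = sorted(chains["TRA"], key=_contig_sort_key)
        trb_list = sorted(chains["TRB"], key=_contig_sort_key)
        if not tra_list and not trb_list:
            continue
        sample_id, barcode = cid.split(":", 1)
        cells.append(
            CellVDJ(
                cell_id=cid,
                sample_id=sample_id,
                barcode=barcode,
                tra=tra_list[0] if tra_list else None,
                trb=trb_list[0] if trb_list else None,
                multi_tra=len(tra_list) > 1,
                multi_trb=len(trb_list) > 1,
            )
        )
    return cells


def clonotype_key(cell: CellVDJ, key_policy: str = KEY_POLICY_GENES_NT) -> tuple:
    """The exact-match key a paired cell contributes to clonotype calling."""
    assert cell.tra is not None and cell.trb is not None
    if key_policy == KEY_POLICY_GENES_NT:
        return (
            cell.tra.v_gene or "",
            cell.tra.j_gene or "",
            cell.tra.junction_nt,
            cell.trb.v_gene or "",
            cell.trb.d_gene or "",
            cell.trb.j_gene or "",
            cell.trb.junction_nt,
        )
    if key_policy == KEY_POLICY_NT:
        return (cell.tra.junction_nt, cell.trb.junction_nt)
    raise ValueError(f"unknown key policy {key_policy!r}")


def call_clonotypes(
    cells: Sequence[CellVDJ],
    key_policy: str = KEY_POLICY_GENES_NT,
    *,
    require_paired: bool = True,
) -> list[Clonotype]:
    """Partition paired cells into clonotypes by exact key equality.

    Single-chain cells are excluded (and counted in the log) under the
    default strict-paired policy. Clonotype ids are stable: assigned in order
    of decreasing size, ties by lexicographic key.
    """
    eligible = []
    n_single = 0
    for cell in cells:
        if cell.paired:
            eligible.append(cell)
        else:
            n_single += 1
            if not require_paired:
                raise NotImplementedError("single-chain clonotyping is not supported")
    if n_single:
        logger.info("excluded %d single-chain cells from clonotype calling", n_single)
    groups: dict[tuple, list[CellVDJ]] = defaultdict(list)
    for cell in eligible:
        groups[clonotype_key(cell, key_policy)].append(cell)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    clonotypes = []
    width = max(4, len(str(len(ordered))))
    for i, (key, members) in enumerate(ordered, start=1):
        rep = members[0]
        assert rep.tra is not None and rep.trb is not None
        clonotypes.append(
            Clonotype(
                clonotype_id=f"CT{i:0{width}d}",
                key=key,
                tra_v=rep.tra.v_gene,
                tra_j=rep.tra.j_gene,
                tra_junction_nt=rep.tra.junction_nt,
                trb_v=rep.trb.v_gene,
                trb_d=rep.trb.d_gene,
                trb_j=rep.trb.j_gene,
                trb_junction_nt=rep.trb.junction_nt,
                cells=sorted(c.cell_id for c in members),
            )
        )
    return clonotypes


def group_tcr_types(clonotypes: Sequence[Clonotype]) -> list[TCRType]:
    """Partition clonotypes into TCR types by paired amino-acid key.

    Each clonotype's junctions are re-translated; a clonotype whose stored
    amino-acid sequences cannot be derived from its nucleotide junctions is a
    data-corruption signal and raises.
    """
    groups: dict[tuple[str, str], list[Clonotype]] = defaultdict(list)
    for ct in clonotypes:
        if len(ct.tra_junction_nt) % 3 or len(ct.trb_junction_nt) % 3:
            raise ValueError(
                f"{ct.clonotype_id}: junction length not a codon multiple; cannot translate"
            )
        groups[(ct.tra_junction_aa, ct.trb_junction_aa)].append(ct)
    types = []
    ordered = sorted(groups.items(), key=lambda kv: kv[0])
    width = max(4, len(str(len(ordered))))
    for i, ((tra_aa, trb_aa), members) in enumerate(ordered, start=1):
        sizes: Counter = Counter()
        for ct in members:
            sizes.update(ct.size_by_sample)
        types.append(
            TCRType(
                tcr_type_id=f"TT{i:0{width}d}",
                tra_junction_aa=tra_aa,
                trb_junction_aa=trb_aa,
                clonotype_ids=sorted(ct.clonotype_id for ct in members),
                n_cells=sum(ct.size for ct in members),
                size_by_sample=sizes,
            )
        )
    return types


def rank_tcr_types(types: Sequence[TCRType], n: int = 30) -> list[TCRType]:
    """Rank TCR types by total cell count.

    Sorted by cells descending, ties by clonotype count descending, then by
    amino-acid key. Rank 1 is the most dominant type ("TCR 1"). Returns the
    top ``n`` (or all if fewer), each with ``rank`` set.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = sorted(
        types,
        key=lambda t: (-t.n_cells, -t.n_clonotypes, t.tra_junction_aa, t.trb_junction_aa),
    )
    ranked = []
    for rank, t in enumerate(ordered[:n], start=1):
        t.rank = rank
        ranked.append(t)
    return ranked
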