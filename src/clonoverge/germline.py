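"""Germline V/D/J segment references.

The junction-decomposition and simulation stages both need a set of germline
segments with known anchor positions: the conserved Cys codon near the 3' end
of each V segment and the conserved Phe/Trp codon near the 5' end of each J
segment. Junctions are handled anchor-inclusive (the IMGT "junction" sense:
CDR3 plus both anchor codons), so the portion of a V segment that can appear
in a junction is ``seq_nt[anchor_offset:]`` and the portion of a J segment is
``seq_nt[: anchor_offset + 3]``.

References are supplied as a FASTA of segment sequences plus a TSV with
columns ``id``, ``chain``, ``segment_class``, ``anchor_offset`` (0-based;
empty for D segments). A small synthetic reference suitable for tests and
simulation is produced by :func:`make_fixture_germline`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import check_nt

logger = logging.getLogger(__name__)

CHAINS = ("TRA", "TRB")
SEGMENT_CLASSES = ("V", "D", "J")

#: codons that can encode the conserved V anchor (Cys)
_CYS_CODONS = frozenset({"TGT", "TGC"})
#: codons that can encode the conserved J anchor (Phe or Trp)
_PHE_TRP_CODONS = frozenset({"TTT", "TTC", "TGG"})

METADATA_COLUMNS = ["id", "chain", "segment_class", "anchor_offset"]


@dataclass(frozen=True)
class GermlineSegment:
    """One germline V, D or J segment.

    ``anchor_offset`` is the 0-based position of the first nucleotide of the
    conserved anchor codon (Cys for V, Phe/Trp for J); D segments have none.
    """

    id: str
    chain: str
    segment_class: str
    seq_nt: str
    anchor_offset: int | None = None

    def __post_init__(self) -> None:
        if self.chain not in CHAINS:
            raise ValueError(f"{self.id}: unknown chain {self.chain!r}")
        if self.segment_class not in SEGMENT_CLASSES:
            raise ValueError(f"{self.id}: unknown segment class {self.segment_class!r}")
        if self.chain == "TRA" and self.segment_class == "D":
            raise ValueError(f"{self.id}: TRA has no D segments")
        seq = check_nt(self.seq_nt, what=f"segment {self.id}")
        object.__setattr__(self, "seq_nt", seq)
        if not seq:
            raise ValueError(f"{self.id}: empty sequence")
        if self.segment_class == "D":
            if self.anchor_offset is not None:
                raise ValueError(f"{self.id}: D segments carry no anchor_offset")
            return
        if self.anchor_offset is None:
            raise ValueError(f"{self.id}: {self.segment_class} segment requires anchor_offset")
        if not 0 <= self.anchor_offset <= len(seq) - 3:
            raise ValueError(
                f"{self.id}: anchor_offset {self.anchor_offset} outside [0, {len(seq) - 3}]"
            )
        codon = seq[self.anchor_offset : self.anchor_offset + 3]
        expected = _CYS_CODONS if self.segment_class == "V" else _PHE_TRP_CODONS
        if codon not in expected:
            logger.warning(
                "%s: anchor codon %s cannot encode the conserved %s anchor",
                self.id,
                codon,
                "Cys" if self.segment_class == "V" else "Phe/Trp",
            )

    @property
    def anchor_codon(self) -> str | None:
        if self.anchor_offset is None:
            return None
        return self.seq_nt[self.anchor_offset : self.anchor_offset + 3]


@dataclass
class GermlineSet:
    """A validated collection of germline segments with id/class lookups."""

    segments: list[GermlineSegment]
    _by_id: dict[str, GermlineSegment] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {}
        for seg in self.segments:
            if seg.id in self._by_id:
                raise ValueError(f"duplicate segment id {seg.id!r}")
            self._by_id[seg.id] = seg
        for chain in CHAINS:
            has_v = any(s.chain == chain and s.segment_class == "V" for s in self.segments)
            has_j = any(s.chain == chain and s.segment_class == "J" for s in self.segments)
            if has_v and not has_j:
                raise ValueError(f"chain {chain} has V segments but no J segments")

    def __len__(self) -> int:
        return len(self.segments)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GermlineSet):
            return NotImplemented
        return sorted(self.segments, key=lambda s: s.id) == sorted(
            other.segments, key=lambda s: s.id
        )

    def get(self, segment_id: str) -> GermlineSegment:
        try:
            return self._by_id[segment_id]
        except KeyError:
            raise KeyError(f"unknown germline segment {segment_id!r}") from None

    def __contains__(self, segment_id: str) -> bool:
        return segment_id in self._by_id

    def by_class(self, chain: str, segment_class: str) -> list[GermlineSegment]:
        """All segments of one chain and class, sorted by id."""
        return sorted(
            (s for s in self.segments if s.chain == chain and s.segment_class == segment_class),
            key=lambda s: s.id,
        )


def v_junction_region(seg: GermlineSegment) -> str:
    """3' portion of a V segment from its anchor codon onward.

    This is the (untrimmed) part of the V segment that can appear in an
    anchor-inclusive junction.
    """
    if seg.segment_class != "V":
        raise ValueError(f"{seg.id}: v_junction_region requires a V segment")
    assert seg.anchor_offset is not None
    return seg.seq_nt[seg.anchor_offset :]


def j_junction_region(seg: GermlineSegment) -> str:
    """5' portion of a J segment up to and including its anchor codon."""
    if seg.segment_class != "J":
        raise ValueError(f"{seg.id}: j_junction_region requires a J segment")
    assert seg.anchor_offset is not None
    return seg.seq_nt[: seg.anchor_offset + 3]


def load_germline(fasta_path: str | Path, metadata_path: str | Path) -> GermlineSet:
    """Load a germline set from a FASTA plus a metadata TSV.

    The TSV must carry ``id``, ``chain``, ``segment_class`` and
    ``anchor_offset`` columns; FASTA ids and metadata ids must match exactly.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq)
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"id": str})
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"germline metadata missing columns: {missing_cols}")
    if meta["id"].duplicated().any():
        dups = meta.loc[meta["id"].duplicated(), "id"].tolist()
        raise ValueError(f"duplicate metadata ids: {dups}")
    meta_ids = set(meta["id"])
    if meta_ids != set(seqs):
        only_fasta = sorted(set(seqs) - meta_ids)
        only_meta = sorted(meta_ids - set(seqs))
        raise ValueError(
            f"FASTA/metadata id mismatch (FASTA only: {only_fasta}, metadata only: {only_meta})"
        )
    segments = []
    for row in meta.itertuples(index=False):
        anchor = row.anchor_offset
        anchor = None if pd.isna(anchor) else int(anchor)
        segments.append(
            GermlineSegment(
                id=row.id,
                chain=row.chain,
                segment_class=row.segment_class,
                seq_nt=seqs[row.id],
                anchor_offset=anchor,
            )
        )
    return GermlineSet(segments)


def save_germline(gset: GermlineSet, fasta_path: str | Path, metadata_path: str | Path) -> None:
    """Write a germline set back to FASTA + metadata TSV (round-trips with
    :func:`load_germline`)."""
    records = [
        SeqRecord(Seq(s.seq_nt), id=s.id, description="")
        for s in sorted(gset.segments, key=lambda s: s.id)
    ]
    SeqIO.write(records, str(fasta_path), "fasta")
    rows = [
        {
            "id": s.id,
            "chain": s.chain,
            "segment_class": s.segment_class,
            "anchor_offset": "" if s.anchor_offset is None else s.anchor_offset,
        }
        for s in sorted(gset.segments, key=lambda s: s.id)
    ]
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(metadata_path, sep="\t", index=False)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def make_fixture_germline(
    seed: int = 1,
    *,
    n_v: int = 4,
    n_j: int = 3,
    n_d: int = 2,
) -> GermlineSet:
    """Generate a small synthetic germline reference.

    Produces ``n_v`` V and ``n_j`` J segments per chain and ``n_d`` TRB D
    segments. V segments end in an ~10-14 nt junction region opening with a
    Cys codon; J segments begin with an ~9-12 nt junction region closing with
    a Phe/Trp codon; D segments are 12-14 nt, the length range of mouse TRB D
    segments. Sequences are random, so segments are synthetic stand-ins for a
    real reference, not copies of any database release.
    """
    rng = np.random.default_rng(seed)
    segments: list[GermlineSegment] = []
    for chain in CHAINS:
        for i in range(n_v):
            lead = _random_nt(rng, int(rng.integers(24, 40)))
            region_tail = _random_nt(rng, int(rng.integers(7, 12)))
            cys = "TGT" if rng.random() < 0.5 else "TGC"
            seq = lead + cys + region_tail
            segments.append(
                GermlineSegment(
                    id=f"{chain}V{i + 1}",
                    chain=chain,
                    segment_class="V",
                    seq_nt=seq,
                    anchor_offset=len(lead),
                )
            )
        for i in range(n_j):
            region_head = _random_nt(rng, int(rng.integers(6, 10)))
            anchor = ["TTT", "TTC", "TGG"][int(rng.integers(3))]
            tail = _random_nt(rng, int(rng.integers(18, 30)))
            seq = region_head + anchor + tail
            segments.append(
                GermlineSegment(
                    id=f"{chain}J{i + 1}",
                    chain=chain,
                    segment_class="J",
                    seq_nt=seq,
                    anchor_offset=len(region_head),
                )
            )
        if chain == "TRB":
            for i in range(n_d):
                seq = _random_nt(rng, int(rng.integers(12, 15)))
                segments.append(
                    GermlineSegment(
                        id=f"{chain}D{i + 1}",
                        chain=chain,
                        segment_class="D",
                        seq_nt=seq,
                    )
                )
    return GermlineSet(segments)
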