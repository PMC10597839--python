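"""Reading, merging and writing TCR contig annotation tables.

Input is the per-sample ``filtered_contig_annotations.csv`` emitted by 10x-style
V(D)J callers (AIRR rearrangement TSVs are accepted too, with their column
names mapped). Contigs from chains other than TRA/TRB are dropped on read with
a logged count; non-productive contigs are kept at this stage so raw I/O is
lossless — they are excluded later during per-cell chain assembly.

Cell identity throughout the package is the pair ``(sample_id, barcode)``,
rendered as the namespaced string ``"<sample_id>:<barcode>"`` so that barcode
collisions between samples stay distinct cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

KEPT_CHAINS = ("TRA", "TRB")

#: 10x column name -> internal name
_TENX_COLUMNS = {
    "barcode": "barcode",
    "chain": "chain",
    "v_gene": "v_gene",
    "d_gene": "d_gene",
    "j_gene": "j_gene",
    "cdr3": "junction_aa",
    "cdr3_nt": "junction_nt",
    "productive": "productive",
    "umis": "umis",
    "reads": "reads",
}

#: AIRR rearrangement column name -> internal name
_AIRR_COLUMNS = {
    "cell_id": "barcode",
    "locus": "chain",
    "v_call": "v_gene",
    "d_call": "d_gene",
    "j_call": "j_gene",
    "junction_aa": "junction_aa",
    "junction": "junction_nt",
    "productive": "productive",
    "duplicate_count": "umis",
    "consensus_count": "reads",
}

_MANDATORY = ("barcode", "chain", "junction_aa", "junction_nt", "productive")

#: strings parsed as productive=True; anything else (incl. "None") is False
_TRUE_STRINGS = frozenset({"true", "t", "yes", "1", "1.0"})


def cell_id(sample_id: str, barcode: str) -> str:
    """Namespaced cell identifier used package-wide."""
    return f"{sample_id}:{barcode}"


@dataclass(frozen=True)
class ContigRecord:
    """One sequenced TCR chain contig for one cell barcode."""

    barcode: str
    sample_id: str
    chain: str
    junction_nt: str
    junction_aa: str
    productive: bool
    v_gene: str | None = None
    d_gene: str | None = None
    j_gene: str | None = None
    umis: int = 0
    reads: int = 0

    def __post_init__(self) -> None:
        if self.chain not in KEPT_CHAINS:
            raise ValueError(f"unsupported chain {self.chain!r}")
        if self.chain == "TRA" and self.d_gene is not None:
            raise ValueError("TRA contigs cannot carry a D gene call")
        if self.umis < 0 or self.reads < 0:
            raise ValueError("umis/reads must be non-negative")

    @property
    def cell_id(self) -> str:
        return cell_id(self.sample_id, self.barcode)


@dataclass(frozen=True)
class CellLabel:
    """Optional per-cell annotations: GFP compartment, condition, cluster."""

    barcode: str
    sample_id: str
    gfp_status: str | None = None  # "GFP_pos" | "GFP_neg"
    condition: str | None = None  # "control" | "HCC"
    cluster: str | None = None  # e.g. "C3"

    @property
    def cell_id(self) -> str:
        return cell_id(self.sample_id, self.barcode)


def _parse_productive(value: object) -> bool:
    if isinstance(value, bool):
        return value
    if pd.isna(value):
        return False
    return str(value).strip().lower() in _TRUE_STRINGS


def _opt_str(value: object) -> str | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s if s and s.lower() not in {"nan", "none"} else None


def read_contig_annotations(
    path: str | Path,
    sample_id: str,
    *,
    high_confidence_only: bool = False,
) -> list[ContigRecord]:
    """Read one sample's contig annotation table (10x CSV or AIRR TSV).

    Rows whose chain is not TRA/TRB are dropped (count logged). The
    ``productive`` column is parsed permissively: any casing of "true" means
    productive; "None", "False" and blanks mean non-productive. With
    ``high_confidence_only`` the 10x ``high_confidence`` column, when
    present, filters rows too (default keeps everything).
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        logger.warning("%s: empty contig table for sample %s", path, sample_id)
        return []
    if "cdr3_nt" in df.columns or "cdr3" in df.columns:
        mapping = _TENX_COLUMNS
    else:
        mapping = _AIRR_COLUMNS
    df = df.rename(columns={k: v for k, v in mapping.items() if k in df.columns})
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    n_in = len(df)
    kept = df[df["chain"].isin(KEPT_CHAINS)]
    if high_confidence_only and "high_confidence" in kept.columns:
        kept = kept[kept["high_confidence"].map(_parse_productive)]
    n_dropped = n_in - len(kept)
    if n_dropped:
        logger.info("%s: dropped %d non-TRA/TRB contig rows", path, n_dropped)
    records = []
    for row in kept.itertuples(index=False):
        d = row._asdict()
        chain = d["chain"]
        records.append(
            ContigRecord(
                barcode=d["barcode"],
                sample_id=sample_id,
                chain=chain,
                junction_nt=(_opt_str(d.get("junction_nt")) or "").upper(),
                junction_aa=_opt_str(d.get("junction_aa")) or "",
                productive=_parse_productive(d.get("productive")),
                v_gene=_opt_str(d.get("v_gene")),
                d_gene=_opt_str(d.get("d_gene")) if chain == "TRB" else None,
                j_gene=_opt_str(d.get("j_gene")),
                umis=int(float(d.get("umis") or 0)),
                reads=int(float(d.get("reads") or 0)),
            )
        )
    return records


def read_cell_labels(path: str | Path) -> list[CellLabel]:
    """Read a per-cell label TSV with columns sample_id, barcode and any of
    gfp_status, condition, cluster."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "barcode"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column(s) ['{col}']")
    labels = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        labels.append(
            CellLabel(
                barcode=d["barcode"],
                sample_id=d["sample_id"],
                gfp_status=_opt_str(d.get("gfp_status")),
                condition=_opt_str(d.get("condition")),
                cluster=_opt_str(d.get("cluster")),
            )
        )
    return labels


def merge_samples(
    collections: Iterable[Sequence[ContigRecord]],
    labels: Iterable[CellLabel] | None = None,
) -> tuple[list[ContigRecord], dict[str, CellLabel]]:
    """Merge per-sample contig collections, joining labels where present.

    Returns the merged record list and a dict mapping namespaced cell id to
    its :class:`CellLabel`. Sample ids must be distinct across collections;
    cells without a label entry are simply absent from the dict (left-join).
    """
    merged: list[ContigRecord] = []
    seen_samples: set[str] = set()
    for coll in collections:
        coll = list(coll)
        if not coll:
            continue
        sids = {r.sample_id for r in coll}
        dup = sids & seen_samples
        if dup:
            raise ValueError(f"duplicate sample_id across collections: {sorted(dup)}")
        seen_samples |= sids
        merged.extend(coll)
    label_map: dict[str, CellLabel] = {}
    if labels is not None:
        for lab in labels:
            if lab.cell_id in label_map:
                raise ValueError(f"duplicate label for cell {lab.cell_id}")
            label_map[lab.cell_id] = lab
    return merged, label_map


# ---------------------------------------------------------------------------
# result tables

TABLE_COLUMNS: Mapping[str, list[str]] = {
    "contigs": [
        "sample_id",
        "barcode",
        "chain",
        "v_gene",
        "d_gene",
        "j_gene",
        "junction_nt",
        "junction_aa",
        "productive",
        "umis",
        "reads",
    ],
    "clonotypes": [
        "clonotype_id",
        "tra_v",
        "tra_j",
        "tra_junction_nt",
        "trb_v",
        "trb_d",
        "trb_j",
        "trb_junction_nt",
        "n_cells",
        "cells",
    ],
    "tcr_types": [
        "tcr_type_id",
        "rank",
        "tra_junction_aa",
        "trb_junction_aa",
        "n_clonotypes",
        "n_cells",
        "clonotype_ids",
    ],
    "decompositions": [
        "clonotype_id",
        "chain",
        "junction_nt",
        "parts",
        "v_trim",
        "d5_trim",
        "d3_trim",
        "j_trim",
        "d_assigned",
    ],
    "mismatches": ["tcr_type_id", "chain", "reference_clonotype", "clonotype_id", "positions"],
    "convergence": [
        "tcr_type_id",
        "rank",
        "n_clonotypes",
        "n_cells",
        "convergent",
        "gene_concordant",
        "samples",
        "conditions",
    ],
    "sharing_summary": ["condition_a", "condition_b", "n_top", "a_only", "b_only", "both"],
    "composition": ["tcr_type_id", "clonotype_id", "gfp_status", "cluster", "n_cells"],
    "demux": ["cell_id", "call", "assigned_to", "top", "second", "margin"],
}


def _contigs_frame(records: Sequence[ContigRecord]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": r.sample_id,
            "barcode": r.barcode,
            "chain": r.chain,
            "v_gene": r.v_gene or "",
            "d_gene": r.d_gene or "",
            "j_gene": r.j_gene or "",
            "junction_nt": r.junction_nt,
            "junction_aa": r.junction_aa,
            "productive": r.productive,
            "umis": r.umis,
            "reads": r.reads,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=TABLE_COLUMNS["contigs"])


def write_table(
    records: Sequence[ContigRecord] | pd.DataFrame,
    path: str | Path,
    kind: str,
    *,
    overwrite: bool = False,
) -> Path:
    """Write a result table as TSV with a deterministic column order.

    ``records`` is either a list of :class:`ContigRecord` (kind="contigs") or
    a DataFrame already shaped for ``kind``. Existing files are only replaced
    with ``overwrite=True``.
    """
    if kind not in TABLE_COLUMNS:
        raise ValueError(f"unknown table kind {kind!r}; expected one of {sorted(TABLE_COLUMNS)}")
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    if isinstance(records, pd.DataFrame):
        df = records
    elif kind == "contigs":
        df = _contigs_frame(records)
    else:
        raise TypeError(f"table kind {kind!r} requires a DataFrame input")
    missing = [c for c in TABLE_COLUMNS[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"table kind {kind!r} missing columns {missing}")
    df = df[TABLE_COLUMNS[kind]]
    df.to_csv(path, sep="\t", index=False)
    return path


def read_contigs_table(path: str | Path) -> list[ContigRecord]:
    """Read back a ``contigs`` TSV written by :func:`write_table`."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            ContigRecord(
                barcode=d["barcode"],
                sample_id=d["sample_id"],
                chain=d["chain"],
                junction_nt=d["junction_nt"],
                junction_aa=d["junction_aa"],
                productive=_parse_productive(d["productive"]),
                v_gene=_opt_str(d["v_gene"]),
                d_gene=_opt_str(d["d_gene"]) if d["chain"] == "TRB" else None,
                j_gene=_opt_str(d["j_gene"]),
                umis=int(float(d["umis"] or 0)),
                reads=int(float(d["reads"] or 0)),
            )
        )
    return records
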