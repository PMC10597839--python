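"""Convergence, sharing and compartment-composition reports.

These are the tabular counterparts of the study's repertoire figures: which
TCR types are convergent (multiple synonymous clonotypes), whether each
top-ranked type is seen in control animals, tumor-bearing animals or both,
and how each clonotype's cells split across GFP compartments and expression
clusters. Circos-style rendering is out of scope — the tables are tidy
long-format and plot-ready.
"""

from __future__ import annotations

import logging
import numbers
from collections import Counter
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import fisher_exact

from .clonotyping import Clonotype, TCRType
from .contigs import CellLabel

logger = logging.getLogger(__name__)

UNLABELED = "unlabeled"


def _clonotype_index(clonotypes: Iterable[Clonotype]) -> dict[str, Clonotype]:
    return {ct.clonotype_id: ct for ct in clonotypes}


def detect_convergent_types(
    types: Sequence[TCRType],
    clonotypes: Sequence[Clonotype],
    labels: Mapping[str, CellLabel] | None = None,
) -> pd.DataFrame:
    """Per-TCR-type convergence report.

    A type is convergent iff it contains >= 2 clonotypes (distinct nucleotide
    variants of one amino-acid receptor). ``gene_concordant`` records whether
    all member clonotypes use the same V/D/J combination — an observed
    outcome, not part of the grouping. Rows sorted by rank when ranked, else
    by cell count.
    """
    by_id = _clonotype_index(clonotypes)
    labels = labels or {}
    rows = []
    for t in types:
        members = [by_id[cid] for cid in t.clonotype_ids]
        gene_combos = {ct.gene_combination for ct in members}
        samples = sorted({s for ct in members for s in ct.size_by_sample})
        conditions = sorted(
            {
                labels[c].condition
                for ct in members
                for c in ct.cells
                if c in labels and labels[c].condition
            }
        )
        rows.append(
            {
                "tcr_type_id": t.tcr_type_id,
                "rank": t.rank if t.rank is not None else "",
                "n_clonotypes": t.n_clonotypes,
                "n_cells": t.n_cells,
                "convergent": t.n_clonotypes >= 2,
                "gene_concordant": len(gene_combos) == 1,
                "samples": ";".join(samples),
                "conditions": ";".join(conditions),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "tcr_type_id",
            "rank",
            "n_clonotypes",
            "n_cells",
            "convergent",
            "gene_concordant",
            "samples",
            "conditions",
        ],
    )
    if len(df):
        sort_rank = df["rank"].map(lambda r: 10**9 if r == "" else int(r))
        df = (
            df.assign(_r=sort_rank)
            .sort_values(by=["_r", "n_cells"], ascending=[True, False])
            .drop(columns="_r")
            .reset_index(drop=True)
        )
    return df


def type_conditions(
    t: TCRType,
    clonotypes_by_id: Mapping[str, Clonotype],
    labels: Mapping[str, CellLabel],
    *,
    min_cells: int = 1,
) -> set[str]:
    """Conditions in which a TCR type is present (>= min_cells labeled
    member cells carrying that condition)."""
    counts: Counter = Counter()
    for cid in t.clonotype_ids:
        for cell in clonotypes_by_id[cid].cells:
            lab = labels.get(cell)
            if lab is not None and lab.condition:
                counts[lab.condition] += 1
    return {cond for cond, n in counts.items() if n >= min_cells}


def sharing_summary(
    ranked_types: Sequence[TCRType],
    clonotypes: Sequence[Clonotype],
    labels: Mapping[str, CellLabel],
    n: int = 30,
    *,
    condition_a: str = "control",
    condition_b: str = "HCC",
    min_cells: int = 1,
) -> pd.DataFrame:
    """Cross-condition sharing of the top-``n`` TCR types.

    Counts how many of the top types are present only in ``condition_a``,
    only in ``condition_b``, or in both. Cells without a condition label are
    excluded (warned once). The three counts sum to the number of types
    summarized.
    """
    by_id = _clonotype_index(clonotypes)
    top = ranked_types[:n]
    n_unlabeled = sum(
        1
        for t in top
        for cid in t.clonotype_ids
        for cell in by_id[cid].cells
        if cell not in labels or not labels[cell].condition
    )
    if n_unlabeled:
        logger.warning("%d cells without condition labels excluded from sharing", n_unlabeled)
    a_only = b_only = both = neither = 0
    for t in top:
        conds = type_conditions(t, by_id, labels, min_cells=min_cells)
        in_a, in_b = condition_a in conds, condition_b in conds
        if in_a and in_b:
            both += 1
        elif in_a:
            a_only += 1
        elif in_b:
            b_only += 1
        else:
            neither += 1
    if neither:
        logger.warning("%d top types had no labeled cells in either condition", neither)
    return pd.DataFrame(
        [
            {
                "condition_a": condition_a,
                "condition_b": condition_b,
                "n_top": len(top),
                "a_only": a_only,
                "b_only": b_only,
                "both": both,
            }
        ]
    )


def compartment_composition(
    t: TCRType,
    clonotypes: Sequence[Clonotype],
    labels: Mapping[str, CellLabel],
) -> pd.DataFrame:
    """Per-clonotype cell counts by GFP compartment x cluster for one type.

    Cells without a label are binned as "unlabeled". One row per
    (clonotype, gfp_status, cluster) combination observed; counts sum to the
    type's cell total.
    """
    by_id = _clonotype_index(clonotypes)
    counts: Counter = Counter()
    for cid in t.clonotype_ids:
        for cell in by_id[cid].cells:
            lab = labels.get(cell)
            gfp = (lab.gfp_status if lab and lab.gfp_status else UNLABELED)
            cluster = (lab.cluster if lab and lab.cluster else UNLABELED)
            counts[(cid, gfp, cluster)] += 1
    rows = [
        {
            "tcr_type_id": t.tcr_type_id,
            "clonotype_id": cid,
            "gfp_status": gfp,
            "cluster": cluster,
            "n_cells": n,
        }
        for (cid, gfp, cluster), n in sorted(counts.items())
    ]
    return pd.DataFrame(
        rows, columns=["tcr_type_id", "clonotype_id", "gfp_status", "cluster", "n_cells"]
    )


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p-value for the 2x2 table [[a, b], [c, d]].

    Sums hypergeometric probabilities of all tables with the observed margins
    that are no more probable than the observed one. Entries must be
    non-negative integers and not all zero; the result lies in (0, 1].
    """
    for x in (a, b, c, d):
        if not isinstance(x, numbers.Integral) or x < 0:
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if a + b + c + d == 0:
        raise ValueError("all-zero table has no defined test")
    p = float(fisher_exact([[a, b], [c, d]], alternative="two-sided").pvalue)
    return min(max(p, 5e-324), 1.0)
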