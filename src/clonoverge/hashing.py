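"""Hashtag (cell-hashing) normalization, demultiplexing and cell QC.

Cells from several mice are pooled in one droplet run after staining each
mouse's cells with a distinct DNA-barcoded antibody (hashtag). Raw hashtag
counts are normalized per cell with the transform

    value = log2( (count + 1) / g + 1 ),   g = geomean over hashtags of (count + 1)

i.e. add one, divide by the per-cell geometric mean, add one, take log base 2.
Equal counts across hashtags therefore normalize to exactly 1.0. A cell is
assigned to the mouse of its top hashtag when that value clears a floor and
leads the runner-up by a margin; a strong-but-contested profile is called a
multiplet and a weak one ambiguous, both of which are filtered before
downstream analysis. The margin rule (defaults: floor 2.0, margin 1.0 in
log2 units) is a transparent, configurable stand-in for proprietary
demultiplexers whose logic is unpublished.

Cell QC keeps cells by total molecule count and mitochondrial percentage
(defaults 30,000 and 30). The count threshold direction is configurable
because "counts of <30,000" can be read either as the retention or the
exclusion criterion; the default retains cells at or below the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread

logger = logging.getLogger(__name__)

CALL_ASSIGNED = "assigned"
CALL_MULTIPLET = "multiplet"
CALL_AMBIGUOUS = "ambiguous"


@dataclass
class HashtagMatrix:
    """Non-negative integer counts, cells x hashtag features."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate hashtag feature ids")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate cell ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative hashtag counts")

    @property
    def cells(self) -> list[str]:
        return list(self.counts.index)

    @property
    def features(self) -> list[str]:
        return list(self.counts.columns)

    @classmethod
    def from_mtx_dir(cls, directory: str | Path) -> "HashtagMatrix":
        """Read a 10x-style MTX triplet: matrix.mtx (features x barcodes),
        features.tsv, barcodes.tsv."""
        directory = Path(directory)
        mat = mmread(directory / "matrix.mtx").toarray()
        features = pd.read_csv(directory / "features.tsv", sep="\t", header=None)[0].tolist()
        barcodes = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0].tolist()
        if mat.shape != (len(features), len(barcodes)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match {len(features)} features x "
                f"{len(barcodes)} barcodes"
            )
        counts = pd.DataFrame(mat.T.astype(int), index=barcodes, columns=features)
        return cls(counts)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HashtagMatrix":
        """Read a dense TSV, cells as rows, hashtags as columns."""
        return cls(pd.read_csv(path, sep="\t", index_col=0))


def normalize_hashtags(matrix: HashtagMatrix | pd.DataFrame) -> pd.DataFrame:
    """Per-cell normalized hashtag values (see module docstring for the
    transform). All outputs are finite and > 0; a single-hashtag matrix
    self-normalizes to 1.0 everywhere."""
    counts = matrix.counts if isinstance(matrix, HashtagMatrix) else matrix
    if counts.shape[1] < 1:
        raise ValueError("need at least one hashtag feature")
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("negative hashtag counts")
    cp1 = arr + 1.0
    # ratio to the per-cell geometric mean of (count+1), computed as the
    # exponential of centered logs so equal counts give a ratio of exactly 1
    logs = np.log(cp1)
    ratio = np.exp(logs - logs.mean(axis=1, keepdims=True))
    values = np.log2(ratio + 1.0)
    return pd.DataFrame(values, index=counts.index, columns=counts.columns)


def assign_hashtags(
    normalized: pd.DataFrame,
    delta: float = 1.0,
    floor: float = 2.0,
) -> pd.DataFrame:
    """Call each cell assigned / multiplet / ambiguous from normalized values.

    assigned   : top value >= floor and (top - second) >= delta
    multiplet  : top value >= floor but margin < delta
    ambiguous  : top value < floor

    Returns a DataFrame indexed by cell with columns ``call``, ``assigned_to``
    (hashtag feature id, empty unless assigned), ``top``, ``second``,
    ``margin``.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    vals = normalized.to_numpy(dtype=float)
    features = np.asarray(normalized.columns)
    order = np.argsort(-vals, axis=1)
    top_idx = order[:, 0]
    top = vals[np.arange(len(vals)), top_idx]
    if vals.shape[1] > 1:
        second = vals[np.arange(len(vals)), order[:, 1]]
    else:
        second = np.zeros(len(vals))
    margin = top - second
    call = np.where(
        top < floor,
        CALL_AMBIGUOUS,
        np.where(margin >= delta, CALL_ASSIGNED, CALL_MULTIPLET),
    )
    # keep original feature ids (whatever their type) rather than str-coercing
    assigned_to = [
        normalized.columns[i] if c == CALL_ASSIGNED else ""
        for i, c in zip(top_idx, call)
    ]
    return pd.DataFrame(
        {
            "call": call,
            "assigned_to": assigned_to,
            "top": top,
            "second": second,
            "margin": margin,
        },
        index=normalized.index,
    )


def demux_table(result: pd.DataFrame) -> pd.DataFrame:
    """Shape an :func:`assign_hashtags` result for ``write_table(kind="demux")``."""
    out = result.reset_index(names="cell_id")
    return out[["cell_id", "call", "assigned_to", "top", "second", "margin"]]


def qc_filter(
    qc: pd.DataFrame,
    max_counts: float = 30000,
    max_mito: float = 30,
    counts_direction: str = "le",
) -> tuple[list[str], dict[str, int]]:
    """Apply the per-cell QC filter.

    ``qc`` is indexed by cell id with columns ``total_counts`` and
    ``mito_pct``. With the default ``counts_direction="le"`` a cell is kept iff
    total_counts <= max_counts and mito_pct <= max_mito; ``"ge"`` flips the
    count comparison (total_counts >= max_counts) for the alternative reading
    of the threshold. Returns kept cell ids plus per-reason exclusion counts.
    """
    if max_counts <= 0 or max_mito <= 0:
        raise ValueError("thresholds must be positive")
    if counts_direction not in {"le", "ge"}:
        raise ValueError("counts_direction must be 'le' or 'ge'")
    if qc.empty:
        return [], {"counts": 0, "mito": 0}
    mito = qc["mito_pct"].to_numpy(dtype=float)
    if ((mito < 0) | (mito > 100)).any():
        raise ValueError("mito_pct outside [0, 100]")
    counts = qc["total_counts"].to_numpy(dtype=float)
    counts_ok = counts <= max_counts if counts_direction == "le" else counts >= max_counts
    mito_ok = mito <= max_mito
    kept = qc.index[counts_ok & mito_ok].tolist()
    excluded = {
        "counts": int((~counts_ok).sum()),
        "mito": int((counts_ok & ~mito_ok).sum()),
    }
    return kept, excluded
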