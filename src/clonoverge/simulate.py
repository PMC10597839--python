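"""Ground-truth paired TCR repertoire simulation.

The generator emulates the study design the pipeline analyses: GFP+ and GFP-
CD4 T cells sorted from four control and four tumor-bearing mice, pooled into
four samples (condition x GFP compartment), with mouse identity carried by
per-mouse hashtag antibodies. It produces

* paired TRA/TRB rearrangements from an explicit trimming / P-addition /
  N-insertion model over a germline segment set, with full per-event ground
  truth (segments, trims, P and N parts);
* power-law clonal expansion with condition-specific and shared clones;
* planted convergent TCR types: several clonotypes with pairwise-distinct
  nucleotide junctions that translate to the same paired amino-acid
  sequences, using one V/D/J combination;
* per-cell GFP labels with configurable per-clone enrichment, synthetic
  cluster ids, per-mouse hashtag count profiles with planted cross-mouse
  doublets, and per-cell QC metrics;

and exports everything in the formats the pipeline ingests (10x-dialect
contig CSVs, MTX hashtag triplets, label/QC TSVs) next to ``truth/`` tables.

Every sampled quantity flows through a single seeded generator, so a bundle
is fully reproducible from its config.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.io import mmwrite
from scipy.sparse import coo_matrix

from ._seq import revcomp, translate_nt
from .germline import (
    GermlineSet,
    j_junction_region,
    make_fixture_germline,
    save_germline,
    v_junction_region,
)

logger = logging.getLogger(__name__)

#: codon -> amino acid, derived once from the standard-code translator
CODON_TABLE = {
    "".join(c): translate_nt("".join(c)) for c in itertools.product("ACGT", repeat=3)
}

SAMPLES = ("control_GFPneg", "control_GFPpos", "HCC_GFPneg", "HCC_GFPpos")
CONDITIONS = ("control", "HCC")


@dataclass(frozen=True)
class RecombinationEvent:
    """One simulated V(D)J rearrangement with its full ground truth."""

    chain: str
    v_id: str
    j_id: str
    d_id: str | None
    v_trim: int
    j_trim: int
    d5_trim: int | None
    d3_trim: int | None
    p_v: str
    p_d5: str
    p_d3: str
    p_j: str
    n1: str
    n2: str
    v_part: str  # trimmed V junction region (junction prefix)
    d_part: str  # trimmed D fragment ("" for TRA)
    j_part: str  # trimmed J junction region (junction suffix)
    junction_nt: str
    junction_aa: str
    productive: bool

    def __post_init__(self) -> None:
        rebuilt = (
            self.v_part
            + self.p_v
            + self.n1
            + self.p_d5
            + self.d_part
            + self.p_d3
            + self.n2
            + self.p_j
            + self.j_part
        )
        if rebuilt != self.junction_nt:
            raise ValueError("event parts do not reconstruct the junction")

    @property
    def boundaries(self) -> tuple:
        """Ground-truth germline attribution, comparable with
        :attr:`JunctionDecomposition.boundaries`."""
        if self.d_id is None:
            return (len(self.v_part), len(self.j_part), None, None, None, None)
        d_start = len(self.v_part) + len(self.p_v) + len(self.n1) + len(self.p_d5)
        return (
            len(self.v_part),
            len(self.j_part),
            self.d_id,
            d_start,
            self.d5_trim,
            self.d3_trim,
        )

    def n_span(self, which: str) -> range:
        """Junction index range of the N1 or N2 part."""
        n1_start = len(self.v_part) + len(self.p_v)
        if which == "n1":
            return range(n1_start, n1_start + len(self.n1))
        n2_start = (
            n1_start + len(self.n1) + len(self.p_d5) + len(self.d_part) + len(self.p_d3)
        )
        return range(n2_start, n2_start + len(self.n2))


@dataclass
class ConvergenceSpike:
    """A planted convergent TCR type: ``n_variants`` synonymous clonotypes
    together receiving ``target_share`` of the tumor-condition cells."""

    n_variants: int = 5
    target_share: float = 0.05

    def __post_init__(self) -> None:
        if self.n_variants < 2:
            raise ValueError("a convergence spike needs at least 2 variants")
        if not 0 < self.target_share < 1:
            raise ValueError("target_share must be in (0, 1)")


@dataclass
class SimulationConfig:
    """Study-level generator settings.

    Defaults emulate the analysed study's scale: 50 clones across 4 control +
    4 tumor-bearing mice (250 cells per mouse, ~2,000 cells), one planted
    5-variant convergent TCR type concentrated in the tumor condition, four
    hashtags per pooled sample and a 5% cross-mouse doublet rate.
    """

    seed: int = 0
    n_clones: int = 50
    clone_alpha: float = 1.2  # power-law exponent of the rank-size law
    shared_clone_fraction: float = 0.3
    n_mice_per_condition: int = 4
    n_cells_per_mouse: int = 250
    # recombination model
    trim_continuation: float = 0.05  # truncated-geometric continuation prob
    max_trim: int = 4
    lambda_n: float = 4.0  # Poisson mean of each N-insertion length
    p_palindrome: float = 0.5  # P-addition prob at each untrimmed end
    max_p: int = 2
    max_attempts: int = 1000  # productive-rejection bound
    # planted convergence
    spikes: list[ConvergenceSpike] = field(default_factory=lambda: [ConvergenceSpike()])
    # labels
    gfp_prob_background: float = 0.15
    gfp_prob_expanded: float = 0.85  # spiked clones in the tumor condition
    clusters: tuple = ("C1", "C2", "C4", "C7", "C9", "C10")
    cluster_probs: tuple = (0.25, 0.15, 0.1, 0.2, 0.2, 0.1)
    spike_cluster: str = "C3"
    # hashtags
    hashtag_signal_mean: float = 200.0
    hashtag_background_mean: float = 2.0
    hashtag_dispersion: float = 10.0
    doublet_rate: float = 0.05
    # QC metric laws
    qc_counts_meanlog: float = 9.4  # lognormal, median ~12k counts
    qc_counts_sdlog: float = 0.5
    qc_mito_alpha: float = 2.0  # Beta * 100 -> percent
    qc_mito_beta: float = 20.0
    # I/O extras
    nonproductive_contig_rate: float = 0.05


def _sample_trim(rng: np.random.Generator, continuation: float, max_trim: int) -> int:
    """Truncated geometric trim length: P(t) proportional to continuation**t
    on 0..max_trim."""
    weights = np.array([continuation**t for t in range(max_trim + 1)])
    return int(rng.choice(max_trim + 1, p=weights / weights.sum()))


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _maybe_p(rng: np.random.Generator, end: str, cfg: SimulationConfig, *, five_prime: bool) -> str:
    """P nucleotides at one untrimmed germline end (or '')."""
    if rng.random() >= cfg.p_palindrome:
        return ""
    k = int(rng.integers(1, cfg.max_p + 1))
    k = min(k, len(end))
    # hairpin opening copies the terminal nucleotides in reverse complement
    return revcomp(end[:k]) if five_prime else revcomp(end[-k:])


def simulate_recombination(
    germline: GermlineSet,
    chain: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    productive_only: bool = True,
) -> RecombinationEvent:
    """Sample one rearrangement: segment choice, exonuclease trimming,
    P additions at untrimmed ends, Poisson N insertions.

    With ``productive_only`` (default) the event is rejection-sampled until
    its junction is in frame and stop-free, up to ``config.max_attempts``.
    """
    v_segs = germline.by_class(chain, "V")
    j_segs = germline.by_class(chain, "J")
    d_segs = germline.by_class(chain, "D") if chain == "TRB" else []
    if not v_segs or not j_segs:
        raise ValueError(f"germline lacks V or J segments for {chain}")
    if chain == "TRB" and not d_segs:
        raise ValueError("germline lacks TRB D segments")

    for _ in range(config.max_attempts):
        v = v_segs[int(rng.integers(len(v_segs)))]
        j = j_segs[int(rng.integers(len(j_segs)))]
        v_region = v_junction_region(v)
        j_region = j_junction_region(j)
        v_trim = min(_sample_trim(rng, config.trim_continuation, config.max_trim),
                     len(v_region) - 3)
        j_trim = min(_sample_trim(rng, config.trim_continuation, config.max_trim),
                     len(j_region) - 3)
        v_part = v_region[: len(v_region) - v_trim]
        j_part = j_region[j_trim:]
        p_v = _maybe_p(rng, v_region, config, five_prime=False) if v_trim == 0 else ""
        p_j = _maybe_p(rng, j_region, config, five_prime=True) if j_trim == 0 else ""
        n1 = _random_nt(rng, int(rng.poisson(config.lambda_n)))
        if chain == "TRB":
            d = d_segs[int(rng.integers(len(d_segs)))]
            d5_trim = _sample_trim(rng, config.trim_continuation, config.max_trim)
            d3_trim = _sample_trim(rng, config.trim_continuation, config.max_trim)
            d_part = d.seq_nt[d5_trim : len(d.seq_nt) - d3_trim]
            p_d5 = _maybe_p(rng, d.seq_nt, config, five_prime=True) if d5_trim == 0 else ""
            p_d3 = _maybe_p(rng, d.seq_nt, config, five_prime=False) if d3_trim == 0 else ""
            n2 = _random_nt(rng, int(rng.poisson(config.lambda_n)))
            d_id = d.id
        else:
            d_id, d5_trim, d3_trim = None, None, None
            d_part, p_d5, p_d3, n2 = "", "", "", ""
        junction = v_part + p_v + n1 + p_d5 + d_part + p_d3 + n2 + p_j + j_part
        in_frame = len(junction) % 3 == 0
        aa = translate_nt(junction) if in_frame else ""
        productive = in_frame and "*" not in aa
        if productive_only and not productive:
            continue
        return RecombinationEvent(
            chain=chain,
            v_id=v.id,
            j_id=j.id,
            d_id=d_id,
            v_trim=v_trim,
            j_trim=j_trim,
            d5_trim=d5_trim,
            d3_trim=d3_trim,
            p_v=p_v,
            p_d5=p_d5,
            p_d3=p_d3,
            p_j=p_j,
            n1=n1,
            n2=n2,
            v_part=v_part,
            d_part=d_part,
            j_part=j_part,
            junction_nt=junction,
            junction_aa=aa,
            productive=productive,
        )
    raise RuntimeError(
        f"no productive {chain} rearrangement in {config.max_attempts} attempts; "
        "the configuration is pathological"
    )


# ---------------------------------------------------------------------------
# planted convergent types


def _synonymous_codon_choices(event: RecombinationEvent) -> list[list[str]]:
    """Per-codon nucleotide choices that keep the event's amino acids fixed.

    Only positions inside the N1/N2 parts are free (germline and P parts stay
    as sampled); for each codon, all settings of its free positions that
    preserve the encoded amino acid are enumerated. The product of the list
    sizes is the number of distinct synonymous junction variants reachable.
    """
    free = set(event.n_span("n1")) | set(event.n_span("n2"))
    junction = event.junction_nt
    choices: list[list[str]] = []
    for i in range(0, len(junction), 3):
        codon = junction[i : i + 3]
        free_here = [k for k in range(3) if i + k in free]
        if not free_here:
            choices.append([codon])
            continue
        target = CODON_TABLE[codon]
        opts = []
        for combo in itertools.product("ACGT", repeat=len(free_here)):
            cand = list(codon)
            for k, nt in zip(free_here, combo):
                cand[k] = nt
            cand_codon = "".join(cand)
            if CODON_TABLE[cand_codon] == target:
                opts.append(cand_codon)
        choices.append(opts)
    return choices


def _variant_from_choices(
    event: RecombinationEvent,
    choices: Sequence[Sequence[str]],
    rng: np.random.Generator,
) -> RecombinationEvent:
    junction = "".join(opts[int(rng.integers(len(opts)))] for opts in choices)
    n1 = "".join(junction[i] for i in event.n_span("n1"))
    n2 = "".join(junction[i] for i in event.n_span("n2"))
    return replace(event, junction_nt=junction, n1=n1, n2=n2)


def spike_convergent_type(
    germline: GermlineSet,
    n_variants: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple[RecombinationEvent, RecombinationEvent]]:
    """Generate ``n_variants`` paired rearrangements sharing identical paired
    amino-acid junctions but pairwise-distinct nucleotide junctions.

    All variants use the same V/D/J combination on both chains. The TRA event
    is shared; TRB variants are drawn uniformly from the set of N-region
    resamplings consistent with the reference amino-acid sequence (exact
    conditional sampling — whole-event rejection until amino acids coincide
    would be astronomically slow). Raises when the synonymous support is too
    small, which longer N insertions (larger ``lambda_n``) enlarge.
    """
    if n_variants < 2:
        raise ValueError("n_variants must be >= 2")
    for _ in range(200):
        tra = simulate_recombination(germline, "TRA", config, rng)
        trb = simulate_recombination(germline, "TRB", config, rng)
        choices = _synonymous_codon_choices(trb)
        support = int(np.prod([len(c) for c in choices]))
        if support >= n_variants:
            break
    else:
        raise RuntimeError(
            "could not find a reference rearrangement with enough synonymous "
            "variants; increase lambda_n"
        )
    variants = [trb]
    seen = {trb.junction_nt}
    attempts = 0
    while len(variants) < n_variants:
        attempts += 1
        if attempts > 10000 * n_variants:
            raise RuntimeError("synonymous variant sampling stalled; increase lambda_n")
        cand = _variant_from_choices(trb, choices, rng)
        if cand.junction_nt not in seen:
            seen.add(cand.junction_nt)
            variants.append(cand)
    return [(tra, v) for v in variants]


# ---------------------------------------------------------------------------
# study-level simulation


@dataclass
class SimClone:
    clone_id: str
    tra: RecombinationEvent
    trb: RecombinationEvent
    conditions: tuple
    cluster: str
    gfp_prob: dict
    spike_id: str | None = None


@dataclass
class SimCell:
    barcode: str
    sample_id: str
    mouse_id: str
    mouse_index: int  # hashtag feature index within the pooled sample
    clone: SimClone
    condition: str
    gfp_status: str
    is_doublet: bool = False
    secondary_clone: SimClone | None = None
    secondary_mouse_index: int | None = None
    secondary_mouse_id: str | None = None

    @property
    def cell_id(self) -> str:
        return f"{self.sample_id}:{self.barcode}"


@dataclass
class SimulationBundle:
    """In-memory truth plus the paths of everything exported."""

    out_dir: Path
    config: SimulationConfig
    germline: GermlineSet
    clones: list[SimClone]
    cells: list[SimCell]
    sample_ids: tuple = SAMPLES

    def contig_csv(self, sample_id: str) -> Path:
        return self.out_dir / f"{sample_id}_filtered_contig_annotations.csv"

    def hashtag_dir(self, sample_id: str) -> Path:
        return self.out_dir / "hashtags" / sample_id

    @property
    def labels_path(self) -> Path:
        return self.out_dir / "labels.tsv"

    @property
    def qc_path(self) -> Path:
        return self.out_dir / "qc.tsv"

    def truth_partition(self, *, singlets_only: bool = True) -> dict[str, str]:
        """cell id -> true clone id (doublets resolve to their primary clone)."""
        return {
            c.cell_id: c.clone.clone_id
            for c in self.cells
            if not (singlets_only and c.is_doublet)
        }

    def spike_clones(self) -> list[SimClone]:
        return [c for c in self.clones if c.spike_id is not None]


def clone_weights(n: int, alpha: float) -> np.ndarray:
    """Normalized rank-size power-law weights: w_r proportional to r**-alpha."""
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks**-alpha
    return w / w.sum()


def _unique_barcode(rng: np.random.Generator, used: set) -> str:
    while True:
        bc = _random_nt(rng, 14) + "-1"
        if bc not in used:
            used.add(bc)
            return bc


def _nb(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_hashtag_profile(
    rng: np.random.Generator,
    mouse_index: int,
    n_features: int,
    config: SimulationConfig,
) -> np.ndarray:
    """One cell's hashtag counts: negative-binomial signal on its own mouse's
    feature, low negative-binomial background elsewhere."""
    counts = _nb(rng, config.hashtag_background_mean, config.hashtag_dispersion, n_features)
    counts[mouse_index] = _nb(rng, config.hashtag_signal_mean, config.hashtag_dispersion, 1)[0]
    return counts


def simulate_hashtag_matrix(
    n_singlets: int,
    n_doublets: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    *,
    n_features: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standalone hashtag-count simulation with known singlet/doublet truth.

    Returns ``(counts, truth)``: counts is cells x hashtags; truth carries
    ``kind`` ("singlet"/"doublet") and, for singlets, the true hashtag
    feature. Doublets combine two *different* mice — same-mouse doublets are
    invisible to hashing and are not planted.
    """
    k = n_features or config.n_mice_per_condition
    features = [f"hashtag_{i + 1}" for i in range(k)]
    rows, truth_rows, index = [], [], []
    for i in range(n_singlets):
        m = int(rng.integers(k))
        rows.append(simulate_hashtag_profile(rng, m, k, config))
        index.append(f"cell{i + 1:05d}")
        truth_rows.append({"kind": "singlet", "hashtag": features[m]})
    for i in range(n_doublets):
        m1 = int(rng.integers(k))
        m2 = int((m1 + 1 + rng.integers(k - 1)) % k)
        prof = simulate_hashtag_profile(rng, m1, k, config) + simulate_hashtag_profile(
            rng, m2, k, config
        )
        rows.append(prof)
        index.append(f"dbl{i + 1:05d}")
        truth_rows.append({"kind": "doublet", "hashtag": ""})
    counts = pd.DataFrame(np.array(rows, dtype=int), index=index, columns=features)
    truth = pd.DataFrame(truth_rows, index=index)
    return counts, truth


def _generate_clones(
    germline: GermlineSet, config: SimulationConfig, rng: np.random.Generator
) -> list[SimClone]:
    clones: list[SimClone] = []
    seen_nt: set = set()
    seen_aa: set = set()
    for s, spike in enumerate(config.spikes, start=1):
        pairs = spike_convergent_type(germline, spike.n_variants, config, rng)
        aa_key = (pairs[0][0].junction_aa, pairs[0][1].junction_aa)
        seen_aa.add(aa_key)
        for v, (tra, trb) in enumerate(pairs, start=1):
            seen_nt.add((tra.junction_nt, trb.junction_nt))
            clones.append(
                SimClone(
                    clone_id=f"spike{s}_v{v}",
                    tra=tra,
                    trb=trb,
                    conditions=("HCC",),
                    cluster=config.spike_cluster,
                    gfp_prob={"HCC": config.gfp_prob_expanded},
                    spike_id=f"spike{s}",
                )
            )
    for i in range(1, config.n_clones + 1):
        for _ in range(config.max_attempts):
            tra = simulate_recombination(germline, "TRA", config, rng)
            trb = simulate_recombination(germline, "TRB", config, rng)
            nt_key = (tra.junction_nt, trb.junction_nt)
            aa_key = (tra.junction_aa, trb.junction_aa)
            if nt_key not in seen_nt and aa_key not in seen_aa:
                seen_nt.add(nt_key)
                seen_aa.add(aa_key)
                break
        else:
            raise RuntimeError("could not draw a distinct background clone")
        r = rng.random()
        if r < config.shared_clone_fraction:
            conds: tuple = CONDITIONS
        elif r < config.shared_clone_fraction + (1 - config.shared_clone_fraction) / 2:
            conds = ("control",)
        else:
            conds = ("HCC",)
        cluster = str(rng.choice(config.clusters, p=config.cluster_probs))
        clones.append(
            SimClone(
                clone_id=f"clone{i:04d}",
                tra=tra,
                trb=trb,
                conditions=conds,
                cluster=cluster,
                gfp_prob={c: config.gfp_prob_background for c in conds},
                spike_id=None,
            )
        )
    return clones


def _condition_weights(
    clones: Sequence[SimClone], condition: str, config: SimulationConfig
) -> np.ndarray:
    """Per-clone sampling weights within one condition."""
    idx = [i for i, c in enumerate(clones) if condition in c.conditions]
    weights = np.zeros(len(clones))
    spike_total = 0.0
    if condition == "HCC":
        for s, spike in enumerate(config.spikes, start=1):
            sid = f"spike{s}"
            members = [i for i in idx if clones[i].spike_id == sid]
            for i in members:
                weights[i] = spike.target_share / len(members)
            spike_total += spike.target_share
    background = [i for i in idx if clones[i].spike_id is None]
    w = clone_weights(len(background), config.clone_alpha) * (1.0 - spike_total)
    for rank, i in enumerate(background):
        weights[i] = w[rank]
    return weights / weights.sum()


def _simulate_cells(
    clones: list[SimClone], config: SimulationConfig, rng: np.random.Generator
) -> list[SimCell]:
    cells: list[SimCell] = []
    used_barcodes: dict[str, set] = {s: set() for s in SAMPLES}
    for condition in CONDITIONS:
        weights = _condition_weights(clones, condition, config)
        cond_cells: list[SimCell] = []
        for m in range(config.n_mice_per_condition):
            mouse_id = f"{condition}_m{m + 1}"
            draws = rng.choice(len(clones), size=config.n_cells_per_mouse, p=weights)
            for ci in draws:
                clone = clones[int(ci)]
                gfp = rng.random() < clone.gfp_prob.get(condition, 0.0)
                gfp_status = "GFP_pos" if gfp else "GFP_neg"
                sample_id = f"{condition}_{'GFPpos' if gfp else 'GFPneg'}"
                cond_cells.append(
                    SimCell(
                        barcode=_unique_barcode(rng, used_barcodes[sample_id]),
                        sample_id=sample_id,
                        mouse_id=mouse_id,
                        mouse_index=m,
                        clone=clone,
                        condition=condition,
                        gfp_status=gfp_status,
                    )
                )
        if condition == "HCC":
            # guarantee every planted variant is observed at least once
            present = {c.clone.clone_id for c in cond_cells}
            replaceable = [c for c in cond_cells if c.clone.spike_id is None]
            for clone in clones:
                if clone.spike_id is not None and clone.clone_id not in present:
                    victim = replaceable.pop()
                    victim.clone = clone
        cells.extend(cond_cells)
    # plant cross-mouse doublets within each pooled sample
    for sample_id in SAMPLES:
        sample_cells = [c for c in cells if c.sample_id == sample_id]
        n_doublets = int(round(config.doublet_rate * len(sample_cells)))
        order = rng.permutation(len(sample_cells))
        made = 0
        absorbed: set[int] = set()
        for i, j in zip(order[0::2], order[1::2]):
            if made >= n_doublets:
                break
            a, b = sample_cells[int(i)], sample_cells[int(j)]
            if a.mouse_index == b.mouse_index:
                continue
            a.is_doublet = True
            a.secondary_clone = b.clone
            a.secondary_mouse_index = b.mouse_index
            a.secondary_mouse_id = b.mouse_id
            absorbed.add(id(b))
            made += 1
        if absorbed:
            cells = [c for c in cells if id(c) not in absorbed]
    return cells


def _contig_rows(
    cell: SimCell,
    germline: GermlineSet,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[dict]:
    """10x-dialect contig CSV rows for one exported barcode."""

    def rows_for(clone: SimClone, umi_lo: int, umi_hi: int) -> list[dict]:
        out = []
        for event in (clone.tra, clone.trb):
            umis = int(rng.integers(umi_lo, umi_hi))
            out.append(
                {
                    "barcode": cell.barcode,
                    "is_cell": "True",
                    "high_confidence": "True",
                    "chain": event.chain,
                    "v_gene": event.v_id,
                    "d_gene": event.d_id or "",
                    "j_gene": event.j_id,
                    "cdr3": event.junction_aa,
                    "cdr3_nt": event.junction_nt,
                    "reads": umis * int(rng.integers(5, 20)),
                    "umis": umis,
                    "productive": "True",
                }
            )
        return out

    rows = rows_for(cell.clone, 3, 15)
    if cell.is_doublet and cell.secondary_clone is not None:
        # the secondary cell's chains are recovered at strictly lower depth
        rows.extend(rows_for(cell.secondary_clone, 1, 3))
    if rng.random() < config.nonproductive_contig_rate:
        event = simulate_recombination(germline, "TRA", config, rng, productive_only=False)
        rows.append(
            {
                "barcode": cell.barcode,
                "is_cell": "True",
                "high_confidence": "False",
                "chain": "TRA",
                "v_gene": event.v_id,
                "d_gene": "",
                "j_gene": event.j_id,
                "cdr3": "",
                "cdr3_nt": event.junction_nt,
                "reads": 5,
                "umis": 1,
                "productive": "None",
            }
        )
    return rows


def simulate_study(config: SimulationConfig, out_dir: str | Path) -> SimulationBundle:
    """Run the full study-level simulation and export the ingestible bundle.

    Writes, under ``out_dir``: one ``<sample>_filtered_contig_annotations.csv``
    and one ``hashtags/<sample>/`` MTX triplet per pooled sample,
    ``labels.tsv``, ``qc.tsv``, the germline reference under ``germline/``,
    and ground-truth tables under ``truth/``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    germline = make_fixture_germline(int(rng.integers(2**31)))
    clones = _generate_clones(germline, config, rng)
    cells = _simulate_cells(clones, config, rng)

    # germline reference
    gdir = out_dir / "germline"
    gdir.mkdir(exist_ok=True)
    save_germline(germline, gdir / "segments.fasta", gdir / "segments.tsv")

    # contig CSVs (per pooled sample)
    for sample_id in SAMPLES:
        rows: list[dict] = []
        for cell in cells:
            if cell.sample_id == sample_id:
                rows.extend(_contig_rows(cell, germline, config, rng))
        pd.DataFrame(
            rows,
            columns=[
                "barcode",
                "is_cell",
                "high_confidence",
                "chain",
                "v_gene",
                "d_gene",
                "j_gene",
                "cdr3",
                "cdr3_nt",
                "reads",
                "umis",
                "productive",
            ],
        ).to_csv(out_dir / f"{sample_id}_filtered_contig_annotations.csv", index=False)

    # hashtag MTX triplets
    n_features = config.n_mice_per_condition
    features = [f"hashtag_{i + 1}" for i in range(n_features)]
    for sample_id in SAMPLES:
        sample_cells = [c for c in cells if c.sample_id == sample_id]
        profiles = []
        for cell in sample_cells:
            prof = simulate_hashtag_profile(rng, cell.mouse_index, n_features, config)
            if cell.is_doublet and cell.secondary_mouse_index is not None:
                prof = prof + simulate_hashtag_profile(
                    rng, cell.secondary_mouse_index, n_features, config
                )
            profiles.append(prof)
        mat = np.array(profiles, dtype=int).T if profiles else np.zeros((n_features, 0), int)
        hdir = out_dir / "hashtags" / sample_id
        hdir.mkdir(parents=True, exist_ok=True)
        mmwrite(str(hdir / "matrix.mtx"), coo_matrix(mat))
        pd.Series(features).to_csv(hdir / "features.tsv", sep="\t", index=False, header=False)
        pd.Series([c.barcode for c in sample_cells]).to_csv(
            hdir / "barcodes.tsv", sep="\t", index=False, header=False
        )

    # labels and QC
    labels = pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "barcode": c.barcode,
                "condition": c.condition,
                "gfp_status": c.gfp_status,
                "cluster": c.clone.cluster,
            }
            for c in cells
        ]
    )
    labels.to_csv(out_dir / "labels.tsv", sep="\t", index=False)
    qc = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "total_counts": np.round(
                rng.lognormal(config.qc_counts_meanlog, config.qc_counts_sdlog, len(cells))
            ).astype(int),
            "mito_pct": 100.0 * rng.beta(config.qc_mito_alpha, config.qc_mito_beta, len(cells)),
        }
    )
    qc.to_csv(out_dir / "qc.tsv", sep="\t", index=False)

    # truth tables
    tdir = out_dir / "truth"
    tdir.mkdir(exist_ok=True)
    pd.DataFrame(
        [
            {
                "cell_id": c.cell_id,
                "sample_id": c.sample_id,
                "barcode": c.barcode,
                "mouse_id": c.mouse_id,
                "clone_id": c.clone.clone_id,
                "is_doublet": c.is_doublet,
                "secondary_clone_id": c.secondary_clone.clone_id if c.secondary_clone else "",
                "secondary_mouse_id": c.secondary_mouse_id or "",
                "condition": c.condition,
                "gfp_status": c.gfp_status,
                "cluster": c.clone.cluster,
            }
            for c in cells
        ]
    ).to_csv(tdir / "cells.tsv", sep="\t", index=False)
    event_rows = []
    for clone in clones:
        for event in (clone.tra, clone.trb):
            event_rows.append(
                {
                    "clone_id": clone.clone_id,
                    "spike_id": clone.spike_id or "",
                    "conditions": "+".join(clone.conditions),
                    "cluster": clone.cluster,
                    "chain": event.chain,
                    "v_id": event.v_id,
                    "d_id": event.d_id or "",
                    "j_id": event.j_id,
                    "v_trim": event.v_trim,
                    "d5_trim": "" if event.d5_trim is None else event.d5_trim,
                    "d3_trim": "" if event.d3_trim is None else event.d3_trim,
                    "j_trim": event.j_trim,
                    "p_v": event.p_v,
                    "p_d5": event.p_d5,
                    "p_d3": event.p_d3,
                    "p_j": event.p_j,
                    "n1": event.n1,
                    "n2": event.n2,
                    "junction_nt": event.junction_nt,
                    "junction_aa": event.junction_aa,
                }
            )
    pd.DataFrame(event_rows).to_csv(tdir / "events.tsv", sep="\t", index=False)

    return SimulationBundle(
        out_dir=out_dir,
        config=config,
        germline=germline,
        clones=clones,
        cells=cells,
    )
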