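"""V(D)J junction decomposition into germline and non-templated parts.

Each junction nucleotide sequence is partitioned, left to right, into

    V | P_V | N1 | P_D5 | D | P_D3 | N2 | P_J | J

where the V part is germline V sequence (possibly 3'-trimmed), the J part is
germline J sequence (possibly 5'-trimmed), D (TRB only) is a contiguous
fragment of a germline D segment, P parts are short palindromic nucleotides
(the reverse complement of the adjacent *untrimmed* germline terminus, created
during hairpin opening) and N1/N2 are non-templated nucleotides inserted by
TdT. Every part may be empty; the concatenation of the parts always equals
the input junction exactly.

The decomposition is the deterministic maximal-attribution one: the V part is
the longest junction prefix matching the germline V junction region, then the
J part is the longest remaining suffix matching the germline J junction
region (V takes precedence over J when they could overlap), then D is the
longest contiguous exact match of at least ``min_d_match`` nucleotides to any
candidate D segment (ties: 5'-most placement in the junction, then candidate
id, then 5'-most position within the D segment), and finally P parts are
assigned greedily (longest first, up to ``max_p`` per end) wherever the
adjacent germline end is untrimmed. Probabilistic inference over alternative
recombination scenarios is out of scope; when several scenarios tie, the
stated precedence picks one reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from ._seq import check_nt, revcomp
from .germline import GermlineSegment, j_junction_region, v_junction_region

PART_ORDER = ("V", "P_V", "N1", "P_D5", "D", "P_D3", "N2", "P_J", "J")


@dataclass(frozen=True)
class Part:
    """One labeled slice of a junction."""

    kind: str
    seq: str
    germline_id: str | None = None
    germline_start: int | None = None  # coords within the segment's seq_nt
    germline_end: int | None = None


@dataclass
class JunctionDecomposition:
    """Ordered partition of one junction with trim lengths and D assignment."""

    junction_nt: str
    chain: str
    parts: list[Part]
    v_trim: int
    j_trim: int
    d5_trim: int | None = None
    d3_trim: int | None = None
    d_assigned: bool = False
    d_id: str | None = None
    no_germline_v: bool = False
    no_germline_j: bool = False

    def __post_init__(self) -> None:
        if "".join(p.seq for p in self.parts) != self.junction_nt:
            raise ValueError("decomposition parts do not reconstruct the junction")
        kinds = [p.kind for p in self.parts if p.seq]
        order = [k for k in PART_ORDER if k in kinds]
        if kinds != order:
            raise ValueError(f"parts out of canonical order: {kinds}")
        if self.chain == "TRA" and any(
            p.kind in {"P_D5", "D", "P_D3", "N2"} and p.seq for p in self.parts
        ):
            raise ValueError("TRA decompositions cannot contain a D block")

    def part(self, kind: str) -> str:
        """Sequence of the (single) part of ``kind``; empty string if absent."""
        for p in self.parts:
            if p.kind == kind:
                return p.seq
        return ""

    @property
    def boundaries(self) -> tuple:
        """(v_len, j_len, d_id, d_start_in_junction, d5_trim, d3_trim) —
        the germline attribution compared against simulator ground truth."""
        v_len = len(self.part("V"))
        j_len = len(self.part("J"))
        if not self.d_assigned:
            return (v_len, j_len, None, None, None, None)
        d_start = 0
        for p in self.parts:
            if p.kind == "D":
                break
            d_start += len(p.seq)
        return (v_len, j_len, self.d_id, d_start, self.d5_trim, self.d3_trim)


def _longest_common_prefix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(n):
        if a[i] != b[i]:
            return i
    return n


def _longest_common_suffix(a: str, b: str) -> int:
    n = min(len(a), len(b))
    for i in range(1, n + 1):
        if a[-i] != b[-i]:
            return i - 1
    return n


def _greedy_p(segment_end: str, candidate: str, max_p: int, *, prefix: bool) -> str:
    """Longest P run (<= max_p) at one untrimmed germline end.

    ``prefix=True`` checks the start of ``candidate`` against the reverse
    complement of the *tail* of ``segment_end`` (V-like / D-3'-like ends read
    the other way for J-like / D-5'-like starts).
    """
    for k in range(min(max_p, len(segment_end), len(candidate)), 0, -1):
        if prefix:
            p = revcomp(segment_end[-k:])
            if candidate.startswith(p):
                return p
        else:
            p = revcomp(segment_end[:k])
            if candidate.endswith(p):
                return p
    return ""


def _find_d_match(
    middle: str,
    d_candidates: Sequence[GermlineSegment],
    min_d_match: int,
) -> tuple[str, int, int, int] | None:
    """Longest contiguous exact match of ``middle`` to any D segment.

    Returns (d_id, start_in_middle, length, start_in_d) or None. Ties broken
    by 5'-most start in the junction middle, then candidate id, then 5'-most
    position within the D segment — enforced by the loop order.
    """
    if not middle or not d_candidates:
        return None
    cands = sorted(d_candidates, key=lambda s: s.id)
    max_len = min(len(middle), max(len(c.seq_nt) for c in cands))
    for length in range(max_len, min_d_match - 1, -1):
        for start in range(len(middle) - length + 1):
            window = middle[start : start + length]
            for cand in cands:
                pos = cand.seq_nt.find(window)
                if pos >= 0:
                    return (cand.id, start, length, pos)
    return None


def decompose_junction(
    junction_nt: str,
    v_seg: GermlineSegment,
    j_seg: GermlineSegment,
    d_candidates: Sequence[GermlineSegment] = (),
    *,
    max_p: int = 2,
    min_d_match: int = 3,
    convention: str = "junction",
) -> JunctionDecomposition:
    """Decompose one junction against its called germline segments.

    ``convention`` is ``"junction"`` (anchor-inclusive, default) or
    ``"cdr3"`` (anchors stripped from the input, so the anchor codons are
    also stripped from the germline regions before matching).
    """
    junction = check_nt(junction_nt, what="junction")
    if len(junction) < 6:
        raise ValueError(f"junction shorter than two codons: {junction!r}")
    if v_seg.chain != j_seg.chain:
        raise ValueError("V and J segments come from different chains")
    chain = v_seg.chain
    if chain == "TRA" and d_candidates:
        raise ValueError("TRA junctions take no D candidates")

    v_region = v_junction_region(v_seg)
    j_region = j_junction_region(j_seg)
    if convention == "cdr3":
        v_region = v_region[3:]
        j_region = j_region[:-3]
    elif convention != "junction":
        raise ValueError(f"unknown convention {convention!r}")

    v_len = _longest_common_prefix(junction, v_region)
    j_len = _longest_common_suffix(junction[v_len:], j_region)
    v_trim = len(v_region) - v_len
    j_trim = len(j_region) - j_len
    middle = junction[v_len : len(junction) - j_len]

    parts: list[Part] = [
        Part(
            "V",
            junction[:v_len],
            v_seg.id,
            v_seg.anchor_offset,
            (v_seg.anchor_offset or 0) + v_len,
        )
    ]

    # D is attributed on the full middle segment first; P parts are assigned
    # afterwards inside the gaps D leaves, so palindromic labeling can never
    # shorten the maximal germline D match.
    d5_trim = d3_trim = None
    d_id = None
    d_assigned = False
    if chain == "TRB" and d_candidates:
        hit = _find_d_match(middle, list(d_candidates), min_d_match)
    else:
        hit = None

    if hit is not None:
        d_id, d_start, d_len, pos_in_d = hit
        d_seq_full = next(c for c in d_candidates if c.id == d_id).seq_nt
        d5_trim = pos_in_d
        d3_trim = len(d_seq_full) - pos_in_d - d_len
        d_assigned = True
        left = middle[:d_start]
        d_match = middle[d_start : d_start + d_len]
        right = middle[d_start + d_len :]
        p_v = _greedy_p(v_region, left, max_p, prefix=True) if v_trim == 0 and v_len else ""
        left = left[len(p_v) :]
        p_d5 = _greedy_p(d_seq_full, left, max_p, prefix=False) if d5_trim == 0 else ""
        n1 = left[: len(left) - len(p_d5)] if p_d5 else left
        p_j = _greedy_p(j_region, right, max_p, prefix=False) if j_trim == 0 and j_len else ""
        right = right[: len(right) - len(p_j)] if p_j else right
        p_d3 = _greedy_p(d_seq_full, right, max_p, prefix=True) if d3_trim == 0 else ""
        n2 = right[len(p_d3) :]
        if p_v:
            parts.append(Part("P_V", p_v))
        if n1:
            parts.append(Part("N1", n1))
        if p_d5:
            parts.append(Part("P_D5", p_d5))
        parts.append(Part("D", d_match, d_id, d5_trim, d5_trim + d_len))
        if p_d3:
            parts.append(Part("P_D3", p_d3))
        if n2:
            parts.append(Part("N2", n2))
        if p_j:
            parts.append(Part("P_J", p_j))
    else:
        p_v = _greedy_p(v_region, middle, max_p, prefix=True) if v_trim == 0 and v_len else ""
        rest = middle[len(p_v) :]
        p_j = _greedy_p(j_region, rest, max_p, prefix=False) if j_trim == 0 and j_len else ""
        core = rest[: len(rest) - len(p_j)] if p_j else rest
        if p_v:
            parts.append(Part("P_V", p_v))
        if core:
            parts.append(Part("N1", core))
        if p_j:
            parts.append(Part("P_J", p_j))

    parts.append(
        Part(
            "J",
            junction[len(junction) - j_len :] if j_len else "",
            j_seg.id,
            j_trim,
            j_trim + j_len,
        )
    )

    return JunctionDecomposition(
        junction_nt=junction,
        chain=chain,
        parts=[p for p in parts if p.seq or p.kind in {"V", "J"}],
        v_trim=v_trim,
        j_trim=j_trim,
        d5_trim=d5_trim,
        d3_trim=d3_trim,
        d_assigned=d_assigned,
        d_id=d_id,
        no_germline_v=v_len == 0,
        no_germline_j=j_len == 0,
    )


@dataclass
class MismatchProfile:
    """Per-chain nucleotide mismatches of a TCR type's synonymous clonotypes
    against a reference clonotype (the largest member; ties by id)."""

    tcr_type_id: str
    reference_id: str
    mismatches: dict[str, dict[str, list[int]]] = field(default_factory=dict)
    # chain -> clonotype_id -> 0-based mismatch positions within the junction


def compare_synonymous(tcr_type, clonotypes: Iterable) -> MismatchProfile:
    """Positional nucleotide differences among one TCR type's clonotypes.

    ``clonotypes`` are the member :class:`~clonoverge.clonotyping.Clonotype`
    objects. All members of a TCR type translate to the same amino acids, so
    junctions per chain necessarily have equal length; unequal lengths signal
    an upstream invariant breach and raise.
    """
    members = sorted(clonotypes, key=lambda ct: (-ct.size, ct.clonotype_id))
    if not members:
        raise ValueError("no member clonotypes")
    ref = members[0]
    profile = MismatchProfile(
        tcr_type_id=tcr_type.tcr_type_id, reference_id=ref.clonotype_id
    )
    for chain, attr in (("TRA", "tra_junction_nt"), ("TRB", "trb_junction_nt")):
        ref_nt = getattr(ref, attr)
        chain_map: dict[str, list[int]] = {}
        for ct in members:
            nt = getattr(ct, attr)
            if len(nt) != len(ref_nt):
                raise ValueError(
                    f"{tcr_type.tcr_type_id}/{chain}: junction length mismatch between "
                    f"{ref.clonotype_id} and {ct.clonotype_id}"
                )
            chain_map[ct.clonotype_id] = [
                i for i, (a, b) in enumerate(zip(nt, ref_nt)) if a != b
            ]
        profile.mismatches[chain] = chain_map
    return profile


def is_synonymous(c1, c2) -> bool:
    """True iff two clonotypes share paired amino-acid keys but differ at the
    nucleotide level (the convergent-recombination relation)."""
    aa_equal = (
        c1.tra_junction_aa == c2.tra_junction_aa
        and c1.trb_junction_aa == c2.trb_junction_aa
    )
    nt_equal = (
        c1.tra_junction_nt == c2.tra_junction_nt
        and c1.trb_junction_nt == c2.trb_junction_nt
    )
    return aa_equal and not nt_equal
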