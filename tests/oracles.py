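"""Independent oracles used by the test suite.

Each oracle re-derives an expected result by a different route than the
implementation under test: a literal codon table for translation, full
enumeration over germline attributions for junction decomposition, and full
hypergeometric enumeration for the 2x2 exact test.
"""

from __future__ import annotations

from math import comb

# Literal standard genetic code (independent of the Bio.Seq-backed translator).
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_oracle(seq: str) -> str:
    assert len(seq) % 3 == 0
    return "".join(CODON_TABLE[seq[i : i + 3]] for i in range(0, len(seq), 3))


def enumerate_attributions(
    junction: str,
    v_region: str,
    j_region: str,
    d_seqs: dict[str, str],
    min_d_match: int = 3,
):
    """All germline attributions of a junction, with the optimal set.

    An attribution is (v_len, j_len, d_id, d_start, d5_trim, d3_trim), where
    ``d_start`` indexes the junction; ``d_id`` is None when no D is assigned.
    Valid v_len: any common-prefix length of junction and v_region; valid
    j_len: any common-suffix length of the remainder with j_region; a D
    assignment is any contiguous substring of a candidate of length >=
    min_d_match lying fully between the V and J parts. Optimality is
    lexicographic on (v_len, j_len, d_len): maximal V, then J, then D.

    Returns (optima, best_objective): the list of attributions achieving the
    maximal objective, and that objective.
    """
    L = len(junction)
    max_v = 0
    while max_v < min(L, len(v_region)) and junction[max_v] == v_region[max_v]:
        max_v += 1
    results = []
    for v_len in range(max_v + 1):
        rem = junction[v_len:]
        max_j = 0
        while (
            max_j < min(len(rem), len(j_region))
            and rem[len(rem) - 1 - max_j] == j_region[len(j_region) - 1 - max_j]
        ):
            max_j += 1
        for j_len in range(max_j + 1):
            middle = junction[v_len : L - j_len]
            d_options = [(0, None, None, None, None)]  # (d_len, id, start, d5, d3)
            for d_id in sorted(d_seqs):
                d_seq = d_seqs[d_id]
                for length in range(min_d_match, min(len(middle), len(d_seq)) + 1):
                    for start in range(len(middle) - length + 1):
                        window = middle[start : start + length]
                        pos = d_seq.find(window)
                        if pos >= 0:
                            d_options.append(
                                (
                                    length,
                                    d_id,
                                    v_len + start,
                                    pos,
                                    len(d_seq) - pos - length,
                                )
                            )
            for d_len, d_id, d_start, d5, d3 in d_options:
                results.append(((v_len, j_len, d_len), (v_len, j_len, d_id, d_start, d5, d3)))
    best = max(obj for obj, _ in results)
    optima = sorted({attr for obj, attr in results if obj == best})
    return optima, best


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full enumeration of tables with the
    observed margins (hypergeometric; sums probabilities <= observed)."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1)

    def prob(x: int) -> float:
        return comb(r1, x) * comb(r2, c1 - x) / denom

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)
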