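"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

from Bio.Seq import Seq

NT_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def check_nt(seq: str, *, what: str = "sequence") -> str:
    """Upper-case ``seq`` and reject anything outside {A,C,G,T}.

    IUPAC ambiguity codes are rejected rather than expanded; gaps and
    lower-case input are not part of the data model this package accepts.
    """
    s = seq.upper()
    bad = set(s) - NT_ALPHABET
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)!r}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def translate_nt(seq: str) -> str:
    """Translate an in-frame nucleotide string with the standard code.

    Stop codons render as ``*``. The empty string translates to the empty
    string. Length must be a multiple of three and the alphabet strict ACGT.
    """
    s = check_nt(seq, what="coding sequence")
    if len(s) % 3 != 0:
        raise ValueError(f"sequence length {len(s)} is not a multiple of 3")
    if not s:
        return ""
    return str(Seq(s).translate())
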