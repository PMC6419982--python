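"""IUPAC degenerate nucleotide codes and matching.

16S primers are written with degenerate positions (e.g. 515F
``GTGCCAGCMGCCGCGGTAA`` where M stands for A or C).  Technical-sequence
matching during demultiplexing and primer localisation during reference
trimming both reduce to asking whether a concrete read base is contained
in the set a degenerate code denotes.
"""

from __future__ import annotations

import random

#: IUPAC code -> set of concrete bases it denotes.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

# Commonly used primer pairs for the V4 and V5-V6 regions.
PRIMER_515F = "GTGCCAGCMGCCGCGGTAA"
PRIMER_806R = "GGACTACHVGGGTWTCTAAT"
PRIMER_BSF784F = "RGGATTAGATACCC"
PRIMER_1064R = "CGACRRCCATGCANCACCT"


class IUPACSequence(str):
    """An uppercase string over the 15 IUPAC nucleotide codes.

    Behaves as a plain ``str``; construction validates the alphabet.
    """

    def __new__(cls, letters: str) -> "IUPACSequence":
        letters = letters.upper()
        bad = set(letters) - set(IUPAC)
        if bad:
            raise ValueError(f"invalid IUPAC code(s) {sorted(bad)} in {letters!r}")
        return super().__new__(cls, letters)


def base_matches(code: str, base: str) -> bool:
    """True if concrete ``base`` is among the bases IUPAC ``code`` denotes."""
    try:
        return base in IUPAC[code]
    except KeyError:
        raise ValueError(f"invalid IUPAC code {code!r}") from None


def matches(pattern: str, seq: str, max_mismatch: int = 0) -> bool:
    """Match ``seq`` against degenerate ``pattern`` position by position.

    Equal lengths required.  A position mismatches when the concrete base
    is not in the pattern code's expansion; at most ``max_mismatch`` such
    positions are tolerated.
    """
    if len(pattern) != len(seq):
        return False
    mm = 0
    for code, base in zip(pattern, seq):
        if base not in IUPAC[code]:
            mm += 1
            if mm > max_mismatch:
                return False
    return True


def count_mismatches(pattern: str, seq: str) -> int:
    """Number of positions of ``seq`` outside the pattern codes' expansions."""
    if len(pattern) != len(seq):
        raise ValueError("pattern and sequence lengths differ")
    return sum(base not in IUPAC[code] for code, base in zip(pattern, seq))


def expand(pattern: str, rng: random.Random | None = None) -> str:
    """One concrete ACGT expansion of a degenerate pattern.

    Deterministic (alphabetically first option per code) without an
    ``rng``; random choice per degenerate position with one.
    """
    out = []
    for code in pattern:
        options = sorted(IUPAC[code])
        out.append(options[0] if rng is None else rng.choice(options))
    return "".join(out)


def reverse_complement(seq: str) -> str:
    """Reverse complement; degenerate codes map to their complements."""
    return seq.translate(_COMPLEMENT)[::-1]
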