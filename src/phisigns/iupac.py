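"""IUPAC nucleotide ambiguity codes and the operations defined on them.

Every degenerate-primer computation in the package reduces to set
operations on the disambiguation sets of IUPAC codes, so those tables
live here in one place.
"""

from __future__ import annotations

# code -> frozenset of plain bases it stands for
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("GC"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# frozenset of bases -> minimal covering code (unique by construction)
SET_TO_CODE: dict[frozenset[str], str] = {s: c for c, s in IUPAC_SETS.items()}

BASE_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# complement of a code = code of the complemented disambiguation set
IUPAC_COMPLEMENT: dict[str, str] = {
    c: SET_TO_CODE[frozenset(BASE_COMPLEMENT[b] for b in s)] for c, s in IUPAC_SETS.items()
}

GAP = "-"

VALID_CODES = frozenset(IUPAC_SETS)

# str.translate tables for the hot paths
COMPLEMENT_TRANS = str.maketrans({**IUPAC_COMPLEMENT, GAP: GAP})
CODE_SIZE = {c: len(s) for c, s in IUPAC_SETS.items()}
GC_FRACTION = {c: len(s & {"G", "C"}) / len(s) for c, s in IUPAC_SETS.items()}


def disambiguation_set(code: str) -> frozenset[str]:
    """Plain-base set for one IUPAC code; raises on anything else."""
    try:
        return IUPAC_SETS[code.upper()]
    except KeyError:
        raise ValueError(f"not an IUPAC nucleotide code: {code!r}") from None


def minimal_code(bases) -> str:
    """Smallest IUPAC code whose disambiguation set equals the union of *bases*.

    *bases* may contain IUPAC codes; their sets are unioned first.
    """
    union: frozenset[str] = frozenset()
    for b in bases:
        union |= disambiguation_set(b)
    if not union:
        raise ValueError("empty base set has no IUPAC code")
    return SET_TO_CODE[union]


def can_pair(a: str, b: str) -> bool:
    """True if some disambiguation of *a* is Watson-Crick complementary to one of *b*."""
    sa = disambiguation_set(a)
    return any(BASE_COMPLEMENT[x] in disambiguation_set(b) for x in sa)


def matches(code: str, base: str) -> bool:
    """True if plain *base* is covered by IUPAC *code* (primer-site match test)."""
    return base.upper() in disambiguation_set(code)


def code_size(code: str) -> int:
    return len(disambiguation_set(code))
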