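"""IUPAC degenerate-base utilities shared by the panel-QC operations.

Degenerate codes are treated with base-set semantics: a code stands for the
set of plain bases it may resolve to, two codes are compatible when their
sets intersect, and two codes can pair when one's set intersects the
complement of the other's. ``N`` therefore matches everything.
"""

from __future__ import annotations

from itertools import product

from .errors import AlphabetError, DegeneracyError

IUPAC_SETS: dict[str, frozenset[str]] = {
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

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "G": "C", "C": "G",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}


def validate_iupac(seq: str, *, context: str = "sequence") -> str:
    """Uppercase ``seq`` and verify every character is an IUPAC DNA code."""
    seq = seq.upper()
    for i, ch in enumerate(seq):
        if ch not in IUPAC_SETS:
            raise AlphabetError(
                f"{context}: invalid IUPAC DNA character {ch!r} at position {i}"
            )
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement preserving degenerate codes (Y ↔ R etc.)."""
    return "".join(IUPAC_COMPLEMENT[ch] for ch in reversed(seq))


def bases_compatible(a: str, b: str) -> bool:
    """True when the base sets of two IUPAC codes intersect."""
    return bool(IUPAC_SETS[a] & IUPAC_SETS[b])


def bases_pair(a: str, b: str) -> bool:
    """True when code ``a`` can Watson–Crick pair with code ``b``."""
    return bool(IUPAC_SETS[a] & IUPAC_SETS[IUPAC_COMPLEMENT[b]])


def degeneracy(seq: str) -> int:
    """Number of plain-base sequences a degenerate sequence expands to."""
    n = 1
    for ch in seq:
        n *= len(IUPAC_SETS[ch])
    return n


def expand_degenerate(seq: str, cap: int = 64) -> list[str]:
    """Enumerate all plain A/C/G/T expansions of a degenerate sequence.

    Raises :class:`DegeneracyError` when the expansion count exceeds ``cap``
    (primers with many degenerate sites should be handled per-lot instead).
    """
    n = degeneracy(seq)
    if n > cap:
        raise DegeneracyError(
            f"sequence expands to {n} variants, above the cap of {cap}"
        )
    pools = [sorted(IUPAC_SETS[ch]) for ch in seq]
    return ["".join(p) for p in product(*pools)]


def first_expansion(seq: str) -> str:
    """A deterministic concrete expansion (alphabetically first base per site)."""
    return "".join(sorted(IUPAC_SETS[ch])[0] for ch in seq)
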