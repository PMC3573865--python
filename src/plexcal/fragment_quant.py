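"""Absolute copy-number quantification of cleaned PCR products.

A cleaned double-stranded amplicon of known sequence has a molecular weight
that is a simple linear function of its base-pair composition,

    MW = n_AT * m_AT + n_GC * m_GC + end_correction   [g/mol],

and a fluorometric concentration ``q`` (ng/µL) then converts to an absolute
copy number per microlitre through Avogadro's constant,

    copies/µL = q * 1e-9 * N_A / MW.

The default pair masses are the anhydrous average duplex base-pair masses
(A–T 617.4, G–C 618.4 g/mol); every constant is overridable through
:class:`MassConstants` so an alternative coefficient set can be reproduced
exactly.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field

from .errors import CompositionError, InputError, LinkageError

_PLAIN_BASES = frozenset("ACGT")

#: Anhydrous average masses of the two duplex base pairs, g/mol.
DEFAULT_MASS_AT_PAIR = 617.4
DEFAULT_MASS_GC_PAIR = 618.4
AVOGADRO = 6.02214076e23


@dataclass(frozen=True)
class MassConstants:
    """Coefficients of the composition → molecular-weight conversion.

    Parameters
    ----------
    mass_at_pair, mass_gc_pair:
        Mass of one A–T / G–C base pair in the duplex, g/mol.
    end_correction:
        Constant added once per duplex (g/mol); 0 for anhydrous pair masses,
        may be negative for coefficient sets that subtract a condensation
        water or add 5'-end groups.
    avogadro:
        Avogadro's constant, 1/mol.
    """

    mass_at_pair: float = DEFAULT_MASS_AT_PAIR
    mass_gc_pair: float = DEFAULT_MASS_GC_PAIR
    end_correction: float = 0.0
    avogadro: float = AVOGADRO

    def __post_init__(self) -> None:
        if self.mass_at_pair <= 0 or self.mass_gc_pair <= 0:
            raise InputError("base-pair masses must be positive")
        if self.avogadro <= 0:
            raise InputError("Avogadro's constant must be positive")


def count_pairs(sequence: str) -> tuple[int, int]:
    """Count A–T and G–C base pairs of a duplex from one strand.

    The count is strand-invariant: an A or T on the given strand marks an
    A–T pair, a G or C marks a G–C pair. Degenerate IUPAC codes are rejected
    because an ambiguous base has no single pair mass.

    Returns
    -------
    (n_at, n_gc) with ``n_at + n_gc == len(sequence)``.
    """
    if not sequence:
        raise InputError("empty sequence")
    seq = sequence.upper()
    n_at = 0
    for i, ch in enumerate(seq):
        if ch not in _PLAIN_BASES:
            raise CompositionError(i, ch)
        if ch in "AT":
            n_at += 1
    return n_at, len(seq) - n_at


def molecular_weight(
    n_at: int, n_gc: int, constants: MassConstants = MassConstants()
) -> float:
    """Molecular weight (g/mol) of a double-stranded fragment."""
    if n_at < 0 or n_gc < 0:
        raise InputError("pair counts must be non-negative")
    if n_at + n_gc < 1:
        raise InputError("zero-length fragment has no molecular weight")
    return (
        n_at * constants.mass_at_pair
        + n_gc * constants.mass_gc_pair
        + constants.end_correction
    )


def copies_per_ul(
    q_mean: float, mw: float, constants: MassConstants = MassConstants()
) -> float:
    """Double-stranded copies per µL from a concentration in ng/µL.

    ``q`` ng/µL is ``q * 1e-9`` g/µL; dividing by the molar mass and
    multiplying by Avogadro's constant gives molecules per µL.
    """
    if mw <= 0:
        raise InputError("molecular weight must be positive")
    if q_mean < 0:
        raise InputError("concentration must be non-negative")
    return q_mean * 1e-9 * constants.avogadro / mw


@dataclass(frozen=True)
class Fragment:
    """One strand of a double-stranded amplicon plus its pair composition."""

    id: str
    sequence: str
    length_bp: int = field(init=False)
    n_at: int = field(init=False)
    n_gc: int = field(init=False)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        n_at, n_gc = count_pairs(seq)
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "length_bp", n_at + n_gc)
        object.__setattr__(self, "n_at", n_at)
        object.__setattr__(self, "n_gc", n_gc)


@dataclass(frozen=True)
class ConcentrationMeasurement:
    """Replicated fluorometric readings of one fragment, ng/µL."""

    fragment_id: str
    replicates: tuple[float, ...]
    q_mean: float = field(init=False)

    def __post_init__(self) -> None:
        reps = tuple(float(r) for r in self.replicates)
        if not reps:
            raise InputError(f"{self.fragment_id}: at least one replicate required")
        if any(r < 0 for r in reps):
            raise InputError(f"{self.fragment_id}: negative concentration replicate")
        object.__setattr__(self, "replicates", reps)
        object.__setattr__(self, "q_mean", statistics.fmean(reps))

    @property
    def cv(self) -> float:
        """Coefficient of variation of the replicates (0 when mean is 0)."""
        if len(self.replicates) < 2 or self.q_mean == 0:
            return 0.0
        return statistics.stdev(self.replicates) / self.q_mean


@dataclass(frozen=True)
class TemplateStock:
    """A quantified fragment: everything needed to plan its dilution."""

    fragment: Fragment
    measurement: ConcentrationMeasurement
    molecular_weight: float
    copies_per_ul: float


def quantify_stock(
    fragment: Fragment,
    measurement: ConcentrationMeasurement,
    constants: MassConstants = MassConstants(),
    cv_warn_threshold: float = 0.10,
) -> TemplateStock:
    """Chain composition → molecular weight → copies/µL for one fragment.

    Replicate scatter above ``cv_warn_threshold`` (default 10%) triggers a
    warning: large measurement CVs defeat the point of standardising copies.
    """
    if measurement.fragment_id != fragment.id:
        raise LinkageError(
            f"measurement is for {measurement.fragment_id!r}, "
            f"fragment is {fragment.id!r}"
        )
    mw = molecular_weight(fragment.n_at, fragment.n_gc, constants)
    if measurement.cv > cv_warn_threshold:
        warnings.warn(
            f"{fragment.id}: replicate CV {measurement.cv:.1%} exceeds "
            f"{cv_warn_threshold:.0%}; check pipetting",
            stacklevel=2,
        )
    return TemplateStock(
        fragment=fragment,
        measurement=measurement,
        molecular_weight=mw,
        copies_per_ul=copies_per_ul(measurement.q_mean, mw, constants),
    )
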