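"""Serial dilution planning with pipetting-error propagation.

Standardising template copies requires diluting each stock by a different,
often large, factor. Pipetting error (as a coefficient of variation, CV)
shrinks with pipetted volume, so several moderate steps at comfortable
volumes beat a single extreme step: three 1:10 steps pipetting 10 µL carry
far less relative error than one 1:1000 step pipetting 1 µL. The planner
decomposes a required total factor into the fewest admissible steps and the
quadrature rule combines the per-step CVs (independent errors):

    total_cv = sqrt(sum_i cv_i**2)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ComparabilityError, ExtrapolationError, InputError, PlanningError

_REL_TOL = 1e-9


@dataclass(frozen=True)
class DilutionStep:
    """One transfer: ``aliquot_volume`` µL of source into ``diluent_volume`` µL."""

    aliquot_volume: float
    diluent_volume: float
    factor: float = field(init=False)

    def __post_init__(self) -> None:
        if self.aliquot_volume <= 0:
            raise InputError("aliquot volume must be positive")
        if self.diluent_volume < 0:
            raise InputError("diluent volume must be non-negative")
        object.__setattr__(
            self,
            "factor",
            (self.aliquot_volume + self.diluent_volume) / self.aliquot_volume,
        )

    @classmethod
    def from_factor(cls, factor: float, aliquot_volume: float) -> "DilutionStep":
        if factor < 1:
            raise InputError("dilution factor must be >= 1")
        return cls(
            aliquot_volume=aliquot_volume,
            diluent_volume=aliquot_volume * (factor - 1.0),
        )


@dataclass(frozen=True)
class PipettingErrorModel:
    """Volume-indexed pipetting CV, linearly interpolated between nodes.

    ``volume_cv_table`` maps pipetted volume (µL) to CV (fraction); the CV
    must be non-increasing in volume. No extrapolation: volumes outside the
    table raise :class:`ExtrapolationError`.
    """

    volume_cv_table: dict[float, float]
    min_pipettable_volume: float = 1.0

    def __post_init__(self) -> None:
        if not self.volume_cv_table:
            raise InputError("error model needs at least one (volume, CV) node")
        vols = sorted(self.volume_cv_table)
        cvs = [self.volume_cv_table[v] for v in vols]
        if any(v <= 0 for v in vols) or any(c < 0 for c in cvs):
            raise InputError("volumes must be positive and CVs non-negative")
        if any(b > a for a, b in zip(cvs, cvs[1:])):
            raise InputError("CV must be non-increasing in volume")

    def cv_for_volume(self, volume: float) -> float:
        vols = sorted(self.volume_cv_table)
        if volume < vols[0] or volume > vols[-1]:
            raise ExtrapolationError(
                f"volume {volume} µL outside calibrated range "
                f"[{vols[0]}, {vols[-1]}] µL"
            )
        return float(np.interp(volume, vols, [self.volume_cv_table[v] for v in vols]))


#: Typical air-displacement pipette precision by volume.
DEFAULT_ERROR_MODEL = PipettingErrorModel(
    volume_cv_table={1.0: 0.08, 5.0: 0.03, 10.0: 0.01, 100.0: 0.005},
    min_pipettable_volume=1.0,
)


@dataclass(frozen=True)
class DilutionPlan:
    steps: tuple[DilutionStep, ...]
    source_copies: float
    final_copies: float
    total_factor: float
    total_cv: float


def total_factor(steps: list[DilutionStep] | tuple[DilutionStep, ...]) -> float:
    """Product of the per-step factors (order-invariant)."""
    if not steps:
        raise InputError("empty step list")
    return math.prod(s.factor for s in steps)


def propagate_cv(
    steps: list[DilutionStep] | tuple[DilutionStep, ...],
    error_model: PipettingErrorModel = DEFAULT_ERROR_MODEL,
) -> float:
    """Total CV of a serial dilution by quadrature over per-step CVs.

    Each step's CV is looked up by its aliquot volume — the small transferred
    volume dominates the step's relative error.
    """
    return math.sqrt(
        sum(error_model.cv_for_volume(s.aliquot_volume) ** 2 for s in steps)
    )


def plan_serial_dilution(
    source_copies: float,
    target_copies: float,
    max_step_factor: float = 10.0,
    step_volume: float = 10.0,
    error_model: PipettingErrorModel = DEFAULT_ERROR_MODEL,
) -> DilutionPlan:
    """Plan the fewest-step serial dilution from source to target copies/µL.

    The required ratio ``source/target`` is decomposed into the minimum
    number of steps with every factor ≤ ``max_step_factor``: full-strength
    ``max_step_factor`` steps first and one residual step last, so the
    smallest factor acts on the already most-dilute material. Each step
    transfers ``step_volume`` µL of the previous dilution.
    """
    if target_copies <= 0:
        raise InputError("target copies must be positive")
    if source_copies < target_copies:
        raise InputError("target copies exceed source copies")
    if max_step_factor <= 1:
        raise InputError("max step factor must be > 1")
    if step_volume < error_model.min_pipettable_volume:
        raise PlanningError(
            f"step volume {step_volume} µL is below the minimum pipettable "
            f"volume {error_model.min_pipettable_volume} µL"
        )

    ratio = source_copies / target_copies
    if abs(ratio - 1.0) <= _REL_TOL:
        return DilutionPlan(
            steps=(),
            source_copies=source_copies,
            final_copies=source_copies,
            total_factor=1.0,
            total_cv=0.0,
        )

    n_steps = max(1, math.ceil(math.log(ratio) / math.log(max_step_factor) - 1e-12))
    residual = ratio / max_step_factor ** (n_steps - 1)
    factors = [max_step_factor] * (n_steps - 1) + [residual]

    steps = tuple(DilutionStep.from_factor(f, step_volume) for f in factors)
    achieved = total_factor(steps)
    if not math.isclose(achieved, ratio, rel_tol=_REL_TOL):
        raise PlanningError(
            f"decomposed factor {achieved} does not reach required ratio {ratio}"
        )
    return DilutionPlan(
        steps=steps,
        source_copies=source_copies,
        final_copies=source_copies / achieved,
        total_factor=achieved,
        total_cv=propagate_cv(steps, error_model),
    )


@dataclass(frozen=True)
class PlanComparison:
    """Outcome of ranking two plans that achieve the same total factor."""

    better: str  # "a", "b" or "tie"
    cv_a: float
    cv_b: float
    cv_difference: float  # cv_a - cv_b


def compare_plans(a: DilutionPlan, b: DilutionPlan) -> PlanComparison:
    """Rank two same-factor plans by propagated CV (lower wins)."""
    if not math.isclose(a.total_factor, b.total_factor, rel_tol=_REL_TOL):
        raise ComparabilityError(
            f"plans achieve different total factors "
            f"({a.total_factor} vs {b.total_factor})"
        )
    diff = a.total_cv - b.total_cv
    if math.isclose(a.total_cv, b.total_cv, rel_tol=0.0, abs_tol=1e-12):
        better = "tie"
    else:
        better = "a" if diff < 0 else "b"
    return PlanComparison(better=better, cv_a=a.total_cv, cv_b=b.total_cv,
                          cv_difference=diff)
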