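"""Primer-concentration balancing and limit-of-detection logic.

With standardised templates (equal copies per target), uneven band
strengths reflect primer efficiency, not template amount. Balancing is
iterative: primer pairs with relatively strong signals are decreased and
weak ones increased, in 0.1 µM steps, until every target's signal sits
within a tolerance band around the panel median.

The limit of detection (LOD) for a target is the smallest tested copy
number at which every replicate produces a detected signal (>= 0.1 RFU by
default) with no failure at any higher tested level — the "stable
reaction" requirement. Levels below the LOD with partial detection are
reported as the unstable range.
"""

from __future__ import annotations

import itertools
import statistics
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import pandas as pd

from .errors import CoverageError, InputError

CONDITIONS = (
    "single_target",
    "target_mix",
    "single_plus_background",
    "mix_plus_background",
)

DEFAULT_DETECTION_THRESHOLD = 0.1  # RFU
DEFAULT_BACKGROUND_NG = 300.0  # non-target DNA per reaction


@dataclass(frozen=True)
class SignalReading:
    """One electropherogram readout for one target lane."""

    target_name: str
    template_copies: float
    condition: str
    replicate: int
    rfu: float

    def __post_init__(self) -> None:
        if self.rfu < 0:
            raise InputError(f"{self.target_name}: negative RFU")
        if self.template_copies < 0:
            raise InputError(f"{self.target_name}: negative template copies")
        if self.condition not in CONDITIONS:
            raise InputError(
                f"unknown condition {self.condition!r}; expected one of {CONDITIONS}"
            )


def is_detected(rfu: float, threshold: float = DEFAULT_DETECTION_THRESHOLD) -> bool:
    """Detection rule: signal at or above the threshold (closed bound)."""
    if rfu < 0:
        raise InputError("RFU must be non-negative")
    if threshold <= 0:
        raise InputError("detection threshold must be positive")
    return rfu >= threshold


@dataclass(frozen=True)
class LodResult:
    target_name: str
    condition: str
    lod_copies: float | None
    unstable_range: tuple[float, ...]
    detection_by_level: dict[float, tuple[int, int]]  # level -> (detected, total)


def lod_from_grid(
    readings: Iterable[SignalReading],
    target: str,
    condition: str,
    threshold: float = DEFAULT_DETECTION_THRESHOLD,
) -> LodResult:
    """LOD for one (target, condition) slice of a sensitivity grid.

    The LOD is the smallest tested level at which all replicates are
    detected and above which no tested level has any failure; a grid where
    a higher level fails (non-monotone detection) yields an undefined LOD
    rather than a misleading number.
    """
    slice_ = [
        r for r in readings
        if r.target_name == target and r.condition == condition
    ]
    if not slice_:
        raise InputError(f"no readings for target {target!r}, condition {condition!r}")

    by_level: dict[float, tuple[int, int]] = {}
    for level, group in itertools.groupby(
        sorted(slice_, key=lambda r: r.template_copies),
        key=lambda r: r.template_copies,
    ):
        rfus = [g.rfu for g in group]
        by_level[level] = (sum(is_detected(v, threshold) for v in rfus), len(rfus))

    levels = sorted(by_level)
    fully = {lv: d == t for lv, (d, t) in by_level.items()}
    lod: float | None = None
    # walk from the top: the LOD extends downwards while levels stay fully detected
    for lv in reversed(levels):
        if fully[lv]:
            lod = lv
        else:
            break

    if lod is None:
        unstable = tuple(lv for lv in levels if 0 < by_level[lv][0] < by_level[lv][1])
    else:
        unstable = tuple(
            lv for lv in levels
            if lv < lod and 0 < by_level[lv][0] < by_level[lv][1]
        )
    return LodResult(
        target_name=target,
        condition=condition,
        lod_copies=lod,
        unstable_range=unstable,
        detection_by_level=by_level,
    )


@dataclass(frozen=True)
class SignalSummary:
    median: float
    minimum: float
    maximum: float
    n_replicates: int


def summarize_signals(
    readings: Iterable[SignalReading],
    copies: float,
    condition: str,
) -> dict[str, SignalSummary]:
    """Per-target median RFU (with min/max) at one (copies, condition) cell.

    Every target present anywhere in the readings must have at least one
    replicate in the requested cell; a missing target is a coverage error,
    not a silent omission.
    """
    readings = list(readings)
    targets = sorted({r.target_name for r in readings})
    if not targets:
        raise InputError("no readings supplied")
    out: dict[str, SignalSummary] = {}
    for t in targets:
        vals = [
            r.rfu for r in readings
            if r.target_name == t and r.template_copies == copies
            and r.condition == condition
        ]
        if not vals:
            raise CoverageError(
                f"target {t!r} has no readings at {copies} copies, {condition!r}"
            )
        out[t] = SignalSummary(
            median=statistics.median(vals),
            minimum=min(vals),
            maximum=max(vals),
            n_replicates=len(vals),
        )
    return out


# ---------------------------------------------------------------------------
# Balancing


@dataclass(frozen=True)
class BalanceState:
    """Primer concentrations plus the signals they produced at equal copies."""

    concentrations: dict[str, float]  # µM per target
    signals: dict[str, float]  # summary RFU per target
    tolerance: float = 0.25  # relative band around the panel median
    step: float = 0.1  # µM
    bounds: tuple[float, float] = (0.1, 1.0)

    def __post_init__(self) -> None:
        if not 0 < self.tolerance < 1:
            raise InputError("tolerance must lie in (0, 1)")
        if self.step <= 0:
            raise InputError("step must be positive")
        lo, hi = self.bounds
        if not all(lo <= c <= hi for c in self.concentrations.values()):
            raise InputError("a concentration lies outside the bounds")
        missing = set(self.concentrations) - set(self.signals)
        if missing:
            raise InputError(f"signals missing for targets: {sorted(missing)}")


@dataclass(frozen=True)
class AdjustmentEvent:
    target_name: str
    old_uM: float
    new_uM: float
    reason: str  # "too_strong" | "too_weak"
    clamped: bool


def is_balanced(state: BalanceState) -> bool:
    """True when every target's signal is within median × (1 ± tolerance)."""
    med = statistics.median(state.signals[t] for t in state.concentrations)
    lo = med * (1 - state.tolerance)
    hi = med * (1 + state.tolerance)
    return all(lo <= state.signals[t] <= hi for t in state.concentrations)


def propose_adjustment(
    state: BalanceState,
) -> tuple[dict[str, float], list[AdjustmentEvent]]:
    """One balancing move: ±step µM against the panel median, clamped to bounds.

    Targets with signal above median × (1 + tolerance) lose one step; those
    below median × (1 − tolerance) gain one. The band is closed, so a state
    that is already balanced is a fixed point.
    """
    med = statistics.median(state.signals[t] for t in state.concentrations)
    lo_bound, hi_bound = state.bounds
    new = dict(state.concentrations)
    log: list[AdjustmentEvent] = []
    for t, conc in state.concentrations.items():
        s = state.signals[t]
        if s > med * (1 + state.tolerance):
            proposed, reason = conc - state.step, "too_strong"
        elif s < med * (1 - state.tolerance):
            proposed, reason = conc + state.step, "too_weak"
        else:
            continue
        clamped_val = min(max(proposed, lo_bound), hi_bound)
        if clamped_val != conc:
            new[t] = round(clamped_val, 10)  # keep 0.1 µM grid clean
        log.append(
            AdjustmentEvent(
                target_name=t,
                old_uM=conc,
                new_uM=new[t],
                reason=reason,
                clamped=clamped_val != proposed,
            )
        )
    return new, log


@dataclass(frozen=True)
class BalanceOutcome:
    converged: bool
    oscillating: bool
    iterations: int
    final_state: BalanceState
    history: tuple[dict[str, float], ...]


def run_balancing(
    state: BalanceState,
    response: Callable[[dict[str, float]], dict[str, float]],
    max_iterations: int | None = None,
) -> BalanceOutcome:
    """Iterate propose → re-measure until balanced, oscillating, or exhausted.

    ``response`` maps concentrations to summary signals (in the lab this is
    a PCR run; in tests a monotone toy model). The iteration bound defaults
    to (bound span / step) × number of targets, enough for every target to
    traverse its whole range once. Revisiting an earlier concentration
    vector is reported as oscillation, never silently looped through.
    """
    lo, hi = state.bounds
    n = len(state.concentrations)
    if max_iterations is None:
        max_iterations = max(1, round((hi - lo) / state.step)) * n

    seen = {tuple(sorted(state.concentrations.items()))}
    history = [dict(state.concentrations)]
    current = state
    for it in range(1, max_iterations + 1):
        if is_balanced(current):
            return BalanceOutcome(True, False, it - 1, current, tuple(history))
        new_conc, _ = propose_adjustment(current)
        current = replace(current, concentrations=new_conc,
                          signals=response(new_conc))
        history.append(dict(new_conc))
        key = tuple(sorted(new_conc.items()))
        if key in seen and not is_balanced(current):
            return BalanceOutcome(False, True, it, current, tuple(history))
        seen.add(key)
    return BalanceOutcome(
        is_balanced(current), False, max_iterations, current, tuple(history)
    )


# ---------------------------------------------------------------------------
# Sensitivity grid design


def design_sensitivity_grid(
    targets: Sequence[str],
    copy_levels: Sequence[float],
    conditions: Sequence[str] = CONDITIONS,
    replicates: int = 3,
    background_ng: float = DEFAULT_BACKGROUND_NG,
) -> pd.DataFrame:
    """Full-factorial bench layout: target × copy level × condition × replicate.

    ``background_ng`` of non-target DNA is attached to the two background
    conditions (simulating excess non-amplifiable consumer DNA) and 0 to the
    others.
    """
    if not copy_levels:
        raise InputError("copy_levels must be non-empty")
    if replicates < 1:
        raise InputError("replicates must be >= 1")
    for c in conditions:
        if c not in CONDITIONS:
            raise InputError(f"unknown condition {c!r}")
    rows = [
        {
            "target": t,
            "copies": lv,
            "condition": cond,
            "replicate": rep,
            "background_ng": background_ng if "background" in cond else 0.0,
        }
        for t in targets
        for lv in copy_levels
        for cond in conditions
        for rep in range(1, replicates + 1)
    ]
    return pd.DataFrame(rows)
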