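"""Run configuration: every tunable default in one serialisable object."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .dilution import PipettingErrorModel
from .errors import InputError
from .fragment_quant import MassConstants


@dataclass(frozen=True)
class QCThresholds:
    tm_tolerance_c: float = 5.0
    tm_method: str = "wallace"
    dimer_score_threshold: int = 8
    dimer_anchored_threshold: int = 5
    platform: str = "capillary"
    degraded_max_len_bp: int = 300
    degeneracy_cap: int = 64
    max_product_length_bp: int = 2000


@dataclass(frozen=True)
class BalanceSettings:
    tolerance: float = 0.25
    step_uM: float = 0.1
    min_uM: float = 0.1
    max_uM: float = 1.0


@dataclass(frozen=True)
class PlannerSettings:
    max_step_factor: float = 10.0
    step_volume_ul: float = 10.0


@dataclass(frozen=True)
class RunConfig:
    mass_constants: MassConstants = field(default_factory=MassConstants)
    error_model: PipettingErrorModel = field(
        default_factory=lambda: PipettingErrorModel(
            volume_cv_table={1.0: 0.08, 5.0: 0.03, 10.0: 0.01, 100.0: 0.005},
            min_pipettable_volume=1.0,
        )
    )
    qc: QCThresholds = field(default_factory=QCThresholds)
    balance: BalanceSettings = field(default_factory=BalanceSettings)
    planner: PlannerSettings = field(default_factory=PlannerSettings)
    detection_threshold_rfu: float = 0.1
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        # JSON object keys are strings; stringify table keys explicitly so the
        # round-trip is loss-free
        d["error_model"]["volume_cv_table"] = {
            str(k): v for k, v in self.error_model.volume_cv_table.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        try:
            em = d.get("error_model", {})
            table = {float(k): float(v)
                     for k, v in em.get("volume_cv_table", {}).items()}
            return cls(
                mass_constants=MassConstants(**d.get("mass_constants", {})),
                error_model=PipettingErrorModel(
                    volume_cv_table=table or
                    RunConfig().error_model.volume_cv_table,
                    min_pipettable_volume=em.get("min_pipettable_volume", 1.0),
                ),
                qc=QCThresholds(**d.get("qc", {})),
                balance=BalanceSettings(**d.get("balance", {})),
                planner=PlannerSettings(**d.get("planner", {})),
                detection_threshold_rfu=d.get("detection_threshold_rfu", 0.1),
                seed=int(d.get("seed", 0)),
            )
        except TypeError as exc:
            raise InputError(f"bad configuration: {exc}") from exc

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
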