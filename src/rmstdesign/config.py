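"""Structured-text configuration for scenarios and batch runs."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .scenario import ArmModel, ScenarioSpec

__all__ = ["load_scenario", "save_scenario", "scenario_from_dict", "RunConfig"]


def _arm_from_dict(d: dict) -> ArmModel:
    return ArmModel(
        kind=d.get("kind", "exponential"),
        lam0=float(d["lam0"]),
        delta1=float(d.get("delta1", 1.0)),
        delta2=float(d.get("delta2", 1.0)),
        change_time=float(d.get("change_time", 0.0)),
    )


def scenario_from_dict(d: dict) -> ScenarioSpec:
    return ScenarioSpec(
        experimental=_arm_from_dict(d["experimental"]),
        control=_arm_from_dict(d["control"]),
        min_followup=float(d["min_followup"]),
        tau=float(d["tau"]),
        accrual_period=(
            float(d["accrual_period"]) if d.get("accrual_period") is not None else None
        ),
        accrual_rate=(
            float(d["accrual_rate"]) if d.get("accrual_rate") is not None else None
        ),
        label=str(d.get("label", "")),
    )


def load_scenario(path) -> ScenarioSpec:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))


def save_scenario(spec: ScenarioSpec, path) -> None:
    d = {
        "label": spec.label,
        "experimental": asdict(spec.experimental),
        "control": asdict(spec.control),
        "accrual_period": spec.accrual_period,
        "accrual_rate": spec.accrual_rate,
        "min_followup": spec.min_followup,
        "tau": spec.tau,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class RunConfig:
    """Orchestration settings for a side-by-side design table."""

    scenario: ScenarioSpec
    alpha0: float = 0.05
    beta0: float = 0.2
    b_reps: int = 10000
    seed: int = 0
    methods: tuple[str, ...] = ("logrank", "simple", "sculpted")
    design: str = "minimax"  # which stored design each row reports
    stride: int = 2
    interim_stride: int | None = None
    search_kwargs: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        scenario = scenario_from_dict(raw.pop("scenario"))
        methods = tuple(raw.pop("methods", ("logrank", "simple", "sculpted")))
        return cls(scenario=scenario, methods=methods, **raw)

    def fingerprint(self) -> str:
        return (
            f"{self.scenario!r}|alpha0={self.alpha0}|beta0={self.beta0}"
            f"|B={self.b_reps}|seed={self.seed}|stride={self.stride}"
            f"|interim_stride={self.interim_stride}|design={self.design}"
        )
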