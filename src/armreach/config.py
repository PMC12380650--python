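"""Run configuration: schema-validated YAML driving one simulation or report.

A minimal config needs only ``model`` and ``task``; everything else defaults
to the headline study condition — the ``table2_mean`` arm, muscle selection
S21 and viscosity B10A10.  Unknown keys are rejected (typos should fail
loudly, not fall back to defaults silently).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import arm_model as am
from .exceptions import InvalidArgumentError
from .muscle_model import MuscleSelection, build_selection, SELECTION_NAMES
from .optimizer import GAConfig
from .synthetic import make_task
from .trajectory import MovementTask

__all__ = ["RunConfig", "load_config"]

DEFAULT_ARM = "table2_mean"
DEFAULT_SELECTION = "S21"
DEFAULT_VISCOSITY = "B10A10"


@dataclass
class RunConfig:
    """Fully resolved inputs for one optimization/comparison run."""

    model: str
    task: MovementTask
    arm: am.ArmParameters
    selection: MuscleSelection
    viscosity: am.ViscosityCondition
    ga: GAConfig = field(default_factory=GAConfig)
    spline_ends: str = "clamped"
    ik_branch: str = "elbow-cw"
    dt: float | None = None
    output: str | None = None
    defaults_used: tuple = ()

    def __post_init__(self):
        if self.model not in ("HJ", "AJ", "TC", "MSC"):
            raise InvalidArgumentError(
                f"model must be one of HJ/AJ/TC/MSC, got {self.model!r}")


def _reject_unknown(mapping, allowed, context):
    unknown = set(mapping) - set(allowed)
    if unknown:
        raise InvalidArgumentError(
            f"unknown key(s) {sorted(unknown)} in {context}; allowed: {sorted(allowed)}")


def _resolve_task(spec) -> MovementTask:
    if isinstance(spec, str):
        return make_task(spec)
    if isinstance(spec, dict):
        _reject_unknown(spec, {"name", "start", "target", "tf", "initial_wrist_deg"},
                        "task")
        if set(spec) <= {"name", "initial_wrist_deg", "tf"} and "name" in spec:
            return make_task(spec["name"],
                             initial_wrist_deg=spec.get("initial_wrist_deg", 0.0),
                             tf=spec.get("tf"))
        try:
            return MovementTask(
                start=np.asarray(spec["start"], dtype=float),
                target=np.asarray(spec["target"], dtype=float),
                tf=float(spec["tf"]),
                initial_wrist=np.deg2rad(float(spec.get("initial_wrist_deg", 0.0))),
                name=spec.get("name"),
            )
        except KeyError as exc:
            raise InvalidArgumentError(f"task is missing key {exc}") from None
    raise InvalidArgumentError("task must be a name or a mapping")


def _resolve_viscosity(spec) -> am.ViscosityCondition:
    if isinstance(spec, str):
        return am.ViscosityCondition.named(spec)
    if isinstance(spec, dict):
        _reject_unknown(spec, {"name", "alphaA", "alphaB"}, "viscosity")
        try:
            return am.ViscosityCondition(
                name=spec.get("name", "custom"),
                alpha_a=float(spec["alphaA"]),
                alpha_b=float(spec["alphaB"]),
            )
        except KeyError as exc:
            raise InvalidArgumentError(f"viscosity is missing key {exc}") from None
    raise InvalidArgumentError("viscosity must be a name or a mapping")


def _resolve_arm(spec) -> am.ArmParameters:
    if isinstance(spec, str):
        return am.ArmParameters.from_profile(spec)
    if isinstance(spec, dict):
        return am.ArmParameters.from_mapping(spec)
    raise InvalidArgumentError("arm must be a profile name/path or a mapping")


_TOP_KEYS = {"model", "task", "arm", "selection", "viscosity", "ga",
             "spline_ends", "ik_branch", "dt", "output"}


def from_mapping(raw: dict) -> RunConfig:
    """Build a validated :class:`RunConfig` from a plain mapping."""
    if not isinstance(raw, dict):
        raise InvalidArgumentError("config root must be a mapping")
    _reject_unknown(raw, _TOP_KEYS, "config")
    for key in ("model", "task"):
        if key not in raw:
            raise InvalidArgumentError(f"config is missing required key {key!r}")

    defaults_used = tuple(k for k, d in (
        ("arm", DEFAULT_ARM), ("selection", DEFAULT_SELECTION),
        ("viscosity", DEFAULT_VISCOSITY)) if k not in raw)

    selection = raw.get("selection", DEFAULT_SELECTION)
    if isinstance(selection, str):
        if selection not in SELECTION_NAMES:
            raise InvalidArgumentError(
                f"unknown selection {selection!r}; valid: {list(SELECTION_NAMES)}")
        selection = build_selection(selection)

    ga_spec = raw.get("ga", {})
    ga_fields = {f.name for f in dataclasses.fields(GAConfig)}
    _reject_unknown(ga_spec, ga_fields, "ga")
    ga = GAConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                     for k, v in ga_spec.items()})

    return RunConfig(
        model=str(raw["model"]),
        task=_resolve_task(raw["task"]),
        arm=_resolve_arm(raw.get("arm", DEFAULT_ARM)),
        selection=selection,
        viscosity=_resolve_viscosity(raw.get("viscosity", DEFAULT_VISCOSITY)),
        ga=ga,
        spline_ends=raw.get("spline_ends", "clamped"),
        ik_branch=raw.get("ik_branch", "elbow-cw"),
        dt=raw.get("dt"),
        output=raw.get("output"),
        defaults_used=defaults_used,
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return from_mapping(raw if raw is not None else {})
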