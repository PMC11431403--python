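"""Run-specification files: JSON (or YAML, when a parser is available)
configs resolving to parameters, integrator settings, noise and sweep plans.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .dynamics import IntegratorConfig, NoiseModel
from .model import DimerParams
from .observables import COMPLETION_THRESHOLD
from .presets import get_preset

__all__ = ["RunSpec", "SweepPlan", "load_config", "resolve_spec"]

logger = logging.getLogger("tetdimer")


@dataclass(frozen=True)
class SweepPlan:
    """Temperatures and ensemble size for a temperature sweep."""

    kBT_values: tuple[float, ...] = (0.5, 0.8, 1.0, 1.5, 2.0)
    n_runs: int = 20
    completion_threshold: float = COMPLETION_THRESHOLD

    def __post_init__(self) -> None:
        if len(self.kBT_values) == 0:
            raise ValueError("sweep.kBT_values must be non-empty")
        if any(k < 0 for k in self.kBT_values):
            raise ValueError("sweep.kBT_values must be non-negative")
        if self.n_runs < 1:
            raise ValueError(f"sweep.n_runs must be >= 1, got {self.n_runs}")


@dataclass(frozen=True)
class RunSpec:
    """Fully resolved run specification."""

    params: DimerParams
    integrator: IntegratorConfig = IntegratorConfig()
    noise: NoiseModel = NoiseModel()
    sweep: SweepPlan = SweepPlan()
    preset: str | None = None

    def to_dict(self) -> dict:
        return {
            "preset": self.preset,
            "params": self.params.to_dict(),
            "integrator": dataclasses.asdict(self.integrator),
            "noise": dataclasses.asdict(self.noise),
            "sweep": dataclasses.asdict(self.sweep),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _build_section(cls, data: dict, section: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) in '{section}': {sorted(unknown)}; "
            f"expected a subset of {sorted(known)}"
        )
    if cls is SweepPlan and "kBT_values" in data:
        data = dict(data, kBT_values=tuple(data["kBT_values"]))
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid '{section}' section: {exc}") from exc


def resolve_spec(raw: dict) -> RunSpec:
    """Validate a raw config mapping and fill defaults.

    Top-level keys: ``preset`` (optional name), ``params`` (overrides applied
    on top of the preset, or a complete set when no preset is given),
    ``integrator``, ``noise``, ``sweep``.  Unknown keys anywhere are
    rejected with the offending field path.
    """
    allowed = {"preset", "params", "integrator", "noise", "sweep"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown top-level key(s): {sorted(unknown)}; "
                         f"expected a subset of {sorted(allowed)}")
    preset_name = raw.get("preset")
    overrides = raw.get("params", {})
    if not isinstance(overrides, dict):
        raise ValueError("'params' must be a mapping")
    if preset_name is not None:
        base = get_preset(preset_name).params.to_dict()
        known = set(base)
        bad = set(overrides) - known
        if bad:
            raise ValueError(f"unknown key(s) in 'params': {sorted(bad)}")
        base.update(overrides)
        params = DimerParams.from_dict(base)
    else:
        params = DimerParams.from_dict(overrides)
    spec = RunSpec(
        params=params,
        integrator=_build_section(IntegratorConfig, dict(raw.get("integrator", {})),
                                  "integrator"),
        noise=_build_section(NoiseModel, dict(raw.get("noise", {})), "noise"),
        sweep=_build_section(SweepPlan, dict(raw.get("sweep", {})), "sweep"),
        preset=preset_name,
    )
    logger.info("resolved run specification: %s", json.dumps(spec.to_dict()))
    return spec


def load_config(path) -> RunSpec:
    """Load and resolve a JSON (or YAML) run specification file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        try:
            import yaml
        except ImportError as exc:
            raise ValueError(
                f"cannot read {path}: no YAML parser installed; use JSON"
            ) from exc
        raw = yaml.safe_load(text)
    else:
        try:
            raw = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ValueError(f"cannot parse {path} as JSON: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must contain a mapping at top level")
    return resolve_spec(raw)
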