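"""Run configuration: a single YAML (or JSON) file describing archetypes,
the evidence stream, the bias policy and output settings.

Unknown keys are rejected by name and every probability is range-checked at
load time, so a config error fails fast with a message naming the field.
A loaded :class:`RunConfig` round-trips through :meth:`RunConfig.to_dict`
with no loss, which is what the run manifest relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .core import BiasPolicy
from .evidence import StreamSpec, TrialDesign
from .scenarios import Archetype

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """A malformed or invalid run configuration."""


@dataclass(frozen=True)
class ArchetypeSpec:
    """An archetype plus an optional per-archetype LR override."""

    name: str
    prior: float
    lr: float | None = None

    @property
    def archetype(self) -> Archetype:
        return Archetype(self.name, self.prior)


@dataclass(frozen=True)
class RunConfig:
    name: str
    archetypes: tuple[ArchetypeSpec, ...]
    stream: StreamSpec
    policy: BiasPolicy
    seed: int = 0
    output_dir: str = "out"

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "name": self.name,
            "archetypes": [
                {"name": a.name, "prior": a.prior, **({"lr": a.lr} if a.lr is not None else {})}
                for a in self.archetypes
            ],
            "stream": _stream_to_dict(self.stream),
            "bias": {
                "w_confirming": self.policy.w_confirming,
                "w_disconfirming": self.policy.w_disconfirming,
                "threshold": self.policy.threshold,
            },
            "seed": self.seed,
            "output_dir": self.output_dir,
        }
        return d


def _stream_to_dict(s: StreamSpec) -> dict[str, Any]:
    d: dict[str, Any] = {"mode": s.mode, "n_trials": s.n_trials}
    if s.lr is not None:
        d["lr"] = s.lr
    if s.mode == "mixed":
        d["n_favoring_A"] = s.n_favoring_A
        d["n_favoring_B"] = s.n_favoring_B
        d["seed"] = s.seed
    if s.mode == "binomial":
        d["design"] = {
            "n_per_arm": s.design.n_per_arm,
            "p_success_A_under_HA": s.design.p_success_A_under_HA,
            "p_success_B_under_HA": s.design.p_success_B_under_HA,
            "p_success_A_under_HB": s.design.p_success_A_under_HB,
            "p_success_B_under_HB": s.design.p_success_B_under_HB,
        }
        d["true_hypothesis"] = s.true_hypothesis
        d["seed"] = s.seed
    return d


def _require_keys(mapping: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {', '.join(sorted(unknown))}")


def _probability(value: Any, name: str) -> float:
    try:
        p = float(value)
    except (TypeError, ValueError):
        raise ConfigError(f"{name} must be a number, got {value!r}") from None
    if not 0.0 <= p <= 1.0:
        raise ConfigError(f"{name} must lie in [0, 1], got {p}")
    return p


def _parse_stream(raw: Mapping[str, Any]) -> StreamSpec:
    _require_keys(
        raw,
        {"mode", "n_trials", "lr", "n_favoring_A", "n_favoring_B", "design", "true_hypothesis", "seed"},
        "stream",
    )
    mode = raw.get("mode", "fixed")
    kwargs: dict[str, Any] = {
        "n_trials": int(raw.get("n_trials", 0)),
        "mode": mode,
        "seed": int(raw.get("seed", 0)),
    }
    if "lr" in raw:
        lr = float(raw["lr"])
        if lr <= 0:
            raise ConfigError(f"stream.lr must be positive, got {lr}")
        kwargs["lr"] = lr
    if mode == "mixed":
        kwargs["n_favoring_A"] = int(raw.get("n_favoring_A", 0))
        kwargs["n_favoring_B"] = int(raw.get("n_favoring_B", 0))
    if mode == "binomial":
        design = raw.get("design")
        if not isinstance(design, Mapping):
            raise ConfigError("stream.design must be a mapping for binomial mode")
        _require_keys(
            design,
            {
                "n_per_arm",
                "p_success_A_under_HA",
                "p_success_B_under_HA",
                "p_success_A_under_HB",
                "p_success_B_under_HB",
            },
            "stream.design",
        )
        kwargs["design"] = TrialDesign(
            n_per_arm=int(design.get("n_per_arm", 0)),
            p_success_A_under_HA=_probability(
                design.get("p_success_A_under_HA"), "stream.design.p_success_A_under_HA"
            ),
            p_success_B_under_HA=_probability(
                design.get("p_success_B_under_HA"), "stream.design.p_success_B_under_HA"
            ),
            p_success_A_under_HB=_probability(
                design.get("p_success_A_under_HB"), "stream.design.p_success_A_under_HB"
            ),
            p_success_B_under_HB=_probability(
                design.get("p_success_B_under_HB"), "stream.design.p_success_B_under_HB"
            ),
        )
        kwargs["true_hypothesis"] = raw.get("true_hypothesis", "HB")
    try:
        return StreamSpec(**kwargs)
    except ValueError as exc:
        raise ConfigError(f"stream: {exc}") from exc


def parse_config(data: Mapping[str, Any], source: str = "<dict>") -> RunConfig:
    """Validate a raw mapping into a :class:`RunConfig`."""
    if not isinstance(data, Mapping):
        raise ConfigError(f"{source}: top level must be a mapping")
    _require_keys(
        data, {"name", "archetypes", "stream", "bias", "seed", "output_dir"}, "config"
    )
    raw_arch = data.get("archetypes")
    if not isinstance(raw_arch, list) or not raw_arch:
        raise ConfigError("archetypes must be a non-empty list")
    archetypes = []
    for i, entry in enumerate(raw_arch):
        if not isinstance(entry, Mapping):
            raise ConfigError(f"archetypes[{i}] must be a mapping")
        _require_keys(entry, {"name", "prior", "lr"}, f"archetypes[{i}]")
        prior = _probability(entry.get("prior"), f"archetypes[{i}].prior")
        if not 0.0 < prior < 1.0:
            raise ConfigError(f"archetypes[{i}].prior must lie strictly in (0, 1), got {prior}")
        lr = entry.get("lr")
        if lr is not None:
            lr = float(lr)
            if lr <= 0:
                raise ConfigError(f"archetypes[{i}].lr must be positive, got {lr}")
        archetypes.append(ArchetypeSpec(name=str(entry.get("name", f"archetype{i}")), prior=prior, lr=lr))
    if "stream" not in data:
        raise ConfigError("missing required section: stream")
    stream = _parse_stream(data["stream"])
    raw_bias = data.get("bias", {})
    if not isinstance(raw_bias, Mapping):
        raise ConfigError("bias must be a mapping")
    _require_keys(raw_bias, {"w_confirming", "w_disconfirming", "threshold"}, "bias")
    try:
        policy = BiasPolicy(
            w_confirming=float(raw_bias.get("w_confirming", 1.0)),
            w_disconfirming=float(raw_bias.get("w_disconfirming", 1.0)),
            threshold=float(raw_bias.get("threshold", 0.5)),
        )
    except ValueError as exc:
        raise ConfigError(f"bias: {exc}") from exc
    return RunConfig(
        name=str(data.get("name", "scenario")),
        archetypes=tuple(archetypes),
        stream=stream,
        policy=policy,
        seed=int(data.get("seed", 0)),
        output_dir=str(data.get("output_dir", "out")),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix == ".json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if data is None:
        raise ConfigError(f"{path} is empty")
    return parse_config(data, source=str(path))


def reference_config(seed: int = 0, output_dir: str = "out") -> RunConfig:
    """The shipped archetype-comparison configuration: three surgeons, ten
    constant B-favouring trials each at the archetype-calibrated LR, bias
    exponent 0.5 on disconfirming evidence."""
    from .scenarios import DEFAULT_ARCHETYPE_LRS, surgeon_archetypes

    return RunConfig(
        name="archetype-comparison",
        archetypes=tuple(
            ArchetypeSpec(a.name, a.prior, DEFAULT_ARCHETYPE_LRS[a.name])
            for a in surgeon_archetypes()
        ),
        stream=StreamSpec(n_trials=10, mode="fixed", lr=0.72),
        policy=BiasPolicy.confirmation_bias(0.5),
        seed=seed,
        output_dir=output_dir,
    )
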