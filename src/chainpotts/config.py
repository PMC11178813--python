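"""Run configuration: YAML parsing, validation, and materialization.

A config file is a nested key/value document with three optional sections::

    seed: 1
    output: runs/demo
    snapshot_every: 0      # cycles between snapshot exports; 0 = never
    verbose: false
    model:                 # any ModelParams field; defaults are the
      Gamma_R: 4.0         # reference defaults
    sweep:
      gamma_r_grid: [0, 1, 2, 3, 4, 6, 10, 16]
      seeds: [1, 2, 3]
      scale: reduced

An empty file yields the pure defaults.  Unknown keys anywhere are hard
errors naming the key; parameter-invariant violations are hard errors too,
except the ECM-stability condition ``2 gamma_E < gamma_C``, which only
warns (deliberate exploration of the unstable regime is allowed).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .params import ModelParams, ParameterError
from .scenarios import SweepPlan


class ConfigError(ValueError):
    """A config file is malformed or violates a model invariant."""


@dataclass(frozen=True)
class RunConfig:
    params: ModelParams
    sweep: SweepPlan
    seed: int = 1
    output: str = "runs/out"
    snapshot_every: int = 0
    verbose: bool = False

    def resolved_yaml(self) -> str:
        """The fully materialized config (all defaults explicit)."""
        doc = dict(
            seed=self.seed,
            output=self.output,
            snapshot_every=self.snapshot_every,
            verbose=self.verbose,
            model={k: getattr(self.params, k) for k in ModelParams.field_names()},
            sweep=dict(
                gamma_r_grid=list(self.sweep.gamma_r_grid),
                seeds=list(self.sweep.seeds),
                scale=self.sweep.scale,
            ),
        )
        return yaml.safe_dump(doc, sort_keys=False)


_TOP_KEYS = {"seed", "output", "snapshot_every", "verbose", "model", "sweep"}
_SWEEP_KEYS = {"gamma_r_grid", "seeds", "scale"}


def _reject_unknown(keys, allowed, where: str) -> None:
    unknown = sorted(set(keys) - allowed)
    if unknown:
        raise ConfigError(
            f"unknown key {unknown[0]!r} in {where} "
            f"(allowed: {', '.join(sorted(allowed))})"
        )


def load_config(path) -> RunConfig:
    """Parse and validate a YAML config file, merged over the defaults."""
    text = Path(path).read_text()
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError(f"top level of {path} must be a mapping")
    _reject_unknown(doc, _TOP_KEYS, "top level")

    model_doc = doc.get("model") or {}
    _reject_unknown(model_doc, set(ModelParams.field_names()), "model section")
    try:
        params = ModelParams(**model_doc)
    except ParameterError as exc:
        raise ConfigError(str(exc)) from exc

    sweep_doc = doc.get("sweep") or {}
    _reject_unknown(sweep_doc, _SWEEP_KEYS, "sweep section")
    plan_kwargs = {}
    if "gamma_r_grid" in sweep_doc:
        plan_kwargs["gamma_r_grid"] = tuple(float(g) for g in sweep_doc["gamma_r_grid"])
    if "seeds" in sweep_doc:
        plan_kwargs["seeds"] = tuple(int(s) for s in sweep_doc["seeds"])
    if "scale" in sweep_doc:
        plan_kwargs["scale"] = str(sweep_doc["scale"])
    try:
        plan = SweepPlan(**plan_kwargs)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    return RunConfig(
        params=params,
        sweep=plan,
        seed=int(doc.get("seed", 1)),
        output=str(doc.get("output", "runs/out")),
        snapshot_every=int(doc.get("snapshot_every", 0)),
        verbose=bool(doc.get("verbose", False)),
    )


def default_config() -> RunConfig:
    return RunConfig(params=ModelParams(), sweep=SweepPlan())
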