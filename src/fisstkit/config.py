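"""Run configuration: a flat YAML document with blocks, validated with key paths.

Schema (blocks marked * are optional):

    seed: int
    system:      {kind: harmonic|double_well|polymer, ...kind parameters}
    integrator:  {timestep, friction, beta|temperature, n_steps, scheme*, record_interval*}
    fisst*:      {f_min, f_max, n_points*, update_interval*, freeze_after*}
    ladder*:     {n_replicas, t_base, t_top, mode, exchange_interval*, pooled*}
    analysis*:   [ {type: histogram|force_extension|pmf, ...}, ... ]

Every run is fully reproducible from (config, seed).  CLI flags override
config keys.  A config written back by the tool re-parses to an equivalent run.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Any

import yaml

from .dynamics import IntegratorSettings
from .fisst import FisstBias, FisstState, ForceGrid
from .replica_exchange import LadderConfig
from .systems import ModelSystem, make_double_well_system, make_harmonic_cv_system, make_polymer_system

__all__ = ["ConfigError", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """Configuration schema violation; the message names the offending key path."""


_SYSTEM_KINDS = {
    "harmonic": (make_harmonic_cv_system, {"stiffness", "center"}),
    "double_well": (make_double_well_system, {"barrier", "well_separation", "form", "wall_sharpness"}),
    "polymer": (
        make_polymer_system,
        {"n_beads", "bond_k", "excluded_volume_eps", "n_solvent", "rest_length", "wca_sigma", "box", "seed"},
    ),
}


def _require(block: dict, key: str, path: str):
    if key not in block:
        raise ConfigError(f"missing required key '{path}.{key}'")
    return block[key]


def _check_keys(block: dict, allowed: set, path: str) -> None:
    extra = set(block) - allowed
    if extra:
        raise ConfigError(f"unknown key(s) {sorted(extra)} under '{path}' (allowed: {sorted(allowed)})")


@dataclass
class RunConfig:
    """Validated run description; ``build_*`` methods construct live objects."""

    raw: dict
    seed: int
    system_block: dict
    integrator_block: dict
    fisst_block: dict | None
    ladder_block: dict | None
    analysis_requests: list = field(default_factory=list)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.raw, sort_keys=True).encode()).hexdigest()[:16]

    def build_system(self) -> ModelSystem:
        blk = dict(self.system_block)
        kind = blk.pop("kind")
        factory, allowed = _SYSTEM_KINDS[kind]
        return factory(**blk)

    def build_settings(self) -> IntegratorSettings:
        blk = dict(self.integrator_block)
        if "temperature" in blk:
            blk["beta"] = 1.0 / float(blk.pop("temperature"))
        blk.setdefault("seed", self.seed)
        try:
            return IntegratorSettings(**blk)
        except ValueError as exc:
            raise ConfigError(f"integrator: {exc}") from exc

    def build_fisst_state(self, beta: float) -> FisstState | None:
        if self.fisst_block is None:
            return None
        blk = self.fisst_block
        grid = ForceGrid(
            f_min=float(blk["f_min"]),
            f_max=float(blk["f_max"]),
            n_points=int(blk.get("n_points", 121)),
        )
        return FisstState(grid, beta=beta, update_interval=int(blk.get("update_interval", 500)))

    def build_fisst_bias(self, beta: float) -> FisstBias | None:
        state = self.build_fisst_state(beta)
        if state is None:
            return None
        return FisstBias(state, freeze_after=self.fisst_block.get("freeze_after"))

    def build_ladder(self) -> LadderConfig | None:
        if self.ladder_block is None:
            return None
        blk = self.ladder_block
        try:
            return LadderConfig(
                n_replicas=int(blk["n_replicas"]),
                t_base=float(blk["t_base"]),
                t_top=float(blk["t_top"]),
                mode=blk.get("mode", "temperature_re"),
                exchange_interval=int(blk.get("exchange_interval", 100)),
            )
        except ValueError as exc:
            raise ConfigError(f"ladder: {exc}") from exc

    @property
    def pooled(self) -> bool:
        return bool((self.ladder_block or {}).get("pooled", False))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.raw, sort_keys=True)


def load_config(source) -> RunConfig:
    """Parse and validate a YAML config from a path or string."""
    if isinstance(source, str) and "\n" in source:
        doc = yaml.safe_load(source)
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(doc, {"seed", "system", "integrator", "fisst", "ladder", "analysis", "output"}, "<root>")

    seed = int(doc.get("seed", 0))

    system = _require(doc, "system", "<root>")
    kind = _require(system, "kind", "system")
    if kind not in _SYSTEM_KINDS:
        raise ConfigError(f"system.kind must be one of {sorted(_SYSTEM_KINDS)}, got {kind!r}")
    _check_keys(system, {"kind"} | _SYSTEM_KINDS[kind][1], "system")

    integrator = _require(doc, "integrator", "<root>")
    _check_keys(
        integrator,
        {"timestep", "friction", "beta", "temperature", "n_steps", "scheme", "record_interval", "seed"},
        "integrator",
    )
    for key in ("timestep", "friction", "n_steps"):
        _require(integrator, key, "integrator")
    if "beta" not in integrator and "temperature" not in integrator:
        raise ConfigError("missing required key 'integrator.beta' (or 'integrator.temperature')")

    fisst = doc.get("fisst")
    if fisst is not None:
        _check_keys(fisst, {"f_min", "f_max", "n_points", "update_interval", "freeze_after"}, "fisst")
        for key in ("f_min", "f_max"):
            _require(fisst, key, "fisst")

    ladder = doc.get("ladder")
    if ladder is not None:
        _check_keys(
            ladder,
            {"n_replicas", "t_base", "t_top", "mode", "exchange_interval", "pooled"},
            "ladder",
        )
        for key in ("n_replicas", "t_base", "t_top"):
            _require(ladder, key, "ladder")

    analysis = doc.get("analysis", []) or []
    if not isinstance(analysis, list):
        raise ConfigError("'analysis' must be a list of request mappings")
    for i, req in enumerate(analysis):
        if not isinstance(req, dict) or "type" not in req:
            raise ConfigError(f"analysis[{i}] must be a mapping with a 'type' key")
        if req["type"] not in ("histogram", "force_extension", "pmf"):
            raise ConfigError(f"analysis[{i}].type must be histogram|force_extension|pmf")

    cfg = RunConfig(
        raw=doc,
        seed=seed,
        system_block=system,
        integrator_block={k: v for k, v in integrator.items()},
        fisst_block=fisst,
        ladder_block=ladder,
        analysis_requests=analysis,
    )
    # construct eagerly so schema violations surface before any compute
    cfg.build_settings()
    cfg.build_system()
    cfg.build_ladder()
    return cfg
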