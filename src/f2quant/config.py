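"""YAML run configuration: parsing, validation, defaults."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .simulate import (DesignConfig, GeneticArchitecture, SimTrait,
                       design_architecture)
from .traits import TraitSpec


class ConfigError(ValueError):
    def __init__(self, errors):
        self.errors = list(errors) if isinstance(errors, (list, tuple)) else [errors]
        super().__init__("; ".join(map(str, self.errors)))


_TOP_KEYS = {"mode", "seed", "output_dir", "design", "architecture", "paths",
             "traits", "pairs", "reml", "power", "log_level"}


@dataclasses.dataclass
class RunConfig:
    mode: str = "simulate"                      # simulate | load
    seed: int = 0
    output_dir: str = "f2quant_out"
    design: DesignConfig = dataclasses.field(default_factory=DesignConfig)
    architecture: GeneticArchitecture = dataclasses.field(
        default_factory=design_architecture)
    pedigree_path: str | None = None
    phenotype_path: str | None = None
    trait_specs: list[TraitSpec] = dataclasses.field(default_factory=list)
    pairs: "str | list[tuple[str, str]]" = "all"
    reml: dict = dataclasses.field(default_factory=dict)
    power_queries: list[dict] = dataclasses.field(default_factory=list)
    log_level: str = "INFO"

    def __post_init__(self):
        if not self.trait_specs:
            self.trait_specs = [TraitSpec(name=t.name, age_column=t.age_column)
                                for t in self.architecture.traits]

    def config_hash(self) -> str:
        payload = {
            "mode": self.mode, "seed": self.seed,
            "design": dataclasses.asdict(self.design),
            "traits": [dataclasses.asdict(t) for t in self.trait_specs],
            "architecture": {
                "traits": [dataclasses.asdict(t) for t in self.architecture.traits],
                "G": self.architecture.G.tolist(),
                "R": self.architecture.R.tolist(),
            },
            "pairs": self.pairs, "reml": self.reml,
            "power": self.power_queries,
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def resolved_pairs(self) -> list[tuple[str, str]]:
        names = [t.name for t in self.trait_specs]
        if self.pairs == "all":
            return [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
        return [tuple(p) for p in self.pairs]


def _build_architecture(node, errors) -> GeneticArchitecture:
    if node in (None, "default"):
        return design_architecture()
    try:
        traits = [SimTrait(**t) for t in node["traits"]]
        return GeneticArchitecture(
            traits=traits, G=np.array(node["G"], dtype=float),
            R=np.array(node["R"], dtype=float))
    except (KeyError, TypeError, ValueError) as exc:
        errors.append(f"architecture: {exc}")
        return design_architecture()


def validate_config(path, strict: bool = True) -> RunConfig:
    """Parse and validate a YAML run configuration.

    Unknown keys raise in strict mode; all cross-field constraints are
    checked and every violation is collected into one :class:`ConfigError`.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw, strict=strict)


def config_from_dict(raw: dict, strict: bool = True) -> RunConfig:
    errors: list[str] = []
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        msg = f"unknown configuration keys: {sorted(unknown)}"
        if strict:
            errors.append(msg)
    mode = raw.get("mode", "simulate")
    if mode not in ("simulate", "load"):
        errors.append(f"mode must be simulate or load, got {mode!r}")

    design = DesignConfig()
    if raw.get("design"):
        node = dict(raw["design"])
        bad = set(node) - {f.name for f in dataclasses.fields(DesignConfig)}
        if bad:
            errors.append(f"unknown design keys: {sorted(bad)}")
        try:
            design = DesignConfig(**{k: v for k, v in node.items() if k not in bad})
        except ValueError as exc:
            errors.append(f"design: {exc}")
    if design.litter_min > design.litter_max:
        errors.append("design: litter_min exceeds litter_max")

    arch = _build_architecture(raw.get("architecture"), errors)

    paths = raw.get("paths") or {}
    ped_path, phe_path = paths.get("pedigree"), paths.get("phenotypes")
    if mode == "load" and (not ped_path or not phe_path):
        errors.append("mode=load requires paths.pedigree and paths.phenotypes")

    specs = []
    sim_names = {t.name for t in arch.traits}
    known_cov = {f"age_{k}" for k in design.age_schedules} | {"age"}
    for node in raw.get("traits") or []:
        try:
            spec = TraitSpec(**node)
        except (TypeError, ValueError) as exc:
            errors.append(f"trait {node!r}: {exc}")
            continue
        if mode == "simulate":
            if spec.name not in sim_names:
                errors.append(f"trait {spec.name!r} not produced by the "
                              "simulation architecture")
            if spec.use_age and spec.age_column not in known_cov:
                errors.append(f"trait {spec.name!r} references undefined "
                              f"covariate {spec.age_column!r}")
            if spec.use_length and spec.length_column not in sim_names:
                errors.append(f"trait {spec.name!r} references undefined "
                              f"length covariate {spec.length_column!r}")
        specs.append(spec)
    if not specs:
        if mode == "simulate":
            specs = [TraitSpec(name=t.name, age_column=t.age_column)
                     for t in arch.traits]
        else:
            errors.append("mode=load requires an explicit trait list")

    pairs = raw.get("pairs", "all")
    if pairs != "all":
        names = {s.name for s in specs}
        for p in pairs:
            if len(p) != 2 or p[0] not in names or p[1] not in names:
                errors.append(f"invalid trait pair {p!r}")

    if errors:
        raise ConfigError(errors)
    return RunConfig(
        mode=mode, seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "f2quant_out")),
        design=design, architecture=arch,
        pedigree_path=ped_path, phenotype_path=phe_path,
        trait_specs=specs, pairs=pairs, reml=raw.get("reml") or {},
        power_queries=raw.get("power") or [],
        log_level=str(raw.get("log_level", "INFO")))
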