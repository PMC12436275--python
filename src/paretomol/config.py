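"""Run configuration: a YAML file describing one pipeline run.

A config gathers file paths, generator and evolution hyperparameters,
the objective list and the reward scheme under one global seed. Unknown
keys are rejected so typos fail loudly. The global seed fans out to
per-stage seeds by fixed offsets, keeping stages reproducible without
seed collisions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path
from typing import Any

import yaml

from .generator import GeneratorConfig
from .rl import EvolutionConfig

#: Fixed per-stage seed offsets derived from the global seed.
SEED_OFFSETS = {
    "corpus": 11,
    "qsar": 23,
    "pretrain": 37,
    "finetune": 53,
    "rl": 71,
    "sample": 97,
}


@dataclass
class ObjectiveConfig:
    """One objective as written in a config file."""

    target_id: str
    direction: str  # high_affinity | low_affinity
    model_path: str | None = None
    threshold: float = 0.5


@dataclass
class RunConfig:
    """Validated run configuration with defaults filled in."""

    corpus_path: str | None = None
    ligand_table: str | None = None
    checkpoint_dir: str = "checkpoints"
    output_dir: str = "outputs"
    scheme: str = "pareto"
    seed: int = 0
    generator: GeneratorConfig | None = None
    evolution: EvolutionConfig = field(default_factory=EvolutionConfig)
    objectives: list[ObjectiveConfig] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.scheme not in ("weighted", "pareto"):
            raise ValueError(f"scheme must be weighted or pareto, "
                             f"got {self.scheme!r}")

    def stage_seed(self, stage: str) -> int:
        return (self.seed + SEED_OFFSETS[stage]) % (2 ** 31)

    def validate_paths(self) -> None:
        for name in ("corpus_path", "ligand_table"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name}: {value} does not exist")


def _check_unknown(section: str, data: dict[str, Any], cls) -> None:
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) in {section}: {sorted(unknown)}")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    _check_unknown("config", raw, RunConfig)
    gen_cfg = None
    if "generator" in raw:
        gen_data = raw.pop("generator")
        _check_unknown("generator", gen_data, GeneratorConfig)
        if "vocab_size" not in gen_data:
            raise ValueError("generator section missing required key "
                             "'vocab_size'")
        gen_cfg = GeneratorConfig(**gen_data)
    evo_cfg = EvolutionConfig()
    if "evolution" in raw:
        evo_data = raw.pop("evolution")
        _check_unknown("evolution", evo_data, EvolutionConfig)
        evo_cfg = EvolutionConfig(**evo_data)
    objectives = []
    for obj in raw.pop("objectives", []):
        _check_unknown("objective", obj, ObjectiveConfig)
        objectives.append(ObjectiveConfig(**obj))
    return RunConfig(generator=gen_cfg, evolution=evo_cfg,
                     objectives=objectives, **raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    data = asdict(config)
    if data["generator"] is None:
        del data["generator"]
    yaml.safe_dump(data, Path(path).open("w"), sort_keys=False)
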