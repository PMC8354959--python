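"""Run configuration: one YAML file with blocks per pipeline stage.

Blocks mirror the dataclasses of the individual modules (network ->
NetworkConfig, training -> TrainConfig, erasing -> ErasingConfig) plus
post-processing and evaluation options and a global seed.  Every block is
validated by its owning dataclass before any work starts, and each CLI run
writes the fully resolved configuration next to its outputs so a run can be
reproduced from its artifacts alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .erasing import ErasingConfig
from .trainer import TrainConfig
from .vae import NetworkConfig


@dataclass
class PostprocessingConfig:
    erosion_radius: int = 1
    median_size: int = 3

    def __post_init__(self):
        if self.erosion_radius < 0 or self.median_size < 1:
            raise ValueError("invalid post-processing parameters")


@dataclass
class EvaluationConfig:
    search_iterations: int = 10
    slice_axis: int = 2

    def __post_init__(self):
        if self.search_iterations < 1:
            raise ValueError("search_iterations must be >= 1")


@dataclass
class RunConfig:
    seed: int = 0
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    erasing: ErasingConfig = field(default_factory=lambda: ErasingConfig("none"))
    postprocessing: PostprocessingConfig = field(default_factory=PostprocessingConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    def __post_init__(self):
        # the training block carries the erasing block so the trainer sees it
        self.training.erasing = self.erasing


def _tupleize(d: dict, keys) -> dict:
    for k in keys:
        if k in d and isinstance(d[k], list):
            d[k] = tuple(d[k])
    return d


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Build a validated RunConfig from a YAML file plus override mapping."""
    raw: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    for key, val in (overrides or {}).items():
        block, _, name = key.partition(".")
        if name:
            raw.setdefault(block, {})[name] = val
        elif val is not None:
            raw[block] = val

    net = _tupleize(dict(raw.get("network", {})), ["stage_channels"])
    tr = dict(raw.get("training", {}))
    tr.pop("erasing", None)
    er = _tupleize(dict(raw.get("erasing", {})), ["budget_range", "slab_range"])
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        network=NetworkConfig(**net),
        training=TrainConfig(**tr),
        erasing=ErasingConfig(**er) if er else ErasingConfig("none"),
        postprocessing=PostprocessingConfig(**raw.get("postprocessing", {})),
        evaluation=EvaluationConfig(**raw.get("evaluation", {})),
    )


def dump_config(cfg: RunConfig, path) -> None:
    data = {
        "seed": cfg.seed,
        "network": asdict(cfg.network),
        "training": asdict(cfg.training),
        "erasing": asdict(cfg.erasing),
        "postprocessing": asdict(cfg.postprocessing),
        "evaluation": asdict(cfg.evaluation),
    }
    data["training"].pop("erasing", None)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
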