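"""YAML configuration loading for the pipeline."""
from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .pipeline import PipelineConfig
from .segmentation import SnakeConfig


def load_config(path: str | Path | None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file.

    Top-level keys map to ``PipelineConfig`` fields; the ``snake`` key holds
    a mapping of :class:`SnakeConfig` fields.  Missing keys keep defaults.
    """
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    snake_doc = doc.pop("snake", {}) or {}
    valid_snake = {f.name for f in fields(SnakeConfig)}
    unknown = set(snake_doc) - valid_snake
    if unknown:
        raise ValueError(f"unknown snake config keys: {sorted(unknown)}")
    snake = SnakeConfig(**snake_doc)
    valid = {f.name for f in fields(PipelineConfig)} - {"snake"}
    unknown = set(doc) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(snake=snake, **doc)
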