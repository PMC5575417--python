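"""Pipeline configuration: YAML/JSON file mirroring the runtime dataclasses.

Defaults reproduce the screening algorithm as published: the packaged
22-term lexicon, all four context filters enabled, positivity threshold 9.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .context import FILTER_NAMES, FilterConfig
from .lexicon import Lexicon, default_lexicon, load_lexicon
from .scoring import ClassifierConfig


@dataclass(frozen=True)
class PipelineConfig:
    lexicon_path: Optional[str] = None  # None -> packaged default lexicon
    threshold: int = 9
    disabled_filters: tuple[str, ...] = ()
    negation_window: int = 5
    subject_window: int = 5
    template_repeat_threshold: int = 5
    seed: int = 0
    log_level: str = "INFO"

    def load_lexicon(self) -> Lexicon:
        if self.lexicon_path is None:
            return default_lexicon()
        return load_lexicon(self.lexicon_path)

    def filter_config(self) -> FilterConfig:
        enabled = frozenset(FILTER_NAMES) - frozenset(self.disabled_filters)
        return FilterConfig(
            negation_window=self.negation_window,
            subject_window=self.subject_window,
            template_repeat_threshold=self.template_repeat_threshold,
            enabled_filters=enabled,
        )

    def classifier_config(self) -> ClassifierConfig:
        return ClassifierConfig(threshold=self.threshold)


def load_pipeline_config(path: Union[str, Path]) -> PipelineConfig:
    """Read a YAML (or JSON) config file; unknown keys are rejected."""
    with open(path, encoding="utf-8") as handle:
        raw = yaml.safe_load(handle) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}")
    if "disabled_filters" in raw:
        raw["disabled_filters"] = tuple(raw["disabled_filters"])
    return PipelineConfig(**raw)
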