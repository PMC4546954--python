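"""Flat key=value run configuration.

Known keys (with defaults) cover the thresholds, allow-list, classifier
parameters and cross-validation controls of the pipeline; unknown keys are
rejected so typos fail loudly. The effective configuration is echoed into
every evaluation report.
"""
from __future__ import annotations

from pathlib import Path
from typing import Mapping, Optional, Union

from .concept_ranking import DEFAULT_ALLOWED_TYPES, RankerConfig
from .exceptions import ConfigurationError

DEFAULTS: dict[str, object] = {
    "ranker.np_threshold": 600,
    "ranker.vp_threshold": 700,
    "ranker.allowed_types": "|".join(sorted(DEFAULT_ALLOWED_TYPES)),
    "chunker.backend": "rule",
    "tagger.backend": "rule",
    "clf.kind": "nb",
    "clf.alpha": 1.0,
    "clf.cost": 0.5,
    "clf.gamma": 0.05,
    "eval.k": 10,
    "eval.seed": 42,
}


def load_config(path: Optional[Union[str, Path]] = None,
                overrides: Optional[Mapping[str, object]] = None) -> dict[str, object]:
    """Merge defaults, an optional key=value file, and in-process overrides."""
    cfg = dict(DEFAULTS)
    if path is not None:
        for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ConfigurationError(f"config line {lineno}: expected key=value")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in cfg:
                raise ConfigurationError(f"config line {lineno}: unknown key {key!r}")
            cfg[key] = _coerce(cfg[key], value)
    for key, value in (overrides or {}).items():
        if key not in cfg:
            raise ConfigurationError(f"unknown config key {key!r}")
        cfg[key] = value
    return cfg


def _coerce(default: object, raw: str) -> object:
    if isinstance(default, bool):
        return raw.lower() in ("1", "true", "yes")
    if isinstance(default, int):
        return int(raw)
    if isinstance(default, float):
        return float(raw)
    return raw


def ranker_config_from(cfg: Mapping[str, object]) -> RankerConfig:
    allowed = frozenset(
        t for t in str(cfg["ranker.allowed_types"]).split("|") if t
    )
    return RankerConfig(
        np_threshold=int(cfg["ranker.np_threshold"]),
        vp_threshold=int(cfg["ranker.vp_threshold"]),
        allowed_semantic_types=allowed,
    )
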