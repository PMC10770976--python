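"""YAML configuration: defaults < config file < CLI overrides.

The schema is the nested default tree below; unknown keys anywhere in a
config file or override set are rejected with the offending key paths
named.  Every run logs its fully resolved configuration.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .detector import DetectorConfig
from .evaluate import DEFAULT_TAUS
from .quantify import DEFAULT_THRESHOLD, GRAY_MODES
from .synth import SceneSpec

logger = logging.getLogger(__name__)


def _defaults() -> dict:
    return {
        "seed": 0,
        "verbosity": "info",
        "detector": asdict(DetectorConfig()),
        "quantify": {
            "threshold": DEFAULT_THRESHOLD,
            "gray_mode": "mean",
        },
        "evaluate": {
            "taus": list(DEFAULT_TAUS),
            "mode": "macro",
        },
        "synth": asdict(SceneSpec()),
    }


class ConfigError(ValueError):
    pass


def _merge(base: dict, update: dict, path: str = "") -> list[str]:
    """Merge ``update`` into ``base`` in place; return unknown key paths."""
    bad = []
    for key, val in update.items():
        here = f"{path}.{key}" if path else str(key)
        if key not in base:
            bad.append(here)
            continue
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                bad.append(f"{here} (expected a mapping)")
                continue
            bad += _merge(base[key], val, here)
        else:
            base[key] = val
    return bad


@dataclass
class RunConfig:
    seed: int
    verbosity: str
    detector: DetectorConfig
    quantify: dict
    evaluate: dict
    synth: SceneSpec
    resolved: dict = field(repr=False, default_factory=dict)

    def log_resolved(self) -> None:
        logger.info("fluorocell %s resolved config: %s", __version__, self.resolved)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load and validate a run configuration.

    ``path`` may be None (all defaults); an empty file is also all
    defaults.  ``overrides`` is a nested dict applied on top of the file.
    """
    tree = _defaults()
    bad: list[str] = []
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        bad += _merge(tree, loaded)
    if overrides:
        bad += _merge(tree, copy.deepcopy(overrides))
    if bad:
        raise ConfigError("unknown config keys: " + ", ".join(sorted(bad)))

    # coerce tuple-valued fields YAML renders as lists
    det = dict(tree["detector"])
    synth = dict(tree["synth"])
    synth["semi_axis_range"] = tuple(synth["semi_axis_range"])
    if tree["quantify"]["gray_mode"] not in GRAY_MODES:
        raise ConfigError(f"quantify.gray_mode must be one of {GRAY_MODES}")
    if tree["quantify"]["threshold"] < 0:
        raise ConfigError("quantify.threshold must be >= 0")
    if tree["evaluate"]["mode"] not in ("macro", "micro"):
        raise ConfigError("evaluate.mode must be 'macro' or 'micro'")
    cfg = RunConfig(
        seed=int(tree["seed"]),
        verbosity=str(tree["verbosity"]),
        detector=DetectorConfig(**det),
        quantify=dict(tree["quantify"]),
        evaluate={"taus": tuple(tree["evaluate"]["taus"]),
                  "mode": tree["evaluate"]["mode"]},
        synth=SceneSpec(**synth),
        resolved=tree,
    )
    return cfg


def setup_logging(verbosity: str = "info") -> None:
    """Logging to stderr only; stdout stays clean for piping."""
    level = getattr(logging, verbosity.upper(), logging.INFO)
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        force=True,
    )
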