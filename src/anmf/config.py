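"""YAML config handling for hyperparameters."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .encoder import CorruptionSpec
from .training import HyperParams

__all__ = ["load_hyperparams", "hyperparams_to_dict"]


def load_hyperparams(path: str | Path | None = None, **overrides) -> HyperParams:
    """Build :class:`HyperParams` from an optional YAML file plus overrides.

    The file mirrors the dataclass fields; ``noise`` is a mapping with
    ``kind`` / ``level`` keys.  CLI flags (passed as ``overrides``) win
    over file values.
    """
    values: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    noise = values.pop("noise", None)
    hp = HyperParams(**values)
    if noise is not None:
        if isinstance(noise, dict):
            hp.noise = CorruptionSpec(**noise)
        else:
            hp.noise = CorruptionSpec(kind=str(noise))
    return hp


def hyperparams_to_dict(hp: HyperParams) -> dict:
    d = asdict(hp)
    d["noise"] = {"kind": hp.noise.kind, "level": hp.noise.level, "seed": hp.noise.seed}
    return d
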