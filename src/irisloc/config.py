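"""Run configuration: one YAML file, CLI overrides, resolved dump."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

from .candidates import CandidateConfig
from .ferns import Hyperparams

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a run needs, serializable to a flat YAML mapping."""

    candidates: CandidateConfig = CandidateConfig()
    hyperparams: Hyperparams = Hyperparams(T=5, K=50, P=100)
    n_init: int = 5
    seed: int = 0
    eye_region_margin: float = 0.4
    eye_region_min_size: int = 24
    error_convention: str = "worst"

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path, **overrides) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    raw.update({k: v for k, v in overrides.items() if v is not None})
    cand = raw.pop("candidates", {})
    if cand and isinstance(cand.get("sigmas"), list):
        cand["sigmas"] = tuple(cand["sigmas"])
    if cand and isinstance(cand.get("r_bounds_frac"), list):
        cand["r_bounds_frac"] = tuple(cand["r_bounds_frac"])
    hp = raw.pop("hyperparams", {})
    return RunConfig(
        candidates=CandidateConfig(**cand),
        hyperparams=Hyperparams(**hp),
        **raw,
    )


def save_config(path, config: RunConfig) -> None:
    """Write the resolved configuration of a run."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
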