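"""Run configuration: study design, cohorts, filters and test settings.

A run is fully reproducible from (config, seed); :func:`load_config` /
:func:`save_config` round-trip the configuration through YAML so every
simulation can carry a provenance sidecar.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Union

import yaml

from .respondents import CohortSpec, ParticipantProfile, expert_cohorts, mturk_cohorts
from .stimuli import StudyConfig

__all__ = ["RunConfig", "load_config", "save_config", "preset_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to simulate and analyze one study."""

    study: StudyConfig = field(default_factory=StudyConfig)
    cohorts: tuple[CohortSpec, ...] = ()
    rt_cutoff: float = 5000.0
    consistency_threshold: float = 0.20
    adjust_method: str = "bh"
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.adjust_method not in ("bh", "holm", "bonferroni"):
            raise ValueError(f"unknown adjust_method {self.adjust_method!r}")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


def preset_config(name: str, seed: int = 0) -> RunConfig:
    """Built-in study presets.

    ``mturk`` — 50 participants per layout (4,500 responses);
    ``expert`` — 10 participants per layout (900 responses).
    """
    if name == "mturk":
        cohorts = tuple(mturk_cohorts())
    elif name == "expert":
        cohorts = tuple(expert_cohorts())
    else:
        raise ValueError(f"unknown preset {name!r}; choose 'mturk' or 'expert'")
    return RunConfig(study=StudyConfig(rng_seed=seed), cohorts=cohorts, seed=seed)


def save_config(config: RunConfig, path: Union[str, Path]) -> Path:
    path = Path(path)
    data = asdict(config)
    path.write_text(yaml.safe_dump(data, sort_keys=False), encoding="utf-8")
    return path


def load_config(path: Union[str, Path]) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    study = StudyConfig(**{
        **data.get("study", {}),
        "layouts": tuple(data.get("study", {}).get("layouts", StudyConfig().layouts)),
    })
    cohorts = tuple(
        CohortSpec(
            layout=c["layout"],
            n_participants=c["n_participants"],
            profile=ParticipantProfile(**c["profile"]),
        )
        for c in data.get("cohorts", [])
    )
    kwargs = {
        k: data[k]
        for k in ("rt_cutoff", "consistency_threshold", "adjust_method", "alpha", "seed")
        if k in data
    }
    return RunConfig(study=study, cohorts=cohorts, **kwargs)
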