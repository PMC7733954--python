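"""Configuration, serialization and tabular output.

Configs are YAML (JSON accepted — it is a YAML subset) with keys:

.. code-block:: yaml

    design:
      builder: {name: acquisition, n_trials: 60, trials_per_block: 10}
      # or an explicit trial list:
      # trials: [{cues: [CS], us: US, reinforced: true, n_epochs: 4}, ...]
      # blocks: [T1, T1, ...]
    subject:            # single-subject runs
      alpha: {CS: 0.3}
      beta: {US: 0.5}
      c: 1.0
      decay_per_epoch: 1.0
    population:         # population runs (mutually exclusive with subject)
      n_subjects: 50
      alpha_distribution: {family: beta, params: [2, 2]}
      beta_distribution: {family: beta, params: [2, 2]}
      count_scale: 20
    seed: 0
    log_level: INFO

Every CSV written through :func:`write_csv` gets a ``<path>.meta.json``
sidecar recording the seed and the sha256 hash of the canonical config,
so outputs are traceable to the exact configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Dict, Optional

import pandas as pd
import yaml

from .core import ConfigurationError, LinkMatrix, SubjectParams
from .designs import (
    Design,
    Trial,
    build_acquisition,
    build_compound,
    build_extinction,
    build_partial_reinforcement,
    build_reversal,
)
from .population import DistributionSpec, PopulationSpec

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "config_hash",
    "design_from_dict",
    "design_to_dict",
    "subject_from_dict",
    "subject_to_dict",
    "population_from_dict",
    "write_csv",
]

_BUILDERS = {
    "acquisition": build_acquisition,
    "extinction": build_extinction,
    "reversal": build_reversal,
    "compound": build_compound,
    "partial_reinforcement": build_partial_reinforcement,
}


@dataclass
class RunConfig:
    """A fully specified run: design + (subject | population) + seed."""

    design: Dict[str, Any]
    subject: Optional[Dict[str, Any]] = None
    population: Optional[Dict[str, Any]] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.subject is not None and self.population is not None:
            raise ConfigurationError(
                "config must specify subject or population, not both"
            )

    def to_dict(self) -> Dict[str, Any]:
        return {k: v for k, v in asdict(self).items() if v is not None}


def load_config(path) -> RunConfig:
    """Read a YAML/JSON config file into a :class:`RunConfig`."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "design" not in raw:
        raise ConfigurationError(f"config {path} must be a mapping with a 'design' key")
    known = {"design", "subject", "population", "seed", "log_level"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def config_hash(config) -> str:
    """sha256 of the canonical (sorted-key JSON) form of a config."""
    payload = config.to_dict() if isinstance(config, RunConfig) else config
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()
    ).hexdigest()


def design_from_dict(spec: Dict[str, Any]) -> Design:
    """Build a design from a ``builder`` entry or an explicit trial list."""
    if "builder" in spec:
        entry = dict(spec["builder"])
        name = entry.pop("name", None)
        if name not in _BUILDERS:
            raise ConfigurationError(
                f"unknown design builder {name!r}; choose from {sorted(_BUILDERS)}"
            )
        return _BUILDERS[name](**entry)
    if "trials" in spec:
        trials = tuple(
            Trial(
                cues=tuple(t["cues"]),
                us=t["us"],
                reinforced=bool(t.get("reinforced", True)),
                n_epochs=int(t.get("n_epochs", 4)),
                epoch_duration=float(t.get("epoch_duration", 2.5)),
            )
            for t in spec["trials"]
        )
        return Design(trials, tuple(spec.get("blocks", ())))
    raise ConfigurationError("design spec needs a 'builder' or 'trials' key")


def design_to_dict(design: Design) -> Dict[str, Any]:
    return {
        "trials": [
            {
                "cues": list(t.cues),
                "us": t.us,
                "reinforced": t.reinforced,
                "n_epochs": t.n_epochs,
                "epoch_duration": t.epoch_duration,
            }
            for t in design.trials
        ],
        "blocks": list(design.blocks),
    }


def _links_from_dict(spec: Optional[Dict[str, Any]]) -> LinkMatrix:
    if spec is None:
        return LinkMatrix()
    return LinkMatrix(
        cs_links=tuple(spec.get("cs_links", LinkMatrix().cs_links)),
        us_links=tuple(spec.get("us_links", LinkMatrix().us_links)),
    )


def subject_from_dict(spec: Dict[str, Any]) -> SubjectParams:
    try:
        alpha = dict(spec["alpha"])
        beta = dict(spec["beta"])
    except KeyError as exc:
        raise ConfigurationError(f"subject spec missing key {exc}") from None
    return SubjectParams(
        alpha=alpha,
        beta=beta,
        c=float(spec.get("c", 1.0)),
        decay_per_epoch=float(spec.get("decay_per_epoch", 1.0)),
        links=_links_from_dict(spec.get("links")),
    )


def subject_to_dict(params: SubjectParams) -> Dict[str, Any]:
    return {
        "alpha": dict(params.alpha),
        "beta": dict(params.beta),
        "c": params.c,
        "decay_per_epoch": params.decay_per_epoch,
        "links": {
            "cs_links": list(params.links.cs_links),
            "us_links": list(params.links.us_links),
        },
    }


def _dist_from_dict(spec: Optional[Dict[str, Any]]) -> Optional[DistributionSpec]:
    if spec is None:
        return None
    return DistributionSpec(spec["family"], tuple(spec["params"]))


def population_from_dict(spec: Dict[str, Any], seed: Optional[int] = None) -> PopulationSpec:
    kwargs: Dict[str, Any] = {"n_subjects": int(spec["n_subjects"])}
    for key in ("alpha_distribution", "beta_distribution"):
        dist = _dist_from_dict(spec.get(key))
        if dist is not None:
            kwargs[key] = dist
    for key in ("count_scale", "c", "decay_per_epoch"):
        if key in spec:
            kwargs[key] = float(spec[key])
    kwargs["seed"] = int(seed if seed is not None else spec.get("seed", 0))
    if "links" in spec:
        kwargs["links"] = _links_from_dict(spec["links"])
    return PopulationSpec(**kwargs)


def write_csv(df: pd.DataFrame, path, seed: Optional[int] = None, config=None) -> None:
    """Write a tidy CSV plus a ``<path>.meta.json`` provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    meta: Dict[str, Any] = {"rows": int(len(df))}
    if seed is not None:
        meta["seed"] = int(seed)
    if config is not None:
        meta["config_sha256"] = config_hash(config)
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True)
    )
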