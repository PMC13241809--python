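"""Pipeline configuration: defaults, YAML round-trip, provenance hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

from .dynamics import DEFAULT_EPOCHS, SNAPSHOT_AGES
from .fp import ALLOWED_POWERS
from .model import DEFAULT_LEVELS

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the end-to-end pipeline needs, with documented defaults.

    ``input=None`` runs the built-in simulator (a multi-cohort synthetic
    dataset with per-tract-feature ground truths named by ``truth_preset``);
    otherwise ``input`` is a long-format observation CSV/TSV.  FP power set,
    order, centile levels, epochs and snapshot ages default to the canonical
    study conventions.
    """

    input: str | None = None
    output_dir: str = "tractlat_out"
    tracts: tuple[str, ...] = ("AF", "CST")
    features: tuple[str, ...] = ("FA", "volume")
    # simulation-mode design
    n_cohorts: int = 8
    subjects_per_cohort: int = 250
    age_range: tuple[float, float] = (0.0, 100.0)
    sex_ratio: float = 0.537
    left_handed_rate: float = 0.093
    truth_preset: str = "varied"
    # model search
    power_set: tuple[float, ...] = ALLOWED_POWERS
    max_order: int = 3
    strategy: str = "staged"
    age_offset: float = 1.0
    # charts and analytics
    grid_size: int = 500
    levels: tuple[float, ...] = DEFAULT_LEVELS
    contexts: tuple[str, ...] = ("female", "male", "average")
    epochs: tuple[tuple[str, float, float], ...] = tuple(
        (e.name, e.lo, e.hi) for e in DEFAULT_EPOCHS
    )
    snapshot_ages: tuple[float, ...] = SNAPSHOT_AGES
    min_excursion: float = 0.0
    handedness: bool = False
    min_stratum_n: int = 100
    plots: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tracts", "features", "power_set", "levels", "contexts",
                     "snapshot_ages", "age_range"):
            object.__setattr__(self, name, tuple(getattr(self, name)))
        object.__setattr__(
            self, "epochs", tuple(tuple(e) for e in self.epochs)
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for key, val in d.items():
            if isinstance(val, tuple):
                d[key] = list(val)
        d["epochs"] = [list(e) for e in self.epochs]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})

    @property
    def config_hash(self) -> str:
        """Short provenance hash of the scientific parameters.

        The output directory is excluded so the same analysis written to two
        locations produces byte-identical artifacts.
        """
        d = self.to_dict()
        d.pop("output_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
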