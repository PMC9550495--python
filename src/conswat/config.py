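"""Run configuration: thresholds, ML settings, serialisation and hashing.

A :class:`RunConfig` aggregates the labeling thresholds, the feature
calculation knobs and the ML settings into one serialisable object with a
content hash.  The hash is computed over a canonical (sorted-key) JSON
rendering, so it is stable under key reordering and is stamped into every
report a run writes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .features import FeatureConfig
from .labeling import LabelingConfig
from .ml_eval import FAMILIES


@dataclass(frozen=True)
class RunConfig:
    labeling: LabelingConfig = field(default_factory=LabelingConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    seed: int = 17
    tolerance: float = 0.001
    families: tuple[str, ...] = FAMILIES
    float_precision: int = 3

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["families"] = list(self.families)
        return d

    def content_hash(self) -> str:
        """Short stable digest of the configuration content."""
        canonical = json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        labeling = LabelingConfig(**d.get("labeling", {}))
        features = FeatureConfig(**d.get("features", {}))
        extra = {k: v for k, v in d.items() if k not in ("labeling", "features")}
        if "families" in extra:
            extra["families"] = tuple(extra["families"])
        return cls(labeling=labeling, features=features, **extra)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))
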