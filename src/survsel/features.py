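"""Named feature subsets with selection provenance."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path


@dataclasses.dataclass
class FeatureSet:
    """A selector's chosen covariates.

    ``features`` preserves selection order; ``scores`` maps each selected
    feature to the selector's importance (|coefficient| for penalized and
    boosted fits, mean minimal depth for forests — note depths rank low =
    good). ``ranking`` optionally orders *all* candidate features best-first
    and backs the empty-selection fallback in the benchmark layer.
    """

    features: list[str]
    method: str
    tuning: dict = dataclasses.field(default_factory=dict)
    scores: dict = dataclasses.field(default_factory=dict)
    ranking: list[str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate features in FeatureSet")

    def __len__(self) -> int:
        return len(self.features)

    def __contains__(self, name: str) -> bool:
        return name in self.features

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "tuning": self.tuning,
            "features": [
                {"name": f, "score": self.scores.get(f)} for f in self.features
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float))
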