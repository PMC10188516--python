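"""Ground-truth bookkeeping persisted alongside every simulated dataset."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field


@dataclass
class GroundTruth:
    seed: int = 0
    causal_log_or: dict = field(default_factory=dict)        # pesticide -> true log-OR per SD
    covariate_effects: dict = field(default_factory=dict)
    coapplication_clusters: list = field(default_factory=list)  # list of member lists
    toxic_compounds: list = field(default_factory=list)
    combination_effects: dict = field(default_factory=dict)  # "a|b" -> multiplier
    ocr_truth: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))
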