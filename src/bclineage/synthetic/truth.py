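"""Planted ground truth shared by the synthetic generators."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field


@dataclass
class PlantedTruth:
    """What was planted, keyed by the entities that actually exist.

    Only the fields relevant to a given generator are populated.
    """

    entity_subtype: dict[str, str] = field(default_factory=dict)
    entity_cell_type: dict[str, str] = field(default_factory=dict)
    er_status: dict[str, str] = field(default_factory=dict)
    lineage_genes: dict[str, list[str]] = field(default_factory=dict)
    lineage_tfs: dict[str, list[str]] = field(default_factory=dict)
    variants: list[dict] = field(default_factory=list)
    gene_copy_calls: dict[str, str] = field(default_factory=dict)
    image_masks: dict[str, list[list[int]]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            return cls(**json.load(fh))
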