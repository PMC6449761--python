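"""Ortholog-group tables: the unit of cross-genome evidence aggregation.

A table maps (genome_id, gene_id) to an ortholog group id and back; genes
lacking an assignment participate in operons but never in cross-genome
support counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["OrthologTable"]


@dataclass
class OrthologTable:
    # group_id -> {genome_id -> [gene_id, ...]}
    groups: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._reverse: dict[tuple[str, str], str] = {}
        for group, per_genome in self.groups.items():
            for genome_id, gene_ids in per_genome.items():
                for gene_id in gene_ids:
                    self._reverse[(genome_id, gene_id)] = group

    def add(self, group_id: str, genome_id: str, gene_id: str) -> None:
        self.groups.setdefault(group_id, {}).setdefault(genome_id, []).append(gene_id)
        self._reverse[(genome_id, gene_id)] = group_id

    def group_of(self, genome_id: str, gene_id: str) -> str | None:
        return self._reverse.get((genome_id, gene_id))

    def genes_of(self, group_id: str) -> dict[str, list[str]]:
        return self.groups.get(group_id, {})

    def genomes_of(self, group_id: str) -> set[str]:
        return set(self.groups.get(group_id, {}))

    def __len__(self) -> int:
        return len(self.groups)

    def to_frame(self) -> pd.DataFrame:
        records = [
            (group, genome_id, gene_id)
            for group, per_genome in self.groups.items()
            for genome_id, gene_ids in per_genome.items()
            for gene_id in gene_ids
        ]
        return pd.DataFrame(records, columns=["group_id", "genome_id", "gene_id"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "OrthologTable":
        table = cls()
        for row in frame.itertuples(index=False):
            table.add(str(row.group_id), str(row.genome_id), str(row.gene_id))
        return table

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthologTable":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype=str))
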