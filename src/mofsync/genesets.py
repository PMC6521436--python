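"""Flat gene-set collections and the tab-separated GMT interchange format.

Each GMT line holds a set name, a free-text description and one or more
member gene identifiers. Term relations (e.g. an ontology DAG) are out of
scope: sets are flat lists of genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate genes in set {self.name!r}")


@dataclass
class GeneSetCollection:
    """An ordered, name-keyed collection of flat gene sets."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self.sets:
            raise ValueError(f"duplicate gene-set name {gene_set.name!r}")
        self.sets[gene_set.name] = gene_set

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.sets == other.sets

    def intersect(self, universe: Iterable[str]) -> "GeneSetCollection":
        """Restrict every set to genes present in ``universe``; drop emptied sets."""
        universe = set(universe)
        out = GeneSetCollection()
        for gs in self:
            kept = tuple(g for g in gs.genes if g in universe)
            if kept:
                out.add(GeneSet(gs.name, gs.description, kept))
        return out

    def as_dict(self) -> Mapping[str, tuple[str, ...]]:
        return {gs.name: gs.genes for gs in self}


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file.

    Duplicate genes within one line are deduplicated with a warning;
    duplicate set names or lines with fewer than three fields are errors.
    """
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            name, description, *genes = fields
            unique = list(dict.fromkeys(genes))
            if len(unique) != len(genes):
                warnings.warn(
                    f"{path}:{lineno}: duplicate genes in set {name!r} deduplicated",
                    stacklevel=2,
                )
            if name in collection:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            collection.add(GeneSet(name, description, tuple(unique)))
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")
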