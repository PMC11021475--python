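"""Gene-set collections and GMT input/output.

A collection maps a set name to an expected-up gene list and an optional
expected-down list (used only by bidirectional scoring). Directional sets
are serialized to GMT as paired ``NAME_UP`` / ``NAME_DN`` entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["GeneSet", "GeneSetCollection", "read_gmt", "write_gmt"]


@dataclass
class GeneSet:
    name: str
    up: list[str]
    down: list[str] | None = None
    description: str = ""

    def __post_init__(self) -> None:
        self.up = list(dict.fromkeys(self.up))
        if self.down is not None:
            self.down = list(dict.fromkeys(self.down))
            if set(self.up) & set(self.down):
                raise ValueError(f"gene set {self.name!r}: up and down lists overlap")
        if not self.up and not self.down:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def add(self, geneset: GeneSet) -> None:
        self.sets[geneset.name] = geneset

    def names(self) -> list[str]:
        return list(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (name, description, then tab-separated genes)."""
    collection = GeneSetCollection()
    pending_down: dict[str, list[str]] = {}
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: line {line_no} is not a valid GMT record")
        name, description, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if name.endswith("_DN"):
            pending_down[name[:-3]] = genes
        else:
            base = name[:-3] if name.endswith("_UP") else name
            collection.add(GeneSet(base, up=genes, description=description))
    for base, down_genes in pending_down.items():
        if base in collection:
            collection[base].down = list(dict.fromkeys(down_genes))
        else:
            collection.add(GeneSet(base, up=[], down=down_genes, description=""))
    return collection


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = []
    for gs in collection:
        if gs.down:
            lines.append("\t".join([f"{gs.name}_UP", gs.description, *gs.up]))
            lines.append("\t".join([f"{gs.name}_DN", gs.description, *gs.down]))
        else:
            lines.append("\t".join([gs.name, gs.description, *gs.up]))
    Path(path).write_text("\n".join(lines) + "\n")
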