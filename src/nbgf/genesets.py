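"""Gene-set collections and the GMT file dialect."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets; duplicate members are collapsed, order preserved."""

    sets: Mapping[str, GeneSet]

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    @classmethod
    def from_lists(cls, lists: Mapping[str, list[str]]) -> "GeneSetCollection":
        sets = {
            name: GeneSet(name, "", tuple(dict.fromkeys(genes)))
            for name, genes in lists.items()
        }
        return cls(sets)


def read_gmt(path) -> GeneSetCollection:
    """Read a tab-delimited GMT file: name, description, then member genes.

    Duplicate genes within a line are collapsed keeping first occurrence;
    a line with fewer than three fields is an error reported by line number.
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one gene ({len(fields)} fields found)"
                )
            name, description = fields[0], fields[1]
            genes = tuple(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = GeneSet(name, description, genes)
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")
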