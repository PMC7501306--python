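"""Gene sets, gene-set collections and GMT I/O.

A :class:`GeneSet` is a named collection of gene symbols with a source label
(hallmark / curated / oncogenic / go / derived, mirroring MSigDB-style
collections) and, for GO-derived sets, an optional ontology-level tag that is
consumed as provided metadata (no DAG traversal happens here).

Gene symbols are upper-cased and de-duplicated on ingest; inputs are expected
to share one symbol namespace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

SOURCES = ("hallmark", "curated", "oncogenic", "go", "derived")


def _normalize_members(members: Iterable[str]) -> frozenset:
    out = frozenset(str(m).strip().upper() for m in members if str(m).strip())
    return out


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with a source label and optional GO level."""

    name: str
    members: frozenset = field(default_factory=frozenset)
    source: str = "curated"
    go_level: int | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be nonempty")
        object.__setattr__(self, "members", _normalize_members(self.members))
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")
        if self.source not in SOURCES:
            raise ValueError(f"unknown source {self.source!r}; expected one of {SOURCES}")

    def __len__(self) -> int:
        return len(self.members)


class SetCollection:
    """An ordered, name-keyed collection of :class:`GeneSet` objects."""

    def __init__(self, sets: Iterable[GeneSet] = ()):
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            self.add(s)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self._sets:
            raise ValueError(f"duplicate gene set name {gene_set.name!r}")
        self._sets[gene_set.name] = gene_set

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def subset(self, names: Iterable[str]) -> "SetCollection":
        return SetCollection(self._sets[n] for n in names)

    def universe(self) -> frozenset:
        out: set = set()
        for s in self:
            out |= s.members
        return frozenset(out)


def _format_description(gene_set: GeneSet) -> str:
    if gene_set.go_level is not None:
        return f"{gene_set.source};go_level={gene_set.go_level}"
    return gene_set.source


def _parse_description(desc: str) -> tuple[str, int | None]:
    source, go_level = "curated", None
    for part in desc.split(";"):
        part = part.strip()
        if part in SOURCES:
            source = part
        elif part.startswith("go_level="):
            go_level = int(part.split("=", 1)[1])
    return source, go_level


def write_gmt(collection: SetCollection, path: str | Path) -> None:
    """Write tab-separated GMT: name, source-bearing description, members."""
    with open(path, "w") as fh:
        for s in collection:
            members = "\t".join(sorted(s.members))
            fh.write(f"{s.name}\t{_format_description(s)}\t{members}\n")


def read_gmt(path: str | Path) -> SetCollection:
    collection = SetCollection()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            name, desc, members = fields[0], fields[1], fields[2:]
            source, go_level = _parse_description(desc)
            collection.add(GeneSet(name=name, members=frozenset(members), source=source, go_level=go_level))
    return collection
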