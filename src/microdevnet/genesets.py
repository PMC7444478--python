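"""Named gene-set collections (GO-like terms, TF regulons, identity signature).

Serialized as GMT: one set per line, ``name<TAB>description<TAB>member...``.
The description field carries the set category so collections round-trip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

CATEGORIES = ("go_like", "tf_regulon", "signature")


@dataclass
class GeneSetCollection:
    sets: dict[str, set[str]]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        for name, cat in self.categories.items():
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r} for set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def subset(self, category: str) -> "GeneSetCollection":
        names = [n for n in self.sets if self.categories.get(n) == category]
        return GeneSetCollection(
            {n: self.sets[n] for n in names}, {n: category for n in names}
        )

    def sizes(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.sets.items()}

    def flag_outside_universe(self, universe) -> dict[str, set[str]]:
        """Members not in the declared universe, per set (empty dict if clean)."""
        uni = set(universe)
        out = {n: s - uni for n, s in self.sets.items() if s - uni}
        return out

    def to_gmt(self, path) -> None:
        lines = []
        for name in sorted(self.sets):
            cat = self.categories.get(name, "go_like")
            members = "\t".join(sorted(self.sets[name]))
            lines.append(f"{name}\t{cat}\t{members}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        sets: dict[str, set[str]] = {}
        categories: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            name, desc, members = fields[0], fields[1], fields[2:]
            sets[name] = set(m for m in members if m)
            if desc in CATEGORIES:
                categories[name] = desc
        return cls(sets, categories)
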