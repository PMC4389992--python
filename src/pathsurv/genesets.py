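"""Gene-set collections with GMT read/write support."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): set name -> member gene ids."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} has no members")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {name!r} has duplicate members")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def restrict_to(self, universe) -> "GeneSetCollection":
        """Intersect every set with *universe*; drop emptied sets with a warning."""
        uni = set(universe)
        kept: dict[str, list[str]] = {}
        desc: dict[str, str] = {}
        for name, members in self.sets.items():
            inside = [g for g in members if g in uni]
            if not inside:
                warnings.warn(
                    f"gene set {name!r} lies entirely outside the universe; skipped",
                    stacklevel=2,
                )
                continue
            kept[name] = inside
            desc[name] = self.descriptions.get(name, "")
        return GeneSetCollection(kept, desc)

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        sets: dict[str, list[str]] = {}
        desc: dict[str, str] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name, description, *members = parts
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r}")
            sets[name] = [m for m in members if m]
            desc[name] = description
        return cls(sets, desc)

    def to_gmt(self, path) -> None:
        lines = [
            "\t".join([name, self.descriptions.get(name, "")] + list(members))
            for name, members in self.sets.items()
        ]
        Path(path).write_text("\n".join(lines) + "\n")
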