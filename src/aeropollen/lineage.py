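"""Ranked taxonomic lineages with a fixed four-level ladder."""

from __future__ import annotations

from dataclasses import dataclass

#: Rank ladder, shallowest to deepest.
RANKS = ("clade", "family", "genus", "species")

#: Rank assigned when no reference hit survives the gates.
UNASSIGNED = "unassigned"


@dataclass(frozen=True, order=True)
class Lineage:
    """A ranked lineage; empty strings mark ranks below the resolved level.

    Non-empty ranks must form a prefix of the ladder: a species-level
    lineage implies genus, family and clade are filled in.
    """

    clade: str = ""
    family: str = ""
    genus: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        names = self.as_tuple()
        seen_empty = False
        for name in names:
            if name == "":
                seen_empty = True
            elif seen_empty:
                raise ValueError(
                    f"non-empty ranks must form a prefix, got {names!r}"
                )

    def as_tuple(self) -> tuple[str, str, str, str]:
        return (self.clade, self.family, self.genus, self.species)

    @property
    def depth(self) -> int:
        """Number of resolved ranks (0 = fully unresolved)."""
        return sum(1 for name in self.as_tuple() if name)

    @property
    def rank(self) -> str:
        """Deepest resolved rank name, or ``unassigned`` if none."""
        if self.depth == 0:
            return UNASSIGNED
        return RANKS[self.depth - 1]

    @property
    def name(self) -> str:
        """Name at the deepest resolved rank ('' if unresolved)."""
        if self.depth == 0:
            return ""
        return self.as_tuple()[self.depth - 1]

    def truncate(self, depth: int) -> "Lineage":
        """Return this lineage cut to at most ``depth`` resolved ranks."""
        if not 0 <= depth <= len(RANKS):
            raise ValueError(f"depth must be in [0, {len(RANKS)}]")
        names = self.as_tuple()
        kept = tuple(n if i < depth else "" for i, n in enumerate(names))
        return Lineage(*kept)

    def to_path(self) -> str:
        """Semicolon-joined resolved ranks, e.g. ``plants;Betulaceae;Alnus``."""
        return ";".join(n for n in self.as_tuple() if n)

    @classmethod
    def from_path(cls, path: str) -> "Lineage":
        parts = [p for p in path.split(";") if p] if path else []
        if len(parts) > len(RANKS):
            raise ValueError(f"too many ranks in {path!r}")
        parts += [""] * (len(RANKS) - len(parts))
        return cls(*parts)


def lca(lineages) -> Lineage:
    """Lowest common ancestor: deepest rank at which all lineages agree.

    Disagreement already at clade level yields a fully-empty lineage.
    """
    lineages = list(lineages)
    if not lineages:
        raise ValueError("lca of an empty set is undefined")
    first = lineages[0].as_tuple()
    depth = 0
    for level in range(len(RANKS)):
        name = first[level]
        if name and all(l.as_tuple()[level] == name for l in lineages):
            depth = level + 1
        else:
            break
    return lineages[0].truncate(depth)
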