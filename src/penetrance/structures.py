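"""Likelihood-relevant structures extracted from a filtered pedigree.

The penetrance likelihood only depends on a small summary of the pedigree:

* ``A`` — affected (penetrant) carriers,
* ``B`` — obligate non-penetrant carriers (normal individuals through whom
  the allele demonstrably passed),
* ``C`` — normal childless individuals born to an obligate carrier,
* rooted trees of normal individuals descending from an obligate carrier,
* counts of same-sex twin pairs by concordance class,
* consanguineous trees, each split into transmission configurations.

``StructureCounts`` holds that summary and is the single argument the
likelihood is built from.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass(frozen=True)
class NormalTree:
    """A rooted tree of phenotypically normal individuals.

    The root is a normal child of an obligate carrier; every node is
    normal and leaves are childless.  ``member_id`` is kept when the tree
    was extracted from a pedigree (``None`` for trees read from a counts
    file, where only the shape is known).
    """

    children: tuple["NormalTree", ...] = ()
    member_id: Optional[str] = None

    @property
    def depth(self) -> int:
        """Number of generations spanned (a childless root has depth 1)."""
        if not self.children:
            return 1
        return 1 + max(c.depth for c in self.children)

    @property
    def size(self) -> int:
        """Total number of individuals in the tree."""
        return 1 + sum(c.size for c in self.children)

    def member_ids(self) -> list[str]:
        out = [] if self.member_id is None else [self.member_id]
        for c in self.children:
            out.extend(c.member_ids())
        return out

    def shape(self) -> "NormalTree":
        """The same tree with member ids stripped (comparable across sources)."""
        return NormalTree(children=tuple(c.shape() for c in self.children))

    @classmethod
    def two_generation(cls, n_offspring: int) -> "NormalTree":
        """A root with ``n_offspring`` childless children (the common case)."""
        if n_offspring < 1:
            raise ValueError("a 2-generation tree needs at least one offspring")
        return cls(children=tuple(NormalTree() for _ in range(n_offspring)))


@dataclass
class StructureCounts:
    """The filtered-pedigree decomposition that determines the likelihood."""

    n_affected: int = 0
    n_obligate_nonpenetrant: int = 0
    n_normal_childless: int = 0
    normal_trees: list[NormalTree] = field(default_factory=list)
    twin_both_normal: int = 0
    twin_discordant: int = 0
    twin_both_affected: int = 0
    consanguineous_trees: list["ConsanguineousTree"] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        for name in (
            "n_affected",
            "n_obligate_nonpenetrant",
            "n_normal_childless",
            "twin_both_normal",
            "twin_discordant",
            "twin_both_affected",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for tree in self.normal_trees:
            if tree.depth < 2:
                raise ValueError(
                    "normal trees must span at least two generations; "
                    "single normal individuals belong in the childless count"
                )

    @property
    def n_twin_pairs(self) -> int:
        return self.twin_both_normal + self.twin_discordant + self.twin_both_affected

    @property
    def n_members(self) -> int:
        """Individuals accounted for (excluding consanguineous trees)."""
        return (
            self.n_affected
            + self.n_obligate_nonpenetrant
            + self.n_normal_childless
            + sum(t.size for t in self.normal_trees)
            + 2 * self.n_twin_pairs
        )

    @property
    def is_empty(self) -> bool:
        return self.n_members == 0 and not self.consanguineous_trees

    def trees_by_depth(self) -> dict[int, list[NormalTree]]:
        out: dict[int, list[NormalTree]] = {}
        for t in self.normal_trees:
            out.setdefault(t.depth, []).append(t)
        return out

    def merged_with(self, *others: "StructureCounts") -> "StructureCounts":
        """Pool counts and structures (used to combine loop configurations
        with the common, non-inbred part of a pedigree)."""
        merged = StructureCounts(
            n_affected=self.n_affected,
            n_obligate_nonpenetrant=self.n_obligate_nonpenetrant,
            n_normal_childless=self.n_normal_childless,
            normal_trees=list(self.normal_trees),
            twin_both_normal=self.twin_both_normal,
            twin_discordant=self.twin_discordant,
            twin_both_affected=self.twin_both_affected,
            label=self.label,
        )
        for other in others:
            if other.consanguineous_trees:
                raise ValueError("cannot merge counts that still contain loops")
            merged.n_affected += other.n_affected
            merged.n_obligate_nonpenetrant += other.n_obligate_nonpenetrant
            merged.n_normal_childless += other.n_normal_childless
            merged.normal_trees.extend(other.normal_trees)
            merged.twin_both_normal += other.twin_both_normal
            merged.twin_discordant += other.twin_discordant
            merged.twin_both_affected += other.twin_both_affected
        return merged

    def equivalent_to(self, other: "StructureCounts") -> bool:
        """Equality up to tree ordering and member-id labels."""

        def key(counts: "StructureCounts"):
            return (
                counts.n_affected,
                counts.n_obligate_nonpenetrant,
                counts.n_normal_childless,
                sorted(repr(t.shape()) for t in counts.normal_trees),
                counts.twin_both_normal,
                counts.twin_discordant,
                counts.twin_both_affected,
                [
                    sorted(repr(c) for c in tree.configuration_keys())
                    for tree in counts.consanguineous_trees
                ],
            )

        return key(self) == key(other)


@dataclass
class ConsanguineousTree:
    """A marriage-loop substructure with its transmission configurations.

    The allele may have reached the loop's affected descendant through any
    one of ``candidate_transmitters``; each possibility yields one
    configuration (a ``StructureCounts`` over the same loop members).
    """

    members: tuple[str, ...] = ()
    candidate_transmitters: tuple[str, ...] = ()
    configurations: list[StructureCounts] = field(default_factory=list)
    anchor: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if self.candidate_transmitters and len(self.candidate_transmitters) < 2:
            raise ValueError(
                "a consanguineous tree needs at least two candidate transmitters"
            )
        for cfg in self.configurations:
            if cfg.consanguineous_trees:
                raise ValueError("configurations cannot nest consanguineous trees")

    def configuration_keys(self) -> list[tuple]:
        return [
            (
                c.n_affected,
                c.n_obligate_nonpenetrant,
                c.n_normal_childless,
                tuple(sorted(repr(t.shape()) for t in c.normal_trees)),
                c.twin_both_normal,
                c.twin_discordant,
                c.twin_both_affected,
            )
            for c in self.configurations
        ]
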