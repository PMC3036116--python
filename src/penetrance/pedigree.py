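"""Core pedigree data structures.

A pedigree is a directed acyclic family graph of individuals.  The model
downstream concerns a single rare autosomal dominant locus (A, a): affected
individuals are taken to be Aa heterozygotes, normal individuals are either
aa homozygotes or non-penetrant Aa carriers, and married-in spouses are aa
with probability one (rare-allele assumption).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Optional

import networkx as nx

MALE = "male"
FEMALE = "female"
UNKNOWN = "unknown"

AFFECTED = "affected"
NORMAL = "normal"

SEXES = (MALE, FEMALE, UNKNOWN)
PHENOTYPES = (AFFECTED, NORMAL, UNKNOWN)


class PedigreeError(ValueError):
    """A structurally invalid pedigree or annotation."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id``/``mother_id`` are either both set or both ``None``
    (founder).  ``twin_pair_id`` links exactly two same-parent individuals.
    ``designated_carrier`` marks the founder through whom the dominant
    allele is assumed to have entered the family, which resolves the
    ambiguity of a founder couple where either spouse could be the origin.
    """

    id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: str = UNKNOWN
    phenotype: str = UNKNOWN
    twin_pair_id: Optional[str] = None
    designated_carrier: bool = False

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise PedigreeError(f"individual {self.id!r}: invalid sex {self.sex!r}")
        if self.phenotype not in PHENOTYPES:
            raise PedigreeError(
                f"individual {self.id!r}: invalid phenotype {self.phenotype!r}"
            )
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeError(
                f"individual {self.id!r}: father and mother must be both "
                "present or both absent"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None

    @property
    def is_affected(self) -> bool:
        return self.phenotype == AFFECTED

    @property
    def is_normal(self) -> bool:
        return self.phenotype == NORMAL


@dataclass
class Pedigree:
    """A validated family: id -> Individual with resolvable, acyclic parentage."""

    family_id: str = "FAM"
    individuals: dict[str, Individual] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self.individuals.values())

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self.individuals

    def __getitem__(self, individual_id: str) -> Individual:
        try:
            return self.individuals[individual_id]
        except KeyError:
            raise KeyError(
                f"no individual {individual_id!r} in family {self.family_id!r}"
            ) from None

    # -- derived structure --------------------------------------------------
    def parent_graph(self) -> "nx.DiGraph":
        """Directed graph with an edge parent -> child for every parent link."""
        g = nx.DiGraph()
        g.add_nodes_from(self.individuals)
        for ind in self:
            if ind.father_id is not None:
                g.add_edge(ind.father_id, ind.id)
                g.add_edge(ind.mother_id, ind.id)
        return g

    def children_of(self, individual_id: str) -> list[Individual]:
        return [
            ind
            for ind in self
            if individual_id in (ind.father_id, ind.mother_id)
        ]

    def parents_of(self, individual_id: str) -> tuple[Individual, ...]:
        ind = self[individual_id]
        if ind.is_founder:
            return ()
        return (self[ind.father_id], self[ind.mother_id])

    def ancestors_of(self, individual_id: str) -> set[str]:
        """All strict ancestors (blood) of an individual."""
        return nx.ancestors(self.parent_graph(), individual_id)

    def descendants_of(self, individual_id: str) -> set[str]:
        return nx.descendants(self.parent_graph(), individual_id)

    def founders(self) -> list[Individual]:
        return [ind for ind in self if ind.is_founder]

    def affected(self) -> list[Individual]:
        return [ind for ind in self if ind.is_affected]

    def twin_pairs(self) -> dict[str, tuple[Individual, Individual]]:
        pairs: dict[str, list[Individual]] = {}
        for ind in self:
            if ind.twin_pair_id is not None:
                pairs.setdefault(ind.twin_pair_id, []).append(ind)
        return {k: (v[0], v[1]) for k, v in sorted(pairs.items())}

    def designated_carriers(self) -> list[Individual]:
        return [ind for ind in self if ind.designated_carrier]

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        for ind in self:
            if ind.is_founder:
                continue
            for role, pid in (("father", ind.father_id), ("mother", ind.mother_id)):
                if pid not in self.individuals:
                    raise PedigreeError(
                        f"individual {ind.id!r}: {role} {pid!r} not in pedigree"
                    )
            father, mother = self.parents_of(ind.id)
            if father.sex == FEMALE:
                raise PedigreeError(
                    f"individual {ind.id!r}: father {father.id!r} is recorded female"
                )
            if mother.sex == MALE:
                raise PedigreeError(
                    f"individual {ind.id!r}: mother {mother.id!r} is recorded male"
                )

        graph = self.parent_graph()
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            involved = sorted({a for a, _ in cycle})
            raise PedigreeError(
                f"pedigree contains an ancestry cycle involving {involved}"
            )

        seen: dict[str, list[Individual]] = {}
        for ind in self:
            if ind.twin_pair_id is not None:
                seen.setdefault(ind.twin_pair_id, []).append(ind)
        for pair_id, members in seen.items():
            if len(members) != 2:
                raise PedigreeError(
                    f"twin pair {pair_id!r} has {len(members)} member(s); "
                    "exactly 2 required"
                )
            a, b = members
            if (a.father_id, a.mother_id) != (b.father_id, b.mother_id) or a.is_founder:
                raise PedigreeError(
                    f"twin pair {pair_id!r}: members {a.id!r} and {b.id!r} "
                    "must share the same (known) parents"
                )

    # -- editing helpers ----------------------------------------------------
    def with_phenotypes(self, phenotypes: dict[str, str]) -> "Pedigree":
        """A copy of this pedigree with some phenotypes replaced."""
        new = {
            iid: (replace(ind, phenotype=phenotypes[iid]) if iid in phenotypes else ind)
            for iid, ind in self.individuals.items()
        }
        return Pedigree(family_id=self.family_id, individuals=new)
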