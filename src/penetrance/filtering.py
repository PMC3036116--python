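"""Decomposition of a pedigree into likelihood-relevant structures.

Under the single-origin, rare-allele model the dominant allele enters the
family through exactly one founder and travels only along parent-child
(blood) edges; married-in spouses are non-carriers.  Consequently:

* every affected individual carries the allele (penetrant carrier),
* every normal individual on the unique transmission path from the origin
  founder down to an affected descendant is an *obligate non-penetrant*
  carrier,
* every other blood relative with observed phenotype falls into exactly one
  of: childless normal born to an obligate carrier, member of a rooted tree
  of normal individuals hanging off an obligate carrier, or member of a
  same-sex twin pair.

A consanguineous marriage loop breaks path uniqueness: the affected
descendant may have received the allele through either branch of the loop.
Such loops are split into one *configuration* per candidate transmitting
branch; each configuration fixes the transmission path and re-classifies
the loop members by the standard rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx

from .pedigree import UNKNOWN, Individual, Pedigree, PedigreeError
from .structures import ConsanguineousTree, NormalTree, StructureCounts

logger = logging.getLogger("penetrance")

# configuration products beyond this trigger a combinatorial warning
MAX_SILENT_COMBINATIONS = 64


class NothingToEstimateError(PedigreeError):
    """Pedigree contains no affected individuals."""


class AmbiguousFounderError(PedigreeError):
    """Neither member of the top founder couple is designated as the carrier."""


class UnsupportedLoopError(PedigreeError):
    """Inbreeding more tangled than a two-branch marriage loop."""


# ---------------------------------------------------------------------------
# origin and obligate carriers
# ---------------------------------------------------------------------------

def _anc_or_self(graph: nx.DiGraph, node: str) -> set[str]:
    return nx.ancestors(graph, node) | {node}


def find_origin(pedigree: Pedigree) -> str:
    """The individual through whom the allele is assumed to have entered.

    This is the designated carrier if one is annotated, otherwise the
    unique lowest common ancestor-or-self of all affected individuals.
    When that ancestor is only determined up to a founder couple (either
    spouse could have transmitted), explicit designation is required.
    """
    affected = pedigree.affected()
    if not affected:
        raise NothingToEstimateError(
            "pedigree has no affected individuals: nothing to estimate"
        )
    graph = pedigree.parent_graph()
    common: set[str] | None = None
    for ind in affected:
        anc = _anc_or_self(graph, ind.id)
        common = anc if common is None else (common & anc)
    assert common is not None

    designated = pedigree.designated_carriers()
    if len(designated) > 1:
        raise PedigreeError(
            f"more than one designated carrier: {sorted(d.id for d in designated)}"
        )
    if designated:
        origin = designated[0].id
        if origin not in common:
            raise PedigreeError(
                f"designated carrier {origin!r} is not an ancestor of every "
                "affected individual"
            )
        return origin

    if not common:
        raise PedigreeError(
            "affected individuals share no common ancestor; a single allele "
            "origin cannot be assumed"
        )
    minimal = sorted(
        x for x in common if not (nx.descendants(graph, x) & common)
    )
    if len(minimal) == 1:
        return minimal[0]
    if len(minimal) == 2:
        a, b = (pedigree[x] for x in minimal)
        shared_child = any(
            {ind.father_id, ind.mother_id} == {a.id, b.id} for ind in pedigree
        )
        if shared_child:
            raise AmbiguousFounderError(
                f"either member of the founder couple ({a.id!r}, {b.id!r}) could "
                "have transmitted the allele; designate one as the carrier "
                "(sidecar key 'carrier')"
            )
    raise PedigreeError(
        f"cannot resolve a unique allele origin among {minimal}; designate the "
        "carrier founder"
    )


def _path_up(
    pedigree: Pedigree, graph: nx.DiGraph, target: str, origin: str
) -> list[str]:
    """Unique blood path origin -> target (climbing from the target)."""
    path = [target]
    current = target
    while current != origin:
        parents = pedigree.parents_of(current)
        on_line = [p for p in parents if p.id == origin or origin in _anc_or_self(graph, p.id)]
        if len(on_line) > 1:
            raise UnsupportedLoopError(
                f"both parents of {current!r} descend from {origin!r}: "
                "consanguineous loop on the transmission path"
            )
        if not on_line:
            raise PedigreeError(
                f"{target!r} is not a blood descendant of the origin {origin!r}"
            )
        current = on_line[0].id
        path.append(current)
    path.reverse()
    return path


def identify_obligate_carriers(pedigree: Pedigree) -> set[str]:
    """All individuals that must carry the allele (penetrant or not).

    The set is the union of the unique transmission paths from the origin
    founder to every affected individual: the affected themselves plus
    every normal ancestor the allele demonstrably passed through.
    """
    origin = find_origin(pedigree)
    graph = pedigree.parent_graph()
    obligate: set[str] = set()
    for ind in pedigree.affected():
        obligate.update(_path_up(pedigree, graph, ind.id, origin))
    return obligate


# ---------------------------------------------------------------------------
# classification engine
# ---------------------------------------------------------------------------

CLASS_AFFECTED = "affected (penetrant carrier)"
CLASS_OBLIGATE = "obligate non-penetrant carrier"
CLASS_CHILDLESS = "childless normal (child of obligate carrier)"
CLASS_TREE = "normal-tree member"
CLASS_TWIN = "twin"
CLASS_SKIPPED = "excluded (unknown phenotype)"


def _children_map(pedigree: Pedigree) -> dict[str, list[Individual]]:
    out: dict[str, list[Individual]] = {iid: [] for iid in pedigree.individuals}
    for ind in pedigree:
        if ind.father_id is not None:
            out[ind.father_id].append(ind)
            out[ind.mother_id].append(ind)
    for lst in out.values():
        lst.sort(key=lambda i: i.id)
    return out


def _decompose(
    pedigree: Pedigree,
    children: dict[str, list[Individual]],
    scope: set[str],
    obligate: set[str],
    extra_carrier_children: frozenset[str] = frozenset(),
) -> tuple[StructureCounts, dict[str, str]]:
    """Classify every individual in ``scope`` exactly once.

    ``obligate`` members of the scope must carry the allele; members of
    ``extra_carrier_children`` are treated as children of an (out-of-scope)
    obligate carrier, which is how loop-configuration splitting grafts the
    non-transmitting branch onto the loop's common ancestor.
    """
    classification: dict[str, str] = {}
    counts = StructureCounts()

    # -- twin pairs first: they are pulled out of the point counts ----------
    twin_done: set[str] = set()
    for pair_id, (x, y) in pedigree.twin_pairs().items():
        if x.id not in scope or y.id not in scope:
            continue
        if children[x.id] or children[y.id]:
            raise PedigreeError(
                f"twin pair {pair_id!r} ({x.id!r}, {y.id!r}) has offspring; "
                "twin pairs with their own children are unsupported"
            )
        if {x.sex, y.sex} == {"male", "female"}:
            # opposite-sex pairs are necessarily dizygotic: ordinary siblings
            logger.info(
                "twin pair %r is opposite-sex; treated as ordinary siblings", pair_id
            )
            continue
        if UNKNOWN in (x.phenotype, y.phenotype):
            logger.warning(
                "twin pair %r has unknown phenotype; excluded from the likelihood",
                pair_id,
            )
            twin_done.update((x.id, y.id))
            classification[x.id] = classification[y.id] = CLASS_SKIPPED
            continue
        parent_in = [p for p in pedigree.parents_of(x.id) if p.id in obligate]
        if not parent_in:
            raise PedigreeError(
                f"twin pair {pair_id!r} is not born to an obligate carrier; "
                "the twin likelihood terms condition on a carrier parent"
            )
        n_affected = sum(1 for t in (x, y) if t.is_affected)
        if n_affected == 0:
            counts.twin_both_normal += 1
            label = f"{CLASS_TWIN} (both normal)"
        elif n_affected == 1:
            counts.twin_discordant += 1
            label = f"{CLASS_TWIN} (discordant)"
        else:
            counts.twin_both_affected += 1
            label = f"{CLASS_TWIN} (both affected)"
        twin_done.update((x.id, y.id))
        classification[x.id] = classification[y.id] = label

    # -- point counts over the obligate skeleton ----------------------------
    for iid in sorted(obligate & scope):
        if iid in twin_done:
            continue
        ind = pedigree[iid]
        if ind.is_affected:
            counts.n_affected += 1
            classification[iid] = CLASS_AFFECTED
        elif ind.is_normal:
            counts.n_obligate_nonpenetrant += 1
            classification[iid] = CLASS_OBLIGATE
        else:
            logger.warning(
                "obligate carrier %r has unknown phenotype; carries the allele "
                "but contributes no likelihood term",
                iid,
            )
            classification[iid] = CLASS_SKIPPED

    # -- normal descendants of obligate carriers ----------------------------
    def build_subtree(ind: Individual) -> NormalTree | None:
        if ind.phenotype == UNKNOWN:
            logger.warning(
                "individual %r has unknown phenotype; excluded (with descendants) "
                "from the likelihood",
                ind.id,
            )
            classification.setdefault(ind.id, CLASS_SKIPPED)
            return None
        if ind.is_affected:
            raise PedigreeError(
                f"affected individual {ind.id!r} inside a normal tree: "
                "filtering invariant violated"
            )
        kids = []
        for child in children[ind.id]:
            if child.id not in scope or child.id in obligate or child.id in twin_done:
                continue
            sub = build_subtree(child)
            if sub is not None:
                kids.append(sub)
        return NormalTree(children=tuple(kids), member_id=ind.id)

    roots: list[str] = []
    seen_roots: set[str] = set()
    for iid in sorted(obligate & scope):
        for child in children[iid]:
            if (
                child.id in scope
                and child.id not in obligate
                and child.id not in twin_done
                and child.id not in seen_roots
            ):
                roots.append(child.id)
                seen_roots.add(child.id)
    for iid in sorted(extra_carrier_children - seen_roots):
        if iid in scope and iid not in obligate and iid not in twin_done:
            roots.append(iid)
            seen_roots.add(iid)

    for root_id in roots:
        tree = build_subtree(pedigree[root_id])
        if tree is None:
            continue
        if tree.size == 1:
            counts.n_normal_childless += 1
            classification[root_id] = CLASS_CHILDLESS
        else:
            counts.normal_trees.append(tree)
            for member in tree.member_ids():
                classification[member] = CLASS_TREE

    return counts, classification


# ---------------------------------------------------------------------------
# consanguineous loops
# ---------------------------------------------------------------------------

def detect_consanguineous_loops(pedigree: Pedigree) -> list[ConsanguineousTree]:
    """Find marriage loops through which the allele has two possible routes.

    A loop arises when a couple are both blood descendants of the carrier
    lineage and have an affected descendant: the allele may have reached
    that descendant through either spouse's branch.  Only the two-branch
    pattern is supported; anything more tangled raises
    :class:`UnsupportedLoopError`.
    """
    try:
        origin = find_origin(pedigree)
    except NothingToEstimateError:
        return []
    graph = pedigree.parent_graph()
    blood = nx.descendants(graph, origin) | {origin}

    couples: dict[tuple[str, str], list[Individual]] = {}
    for ind in pedigree:
        if ind.is_founder or ind.id not in blood:
            continue
        if ind.father_id in blood and ind.mother_id in blood:
            couples.setdefault((ind.father_id, ind.mother_id), []).append(ind)

    loops: list[ConsanguineousTree] = []
    claimed: set[str] = set()
    for n, ((father, mother), loop_children) in enumerate(
        sorted(couples.items()), start=1
    ):
        # branch point: lowest common blood ancestor of the couple
        common = _anc_or_self(graph, father) & _anc_or_self(graph, mother) & blood
        anchors = [x for x in common if not (nx.descendants(graph, x) & common)]
        if len(anchors) != 1:
            raise UnsupportedLoopError(
                f"couple ({father!r}, {mother!r}): no unique common blood "
                "ancestor; unsupported loop topology"
            )
        anchor = anchors[0]
        if anchor in (father, mother):
            raise UnsupportedLoopError(
                f"couple ({father!r}, {mother!r}): one spouse is an ancestor of "
                "the other; unsupported loop topology"
            )
        tops = []
        for spouse in (father, mother):
            paths = list(nx.all_simple_paths(graph, anchor, spouse))
            if len(paths) != 1:
                raise UnsupportedLoopError(
                    f"multiple blood paths from {anchor!r} to {spouse!r}; "
                    "unsupported loop topology"
                )
            tops.append(paths[0][1])
        if tops[0] == tops[1]:
            raise UnsupportedLoopError(
                f"couple ({father!r}, {mother!r}) share the branch {tops[0]!r}; "
                "unsupported loop topology"
            )

        members: set[str] = set()
        for top in tops:
            members |= nx.descendants(graph, top) | {top}
        members &= blood

        affected_below = {
            x.id
            for c in loop_children
            for x in pedigree
            if x.is_affected
            and (x.id == c.id or c.id in _anc_or_self(graph, x.id))
        }
        if not affected_below:
            raise UnsupportedLoopError(
                f"consanguineous couple ({father!r}, {mother!r}) has no affected "
                "descendant; their offspring cannot be decomposed into "
                "independent structures"
            )
        if members & claimed:
            raise UnsupportedLoopError(
                "overlapping consanguineous loops are unsupported"
            )
        claimed |= members

        loops.append(
            ConsanguineousTree(
                members=tuple(sorted(members)),
                candidate_transmitters=tuple(sorted(tops)),
                anchor=anchor,
                label=f"loop{n}",
            )
        )
    return loops


def split_configurations(
    tree: ConsanguineousTree, pedigree: Pedigree
) -> list[StructureCounts]:
    """One :class:`StructureCounts` per candidate transmitter of a loop.

    Each configuration assumes the allele reached the loop's affected
    descendants through one branch top; members of that forced path become
    obligate carriers and the remaining members are re-classified by the
    standard filtering rules (the non-transmitting branch top becomes an
    ordinary normal child of the loop's common ancestor).
    """
    children = _children_map(pedigree)
    graph = pedigree.parent_graph()
    scope = set(tree.members)
    sub = graph.subgraph(scope)
    affected_members = [
        iid for iid in sorted(scope) if pedigree[iid].is_affected
    ]

    configs: list[StructureCounts] = []
    for transmitter in tree.candidate_transmitters:
        forced = {transmitter}
        possible = True
        for x in affected_members:
            if x == transmitter:
                continue
            paths = list(nx.all_simple_paths(sub, transmitter, x))
            if not paths:
                logger.warning(
                    "configuration via %r dropped: affected member %r cannot "
                    "receive the allele on that route",
                    transmitter,
                    x,
                )
                possible = False
                break
            if len(paths) > 1:
                raise UnsupportedLoopError(
                    f"multiple transmission paths from {transmitter!r} to {x!r} "
                    "inside one loop; unsupported topology"
                )
            forced.update(paths[0])
        if not possible:
            continue
        others = frozenset(
            t for t in tree.candidate_transmitters if t != transmitter
        )
        counts, _ = _decompose(
            pedigree,
            children,
            scope=scope,
            obligate=forced,
            extra_carrier_children=others - forced,
        )
        counts.label = f"via {transmitter}"
        configs.append(counts)

    if not configs:
        raise PedigreeError(
            f"consanguineous tree {tree.label!r}: every transmission "
            "configuration is impossible"
        )
    return configs


# ---------------------------------------------------------------------------
# the full filtering pipeline
# ---------------------------------------------------------------------------

@dataclass
class FilteredPedigree:
    """A pedigree reduced to its likelihood-relevant structures."""

    pedigree: Pedigree
    origin: str
    obligate: set[str]
    counts: StructureCounts
    classification: dict[str, str] = field(default_factory=dict)

    @property
    def married_in(self) -> set[str]:
        """Individuals excluded entirely under the rare-allele assumption."""
        return {
            ind.id for ind in self.pedigree if ind.id not in self.classification
        }

    def report(self) -> str:
        lines = [
            f"family {self.pedigree.family_id}: filtered pedigree",
            f"  allele origin: {self.origin}",
            f"  A (affected, penetrant)      : {self.counts.n_affected}",
            f"  B (obligate non-penetrant)   : {self.counts.n_obligate_nonpenetrant}",
            f"  C (childless normals)        : {self.counts.n_normal_childless}",
        ]
        for t in self.counts.normal_trees:
            lines.append(
                f"  normal tree ({t.depth} generations, {t.size} members): "
                + ", ".join(t.member_ids())
            )
        if self.counts.n_twin_pairs:
            lines.append(
                "  twin pairs (NN/NA/AA): "
                f"{self.counts.twin_both_normal}/"
                f"{self.counts.twin_discordant}/"
                f"{self.counts.twin_both_affected}"
            )
        for loop in self.counts.consanguineous_trees:
            lines.append(
                f"  consanguineous tree {loop.label}: members "
                + ", ".join(loop.members)
                + f"; candidate transmitters {', '.join(loop.candidate_transmitters)}"
            )
            for cfg in loop.configurations:
                lines.append(
                    f"    configuration {cfg.label}: "
                    f"A={cfg.n_affected} B={cfg.n_obligate_nonpenetrant} "
                    f"C={cfg.n_normal_childless} "
                    f"trees={[len(t.children) for t in cfg.normal_trees]}"
                )
        by_class: dict[str, list[str]] = {}
        for iid, label in sorted(self.classification.items()):
            by_class.setdefault(label, []).append(iid)
        for label, ids in sorted(by_class.items()):
            lines.append(f"  {label}: " + ", ".join(ids))
        return "\n".join(lines)


def filter_pedigree(pedigree: Pedigree) -> FilteredPedigree:
    """Run the full decomposition: origin, loops, skeleton, classification."""
    origin = find_origin(pedigree)
    graph = pedigree.parent_graph()
    blood = nx.descendants(graph, origin) | {origin}

    loops = detect_consanguineous_loops(pedigree)
    loop_members: set[str] = set()
    for loop in loops:
        loop.configurations = split_configurations(loop, pedigree)
        loop_members |= set(loop.members)

    targets: set[str] = {
        ind.id
        for ind in pedigree.affected()
        if ind.id not in loop_members
    }
    for loop in loops:
        targets.add(loop.anchor)

    skeleton: set[str] = set()
    for target in sorted(targets):
        skeleton.update(_path_up(pedigree, graph, target, origin))

    children = _children_map(pedigree)
    scope = blood - loop_members
    counts, classification = _decompose(pedigree, children, scope, skeleton)
    counts.consanguineous_trees = loops

    n_combinations = 1
    for loop in loops:
        n_combinations *= len(loop.configurations)
    if n_combinations > MAX_SILENT_COMBINATIONS:
        logger.warning(
            "consanguineous configuration product is %d combinations; "
            "estimation may be slow",
            n_combinations,
        )

    for loop in loops:
        for member in loop.members:
            classification.setdefault(member, f"consanguineous-loop member ({loop.label})")

    return FilteredPedigree(
        pedigree=pedigree,
        origin=origin,
        obligate=skeleton,
        counts=counts,
        classification=classification,
    )


def extract_structures(pedigree: Pedigree) -> StructureCounts:
    """The :class:`StructureCounts` of the filtered pedigree (loops included,
    already split into configurations)."""
    return filter_pedigree(pedigree).counts
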