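"""Shared fixtures and independent brute-force oracles.

The oracles enumerate every genotype assignment of a structure's members
and sum phenotype probabilities directly; they share no code with the
recursive likelihood implementation they check.
"""

from __future__ import annotations

import itertools

import pytest

from penetrance import NormalTree, example_pedigree


@pytest.fixture
def classic_ped():
    return example_pedigree("classic")


@pytest.fixture
def loop_ped():
    return example_pedigree("loop")


def tree_nodes_in_order(tree: NormalTree) -> list[NormalTree]:
    """Parent-before-child node list."""
    out = [tree]
    for child in tree.children:
        out.extend(tree_nodes_in_order(child))
    return out


def brute_force_tree(tree: NormalTree, k: float):
    """Enumerate carrier assignments of a normal tree.

    Returns ``(p_all_normal, carrier_mass)`` where ``carrier_mass[i]`` is
    the joint probability that node ``i`` (parent-before-child order)
    carries the allele and every member is phenotypically normal, given
    that the root's parent is a carrier.
    """
    nodes = tree_nodes_in_order(tree)
    index = {id(n): i for i, n in enumerate(nodes)}
    parent = [None] * len(nodes)
    for n in nodes:
        for c in n.children:
            parent[index[id(c)]] = index[id(n)]

    total = 0.0
    carrier_mass = [0.0] * len(nodes)
    for assignment in itertools.product((False, True), repeat=len(nodes)):
        prob = 1.0
        for i, is_carrier in enumerate(assignment):
            parent_carrier = True if parent[i] is None else assignment[parent[i]]
            if parent_carrier:
                prob *= 0.5  # Mendelian coin from the Aa x aa mating
            elif is_carrier:
                prob = 0.0
                break
            if is_carrier:
                prob *= 1.0 - k  # observed normal phenotype
        if prob == 0.0:
            continue
        total += prob
        for i, is_carrier in enumerate(assignment):
            if is_carrier:
                carrier_mass[i] += prob
    return total, carrier_mass


def brute_force_twins(k: float, m: float) -> dict[str, float]:
    """Class probabilities of a carrier's same-sex twin pair by enumeration
    over zygosity and genotypes."""
    probs = {"both_normal": 0.0, "discordant": 0.0, "both_affected": 0.0}

    def add(weight: float, g1: bool, g2: bool) -> None:
        for a1 in (False, True):
            for a2 in (False, True):
                w = weight
                for g, a in ((g1, a1), (g2, a2)):
                    if g:
                        w *= k if a else (1.0 - k)
                    elif a:
                        w = 0.0
                if w == 0.0:
                    continue
                n = a1 + a2
                key = ("both_normal", "discordant", "both_affected")[n]
                probs[key] += w

    # monozygotic: a single genotype draw
    for g, pg in ((True, 0.5), (False, 0.5)):
        add(m * pg, g, g)
    # dizygotic: independent draws
    for g1, p1 in ((True, 0.5), (False, 0.5)):
        for g2, p2 in ((True, 0.5), (False, 0.5)):
            add((1.0 - m) * p1 * p2, g1, g2)
    return probs
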