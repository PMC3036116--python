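"""Per-individual carrier probabilities and offspring risks.

At a given penetrance K, every individual in the filtered pedigree gets a
*heterozygosity probability* -- the posterior probability of carrying the
allele given the observed phenotypes -- and an *offspring risk*, the
probability that a future child with a non-carrier mate is affected:

    offspring risk = P(heterozygote) * 1/2 * K

Affected individuals and obligate carriers carry with probability one;
married-in spouses with probability zero (rare-allele assumption); a
childless normal child of an obligate carrier with (1-K)/(2-K); members of
normal trees by top-down Bayesian peeling using the same subtree
probabilities f(.) that the likelihood uses; twin-pair members by exact
enumeration over zygosity and genotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .filtering import (
    CLASS_SKIPPED,
    FilteredPedigree,
    filter_pedigree,
)
from .likelihood import DEFAULT_MZ_PROB, tree_term
from .pedigree import Pedigree, PedigreeError
from .structures import NormalTree


def _tree_carrier_posteriors(tree: NormalTree, k: float) -> dict[str, float]:
    """P(member is Aa | whole tree normal, root's parent is a carrier)."""
    f_cache: dict[str, float] = {}

    def f(node: NormalTree) -> float:
        val = float(tree_term(node, k))
        if node.member_id is not None:
            f_cache[node.member_id] = val
        return val

    def down(node: NormalTree, p_parent: float, out: dict[str, float]) -> None:
        prod = 1.0
        for child in node.children:
            prod *= f_cache[child.member_id]
        p_here = p_parent * (0.5 * (1.0 - k) * prod) / f_cache[node.member_id]
        out[node.member_id] = p_here
        for child in node.children:
            down(child, p_here, out)

    def prime(node: NormalTree) -> None:
        for child in node.children:
            prime(child)
        f(node)

    prime(tree)
    out: dict[str, float] = {}
    down(tree, 1.0, out)
    return out


def _twin_carrier_posteriors(
    affected: tuple[bool, bool], k: float, mz_prob: float
) -> tuple[float, float]:
    """Exact posterior P(Aa) for each co-twin given the pair's phenotypes."""
    total = 0.0
    carrier = [0.0, 0.0]

    def pheno_prob(is_affected: bool, genotype_carrier: bool) -> float:
        if genotype_carrier:
            return k if is_affected else 1.0 - k
        return 0.0 if is_affected else 1.0

    # monozygotic: one genotype draw shared by both twins
    for g, pg in ((True, 0.5), (False, 0.5)):
        w = mz_prob * pg * pheno_prob(affected[0], g) * pheno_prob(affected[1], g)
        total += w
        if g:
            carrier[0] += w
            carrier[1] += w
    # dizygotic: independent genotype draws
    for g1, p1 in ((True, 0.5), (False, 0.5)):
        for g2, p2 in ((True, 0.5), (False, 0.5)):
            w = (
                (1.0 - mz_prob)
                * p1
                * p2
                * pheno_prob(affected[0], g1)
                * pheno_prob(affected[1], g2)
            )
            total += w
            if g1:
                carrier[0] += w
            if g2:
                carrier[1] += w
    if total == 0.0:
        raise ZeroDivisionError("twin phenotype pattern has probability zero")
    return carrier[0] / total, carrier[1] / total


def carrier_posteriors(
    filtered: FilteredPedigree, k: float, mz_prob: float = DEFAULT_MZ_PROB
) -> dict[str, float]:
    """Heterozygosity probability for every filtered individual."""
    if not 0.0 <= k <= 1.0:
        raise ValueError("penetrance K must lie in [0, 1]")
    if filtered.counts.consanguineous_trees:
        raise PedigreeError(
            "risk computation is not defined for pedigrees with consanguineous "
            "loops: the carrier posterior would depend on the unresolved "
            "transmission configuration"
        )
    pedigree = filtered.pedigree
    out: dict[str, float] = {}

    for iid, label in filtered.classification.items():
        if label == CLASS_SKIPPED:
            continue
        ind = pedigree[iid]
        if iid in filtered.obligate:
            out[iid] = 1.0
        elif label.startswith("twin"):
            pass  # handled pairwise below
        elif ind.is_normal and label.startswith("childless normal"):
            out[iid] = (1.0 - k) / (2.0 - k)

    for tree in filtered.counts.normal_trees:
        out.update(_tree_carrier_posteriors(tree, k))

    for pair_id, (x, y) in pedigree.twin_pairs().items():
        if x.id not in filtered.classification:
            continue
        if not filtered.classification[x.id].startswith("twin"):
            continue
        px, py = _twin_carrier_posteriors(
            (x.is_affected, y.is_affected), k, mz_prob
        )
        out[x.id] = px
        out[y.id] = py

    return out


def heterozygosity_probability(
    individual_id: str,
    pedigree: Pedigree,
    k: float,
    mz_prob: float = DEFAULT_MZ_PROB,
) -> float:
    """Posterior probability that one individual carries the allele.

    Married-in individuals (outside the carrier lineage) return 0;
    individuals excluded from the filtered pedigree (unknown phenotype)
    raise an error.
    """
    filtered = filter_pedigree(pedigree)
    if individual_id not in pedigree:
        raise KeyError(f"no individual {individual_id!r} in the pedigree")
    if individual_id not in filtered.classification:
        return 0.0  # married-in: non-carrier under the rare-allele assumption
    if filtered.classification[individual_id] == CLASS_SKIPPED:
        raise PedigreeError(
            f"individual {individual_id!r} has unknown phenotype: "
            "not in the filtered pedigree"
        )
    return carrier_posteriors(filtered, k, mz_prob)[individual_id]


def offspring_risk(
    individual_id: str,
    pedigree: Pedigree,
    k: float,
    mz_prob: float = DEFAULT_MZ_PROB,
) -> float:
    """P(a future child with a non-carrier mate is affected) = P(het) * K/2."""
    return heterozygosity_probability(individual_id, pedigree, k, mz_prob) * 0.5 * k


@dataclass
class RiskTable:
    """Heterozygosity probabilities and offspring risks for a pedigree."""

    k: float
    frame: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def to_json(self) -> dict:
        return {
            "k": self.k,
            "individuals": {
                row.individual: {
                    "classification": row.classification,
                    "heterozygosity_probability": row.heterozygosity_probability,
                    "offspring_risk": row.offspring_risk,
                }
                for row in self.frame.itertuples()
            },
        }

    def __len__(self) -> int:
        return len(self.frame)


def risk_table(
    pedigree: Pedigree,
    k: float,
    mz_prob: float = DEFAULT_MZ_PROB,
) -> RiskTable:
    """Risk table over every individual in the filtered pedigree.

    Married-in spouses and unknown-phenotype individuals are omitted;
    risks are evaluated at the supplied K (typically the MLE; pass the
    posterior mean for the posterior-mean convention).
    """
    filtered = filter_pedigree(pedigree)
    posteriors = carrier_posteriors(filtered, k, mz_prob)
    rows = []
    for iid in sorted(posteriors):
        p = posteriors[iid]
        rows.append(
            {
                "individual": iid,
                "classification": filtered.classification[iid],
                "heterozygosity_probability": p,
                "offspring_risk": p * 0.5 * k,
            }
        )
    return RiskTable(k=k, frame=pd.DataFrame(rows))
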