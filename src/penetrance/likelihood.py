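"""The pedigree likelihood as a function of the penetrance rate K.

K = Prob(affected | Aa).  Up to K-independent constants (the one-half
transmission probabilities of obligate carriers and founder priors), the
filtered pedigree contributes independent factors:

* each affected (penetrant) carrier:           K
* each obligate non-penetrant carrier:         1 - K
* each childless normal child of a carrier:    (2 - K) / 2
  (the child of an Aa x aa mating is unaffected with probability
  1/2 * 1 + 1/2 * (1 - K))
* each rooted tree of normal individuals:      f(root), where
  f(leaf) = (2 - K)/2 and
  f(node) = 1/2 + 1/2 * (1 - K) * prod over children of f(child) --
  the probability that the node and its entire subtree are normal given
  the node's parent carries the allele; any tree depth is supported
* each same-sex twin pair (childless children of an obligate carrier):
  a mixture over zygosity with mixing weight m = P(monozygotic), where
  monozygotic co-twins share the genotype but express independently and
  dizygotic co-twins draw genotypes independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import NormalTree, StructureCounts

TWIN_CLASSES = ("both_normal", "discordant", "both_affected")

DEFAULT_MZ_PROB = 0.5


def _as_array(k) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    if np.any((k < 0) | (k > 1)):
        raise ValueError("penetrance K must lie in [0, 1]")
    return k


def _xlogy(x: float, y: np.ndarray) -> np.ndarray:
    """x * log(y) with the convention 0 * log(0) = 0."""
    from scipy.special import xlogy

    return xlogy(x, y)


def point_terms(counts: StructureCounts, k) -> np.ndarray:
    """Log-contribution of the three point counts A, B, C at penetrance ``k``.

    ``A log K + B log(1-K) + C log((2-K)/2)``; boundary cases (K = 0 with
    A > 0, K = 1 with B > 0) return ``-inf``, a valid log-likelihood.
    """
    k = _as_array(k)
    with np.errstate(divide="ignore"):
        return (
            _xlogy(counts.n_affected, k)
            + _xlogy(counts.n_obligate_nonpenetrant, 1.0 - k)
            + _xlogy(counts.n_normal_childless, (2.0 - k) / 2.0)
        )


def tree_term(tree: NormalTree, k) -> np.ndarray:
    """Probability that the whole normal tree is phenotypically normal,
    given that the root's parent carries the allele."""
    k = _as_array(k)
    if not tree.children:
        return (2.0 - k) / 2.0
    prod = np.ones_like(k)
    for child in tree.children:
        prod = prod * tree_term(child, k)
    return 0.5 + 0.5 * (1.0 - k) * prod


def twin_terms(twin_class: str, k, mz_prob: float = DEFAULT_MZ_PROB) -> np.ndarray:
    """Probability of a twin-pair concordance class for a carrier's twins.

    ``mz_prob`` is the probability that a same-sex pair is monozygotic.
    Monozygotic twins share one genotype draw (Aa with probability 1/2)
    and express the phenotype independently; dizygotic twins are two
    independent children of the Aa x aa mating.
    """
    if twin_class not in TWIN_CLASSES:
        raise ValueError(f"unknown twin class {twin_class!r}")
    if not 0.0 <= mz_prob <= 1.0:
        raise ValueError("mz_prob must lie in [0, 1]")
    k = _as_array(k)
    if twin_class == "both_normal":
        mz = 0.5 + 0.5 * (1.0 - k) ** 2
        dz = ((2.0 - k) / 2.0) ** 2
    elif twin_class == "discordant":
        mz = k * (1.0 - k)
        dz = k * (2.0 - k) / 2.0
    else:  # both_affected
        mz = 0.5 * k**2
        dz = k**2 / 4.0
    return mz_prob * mz + (1.0 - mz_prob) * dz


def weinberg_mz_probability(n_same_sex: int, n_opposite_sex: int) -> float:
    """Weinberg's differential rule: among same-sex pairs, the monozygotic
    fraction is estimated as (same-sex - opposite-sex) / same-sex."""
    if n_same_sex <= 0:
        raise ValueError("need at least one same-sex twin pair")
    return float(np.clip((n_same_sex - n_opposite_sex) / n_same_sex, 0.0, 1.0))


@dataclass
class LikelihoodModel:
    """log L(K) for one set of structure counts, defined up to a constant.

    Consanguineous trees are not accepted here: each of their
    configurations yields its own model, combined upstream (see
    :func:`penetrance.estimation.combine_configurations`).
    """

    counts: StructureCounts
    mz_prob: float = DEFAULT_MZ_PROB
    label: str = field(default="")

    def __post_init__(self) -> None:
        if self.counts.consanguineous_trees:
            raise ValueError(
                "LikelihoodModel takes loop-free counts; split consanguineous "
                "trees into configurations first"
            )
        if not 0.0 <= self.mz_prob <= 1.0:
            raise ValueError("mz_prob must lie in [0, 1]")

    @property
    def is_constant(self) -> bool:
        """True when the likelihood carries no information about K."""
        return self.counts.n_members == 0

    def log_likelihood(self, k) -> np.ndarray:
        k = _as_array(k)
        out = point_terms(self.counts, k)
        with np.errstate(divide="ignore"):
            for tree in self.counts.normal_trees:
                out = out + np.log(tree_term(tree, k))
            for twin_class, count in (
                ("both_normal", self.counts.twin_both_normal),
                ("discordant", self.counts.twin_discordant),
                ("both_affected", self.counts.twin_both_affected),
            ):
                if count:
                    out = out + count * np.log(
                        twin_terms(twin_class, k, self.mz_prob)
                    )
        return out

    def __call__(self, k) -> np.ndarray:
        return self.log_likelihood(k)

    def merged_with(self, other_counts: StructureCounts) -> "LikelihoodModel":
        return LikelihoodModel(
            counts=self.counts.merged_with(other_counts),
            mz_prob=self.mz_prob,
            label=other_counts.label or self.label,
        )

    # -- human-readable rendering ------------------------------------------
    def formula(self) -> str:
        """The likelihood as plain text, e.g.
        ``K^3 * (1-K)^4 * ((2-K)/2)^2 * [1/2 + 1/2*(1-K)*((2-K)/2)^2]``."""
        parts: list[str] = []
        c = self.counts
        if c.n_affected:
            parts.append("K" + _power(c.n_affected))
        if c.n_obligate_nonpenetrant:
            parts.append("(1-K)" + _power(c.n_obligate_nonpenetrant))
        if c.n_normal_childless:
            parts.append("((2-K)/2)" + _power(c.n_normal_childless))
        for tree in c.normal_trees:
            parts.append(_tree_formula(tree))
        m = self.mz_prob
        twin_text = {
            "both_normal": f"[{m:g}*(1/2+1/2*(1-K)^2) + {1 - m:g}*((2-K)/2)^2]",
            "discordant": f"[{m:g}*K*(1-K) + {1 - m:g}*K*(2-K)/2]",
            "both_affected": f"[{m:g}*K^2/2 + {1 - m:g}*K^2/4]",
        }
        for twin_class, count in (
            ("both_normal", c.twin_both_normal),
            ("discordant", c.twin_discordant),
            ("both_affected", c.twin_both_affected),
        ):
            if count:
                parts.append(twin_text[twin_class] + _power(count))
        if not parts:
            return "1"
        return " * ".join(parts)


def _power(n: int) -> str:
    return "" if n == 1 else f"^{n}"


def _tree_formula(tree: NormalTree) -> str:
    if not tree.children:
        return "(2-K)/2"
    inner = "*".join(_tree_formula(c) for c in tree.children)
    return f"[1/2 + 1/2*(1-K)*{inner}]"
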