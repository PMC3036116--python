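"""Heterozygosity probabilities and offspring risks for counseling.

After estimating K, every individual in the filtered pedigree gets the
posterior probability of carrying the allele given the observed
phenotypes, and the risk that a future child (with a non-carrier mate) is
affected: P(carrier) * 1/2 * K.
"""

from penetrance import (
    estimate_counts,
    example_pedigree,
    extract_structures,
    risk_table,
)

pedigree = example_pedigree("classic")
result = estimate_counts(extract_structures(pedigree))
print(f"estimated K = {result.k_hat:.4f}")
print()

table = risk_table(pedigree, result.k_hat)
print(table.frame.to_string(index=False))
print()
print(
    "Reading: obligate carriers (probability 1) risk K/2 per child; a "
    "normal individual with many normal descendants is unlikely to carry "
    "the allele, so its offspring risk is small."
)
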