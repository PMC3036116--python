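"""Estimate the penetrance rate K from a pedigree.

Builds the bundled four-generation example family, filters it into the
structures the likelihood depends on, and estimates K with its exact 95%
credibility interval.
"""

from penetrance import estimate_counts, example_pedigree, filter_pedigree

pedigree = example_pedigree("classic")
filtered = filter_pedigree(pedigree)

print(filtered.report())
print()

result = estimate_counts(filtered.counts)
print(result.report())
print()
print(
    "Reading: roughly one in three carriers of this family's allele "
    f"expresses the disease (K = {result.k_hat:.3f}); the data are compatible "
    f"with penetrances from {result.ci_lower:.2f} to {result.ci_upper:.2f}."
)
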