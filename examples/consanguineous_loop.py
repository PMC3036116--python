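"""Penetrance estimation across a consanguineous marriage loop.

In the bundled loop example the couple II-1 x II-2 are both blood
descendants of the carrier founder, so the affected great-grandchild may
have received the allele through either branch.  The loop is split into
one transmission configuration per candidate branch; each configuration
gets its own estimate and the results are pooled by inverse-variance
weighting.
"""

from penetrance import estimate_counts, example_pedigree, filter_pedigree

pedigree = example_pedigree("loop")
filtered = filter_pedigree(pedigree)
print(filtered.report())
print()

result = estimate_counts(filtered.counts)
print(result.report())
print()
print(
    "Reading: the two rows above are the per-route estimates; the headline "
    "K pools them, weighting each route by how precisely it determines K."
)
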