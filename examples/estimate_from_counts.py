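"""Estimate K from a pre-tabulated structure-counts file.

The counts dialect summarizes a filtered pedigree in a few comma-separated
lines: affected / obligate non-penetrant / childless-normal counts, then
the normal trees per depth, twin-pair counts, and consanguineous trees.
This reproduces the same estimate as the pedigree route.
"""

import tempfile
from pathlib import Path

from penetrance import estimate_counts, read_counts

TEXT = """\
3,4,2
2,2,3
0
0
0
0,0,0
0
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "family.counts"
    path.write_text(TEXT)
    counts = read_counts(path)

print(
    f"A={counts.n_affected} affected, "
    f"B={counts.n_obligate_nonpenetrant} obligate non-penetrant, "
    f"C={counts.n_normal_childless} childless normals, "
    f"trees with offspring {[len(t.children) for t in counts.normal_trees]}"
)
result = estimate_counts(counts)
print(result.report())
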