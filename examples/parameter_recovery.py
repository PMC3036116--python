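"""Gene-drop check that the estimator recovers a known penetrance.

Simulates replicate phenotype sets on a fixed multiplex kindred with
K_true = 0.7 and re-estimates K from each; the mean estimate should sit
near the truth and the 95% credibility interval should usually cover it.
(The full 500-replicate study runs in the test suite; this is a quick
80-replicate version.)
"""

import numpy as np

from penetrance import (
    NothingToEstimateError,
    SimulationConfig,
    estimate_counts,
    extract_structures,
    gene_drop,
    random_topology,
)

K_TRUE = 0.7
topology = random_topology(seed=1, generations=5, sibship_mean=2.5, mate_prob=1.0)
config = SimulationConfig(topology=topology, k_true=K_TRUE, n_replicates=80, seed=11)

estimates, covered = [], 0
for replicate in gene_drop(config):
    try:
        est = estimate_counts(extract_structures(replicate))
    except NothingToEstimateError:  # no affected individuals this draw
        continue
    estimates.append(est.k_hat)
    covered += est.ci_lower <= K_TRUE <= est.ci_upper

print(f"replicates estimated : {len(estimates)}")
print(f"true K               : {K_TRUE}")
print(f"mean estimate        : {np.mean(estimates):.4f}")
print(f"interval coverage    : {covered / len(estimates):.3f}")
print()
print(
    "Reading: the estimator is approximately unbiased on a family this "
    "informative, and the exact credibility interval covers the truth at "
    "close to its nominal 95% rate."
)
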