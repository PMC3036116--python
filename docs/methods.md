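# Methods

## Genetic model and assumptions

One autosomal locus with a rare dominant allele A.  Because A is rare,
homozygotes AA are ignored and every married-in spouse is assumed aa with
probability one; the allele enters the family through exactly one founder
(the *single-origin assumption*).  Affected individuals are Aa; normal
individuals are aa or non-penetrant Aa.  The penetrance rate
K = Prob(affected | Aa) is the only free parameter.  There are no
phenocopies (an aa individual is never affected), no de-novo mutation,
and no ascertainment correction: the likelihood is conditional on the
origin founder carrying the allele, not on the family having been
noticed because of its affected members.

## Filtering

The allele origin is the designated carrier founder if one is annotated,
otherwise the unique lowest common ancestor-or-self of all affected
individuals.  When that ancestor is only determined up to a founder
couple, the package refuses to guess and asks for a designation (sidecar
key `carrier:`), since either spouse could have transmitted.

Given the origin, the *obligate carriers* are the union of the unique
blood paths from the origin to every affected individual: the affected
themselves (penetrant, count A) plus every normal individual on a path
(obligate non-penetrant, count B).  Every other blood relative with an
observed phenotype is classified exactly once:

* childless normal child of an obligate carrier → count C;
* normal child of an obligate carrier with normal descendants → root of a
  *normal tree* (any depth; the on-disk counts dialect serializes depths
  2–5);
* member of a same-sex twin pair borne by an obligate carrier → one of
  three concordance classes (both normal / discordant / both affected).

Unknown-phenotype individuals contribute no likelihood term and are
excluded together with their descendant subtree (a carrier-status
condition cannot be propagated through an unobserved phenotype); a
warning is logged.  Unknown-phenotype individuals on the transmission
path still anchor the classification of their children but add no factor.
Opposite-sex twins are necessarily dizygotic and are treated as ordinary
siblings.  Twin pairs with children, or borne by a non-obligate parent,
are rejected: the twin terms condition on a carrier parent and childless
twins.

## Likelihood

Up to K-free constants (the ½ transmission factors of obligate carriers
and founder priors, which cancel in the MLE and the normalized
posterior):

* point terms: `A log K + B log(1−K) + C log((2−K)/2)`, where
  `(2−K)/2 = ½·1 + ½·(1−K)` is the probability that a child of an
  Aa × aa mating is unaffected;
* normal-tree terms: `f(leaf) = (2−K)/2`,
  `f(node) = ½ + ½(1−K)·∏ f(child)`, the probability that the node and
  its whole subtree are normal given a carrier parent;
* twin terms: mixtures over zygosity with mixing weight
  m = P(monozygotic | same-sex pair).  Monozygotic co-twins share one
  genotype draw and express independently given genotype (no shared-
  environment concordance parameter); dizygotic co-twins are independent
  children.  Both mixture components sum to one over the three classes
  for every K.

m defaults to 0.5 and is a configuration knob; `weinberg_mz_probability`
implements Weinberg's differential rule ((same-sex − opposite-sex) /
same-sex) when population twin counts are available.  All structure terms
are verified in the test suite against brute-force enumeration of every
genotype assignment, to 1e-12.

## Estimation

**MLE.** Grid pre-scan with step 1e-3 followed by bounded scalar
refinement (`scipy.optimize.minimize_scalar`, xatol 1e-9); the boundary
values 0 and 1 are admissible candidates and reported with a warning when
selected (mixed tree/twin terms can in principle produce mild
multimodality, which the pre-scan guards against).

**Credibility interval.** "Exact" means computed from the normalized
likelihood under a uniform prior on K, not from a normal approximation.
The default convention is the equal-tailed interval (posterior quantiles
at (1−level)/2 and 1−(1−level)/2); a highest-posterior-density interval
(assuming unimodality) is available as an option.  Integration is
composite Gauss–Legendre (400 nodes per panel, panels split at the
posterior mode) restricted to the effective support where the
log-likelihood is within 46 nats of its maximum (density ≥ ~1e-20 of the
peak); the likelihood is evaluated vectorized over all nodes.  On
conjugate cases (likelihood ∝ K^a(1−K)^b) the quantiles reproduce
Beta(a+1, b+1) closed forms to well below the 1e-6 test tolerance, and
quantile root-finding (`brentq`) uses xtol 1e-9.

**Variance.** The default `var(K)` is the posterior variance by
quadrature of the first two moments, consistent with the credibility
framework; the observed-information variance `1/(−d² log L/dK²)` at the
MLE is available as an option (undefined at boundary MLEs).

**Consanguineous loops.** A marriage loop is a couple who are both blood
descendants of the carrier lineage and have an affected descendant; the
allele may have reached that descendant through either spouse's branch.
The supported pattern is the two-branch loop: a unique common blood
ancestor (anchor) with two disjoint branch paths down to the couple.
Each branch top is a candidate transmitter; fixing the transmitter forces
its path to be carriers and re-classifies the remaining loop members by
the standard rules (the non-transmitting branch top becomes an ordinary
normal child of the anchor).  Configurations in which an affected loop
member cannot receive the allele are dropped with a warning.  The full
pedigree likelihood is the common (non-inbred) part times one
configuration per loop; all Cartesian combinations are estimated
separately and pooled with inverse-variance weights (interval limits
pooled with the same weights; the pooled variance reported is
1/Σ weights).  Any number of loops is accepted, with a combinatorial
warning when the configuration product exceeds 64.  More tangled
inbreeding (nested loops, spouse-ancestor unions, overlapping loops, or a
consanguineous couple with no affected descendant, whose offspring cannot
be decomposed into independent structures) raises an explicit
"unsupported loop" error rather than returning silent nonsense — full
Elston–Stewart peeling of arbitrary loop topologies is out of scope.

## Risks

The heterozygosity probability is the exact posterior P(Aa | observed
phenotypes) within the individual's own structure (structures are
independent given the obligate-carrier skeleton): 1 for affected and
obligate carriers, 0 for married-in individuals, (1−K)/(2−K) for a
childless normal child of a carrier, top-down peeling
`P(x) = P(parent)·[½(1−K)∏ f(child)]/f(x)` inside normal trees, and
exact zygosity-genotype enumeration for twin members.  The offspring risk
with an assumed non-carrier mate is P(Aa)·½·K.  Risks are evaluated at
the point estimate K̂ by default; passing the posterior mean gives the
alternative convention.  Risk tables are not defined for pedigrees with
unresolved consanguineous loops (the carrier posterior would depend on
the transmission configuration); the package raises an error instead of
averaging over configurations.

## Simulator

The gene drop implements the model generatively: designated founder Aa,
other founders aa, each child of a carrier inheriting with probability ½
(1 − 0.5^c for c carrier parents, relevant only in consanguineous
topologies), carriers affected with probability k_true, same-sex twin
pairs monozygotic with probability m (shared genotype draw).  A fixed
seed makes the PED output byte-identical.  The random-topology generator
defaults to 4 generations, sibship sizes 1 + Poisson(2), and a 0.6
probability that a non-terminal child reproduces with a married-in
spouse — a plausible clinic-sized kindred.

What the simulations do **not** emulate: ascertainment (families noticed
*because* of affected members), phenocopies, diagnostic error, and
population allele-frequency structure.  Passing recovery tests therefore
show correctness of the likelihood machinery under its own assumptions,
not robustness to ascertainment bias in real collections.

## Problem sizes used in the test suite

* The parameter-recovery study uses 500 gene-drop replicates at
  K_true = 0.7 on one fixed multiplex kindred (5 generations, sibship
  1 + Poisson(2.5), every non-terminal child reproducing; 188 blood
  members).  Interval-coverage calibration is an asymptotic property of
  Bayesian intervals, so the study kindred is chosen large enough for the
  posterior to be approximately normal; on small families the exact
  interval is conservative (it over-covers), which the estimator reports
  honestly rather than correcting.  Replicates with no affected
  individuals (~4%) cannot be estimated ("nothing to estimate") and are
  skipped, a mild ascertainment effect that slightly inflates the mean
  estimate; both effects are visible in `examples/parameter_recovery.py`.
* The simulator-compatibility fuzz runs 1500 random topologies, a
  desktop-scale pass over the topology space.

## Degenerate inputs and numerical choices

* K = 0 with affected present, or K = 1 with obligate non-penetrant
  present, give log-likelihood −∞ (a value, not an exception).
* Empty structure counts give a constant likelihood: estimation raises
  "K not identifiable"; the uniform posterior remains available behind an
  explicit `allow_flat` flag.
* Boundary MLEs are reported as-is with a warning; credibility intervals
  are interior by construction.
* Ties in the grid pre-scan resolve to the smallest K (numpy argmax),
  then refinement makes the choice irrelevant except under exact
  symmetry.
* The counts-file dialect defines this package's own nested-parenthesis
  serialization for trees deeper than two generations and a 6-line block
  per loop configuration; files written by the package flag the extension
  in a header comment, and reading a written file reproduces the
  structure exactly (round-trip tested).
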