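"""MLE, credibility intervals, posterior variance, loop combination."""

import math

import numpy as np
import pytest
from scipy import stats

from penetrance import (
    ConsanguineousTree,
    LikelihoodModel,
    NormalTree,
    NotIdentifiableError,
    Posterior,
    StructureCounts,
    combine_configurations,
    credibility_interval,
    estimate,
    estimate_counts,
    information_variance,
    mle,
    posterior_variance,
)


def _beta_model(a, b):
    return LikelihoodModel(
        StructureCounts(n_affected=a, n_obligate_nonpenetrant=b)
    )


# ---------------------------------------------------------------------------
# MLE
# ---------------------------------------------------------------------------


def test_binomial_mle_closed_form():
    assert mle(_beta_model(3, 4)) == pytest.approx(3 / 7, abs=1e-8)


def test_mle_boundaries():
    assert mle(_beta_model(0, 5)) == 0.0
    assert mle(_beta_model(4, 0)) == 1.0


def test_constant_likelihood_not_identifiable():
    with pytest.raises(NotIdentifiableError):
        mle(LikelihoodModel(StructureCounts()))
    with pytest.raises(NotIdentifiableError):
        posterior_variance(LikelihoodModel(StructureCounts()))


def test_mle_with_tree_matches_fine_grid():
    counts = StructureCounts(
        n_affected=3,
        n_obligate_nonpenetrant=4,
        n_normal_childless=2,
        normal_trees=[NormalTree.two_generation(2), NormalTree.two_generation(3)],
    )
    model = LikelihoodModel(counts)
    grid = np.linspace(1e-9, 1 - 1e-9, 400001)
    brute = grid[np.argmax(model.log_likelihood(grid))]
    assert mle(model) == pytest.approx(brute, abs=1e-5)


# ---------------------------------------------------------------------------
# credibility interval & variance: Beta conjugate oracle
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("a", range(0, 7))
@pytest.mark.parametrize("b", range(0, 7))
def test_beta_conjugate_oracle(a, b):
    """When L is proportional to K^a (1-K)^b the posterior under a uniform
    prior is Beta(a+1, b+1); MLE, interval and variance must match the
    closed forms."""
    if a == 0 and b == 0:
        return  # constant likelihood: covered by the identifiability test
    model = _beta_model(a, b)
    assert mle(model) == pytest.approx(a / (a + b), abs=1e-6)
    lo, hi = credibility_interval(model, 0.95)
    expect_lo, expect_hi = stats.beta.ppf([0.025, 0.975], a + 1, b + 1)
    assert lo == pytest.approx(expect_lo, abs=1e-6)
    assert hi == pytest.approx(expect_hi, abs=1e-6)
    assert posterior_variance(model) == pytest.approx(
        stats.beta.var(a + 1, b + 1), abs=1e-9
    )


def test_uniform_posterior_flat_model():
    model = LikelihoodModel(StructureCounts())
    lo, hi = credibility_interval(model, 0.95, allow_flat=True)
    assert (lo, hi) == (pytest.approx(0.025, abs=1e-6), pytest.approx(0.975, abs=1e-6))
    post = Posterior(model, allow_flat=True)
    assert post.variance == pytest.approx(1 / 12, abs=1e-9)


def test_linear_posterior_closed_form():
    """A single affected individual: posterior density 2K, CDF K^2."""
    model = _beta_model(1, 0)
    lo, hi = credibility_interval(model, 0.95)
    assert lo == pytest.approx(math.sqrt(0.025), abs=1e-6)
    assert hi == pytest.approx(math.sqrt(0.975), abs=1e-6)


def test_point_mass_limit_variance_shrinks():
    model = _beta_model(10_000, 10_000)
    assert posterior_variance(model) < 1e-4


def test_interval_contains_posterior_median_and_tightens():
    counts = StructureCounts(
        n_affected=2,
        n_obligate_nonpenetrant=3,
        normal_trees=[NormalTree.two_generation(2)],
    )
    widths = []
    for scale in (1, 2, 4):
        scaled = StructureCounts(
            n_affected=2 * scale,
            n_obligate_nonpenetrant=3 * scale,
            normal_trees=[NormalTree.two_generation(2)] * scale,
        )
        model = LikelihoodModel(scaled)
        lo, hi = credibility_interval(model, 0.95)
        median = Posterior(model).quantile(0.5)
        assert lo <= median <= hi
        widths.append(hi - lo)
    assert widths[0] >= widths[1] >= widths[2]


def test_hpd_interval_is_narrower_than_equal_tailed():
    model = _beta_model(2, 5)
    lo_et, hi_et = credibility_interval(model, 0.95, method="equal-tailed")
    lo_h, hi_h = credibility_interval(model, 0.95, method="hpd")
    assert (hi_h - lo_h) <= (hi_et - lo_et) + 1e-9
    # HPD of Beta(3,6) still carries 95% mass
    assert stats.beta.cdf(hi_h, 3, 6) - stats.beta.cdf(lo_h, 3, 6) == pytest.approx(
        0.95, abs=1e-4
    )


def test_information_variance_matches_beta_curvature():
    # -d2/dK2 [a log K + b log(1-K)] at K=a/(a+b) gives (a+b)^3/(a*b)
    a, b = 3, 4
    model = _beta_model(a, b)
    k = a / (a + b)
    expected = 1.0 / ((a / k**2) + (b / (1 - k) ** 2))
    assert information_variance(model) == pytest.approx(expected, rel=1e-4)


# ---------------------------------------------------------------------------
# combining loop configurations
# ---------------------------------------------------------------------------


def _loop(cfgs, label="loop"):
    return ConsanguineousTree(configurations=cfgs, label=label)


def test_single_configuration_equals_merged_model():
    common = LikelihoodModel(StructureCounts(n_affected=1, n_obligate_nonpenetrant=1))
    cfg = StructureCounts(n_affected=2, n_obligate_nonpenetrant=3, label="only")
    # a one-configuration "loop" (degenerate; construct directly)
    tree = ConsanguineousTree(configurations=[cfg, cfg], label="dup")
    # identical configurations: pooled estimate equals the single-route one
    pooled = combine_configurations(common, [tree], 0.95)
    merged = estimate(
        LikelihoodModel(common.counts.merged_with(cfg)), 0.95
    )
    assert pooled.k_hat == pytest.approx(merged.k_hat, abs=1e-9)
    assert pooled.ci_lower == pytest.approx(merged.ci_lower, abs=1e-6)
    assert pooled.ci_upper == pytest.approx(merged.ci_upper, abs=1e-6)


def test_equal_variance_combination_is_midpoint():
    common = LikelihoodModel(StructureCounts())
    cfg_a = StructureCounts(n_affected=2, n_obligate_nonpenetrant=3, label="a")
    cfg_b = StructureCounts(n_affected=3, n_obligate_nonpenetrant=2, label="b")
    result = combine_configurations(common, [_loop([cfg_a, cfg_b])], 0.95)
    sub = result.per_configuration
    assert len(sub) == 2
    assert sub[0].variance == pytest.approx(sub[1].variance, rel=1e-9)
    assert result.k_hat == pytest.approx(
        (sub[0].k_hat + sub[1].k_hat) / 2, abs=1e-9
    )
    assert result.k_hat == pytest.approx(0.5, abs=1e-6)


def test_inverse_variance_weighting_arithmetic():
    """K1=0.4 (var 1) and K2=0.8 (var 3) pool to 0.5."""
    from penetrance.estimation import ConfigurationEstimate

    subs = [
        ConfigurationEstimate("c1", 0.4, 1.0, 0.1, 0.7),
        ConfigurationEstimate("c2", 0.8, 3.0, 0.5, 0.9),
    ]
    w = np.array([1.0, 1.0 / 3.0])
    k = float(np.dot(w, [0.4, 0.8]) / w.sum())
    assert k == pytest.approx(0.5)
    lo = float(np.dot(w, [0.1, 0.5]) / w.sum())
    assert lo == pytest.approx(0.2)


def test_combination_invariant_to_ordering():
    common = LikelihoodModel(StructureCounts(n_obligate_nonpenetrant=1))
    cfg_a = StructureCounts(n_affected=1, n_obligate_nonpenetrant=3, label="a")
    cfg_b = StructureCounts(n_affected=1, n_obligate_nonpenetrant=2,
                            normal_trees=[NormalTree.two_generation(1)], label="b")
    cfg_c = StructureCounts(n_affected=2, n_obligate_nonpenetrant=2, label="c")
    cfg_d = StructureCounts(n_affected=1, n_obligate_nonpenetrant=4, label="d")
    t1 = _loop([cfg_a, cfg_b], "t1")
    t2 = _loop([cfg_c, cfg_d], "t2")
    forward = combine_configurations(common, [t1, t2], 0.95)
    t1r = _loop([cfg_b, cfg_a], "t1")
    t2r = _loop([cfg_d, cfg_c], "t2")
    backward = combine_configurations(common, [t2r, t1r], 0.95)
    assert forward.k_hat == pytest.approx(backward.k_hat, abs=1e-9)
    assert forward.ci_lower == pytest.approx(backward.ci_lower, abs=1e-7)
    assert forward.ci_upper == pytest.approx(backward.ci_upper, abs=1e-7)
    assert forward.posterior_variance == pytest.approx(
        backward.posterior_variance, rel=1e-9
    )


def test_estimate_counts_dispatches_on_loops(loop_ped):
    from penetrance import extract_structures

    counts = extract_structures(loop_ped)
    result = estimate_counts(counts)
    assert len(result.per_configuration) == 2
    labels = {c.label for c in result.per_configuration}
    assert labels == {"loop1:via I-1", "loop1:via II-2"}
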