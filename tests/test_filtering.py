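"""Obligate-carrier inference, structure extraction and loop splitting."""

import pytest

from penetrance import (
    AmbiguousFounderError,
    Individual,
    NothingToEstimateError,
    Pedigree,
    PedigreeError,
    detect_consanguineous_loops,
    extract_structures,
    filter_pedigree,
    identify_obligate_carriers,
    split_configurations,
)
from penetrance.pedigree import AFFECTED, FEMALE, MALE, NORMAL, UNKNOWN


def _ped(rows, family="T"):
    inds = {}
    for row in rows:
        iid, father, mother, sex, pheno = row[:5]
        extra = row[5] if len(row) > 5 else {}
        inds[iid] = Individual(
            id=iid, father_id=father, mother_id=mother, sex=sex, phenotype=pheno,
            **extra,
        )
    return Pedigree(family_id=family, individuals=inds)


# ---------------------------------------------------------------------------
# obligate carriers
# ---------------------------------------------------------------------------


def test_classic_obligate_sets(classic_ped):
    obligate = identify_obligate_carriers(classic_ped)
    nonpenetrant = {i for i in obligate if classic_ped[i].is_normal}
    penetrant = {i for i in obligate if classic_ped[i].is_affected}
    assert nonpenetrant == {"I-1", "II-1", "II-3", "III-1"}
    assert penetrant == {"II-4", "III-4", "IV-1"}


def test_single_affected_founder_is_sole_obligate():
    ped = _ped([
        ("A", None, None, MALE, AFFECTED),
        ("B", None, None, FEMALE, NORMAL),
        ("C", "A", "B", MALE, NORMAL),
    ])
    assert identify_obligate_carriers(ped) == {"A"}


def test_normal_middle_parent_between_affecteds_is_obligate():
    """Affected grandparent and grandchild: no allele path avoids the
    normal middle parent, so it must be a non-penetrant carrier."""
    ped = _ped([
        ("GP", None, None, MALE, AFFECTED),
        ("GM", None, None, FEMALE, NORMAL),
        ("P", "GP", "GM", FEMALE, NORMAL),
        ("Ps", None, None, MALE, NORMAL),
        ("GC", "Ps", "P", MALE, AFFECTED),
    ])
    obligate = identify_obligate_carriers(ped)
    assert obligate == {"GP", "P", "GC"}


def test_no_affected_raises_nothing_to_estimate():
    ped = _ped([
        ("A", None, None, MALE, NORMAL),
        ("B", None, None, FEMALE, NORMAL),
        ("C", "A", "B", MALE, NORMAL),
    ])
    with pytest.raises(NothingToEstimateError):
        identify_obligate_carriers(ped)


def test_undesignated_founder_couple_is_ambiguous():
    ped = _ped([
        ("A", None, None, MALE, NORMAL),
        ("B", None, None, FEMALE, NORMAL),
        ("C", "A", "B", MALE, AFFECTED),
        ("D", "A", "B", FEMALE, AFFECTED),
    ])
    with pytest.raises(AmbiguousFounderError, match="designate"):
        identify_obligate_carriers(ped)


# ---------------------------------------------------------------------------
# structure extraction
# ---------------------------------------------------------------------------


def test_classic_decomposition(classic_ped):
    counts = extract_structures(classic_ped)
    assert counts.n_affected == 3
    assert counts.n_obligate_nonpenetrant == 4
    assert counts.n_normal_childless == 2
    assert sorted(len(t.children) for t in counts.normal_trees) == [2, 3]
    assert all(t.depth == 2 for t in counts.normal_trees)
    assert counts.n_twin_pairs == 0
    assert counts.consanguineous_trees == []


def test_affected_parent_with_normal_childless_child():
    ped = _ped([
        ("P", None, None, MALE, AFFECTED),
        ("M", None, None, FEMALE, NORMAL),
        ("C", "P", "M", FEMALE, NORMAL),
    ])
    counts = extract_structures(ped)
    assert (counts.n_affected, counts.n_normal_childless) == (1, 1)
    assert counts.n_obligate_nonpenetrant == 0


def test_three_generation_chain_yields_depth_three_tree():
    ped = _ped([
        ("P", None, None, MALE, AFFECTED),
        ("M", None, None, FEMALE, NORMAL),
        ("C1", "P", "M", MALE, NORMAL),
        ("C1s", None, None, FEMALE, NORMAL),
        ("D1", "C1", "C1s", FEMALE, NORMAL),
        ("D1s", None, None, MALE, NORMAL),
        ("E1", "D1s", "D1", MALE, NORMAL),
    ])
    counts = extract_structures(ped)
    assert len(counts.normal_trees) == 1
    tree = counts.normal_trees[0]
    assert tree.depth == 3
    assert tree.member_id == "C1"
    assert [c.member_id for c in tree.children] == ["D1"]
    assert [c.member_id for c in tree.children[0].children] == ["E1"]


def test_partition_property(classic_ped):
    """A + B + C + tree sizes + 2 * twin pairs covers every filtered
    individual exactly once."""
    filtered = filter_pedigree(classic_ped)
    n_filtered = len(
        [
            ind
            for ind in classic_ped
            if ind.id in filtered.classification and ind.phenotype != UNKNOWN
        ]
    )
    assert filtered.counts.n_members == n_filtered
    # married-in spouses are excluded entirely
    assert "I-2" in filtered.married_in
    assert "II-1s" in filtered.married_in


def test_filtering_invariant_under_relabeling(classic_ped):
    mapping = {iid: f"ind{n:02d}" for n, iid in enumerate(sorted(classic_ped.individuals))}
    relabeled = Pedigree(
        family_id="R",
        individuals={
            mapping[i.id]: Individual(
                id=mapping[i.id],
                father_id=mapping.get(i.father_id),
                mother_id=mapping.get(i.mother_id),
                sex=i.sex,
                phenotype=i.phenotype,
                twin_pair_id=i.twin_pair_id,
                designated_carrier=i.designated_carrier,
            )
            for i in classic_ped
        },
    )
    assert extract_structures(relabeled).equivalent_to(extract_structures(classic_ped))


def test_unknown_phenotype_excluded_with_subtree(caplog):
    ped = _ped([
        ("P", None, None, MALE, AFFECTED),
        ("M", None, None, FEMALE, NORMAL),
        ("C", "P", "M", MALE, UNKNOWN),
        ("Cs", None, None, FEMALE, NORMAL),
        ("D", "C", "Cs", FEMALE, NORMAL),
    ])
    import logging

    with caplog.at_level(logging.WARNING, logger="penetrance"):
        counts = extract_structures(ped)
    assert counts.n_affected == 1
    assert counts.n_members == 1  # C and D both excluded
    assert any("unknown phenotype" in r.message for r in caplog.records)


def test_twins_classified_not_point_counted():
    ped = _ped([
        ("P", None, None, MALE, AFFECTED),
        ("M", None, None, FEMALE, NORMAL),
        ("T1", "P", "M", FEMALE, NORMAL, {"twin_pair_id": "tw"}),
        ("T2", "P", "M", FEMALE, AFFECTED, {"twin_pair_id": "tw"}),
    ])
    counts = extract_structures(ped)
    assert counts.twin_discordant == 1
    assert counts.n_affected == 1  # P only; the affected twin is in the pair
    assert counts.n_normal_childless == 0


def test_twins_of_nonobligate_parent_rejected():
    ped = _ped([
        ("P", None, None, MALE, AFFECTED),
        ("M", None, None, FEMALE, NORMAL),
        ("C", "P", "M", MALE, NORMAL),
        ("Cs", None, None, FEMALE, NORMAL),
        ("T1", "C", "Cs", FEMALE, NORMAL, {"twin_pair_id": "tw"}),
        ("T2", "C", "Cs", FEMALE, NORMAL, {"twin_pair_id": "tw"}),
    ])
    with pytest.raises(PedigreeError, match="obligate carrier"):
        extract_structures(ped)


def test_opposite_sex_twins_are_ordinary_siblings():
    ped = _ped([
        ("P", None, None, MALE, AFFECTED),
        ("M", None, None, FEMALE, NORMAL),
        ("T1", "P", "M", FEMALE, NORMAL, {"twin_pair_id": "tw"}),
        ("T2", "P", "M", MALE, NORMAL, {"twin_pair_id": "tw"}),
    ])
    counts = extract_structures(ped)
    assert counts.n_twin_pairs == 0
    assert counts.n_normal_childless == 2


# ---------------------------------------------------------------------------
# consanguineous loops
# ---------------------------------------------------------------------------


def test_classic_pedigree_has_no_loops(classic_ped):
    assert detect_consanguineous_loops(classic_ped) == []


def test_plain_chain_has_no_loops():
    ped = _ped([
        ("A", None, None, MALE, AFFECTED),
        ("B", None, None, FEMALE, NORMAL),
        ("C", "A", "B", MALE, NORMAL),
        ("Cs", None, None, FEMALE, NORMAL),
        ("D", "C", "Cs", FEMALE, NORMAL),
        ("Ds", None, None, MALE, NORMAL),
        ("E", "Ds", "D", MALE, AFFECTED),
    ])
    assert detect_consanguineous_loops(ped) == []


def test_loop_fixture_detection(loop_ped):
    loops = detect_consanguineous_loops(loop_ped)
    assert len(loops) == 1
    loop = loops[0]
    assert set(loop.candidate_transmitters) == {"I-1", "II-2"}
    assert set(loop.members) == {"I-1", "II-1", "II-2", "III-1", "IV-1", "IV-2"}
    assert loop.anchor == "F-1"


def test_loop_fixture_split_matches_published_configurations(loop_ped):
    loop = detect_consanguineous_loops(loop_ped)[0]
    configs = {c.label: c for c in split_configurations(loop, loop_ped)}
    via_ii2 = configs["via II-2"]
    assert (via_ii2.n_affected, via_ii2.n_obligate_nonpenetrant,
            via_ii2.n_normal_childless) == (1, 2, 1)
    assert [t.depth for t in via_ii2.normal_trees] == [2]
    assert len(via_ii2.normal_trees[0].children) == 1
    assert sorted(via_ii2.normal_trees[0].member_ids()) == ["I-1", "II-1"]

    via_i1 = configs["via I-1"]
    assert (via_i1.n_affected, via_i1.n_obligate_nonpenetrant,
            via_i1.n_normal_childless) == (1, 3, 2)
    assert via_i1.normal_trees == []


def test_configurations_cover_identical_member_multiset(loop_ped):
    filtered = filter_pedigree(loop_ped)
    loop = filtered.counts.consanguineous_trees[0]
    for cfg in loop.configurations:
        assert cfg.n_members == len(loop.members)


def test_single_route_loop_config_drop():
    """If one branch carries an affected individual, only the configuration
    through that branch survives."""
    from dataclasses import replace

    import penetrance

    ped = penetrance.example_pedigree("loop")
    inds = dict(ped.individuals)
    inds["II-2"] = replace(inds["II-2"], phenotype=AFFECTED)
    ped2 = Pedigree(family_id="L2", individuals=inds)
    filtered = filter_pedigree(ped2)
    loop = filtered.counts.consanguineous_trees[0]
    assert len(loop.configurations) == 1
    assert loop.configurations[0].label == "via II-2"


def test_gene_drop_never_misclassifies_affected(classic_ped):
    """Every phenotypically affected individual in simulated data lands in
    the penetrant-carrier class (or an affected twin class)."""
    from penetrance import SimulationConfig, gene_drop

    cfg = SimulationConfig(topology=classic_ped, k_true=0.6, n_replicates=25, seed=3)
    for rep in gene_drop(cfg):
        if not rep.affected():
            continue
        filtered = filter_pedigree(rep)
        for ind in rep.affected():
            label = filtered.classification[ind.id]
            assert label.startswith(("affected", "twin"))
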