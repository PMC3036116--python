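"""Gene-drop simulation and bundled example pedigrees.

The gene drop implements the estimation model generatively: the designated
carrier founder is Aa, every other founder is aa, each child of a carrier
inherits the allele with probability 1/2, and each carrier is affected
with probability ``k_true``.  Same-sex twin pairs in the topology are
monozygotic with probability ``mz_prob`` (shared genotype, independent
expression).  Simulated pedigrees therefore satisfy the estimator's
assumptions exactly, which is what makes them useful for parameter
recovery and coverage studies.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import yaml

from .io import read_ped, write_ped
from .pedigree import (
    AFFECTED,
    FEMALE,
    MALE,
    NORMAL,
    UNKNOWN,
    Individual,
    Pedigree,
    PedigreeError,
)

MAX_SEED = 2**31 - 1


@dataclass
class SimulationConfig:
    """Gene-drop settings: a phenotype-free topology plus the true model."""

    topology: Pedigree
    k_true: float
    n_replicates: int = 1
    seed: int = 0
    mz_prob: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.k_true <= 1.0:
            raise ValueError("k_true must lie in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")
        if not self.topology.designated_carriers():
            raise PedigreeError(
                "simulation topology must designate the carrier founder"
            )


def gene_drop(config: SimulationConfig) -> list[Pedigree]:
    """Simulate phenotypes for each replicate; the seed fixes the stream."""
    rng = np.random.default_rng(config.seed)
    topology = config.topology
    origin = topology.designated_carriers()[0].id
    order = list(nx.lexicographical_topological_sort(topology.parent_graph()))
    twin_partner = {}
    for _, (a, b) in topology.twin_pairs().items():
        twin_partner[a.id] = b.id
        twin_partner[b.id] = a.id

    replicates = []
    for _ in range(config.n_replicates):
        mz: dict[str, bool] = {}
        for pair_id, (a, b) in topology.twin_pairs().items():
            is_mz = bool(a.sex == b.sex and rng.random() < config.mz_prob)
            mz[a.id] = mz[b.id] = is_mz

        carrier: dict[str, bool] = {}
        phenotype: dict[str, str] = {}
        for iid in order:
            ind = topology[iid]
            partner = twin_partner.get(iid)
            if partner is not None and partner in carrier and mz[iid]:
                carrier[iid] = carrier[partner]
            elif ind.is_founder:
                carrier[iid] = iid == origin
            else:
                n_carrier_parents = sum(
                    carrier[p] for p in (ind.father_id, ind.mother_id)
                )
                carrier[iid] = bool(rng.random() < 1.0 - 0.5**n_carrier_parents)
            if carrier[iid]:
                phenotype[iid] = (
                    AFFECTED if rng.random() < config.k_true else NORMAL
                )
            else:
                phenotype[iid] = NORMAL
        replicates.append(topology.with_phenotypes(phenotype))
    return replicates


def simulate_to_files(config: SimulationConfig, outdir) -> dict:
    """Write one PED + sidecar per replicate plus a checksum manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "k_true": config.k_true,
        "seed": config.seed,
        "n_replicates": config.n_replicates,
        "replicates": [],
    }
    for i, ped in enumerate(gene_drop(config), start=1):
        ped_path = outdir / f"replicate_{i:04d}.ped"
        ann_path = outdir / f"replicate_{i:04d}.yaml"
        write_ped(ped, ped_path, annotations=ann_path)
        digest = hashlib.sha256(ped_path.read_bytes()).hexdigest()
        manifest["replicates"].append(
            {"ped": ped_path.name, "annotations": ann_path.name, "sha256": digest}
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_simulation_config(path) -> SimulationConfig:
    """Read a :class:`SimulationConfig` from a YAML file.

    Keys: ``k_true`` (required), ``replicates``, ``seed``, ``mz_prob`` and
    ``topology``, which is either ``{ped: file, annotations: file}`` or
    ``{random: {generations, sibship_mean, mate_prob, seed}}``.
    """
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "k_true" not in data:
        raise ValueError(f"{path}: simulation config needs 'k_true'")
    topo_spec = data.get("topology") or {}
    if "ped" in topo_spec:
        ann = topo_spec.get("annotations")
        topology = read_ped(
            path.parent / topo_spec["ped"],
            annotations=path.parent / ann if ann else None,
        )
    else:
        rnd = topo_spec.get("random") or {}
        topology = random_topology(
            seed=int(rnd.get("seed", data.get("seed", 0))),
            generations=int(rnd.get("generations", 4)),
            sibship_mean=float(rnd.get("sibship_mean", 2.0)),
            mate_prob=float(rnd.get("mate_prob", 0.6)),
        )
    return SimulationConfig(
        topology=topology,
        k_true=float(data["k_true"]),
        n_replicates=int(data.get("replicates", 1)),
        seed=int(data.get("seed", 0)),
        mz_prob=float(data.get("mz_prob", 0.5)),
    )


# ---------------------------------------------------------------------------
# random topologies
# ---------------------------------------------------------------------------

def random_topology(
    seed: Optional[int] = None,
    *,
    rng: Optional[np.random.Generator] = None,
    generations: int = 4,
    sibship_mean: float = 2.0,
    mate_prob: float = 0.6,
    family_id: str = "SIM",
) -> Pedigree:
    """A random phenotype-free pedigree skeleton.

    One founder couple, sibship sizes 1 + Poisson(``sibship_mean``), and
    each non-terminal child marrying in a spouse with probability
    ``mate_prob``.  The blood founder is the designated carrier.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    inds: dict[str, Individual] = {}
    father, mother = "G1-1", "G1-1s"
    inds[father] = Individual(id=father, sex=MALE, phenotype=UNKNOWN,
                              designated_carrier=True)
    inds[mother] = Individual(id=mother, sex=FEMALE, phenotype=UNKNOWN)
    couples = [(father, mother)]
    for g in range(2, generations + 1):
        next_couples = []
        n_in_gen = 0
        for f, m in couples:
            n_kids = 1 + int(rng.poisson(sibship_mean))
            for _ in range(n_kids):
                n_in_gen += 1
                kid = f"G{g}-{n_in_gen}"
                sex = MALE if rng.random() < 0.5 else FEMALE
                inds[kid] = Individual(
                    id=kid, father_id=f, mother_id=m, sex=sex, phenotype=UNKNOWN
                )
                if g < generations and rng.random() < mate_prob:
                    spouse = kid + "s"
                    inds[spouse] = Individual(
                        id=spouse,
                        sex=FEMALE if sex == MALE else MALE,
                        phenotype=UNKNOWN,
                    )
                    pair = (kid, spouse) if sex == MALE else (spouse, kid)
                    next_couples.append(pair)
        couples = next_couples
        if not couples:
            break
    return Pedigree(family_id=family_id, individuals=inds)


# ---------------------------------------------------------------------------
# bundled example pedigrees
# ---------------------------------------------------------------------------

def _ind(iid, father=None, mother=None, sex=UNKNOWN, pheno=NORMAL, **kw):
    return Individual(
        id=iid, father_id=father, mother_id=mother, sex=sex, phenotype=pheno, **kw
    )


def _classic_pedigree() -> Pedigree:
    """A four-generation textbook pedigree for an incompletely penetrant
    autosomal dominant trait.

    Three affected individuals (II-4, III-4, IV-1) force four obligate
    non-penetrant carriers (I-1, II-1, II-3, III-1); II-5 and II-6 are
    childless normals born to the carrier founder, and two 2-generation
    normal trees hang off the carrier line (II-2 with III-2, III-3; III-5
    with IV-2 to IV-4).  The founder I-1 is designated as the allele
    origin (either member of the founder couple could otherwise have
    transmitted).
    """
    rows = [
        _ind("I-1", sex=MALE, designated_carrier=True),
        _ind("I-2", sex=FEMALE),
        _ind("II-1", "I-1", "I-2", MALE),
        _ind("II-2", "I-1", "I-2", FEMALE),
        _ind("II-3", "I-1", "I-2", FEMALE),
        _ind("II-4", "I-1", "I-2", MALE, AFFECTED),
        _ind("II-5", "I-1", "I-2", FEMALE),
        _ind("II-6", "I-1", "I-2", MALE),
        # married-in spouses
        _ind("II-1s", sex=FEMALE),
        _ind("II-2s", sex=MALE),
        _ind("II-3s", sex=MALE),
        _ind("II-4s", sex=FEMALE),
        # generation III
        _ind("III-1", "II-1", "II-1s", MALE),
        _ind("III-2", "II-2s", "II-2", FEMALE),
        _ind("III-3", "II-2s", "II-2", MALE),
        _ind("III-4", "II-3s", "II-3", FEMALE, AFFECTED),
        _ind("III-5", "II-4", "II-4s", MALE),
        _ind("III-1s", sex=FEMALE),
        _ind("III-5s", sex=FEMALE),
        # generation IV
        _ind("IV-1", "III-1", "III-1s", MALE, AFFECTED),
        _ind("IV-2", "III-5", "III-5s", FEMALE),
        _ind("IV-3", "III-5", "III-5s", MALE),
        _ind("IV-4", "III-5", "III-5s", FEMALE),
    ]
    return Pedigree(family_id="CLASSIC", individuals={i.id: i for i in rows})


def _loop_pedigree() -> Pedigree:
    """A consanguineous example: the couple II-1 x II-2 are both blood
    descendants of the designated carrier founder F-1, so their affected
    grandchild IV-2 may have received the allele through either I-1's or
    II-2's branch.  Splitting yields two transmission configurations over
    the six loop members (I-1, II-1, II-2, III-1, IV-1, IV-2)."""
    rows = [
        _ind("F-1", sex=MALE, designated_carrier=True),
        _ind("F-2", sex=FEMALE),
        _ind("I-1", "F-1", "F-2", MALE),
        _ind("I-2", sex=FEMALE),
        _ind("II-1", "I-1", "I-2", MALE),
        _ind("II-2", "F-1", "F-2", FEMALE),
        _ind("III-1", "II-1", "II-2", MALE),
        _ind("III-1s", sex=FEMALE),
        _ind("IV-1", "III-1", "III-1s", FEMALE),
        _ind("IV-2", "III-1", "III-1s", MALE, AFFECTED),
    ]
    return Pedigree(family_id="LOOP", individuals={i.id: i for i in rows})


EXAMPLE_NAMES = ("classic", "loop")


def example_pedigree(name: str) -> Pedigree:
    """Bundled example pedigrees: ``classic`` (loop-free, four generations)
    and ``loop`` (one consanguineous tree with two configurations)."""
    if name == "classic":
        return _classic_pedigree()
    if name == "loop":
        return _loop_pedigree()
    raise ValueError(f"unknown example {name!r}; choose from {EXAMPLE_NAMES}")
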