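"""Reading and writing pedigrees and structure-count files.

Two on-disk formats are supported:

* **LINKAGE/PED** (pre-makeped, 6 mandatory whitespace-separated columns:
  family, individual, father, mother, sex, phenotype; ``0`` codes a missing
  parent or unknown sex/phenotype, phenotype ``1`` = normal, ``2`` =
  affected).  Extra columns are ignored with a warning.  Twin pairs and the
  designated carrier founder are not expressible in PED and live in an
  optional YAML sidecar::

      carrier: I-1
      twins:
        - [III-2, III-3]

* **structure counts**, a line-oriented comma-separated dialect.  Line 1
  holds the three point counts ``A,B,C``; line 2 the number of
  2-generation normal trees followed by their offspring numbers; lines 3-5
  the 3-, 4- and 5-generation trees; the next line the three same-sex
  twin-pair counts (both normal, discordant, both affected); the last line
  the number of consanguineous trees.  Trees of depth >= 3 use this
  package's nested-parenthesis extension (each individual is ``(...)``
  wrapping its children, so ``(()())`` is a root with two childless
  children), and each consanguineous tree follows as a configuration count
  on its own line and then one 6-line block per configuration.  Files
  written here carry a header comment flagging the extension.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, TextIO, Union

import yaml

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
from .structures import ConsanguineousTree, NormalTree, StructureCounts

logger = logging.getLogger("penetrance")

_SEX_CODES = {"1": MALE, "2": FEMALE, "0": UNKNOWN}
_SEX_TO_CODE = {v: k for k, v in _SEX_CODES.items()}
_PHENO_CODES = {"1": NORMAL, "2": AFFECTED, "0": UNKNOWN}
_PHENO_TO_CODE = {v: k for k, v in _PHENO_CODES.items()}

COUNTS_HEADER = (
    "# structure counts; extended dialect: depth>=3 trees in "
    "nested-parenthesis form, consanguineous configurations as 6-line blocks"
)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input file; carries file name and line number."""

    def __init__(self, path: PathLike, line_no: Optional[int], message: str):
        where = f"{path}:{line_no}" if line_no is not None else str(path)
        super().__init__(f"{where}: {message}")
        self.path = str(path)
        self.line_no = line_no


# ---------------------------------------------------------------------------
# PED + sidecar
# ---------------------------------------------------------------------------

def read_ped(path: PathLike, annotations: Optional[PathLike] = None) -> Pedigree:
    """Read a 6-column LINKAGE/PED file into a validated :class:`Pedigree`.

    ``annotations`` optionally points at a YAML sidecar declaring twin
    pairs and the designated carrier founder (see module docstring).
    """
    path = Path(path)
    rows: list[tuple[int, list[str]]] = []
    with open(path) as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 6:
                raise ParseError(
                    path, line_no, f"expected 6 columns, got {len(fields)}"
                )
            if len(fields) > 6:
                logger.warning(
                    "%s:%d: ignoring %d extra column(s)",
                    path,
                    line_no,
                    len(fields) - 6,
                )
            rows.append((line_no, fields[:6]))

    individuals: dict[str, Individual] = {}
    family_id: Optional[str] = None
    for line_no, (fam, iid, father, mother, sex, pheno) in rows:
        if family_id is None:
            family_id = fam
        elif fam != family_id:
            raise ParseError(
                path, line_no, f"multiple families in one file ({family_id!r}, {fam!r})"
            )
        if iid == "0":
            raise ParseError(path, line_no, "individual id '0' is reserved")
        if iid in individuals:
            raise ParseError(path, line_no, f"duplicate individual {iid!r}")
        if sex not in _SEX_CODES:
            raise ParseError(path, line_no, f"invalid sex code {sex!r}")
        if pheno not in _PHENO_CODES:
            raise ParseError(path, line_no, f"invalid phenotype code {pheno!r}")
        if (father == "0") != (mother == "0"):
            raise ParseError(
                path, line_no, f"individual {iid!r}: exactly one parent is missing"
            )
        if iid in (father, mother):
            raise PedigreeError(f"individual {iid!r} listed as its own parent")
        individuals[iid] = Individual(
            id=iid,
            father_id=None if father == "0" else father,
            mother_id=None if mother == "0" else mother,
            sex=_SEX_CODES[sex],
            phenotype=_PHENO_CODES[pheno],
        )
    if not individuals:
        raise ParseError(path, None, "empty pedigree file")

    if annotations is not None:
        individuals = _apply_annotations(Path(annotations), individuals)

    return Pedigree(family_id=family_id or "FAM", individuals=individuals)


def _apply_annotations(
    path: Path, individuals: dict[str, Individual]
) -> dict[str, Individual]:
    from dataclasses import replace

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ParseError(path, None, "annotation file must be a YAML mapping")

    out = dict(individuals)
    carrier = data.get("carrier")
    if carrier is not None:
        carrier = str(carrier)
        if carrier not in out:
            raise PedigreeError(
                f"designated carrier {carrier!r} is not in the pedigree"
            )
        out[carrier] = replace(out[carrier], designated_carrier=True)

    for n, pair in enumerate(data.get("twins") or [], start=1):
        if not isinstance(pair, (list, tuple)) or len(pair) != 2:
            raise ParseError(path, None, f"twin entry {pair!r} is not a pair")
        a, b = (str(x) for x in pair)
        for iid in (a, b):
            if iid not in out:
                raise PedigreeError(f"twin annotation names unknown individual {iid!r}")
        pair_id = f"T{n}"
        out[a] = replace(out[a], twin_pair_id=pair_id)
        out[b] = replace(out[b], twin_pair_id=pair_id)
    return out


def write_ped(
    pedigree: Pedigree,
    path: PathLike,
    annotations: Optional[PathLike] = None,
) -> None:
    """Write a pedigree as 6-column PED, optionally with a YAML sidecar."""
    with open(path, "w") as fh:
        for ind in pedigree:
            fh.write(
                " ".join(
                    [
                        pedigree.family_id,
                        ind.id,
                        ind.father_id or "0",
                        ind.mother_id or "0",
                        _SEX_TO_CODE[ind.sex],
                        _PHENO_TO_CODE[ind.phenotype],
                    ]
                )
                + "\n"
            )
    if annotations is not None:
        data: dict = {}
        carriers = pedigree.designated_carriers()
        if carriers:
            data["carrier"] = carriers[0].id
        pairs = pedigree.twin_pairs()
        if pairs:
            data["twins"] = [[a.id, b.id] for a, b in pairs.values()]
        with open(annotations, "w") as fh:
            yaml.safe_dump(data, fh, default_flow_style=None, sort_keys=False)


# ---------------------------------------------------------------------------
# structure-counts dialect
# ---------------------------------------------------------------------------

def _tree_to_parens(tree: NormalTree) -> str:
    return "(" + "".join(_tree_to_parens(c) for c in tree.children) + ")"


def _tree_from_parens(text: str, path: PathLike, line_no: int) -> NormalTree:
    pos = 0

    def parse() -> NormalTree:
        nonlocal pos
        if pos >= len(text) or text[pos] != "(":
            raise ParseError(path, line_no, f"bad tree syntax at {text[pos:]!r}")
        pos += 1
        children = []
        while pos < len(text) and text[pos] == "(":
            children.append(parse())
        if pos >= len(text) or text[pos] != ")":
            raise ParseError(path, line_no, "unbalanced parentheses in tree")
        pos += 1
        return NormalTree(children=tuple(children))

    tree = parse()
    if pos != len(text):
        raise ParseError(path, line_no, f"trailing characters in tree: {text[pos:]!r}")
    return tree


class _Lines:
    """Iterator over meaningful lines, tracking line numbers for errors."""

    def __init__(self, fh: TextIO, path: PathLike):
        self.path = path
        self.items: list[tuple[int, str]] = []
        for no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if line and not line.startswith("#"):
                self.items.append((no, line))
        self.cursor = 0
        self.last_no = 0

    def next(self, what: str) -> tuple[int, list[str]]:
        if self.cursor >= len(self.items):
            raise ParseError(self.path, self.last_no, f"unexpected end of file ({what})")
        no, line = self.items[self.cursor]
        self.cursor += 1
        self.last_no = no
        return no, [f.strip() for f in line.split(",")]

    @property
    def exhausted(self) -> bool:
        return self.cursor >= len(self.items)


def _int_field(value: str, path: PathLike, line_no: int, what: str) -> int:
    try:
        n = int(value)
    except ValueError:
        raise ParseError(path, line_no, f"{what}: {value!r} is not an integer")
    if n < 0:
        raise ParseError(path, line_no, f"{what}: negative count {n}")
    return n


def _read_counts_block(lines: _Lines, allow_consanguineous: bool) -> StructureCounts:
    path = lines.path
    no, fields = lines.next("A,B,C line")
    if len(fields) != 3:
        raise ParseError(path, no, f"expected 3 point counts, got {len(fields)}")
    a, b, c = (_int_field(f, path, no, "point count") for f in fields)

    trees: list[NormalTree] = []
    # 2-generation trees: count followed by per-tree offspring numbers
    no, fields = lines.next("2-generation tree line")
    n2 = _int_field(fields[0], path, no, "2-generation tree count")
    if len(fields) - 1 != n2:
        raise ParseError(
            path, no, f"declared {n2} two-generation tree(s) but listed {len(fields) - 1}"
        )
    for f in fields[1:]:
        n_off = _int_field(f, path, no, "offspring number")
        if n_off < 1:
            raise ParseError(path, no, "a 2-generation tree needs >= 1 offspring")
        trees.append(NormalTree.two_generation(n_off))

    for depth in (3, 4, 5):
        no, fields = lines.next(f"{depth}-generation tree line")
        n_d = _int_field(fields[0], path, no, f"{depth}-generation tree count")
        if len(fields) - 1 != n_d:
            raise ParseError(
                path, no, f"declared {n_d} tree(s) but listed {len(fields) - 1}"
            )
        for f in fields[1:]:
            tree = _tree_from_parens(f, path, no)
            if tree.depth != depth:
                raise ParseError(
                    path, no, f"tree {f!r} has depth {tree.depth}, expected {depth}"
                )
            trees.append(tree)

    no, fields = lines.next("twin-count line")
    if len(fields) != 3:
        raise ParseError(path, no, f"expected 3 twin counts, got {len(fields)}")
    tw_nn, tw_na, tw_aa = (_int_field(f, path, no, "twin count") for f in fields)

    no, fields = lines.next("consanguineous-tree line")
    n_loops = _int_field(fields[0], path, no, "consanguineous tree count")
    loops: list[ConsanguineousTree] = []
    if n_loops and not allow_consanguineous:
        raise ParseError(path, no, "consanguineous trees cannot nest")
    for i in range(n_loops):
        no, fields = lines.next("configuration-count line")
        n_cfg = _int_field(fields[0], path, no, "configuration count")
        if n_cfg < 2:
            raise ParseError(path, no, "a consanguineous tree needs >= 2 configurations")
        configs = [
            _read_counts_block(lines, allow_consanguineous=False)
            for _ in range(n_cfg)
        ]
        for j, cfg in enumerate(configs, start=1):
            cfg.label = f"loop{i + 1}/config{j}"
        loops.append(ConsanguineousTree(configurations=configs, label=f"loop{i + 1}"))

    return StructureCounts(
        n_affected=a,
        n_obligate_nonpenetrant=b,
        n_normal_childless=c,
        normal_trees=trees,
        twin_both_normal=tw_nn,
        twin_discordant=tw_na,
        twin_both_affected=tw_aa,
        consanguineous_trees=loops,
    )


def read_counts(path: PathLike) -> StructureCounts:
    """Read a structure-counts file (see module docstring for the dialect)."""
    path = Path(path)
    with open(path) as fh:
        lines = _Lines(fh, path)
        counts = _read_counts_block(lines, allow_consanguineous=True)
    if not lines.exhausted:
        no, _ = lines.items[lines.cursor]
        raise ParseError(path, no, "trailing content after counts")
    return counts


def _write_counts_block(counts: StructureCounts, out: list[str]) -> None:
    out.append(
        f"{counts.n_affected},{counts.n_obligate_nonpenetrant},"
        f"{counts.n_normal_childless}"
    )
    by_depth = counts.trees_by_depth()
    too_deep = sorted(d for d in by_depth if d > 5)
    if too_deep:
        raise ValueError(
            f"counts dialect supports trees up to depth 5; got depth {too_deep[-1]}"
        )
    two_gen = by_depth.get(2, [])
    out.append(",".join([str(len(two_gen))] + [str(len(t.children)) for t in two_gen]))
    for depth in (3, 4, 5):
        trees = by_depth.get(depth, [])
        out.append(",".join([str(len(trees))] + [_tree_to_parens(t) for t in trees]))
    out.append(
        f"{counts.twin_both_normal},{counts.twin_discordant},{counts.twin_both_affected}"
    )
    out.append(str(len(counts.consanguineous_trees)))
    for tree in counts.consanguineous_trees:
        out.append(str(len(tree.configurations)))
        for cfg in tree.configurations:
            _write_counts_block(cfg, out)


def write_counts(counts: StructureCounts, path: PathLike) -> None:
    """Write a :class:`StructureCounts` in the counts dialect (round-trips
    with :func:`read_counts` up to tree member ids)."""
    out: list[str] = [COUNTS_HEADER]
    _write_counts_block(counts, out)
    with open(path, "w") as fh:
        fh.write("\n".join(out) + "\n")
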