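"""Modular feature extraction for N-glycan structures.

A glycan tree is decomposed into the modular features used throughout the
mining layer:

* **core class** -- Core-I (plain GlcNAc2Man3), Core-II (core-fucosylated),
  Core-III (bisected), Core-IV (both).  Core fucose is a Fuc child of the
  reducing-end HexNAc; the bisecting GlcNAc is a HexNAc child of the
  beta-mannose.
* **subtype** -- oligo-mannose, hybrid or complex, by whether arm mannoses
  carry only mannose extensions, a mixture, or only HexNAc-initiated branches.
* **branches** -- one motif label per branch position, where a branch is the
  maximal subtree rooted at a child of an arm mannose (the bisecting GlcNAc
  sits on the beta-mannose and is never a branch).  Arms without children
  contribute the EMPTY label "⌀".
* **antenna count**, **fucosylation class** (none/core/antenna/both) and
  **sialylation class** (none/Neu5Ac/Neu5Gc/both).

Monosaccharide identity below the Hex/HexNAc level is inferred from tree
position only: core Hex residues are mannoses, the Hex child of a branch
HexNAc is galactose, a branch-initiating HexNAc is GlcNAc and a HexNAc child
of a branch HexNAc is GalNAc -- hence N(N) is LacdiNAc without needing
monosaccharide-resolved input.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

from .glycan import (
    GlycanStructure,
    GlycanStructureError,
    MonosaccharideNode,
    parse_structure,
    serialize_canonical,
)

__all__ = [
    "EMPTY_BRANCH",
    "BRANCH_MOTIFS",
    "MotifTable",
    "GlycanFeatureVector",
    "classify_core",
    "classify_subtype",
    "extract_branches",
    "count_antennae",
    "fucosylation_class",
    "sialylation_class",
    "featurize",
]

EMPTY_BRANCH = "⌀"
OTHER_BRANCH = "other"

#: Built-in branch motif table: canonical branch code -> label.  Codes are
#: canonical serializations of the branch subtree (siblings sorted), so a
#: single exact-match entry covers every sibling ordering.
BRANCH_MOTIFS: dict[str, str] = {
    "N": "sole GlcNAc",
    "N(H)": "LacNAc",
    "N(H(A))": "sialyl-LacNAc-Neu5Ac",
    "N(H(G))": "sialyl-LacNAc-Neu5Gc",
    "N(F)(H)": "Lewis x/a",
    "N(F)(H(F))": "Lewis y/b",
    "N(F)(H(A))": "sLewis x/a",
    "N(F)(H(G))": "sLewis x/a",
    "N(N)": "LacdiNAc",
    "N(N(A))": "sialyl-LacdiNAc",
    "N(N(G))": "sialyl-LacdiNAc",
    "N(F)(N)": "fucosylated LacdiNAc",
}

#: Labels of the built-in motif vocabulary (13 motifs + EMPTY + other).
MOTIF_LABELS: tuple[str, ...] = (
    "Hex",
    "sole GlcNAc",
    "LacNAc",
    "sialyl-LacNAc-Neu5Ac",
    "sialyl-LacNAc-Neu5Gc",
    "Lewis x/a",
    "Lewis y/b",
    "sLewis x/a",
    "LacdiNAc",
    "sialyl-LacdiNAc",
    "fucosylated LacdiNAc",
    "polyLacNAc",
    OTHER_BRANCH,
    EMPTY_BRANCH,
)

#: Motif labels of the LacdiNAc family (plain, sialylated, fucosylated).
LACDINAC_FAMILY = frozenset(
    {"LacdiNAc", "sialyl-LacdiNAc", "fucosylated LacdiNAc"})

#: Motif labels carrying a sialic acid.
SIALYL_MOTIFS = frozenset(
    {"sialyl-LacNAc-Neu5Ac", "sialyl-LacNAc-Neu5Gc", "sLewis x/a",
     "sialyl-LacdiNAc"})


class MotifTable:
    """Extensible branch motif table.

    User entries (label -> branch structure code) take priority over the
    built-in exact matches; the rule-based matchers for oligo-mannose
    extensions (all-Hex subtrees) and polyLacNAc repeats run after exact
    matching, and anything left maps to ``"other"``.
    """

    def __init__(self, extra: dict[str, str] | None = None):
        self._exact: dict[str, str] = {}
        if extra:
            for label, code in extra.items():
                node = parse_structure(code, relaxed=True).root
                self._exact[serialize_canonical(node)] = label
        for code, label in BRANCH_MOTIFS.items():
            self._exact.setdefault(code, label)

    def match(self, branch: MonosaccharideNode) -> str:
        if all(n.symbol == "H" for n in branch.walk()):
            return "Hex"
        canon = serialize_canonical(branch)
        if canon in self._exact:
            return self._exact[canon]
        if _is_poly_lacnac(branch):
            return "polyLacNAc"
        warnings.warn(
            f"branch subtree {canon!r} matches no motif; labelled "
            f"{OTHER_BRANCH!r}", stacklevel=2)
        return OTHER_BRANCH


_DEFAULT_TABLE = MotifTable()


def _is_poly_lacnac(branch: MonosaccharideNode) -> bool:
    """Pure repeated-LacNAc chain N(H(N(H(...)))) with >= 2 units."""
    units = 0
    node: MonosaccharideNode | None = branch
    while node is not None:
        if node.symbol != "N" or len(node.children) != 1:
            return False
        gal = node.children[0]
        if gal.symbol != "H" or len(gal.children) > 1:
            return False
        units += 1
        node = gal.children[0] if gal.children else None
    return units >= 2


@dataclass(frozen=True)
class GlycanFeatureVector:
    """Bundle of modular features for one glycan structure."""

    core_class: str
    subtype: str
    branches: tuple[str, ...]  # sorted multiset of branch labels, incl. EMPTY
    antenna_count: int
    fucosylation: str
    sialylation: str
    bisecting: bool
    branch_set: frozenset[str] = field(default=frozenset())

    def branch_counter(self) -> Counter:
        return Counter(self.branches)


def _require_core(structure: GlycanStructure, op: str) -> None:
    if structure.truncated or structure.beta_mannose is None:
        raise GlycanStructureError(
            f"{op} requires a full N-glycan core; structure is truncated")


def _core_fucose(structure: GlycanStructure) -> bool:
    return any(c.symbol == "F" for c in structure.root.children)


def _bisecting_node(structure: GlycanStructure) -> MonosaccharideNode | None:
    bman = structure.beta_mannose
    if bman is None:
        return None
    return next((c for c in bman.children if c.symbol == "N"), None)


def classify_core(structure: GlycanStructure) -> str:
    """Core-I/II/III/IV by core fucose and bisecting GlcNAc presence."""
    _require_core(structure, "classify_core")
    fuc = _core_fucose(structure)
    bis = _bisecting_node(structure) is not None
    if fuc and bis:
        return "Core-IV"
    if fuc:
        return "Core-II"
    if bis:
        return "Core-III"
    return "Core-I"


def _branch_nodes(structure: GlycanStructure) -> list[tuple[MonosaccharideNode | None, str]]:
    """(subtree, kind) per branch position; kind in {hexnac, hex, other, empty}."""
    out: list[tuple[MonosaccharideNode | None, str]] = []
    for arm in structure.arm_mannoses:
        if not arm.children:
            out.append((None, "empty"))
            continue
        for child in arm.children:
            if child.symbol == "N":
                out.append((child, "hexnac"))
            elif child.symbol == "H":
                out.append((child, "hex"))
            else:
                out.append((child, "other"))
    return out


def classify_subtype(structure: GlycanStructure) -> str:
    """oligo-mannose / hybrid / complex.

    oligo-mannose: no HexNAc-initiated branch on any arm mannose.
    complex: at least one HexNAc-initiated branch and no mannose-extension
    (Hex-only) branch remains.  hybrid: both kinds present (one arm
    mannose-extended, another HexNAc-initiated).
    """
    _require_core(structure, "classify_subtype")
    kinds = {kind for _, kind in _branch_nodes(structure) if kind != "empty"}
    has_n = "hexnac" in kinds
    has_h = "hex" in kinds
    if not has_n:
        return "oligo-mannose"
    return "hybrid" if has_h else "complex"


def extract_branches(
    structure: GlycanStructure, table: MotifTable | None = None
) -> Counter:
    """Multiset of branch motif labels, one per branch position.

    Arm mannoses without children contribute the EMPTY label.  The bisecting
    GlcNAc (on the beta-mannose) is never a branch.
    """
    _require_core(structure, "extract_branches")
    table = table or _DEFAULT_TABLE
    labels: Counter = Counter()
    for node, kind in _branch_nodes(structure):
        if kind == "empty":
            labels[EMPTY_BRANCH] += 1
        else:
            labels[table.match(node)] += 1
    return labels


def count_antennae(structure: GlycanStructure) -> int:
    """Number of non-EMPTY branches (bisecting GlcNAc excluded)."""
    _require_core(structure, "count_antennae")
    return sum(1 for _, kind in _branch_nodes(structure) if kind != "empty")


def fucosylation_class(structure: GlycanStructure) -> str:
    """none / core / antenna / both by fucose location."""
    core = _core_fucose(structure)
    antenna = False
    for node in structure.root.walk():
        if node is structure.root:
            continue
        if any(c.symbol == "F" for c in node.children):
            antenna = True
            break
    if core and antenna:
        return "both"
    if core:
        return "core"
    if antenna:
        return "antenna"
    return "none"


def sialylation_class(structure: GlycanStructure) -> str:
    """none / Neu5Ac / Neu5Gc / both by sialic-acid node presence."""
    has_a = has_g = False
    for node in structure.root.walk():
        if node.symbol == "A":
            has_a = True
        elif node.symbol == "G":
            has_g = True
    if has_a and has_g:
        return "both"
    if has_a:
        return "Neu5Ac"
    if has_g:
        return "Neu5Gc"
    return "none"


def featurize(
    structure: GlycanStructure | str, table: MotifTable | None = None
) -> GlycanFeatureVector:
    """Full modular feature vector of a structure (or structure code)."""
    if isinstance(structure, str):
        structure = parse_structure(structure)
    branches = extract_branches(structure, table)
    labels = tuple(sorted(branches.elements()))
    return GlycanFeatureVector(
        core_class=classify_core(structure),
        subtype=classify_subtype(structure),
        branches=labels,
        antenna_count=count_antennae(structure),
        fucosylation=fucosylation_class(structure),
        sialylation=sialylation_class(structure),
        bisecting=_bisecting_node(structure) is not None,
        branch_set=frozenset(branches),
    )


def featurize_table(df, code_column: str = "glycan_code",
                    table: MotifTable | None = None):
    """Attach feature columns to an IGP DataFrame.

    Adds ``canonical_code``, ``core_class``, ``subtype``, ``antenna_count``,
    ``fucosylation``, ``sialylation``, ``bisecting`` and ``branches`` (a
    frozenset of motif labels).  Each distinct structure code is parsed once.
    """
    import pandas as pd  # deferred: the tree layer itself is pandas-free

    cache: dict[str, tuple] = {}
    for code in df[code_column].unique():
        s = parse_structure(code)
        fv = featurize(s, table)
        cache[code] = (serialize_canonical(s), fv)
    cols = {
        "canonical_code": [], "core_class": [], "subtype": [],
        "antenna_count": [], "fucosylation": [], "sialylation": [],
        "bisecting": [], "branches": [], "branch_list": [],
    }
    for code in df[code_column]:
        canon, fv = cache[code]
        cols["canonical_code"].append(canon)
        cols["core_class"].append(fv.core_class)
        cols["subtype"].append(fv.subtype)
        cols["antenna_count"].append(fv.antenna_count)
        cols["fucosylation"].append(fv.fucosylation)
        cols["sialylation"].append(fv.sialylation)
        cols["bisecting"].append(fv.bisecting)
        cols["branches"].append(fv.branch_set)
        cols["branch_list"].append(fv.branches)
    out = df.copy()
    for name, values in cols.items():
        out[name] = pd.Series(values, index=df.index)
    return out
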