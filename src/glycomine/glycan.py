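"""N-glycan compositions and rooted tree structures.

An N-glycan is modelled as a rooted tree of monosaccharide nodes.  The root is
the reducing-end HexNAc (the residue attached to the asparagine); linkage and
anomericity are deliberately not represented -- topology is the unit of
structural reasoning throughout the package.

Two text codes are used:

* **Composition code** -- letter/count pairs over ``N`` (HexNAc), ``H`` (Hex),
  ``F`` (Fucose), ``S`` (Neu5Ac) and ``G`` (Neu5Gc), e.g. ``"N4H5F1"``.  The
  ``Man<k>`` shorthand expands to ``N2Hk``.
* **Structure code** -- a linear serialization of the tree: each node is a
  single letter from ``{N, H, F, A, G}`` (``A`` = Neu5Ac, ``G`` = Neu5Gc)
  followed by its children, each wrapped in parentheses.  ``"N(N(H(H)(H)))"``
  is the bare N2H3 core.

The canonical form of a structure code orders siblings by the lexicographic
order of their own canonical serializations, so that any two trees equal up to
sibling order map to identical text.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable

__all__ = [
    "GlycanComposition",
    "MonosaccharideNode",
    "GlycanStructure",
    "GlycanParseError",
    "GlycanStructureError",
    "parse_composition",
    "parse_structure",
    "serialize_canonical",
    "composition_of",
    "group_isomers",
    "oligomannose_structure",
    "MAN_TOPOLOGIES",
    "register_converter",
    "convert_structure_code",
]

STRUCTURE_SYMBOLS = frozenset("NHFAG")

#: structure-code letter -> composition field
_SYMBOL_FIELD = {
    "N": "hexnac",
    "H": "hex",
    "F": "fuc",
    "A": "neu5ac",
    "G": "neu5gc",
}

#: composition-code letter -> composition field (note Neu5Ac is ``S`` here)
_COMP_FIELD = {
    "N": "hexnac",
    "H": "hex",
    "F": "fuc",
    "S": "neu5ac",
    "G": "neu5gc",
}


class GlycanParseError(ValueError):
    """Malformed composition or structure code."""


class GlycanStructureError(ValueError):
    """Structurally invalid glycan (e.g. truncated core in strict mode)."""


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Monosaccharide counts of an N-glycan."""

    hexnac: int = 0
    hex: int = 0
    fuc: int = 0
    neu5ac: int = 0
    neu5gc: int = 0

    def __post_init__(self) -> None:
        for name in ("hexnac", "hex", "fuc", "neu5ac", "neu5gc"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative count for {name}")

    @property
    def has_full_core(self) -> bool:
        """Whether the composition can contain the GlcNAc2Man3 core."""
        return self.hexnac >= 2 and self.hex >= 3

    def code(self) -> str:
        """Composition code with counts in N,H,F,S,G order (zeros omitted)."""
        parts = []
        for letter, name in (("N", "hexnac"), ("H", "hex"), ("F", "fuc"),
                             ("S", "neu5ac"), ("G", "neu5gc")):
            n = getattr(self, name)
            if n:
                parts.append(f"{letter}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.code()


_COMP_TOKEN = re.compile(r"([NHFSG])(\d*)")
_MAN_SHORTHAND = re.compile(r"^Man(\d+)$")


def parse_composition(code: str, relaxed: bool = False) -> GlycanComposition:
    """Parse a composition code such as ``"N4H5F1G1"`` or ``"Man5"``.

    A letter without a following integer counts as 1.  In the default strict
    mode a composition too small to contain the N-glycan core (HexNAc < 2 or
    Hex < 3) is rejected; ``relaxed=True`` accepts it.
    """
    code = code.strip()
    if not code:
        raise GlycanParseError("empty composition code")
    m = _MAN_SHORTHAND.match(code)
    if m:
        comp = GlycanComposition(hexnac=2, hex=int(m.group(1)))
        _check_core(comp, code, relaxed)
        return comp
    counts = {v: 0 for v in _COMP_FIELD.values()}
    pos = 0
    while pos < len(code):
        m = _COMP_TOKEN.match(code, pos)
        if not m:
            raise GlycanParseError(
                f"unrecognized token {code[pos:]!r} in composition {code!r}")
        letter, digits = m.group(1), m.group(2)
        counts[_COMP_FIELD[letter]] += int(digits) if digits else 1
        pos = m.end()
    comp = GlycanComposition(**counts)
    _check_core(comp, code, relaxed)
    return comp


def _check_core(comp: GlycanComposition, code: str, relaxed: bool) -> None:
    if not relaxed and not comp.has_full_core:
        raise GlycanParseError(
            f"composition {code!r} too small for an N-glycan core "
            "(needs HexNAc>=2, Hex>=3); use relaxed=True for truncated input")


@dataclass
class MonosaccharideNode:
    """One monosaccharide in the tree; ``symbol`` in {N, H, F, A, G}."""

    symbol: str
    children: list["MonosaccharideNode"] = field(default_factory=list)
    #: role tag assigned at parse time: reducing-end, core-hexnac2,
    #: beta-mannose, arm-mannose, or other
    role: str = "other"

    def walk(self) -> Iterable["MonosaccharideNode"]:
        yield self
        for child in self.children:
            yield from child.walk()

    def subtree_size(self) -> int:
        return sum(1 for _ in self.walk())


@dataclass
class GlycanStructure:
    """Rooted N-glycan tree with role-tagged core residues."""

    root: MonosaccharideNode
    #: True when the structure lacks the full GlcNAc2Man3 core (relaxed mode)
    truncated: bool = False

    # core landmarks resolved at parse/tag time (None when truncated)
    core_hexnac2: MonosaccharideNode | None = None
    beta_mannose: MonosaccharideNode | None = None
    arm_mannoses: list[MonosaccharideNode] = field(default_factory=list)

    def canonical(self) -> str:
        return serialize_canonical(self)

    def composition(self) -> GlycanComposition:
        return composition_of(self)


def _parse_node(code: str, pos: int) -> tuple[MonosaccharideNode, int]:
    if pos >= len(code):
        raise GlycanParseError("unexpected end of structure code")
    symbol = code[pos]
    if symbol not in STRUCTURE_SYMBOLS:
        raise GlycanParseError(
            f"invalid symbol {symbol!r} at position {pos} in structure code")
    node = MonosaccharideNode(symbol)
    pos += 1
    while pos < len(code) and code[pos] == "(":
        child, pos = _parse_node(code, pos + 1)
        if pos >= len(code) or code[pos] != ")":
            raise GlycanParseError("unbalanced parentheses in structure code")
        node.children.append(child)
        pos += 1
    return node, pos


def parse_structure(code: str, relaxed: bool = False) -> GlycanStructure:
    """Parse a linear structure code into a role-tagged tree.

    Strict mode (default) requires the reducing-end HexNAc, the second core
    HexNAc, the beta-mannose and two arm mannoses; ``relaxed=True`` accepts
    truncated/paucimannose structures, which are flagged ``truncated``.
    """
    code = code.strip()
    if not code:
        raise GlycanParseError("empty structure code")
    root, pos = _parse_node(code, 0)
    if pos != len(code):
        raise GlycanParseError(
            f"trailing characters {code[pos:]!r} in structure code")
    return _tag_roles(root, relaxed)


def _tag_roles(root: MonosaccharideNode, relaxed: bool) -> GlycanStructure:
    if root.symbol != "N":
        if not relaxed:
            raise GlycanStructureError(
                "root must be the reducing-end HexNAc (N) in strict mode")
        return GlycanStructure(root=root, truncated=True)
    root.role = "reducing-end"
    core2 = next((c for c in root.children if c.symbol == "N"), None)
    bman = None
    arms: list[MonosaccharideNode] = []
    if core2 is not None:
        core2.role = "core-hexnac2"
        bman = next((c for c in core2.children if c.symbol == "H"), None)
    if bman is not None:
        bman.role = "beta-mannose"
        arms = [c for c in bman.children if c.symbol == "H"]
        for arm in arms:
            arm.role = "arm-mannose"
    truncated = core2 is None or bman is None or len(arms) < 2
    if truncated and not relaxed:
        raise GlycanStructureError(
            "truncated N-glycan core (needs N-N-H with two arm mannoses); "
            "use relaxed=True to accept")
    return GlycanStructure(
        root=root, truncated=truncated, core_hexnac2=core2,
        beta_mannose=bman, arm_mannoses=arms)


def _canonical_text(node: MonosaccharideNode) -> str:
    # Siblings sorted by their own canonical text; equal texts denote
    # identical subtrees, so no further tie-break can matter.
    parts = sorted(_canonical_text(c) for c in node.children)
    return node.symbol + "".join(f"({p})" for p in parts)


def serialize_canonical(structure: GlycanStructure | MonosaccharideNode) -> str:
    """Deterministic linear code, invariant under sibling reordering."""
    node = structure.root if isinstance(structure, GlycanStructure) else structure
    return _canonical_text(node)


def composition_of(structure: GlycanStructure | MonosaccharideNode) -> GlycanComposition:
    """Per-symbol node counts of a structure."""
    node = structure.root if isinstance(structure, GlycanStructure) else structure
    counts = {v: 0 for v in _SYMBOL_FIELD.values()}
    for n in node.walk():
        counts[_SYMBOL_FIELD[n.symbol]] += 1
    return GlycanComposition(**counts)


def group_isomers(
    structures: Iterable[GlycanStructure | str],
) -> dict[GlycanComposition, set[str]]:
    """Bucket structures by composition; bucket size = isomer count.

    Accepts parsed structures or structure codes; the sets hold canonical
    codes, so duplicate serializations of the same topology collapse.
    """
    buckets: dict[GlycanComposition, set[str]] = {}
    for s in structures:
        if isinstance(s, str):
            s = parse_structure(s, relaxed=True)
        buckets.setdefault(composition_of(s), set()).add(serialize_canonical(s))
    return buckets


#: Standard oligomannose topologies Man3-Man9 (processing intermediates).
#: Isomer choice among Man4/Man6/Man7/Man8 intermediates is a convention.
MAN_TOPOLOGIES: dict[int, str] = {
    3: "N(N(H(H)(H)))",
    4: "N(N(H(H)(H(H))))",
    5: "N(N(H(H)(H(H)(H))))",
    6: "N(N(H(H(H))(H(H)(H))))",
    7: "N(N(H(H(H))(H(H)(H(H)))))",
    8: "N(N(H(H(H))(H(H(H))(H(H)))))",
    9: "N(N(H(H(H(H)))(H(H(H))(H(H)))))",
}


def oligomannose_structure(k: int) -> GlycanStructure:
    """The fixed Man-k topology (k in 3..9)."""
    try:
        return parse_structure(MAN_TOPOLOGIES[k])
    except KeyError:
        raise ValueError(f"no fixed topology for Man{k} (supported: 3-9)") from None


# ---------------------------------------------------------------------------
# Pluggable converters for upstream structure-code dialects.  A converter is
# a text->text function mapping a foreign serialization onto this package's
# linear code, so real search-engine exports can be adapted without touching
# the core model.

_CONVERTERS: dict[str, Callable[[str], str]] = {}


def register_converter(dialect: str, func: Callable[[str], str]) -> None:
    _CONVERTERS[dialect] = func


def convert_structure_code(code: str, dialect: str | None = None) -> str:
    """Translate ``code`` from ``dialect`` into the native structure code."""
    if dialect is None or dialect == "native":
        return code
    try:
        conv = _CONVERTERS[dialect]
    except KeyError:
        raise KeyError(
            f"no converter registered for dialect {dialect!r}; "
            f"known: {sorted(_CONVERTERS)}") from None
    return conv(code)
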