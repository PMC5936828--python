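"""Glycan tree model and monoisotopic mass bookkeeping.

Masses follow the conventions of MALDI-TOF glycomics of permethylated and
2-aminobenzamide (2-AB)-labeled N-glycans: singly charged, monosodiated
[M + Na]+ ions, monoisotopic (12C) masses throughout.

Residue increments (Da, monoisotopic)
-------------------------------------
===========  ========  =============
mass class   native    permethylated
===========  ========  =============
Hex          162.0528  204.0998
HexNAc       203.0794  245.1263
dHex (Fuc)   146.0579  174.0892
===========  ========  =============

Permethylation converts every free hydroxyl/amide to a methyl ether, so a
permethylated Hex gains three CH2 (3 x 14.0157 Da) over the native residue
and a dHex gains two.  2-AB labeling is reductive amination of the reducing
end and adds a net 120.0687 Da (C7H8N2) on top of the native end groups.

End-group constants ([M + Na]+):

* intact permethylated molecule: sum of residues + 46.0419 + Na
* intact 2-AB molecule: sum of residues + 18.0106 + 120.0687 + Na
* permethylated B ion: sum of residues + 14.0157 + Na
* permethylated Y ion: sum of residues + 32.0262 + Na
* 2-AB Y ion: same end groups as the intact 2-AB molecule

These constants jointly reproduce the printed anchor masses of the study
system (967.5/1171.6/1375.7 paucimannose; B ions 690..1506; Y ions
474..1494; 2-AB Y ions 364/672/848; 2-AB trimethylated Man-5 at 1419.5).
For a permethylated precursor the B/Y constants give the complementarity
identity B + Y = [M + Na]+ + 22.9898 on every glycosidic cleavage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Optional

__all__ = [
    "CH2",
    "H2O",
    "NA",
    "TWO_AB",
    "Residue",
    "GlycanTree",
    "Composition",
    "MassConvention",
    "GlycanError",
    "StructureParseError",
    "composition_mass",
    "fragment_mass",
    "parse_structure",
    "serialize_structure",
    "tree_composition",
    "tree_mass",
]

# monoisotopic building blocks (Da)
CH2 = 14.0156500
H2O = 18.0105646
NA = 22.9897693
TWO_AB = 120.0687491  # C7H8N2, net 2-aminobenzamide label

Derivatization = Literal["native", "permethylated", "twoAB"]
MassClass = Literal["Hex", "HexNAc", "dHex"]

_IDENTITY_CLASS: dict[str, MassClass] = {
    "Man": "Hex",
    "Gal": "Hex",
    "Glc": "Hex",
    "GlcNAc": "HexNAc",
    "Fuc": "dHex",
    "Hex": "Hex",
    "HexNAc": "HexNAc",
    "dHex": "dHex",
}

_NATIVE_RESIDUE = {"Hex": 162.0528234, "HexNAc": 203.0793725, "dHex": 146.0579088}
# extra CH2 per residue on permethylation (free hydroxyls of the residue)
_PERMETHYL_CH2 = {"Hex": 3, "HexNAc": 3, "dHex": 2}


class GlycanError(ValueError):
    """Invalid glycan input (composition, derivatization, adduct...)."""


class StructureParseError(GlycanError):
    """Malformed condensed structure string; carries the offending position."""

    def __init__(self, message: str, position: int = -1):
        super().__init__(message if position < 0 else f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class Residue:
    """One monosaccharide: identity, anomeric configuration, linkage to its
    parent residue, and the count of natural O-methyl groups it carries."""

    identity: str
    anomericity: str = "?"  # 'a', 'b' or '?'
    linkage: str = "none"  # '1-2', '1-3', '1-4', '1-6', '1-?' or 'none' (root)
    methyl_count: int = 0

    def __post_init__(self) -> None:
        if self.identity not in _IDENTITY_CLASS:
            raise GlycanError(f"unknown residue identity {self.identity!r}")
        if self.anomericity not in ("a", "b", "?"):
            raise GlycanError(f"bad anomericity {self.anomericity!r}")
        if self.methyl_count < 0:
            raise GlycanError("methyl_count must be >= 0")
        if self.methyl_count > 4:
            raise GlycanError("methyl_count exceeds free hydroxyls (bound 4)")

    @property
    def mass_class(self) -> MassClass:
        return _IDENTITY_CLASS[self.identity]


@dataclass
class GlycanNode:
    """A residue plus its child edges (children are toward the non-reducing end)."""

    residue: Residue
    children: list["GlycanNode"] = field(default_factory=list)

    def walk(self) -> Iterator["GlycanNode"]:
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class GlycanTree:
    """Rooted glycan structure; the root residue is the reducing end.

    For N-glycans the root is the proximal core GlcNAc. ``derivatization``
    selects the mass convention applied to the whole molecule.
    """

    root: GlycanNode
    derivatization: Derivatization = "permethylated"

    def walk(self) -> Iterator[GlycanNode]:
        return self.root.walk()

    def residue_count(self) -> int:
        return sum(1 for _ in self.walk())

    def copy(self) -> "GlycanTree":
        def _copy(node: GlycanNode) -> GlycanNode:
            return GlycanNode(node.residue, [_copy(c) for c in node.children])

        return GlycanTree(_copy(self.root), self.derivatization)


@dataclass(frozen=True)
class Composition:
    """Monosaccharide-class composition plus natural methyl count.

    The condensed series notation F1HnN2 of core-galactofucosylated glycans
    maps to ``ndHex=1, nHex=n, nHexNAc=2``.
    """

    nHex: int = 0
    nHexNAc: int = 0
    ndHex: int = 0
    nMe: int = 0
    derivatization: Derivatization = "permethylated"

    def __post_init__(self) -> None:
        if min(self.nHex, self.nHexNAc, self.ndHex, self.nMe) < 0:
            raise GlycanError("composition counts must be non-negative")

    def total_residues(self) -> int:
        return self.nHex + self.nHexNAc + self.ndHex

    def __add__(self, other: "Composition") -> "Composition":
        return Composition(
            self.nHex + other.nHex,
            self.nHexNAc + other.nHexNAc,
            self.ndHex + other.ndHex,
            self.nMe + other.nMe,
            self.derivatization,
        )

    def label(self) -> str:
        """Series-style label, e.g. ``F1H3N2`` or ``H5N2+3Me``."""
        parts = []
        if self.ndHex:
            parts.append(f"F{self.ndHex}")
        parts.append(f"H{self.nHex}")
        parts.append(f"N{self.nHexNAc}")
        out = "".join(parts)
        if self.nMe:
            out += f"+{self.nMe}Me"
        return out


@dataclass(frozen=True)
class MassConvention:
    """Residue increments and end-group constants for one derivatization."""

    residue: dict
    intact_end: float
    b_end: Optional[float]
    y_end: Optional[float]
    methyl: float = CH2
    adduct: float = NA


def _convention(derivatization: str) -> MassConvention:
    if derivatization == "permethylated":
        residue = {
            cls: _NATIVE_RESIDUE[cls] + _PERMETHYL_CH2[cls] * CH2
            for cls in _NATIVE_RESIDUE
        }
        # free reducing end: OH + OMe termini -> H2O + 2 CH2
        return MassConvention(residue, H2O + 2 * CH2, CH2, CH2 + H2O)
    if derivatization == "native":
        return MassConvention(dict(_NATIVE_RESIDUE), H2O, None, None)
    if derivatization == "twoAB":
        end = H2O + TWO_AB
        # Y ions keep the labeled reducing end: same constant as the intact
        # molecule.  The B-ion end group is not anchored by the study data
        # and is configurable at the fragmenter level.
        return MassConvention(dict(_NATIVE_RESIDUE), end, None, end)
    raise GlycanError(f"unsupported derivatization {derivatization!r}")


def composition_mass(comp: Composition, adduct: str = "Na") -> float:
    """Monoisotopic [M + Na]+ m/z of an intact glycan of this composition.

    ``nMe`` counts natural methyl groups; under permethylation those are
    indistinguishable from the derivatization methyls and must already be
    zero in ``comp`` (callers deriving a composition from a tree handle
    this; see :func:`tree_composition`).

    Only singly charged sodium adducts are supported — the convention the
    underlying MALDI data were acquired in.
    """
    if adduct != "Na":
        raise GlycanError(f"unsupported adduct {adduct!r}: only [M+Na]+ is modeled")
    conv = _convention(comp.derivatization)
    mass = (
        comp.nHex * conv.residue["Hex"]
        + comp.nHexNAc * conv.residue["HexNAc"]
        + comp.ndHex * conv.residue["dHex"]
        + comp.nMe * conv.methyl
        + conv.intact_end
        + conv.adduct
    )
    return mass


def fragment_mass(
    comp: Composition,
    ion_type: str,
    adduct: str = "Na",
    two_ab_b_end: Optional[float] = None,
) -> float:
    """Sodiated B- or Y-ion m/z for a fragment of this composition.

    B ions retain the non-reducing end of a glycosidic cleavage, Y ions the
    reducing end (Domon-Costello nomenclature).  For 2-AB spectra only Y
    ions have an anchored end group; requesting a 2-AB B ion without an
    explicit ``two_ab_b_end`` constant raises.
    """
    if adduct != "Na":
        raise GlycanError(f"unsupported adduct {adduct!r}: only [M+Na]+ is modeled")
    conv = _convention(comp.derivatization)
    if comp.derivatization == "native":
        raise GlycanError("fragment masses are undefined for native glycans here")
    if ion_type == "B":
        end = conv.b_end
        if end is None:
            end = two_ab_b_end
        if end is None:
            raise GlycanError(
                "2-AB B-ion end group is not anchored; pass two_ab_b_end explicitly"
            )
    elif ion_type == "Y":
        end = conv.y_end
    else:
        raise GlycanError(f"ion_type must be 'B' or 'Y', got {ion_type!r}")
    mass = (
        comp.nHex * conv.residue["Hex"]
        + comp.nHexNAc * conv.residue["HexNAc"]
        + comp.ndHex * conv.residue["dHex"]
        + comp.nMe * conv.methyl
        + end
        + conv.adduct
    )
    return mass


# ---------------------------------------------------------------------------
# condensed structure grammar
#
#   chain    := unit* residue
#   unit     := residue | '[' chain ']'
#   residue  := IDENT methyl? linkage?
#   methyl   := '{' INT 'Me' '}'
#   linkage  := '(' ('a'|'b'|'?') '1-' ('2'|'3'|'4'|'6'|'?') ')'
#
# The rightmost residue of the top-level chain is the reducing end (root).
# A unit to the left of a residue is a child of that residue; bracketed
# chains are branch children.  Example:
#   Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"(?P<ident>GlcNAc|HexNAc|dHex|Man|Gal|Glc|Fuc|Hex)"
    r"(?:\{(?P<nme>\d+)Me\})?"
    r"(?:\((?P<anom>[ab?])1-(?P<pos>[2346?])\))?"
    r"|(?P<open>\[)|(?P<close>\])"
)


def _tokenize(text: str) -> list:
    tokens = []
    i = 0
    while i < len(text):
        m = _TOKEN_RE.match(text, i)
        if m is None:
            raise StructureParseError(f"unexpected character {text[i]!r}", i)
        if m.group("open"):
            tokens.append(("[", i))
        elif m.group("close"):
            tokens.append(("]", i))
        else:
            anom = m.group("anom")
            pos = m.group("pos")
            linkage = "none" if anom is None else f"1-{pos}"
            residue = Residue(
                identity=m.group("ident"),
                anomericity=anom if anom is not None else "?",
                linkage=linkage,
                methyl_count=int(m.group("nme") or 0),
            )
            tokens.append((residue, i))
        i = m.end()
    return tokens


def _parse_chain(units: list) -> GlycanNode:
    """units: list of GlycanNode ('chain head') or Residue, left to right;
    the rightmost must be a residue — it becomes the local root."""
    if not units:
        raise StructureParseError("empty chain")
    last = units[-1]
    if not isinstance(last, Residue):
        raise StructureParseError("chain must end in a residue, not a branch")
    node = GlycanNode(last)
    rest = units[:-1]
    # trailing bracket groups (immediately left of this residue) are branch
    # children; everything before them is the continuing main chain
    while rest and isinstance(rest[-1], GlycanNode):
        node.children.append(rest.pop())
    if rest:
        node.children.append(_parse_chain(rest))
    node.children.reverse()  # keep left-to-right reading order
    return node


def parse_structure(text: str, derivatization: Derivatization = "permethylated") -> GlycanTree:
    """Parse a condensed structure string into a :class:`GlycanTree`.

    Raises :class:`StructureParseError` with the offending position for
    unbalanced brackets, unknown residue tokens, or a malformed chain.
    """
    text = text.strip()
    if not text:
        raise StructureParseError("empty structure string", 0)
    tokens = _tokenize(text)

    def build(idx: int, depth: int) -> tuple[list, int]:
        units: list = []
        while idx < len(tokens):
            tok, pos = tokens[idx]
            if tok == "[":
                inner, idx = build(idx + 1, depth + 1)
                if not inner:
                    raise StructureParseError("empty bracket group", pos)
                units.append(_parse_chain(inner))
            elif tok == "]":
                if depth == 0:
                    raise StructureParseError("unbalanced ']'", pos)
                return units, idx + 1
            else:
                units.append(tok)
                idx += 1
        if depth != 0:
            raise StructureParseError("unbalanced '[': missing ']'", len(text))
        return units, idx

    units, _ = build(0, 0)
    root = _parse_chain(units)
    if root.residue.linkage != "none":
        raise StructureParseError(
            "reducing-end residue must not carry a linkage (two reducing ends?)"
        )
    for node in root.walk():
        for child in node.children:
            if child.residue.linkage == "none":
                raise StructureParseError(
                    f"non-root residue {child.residue.identity} lacks a linkage "
                    "(two reducing ends?)"
                )
    return GlycanTree(root, derivatization)


def _serialize_node(node: GlycanNode) -> str:
    res = node.residue
    out = res.identity
    if res.methyl_count:
        out += f"{{{res.methyl_count}Me}}"
    if res.linkage != "none":
        out += f"({res.anomericity}1-{res.linkage.split('-')[1]})"
    if node.children:
        rendered = sorted((_serialize_node(c) for c in node.children))
        main, branches = rendered[0], rendered[1:]
        out = main + "".join(f"[{b}]" for b in branches) + out
    return out


def serialize_structure(tree: GlycanTree) -> str:
    """Canonical condensed string: at each residue, children are ordered by
    their serialized form, the first printed in-line and the rest bracketed."""
    return _serialize_node(tree.root)


def tree_composition(tree: GlycanTree) -> Composition:
    """Composition of a tree.

    Natural per-residue methyls are counted into ``nMe`` only for native and
    2-AB derivatizations; under permethylation every free hydroxyl is
    methylated anyway, so natural methyls are mass-invisible and ``nMe`` is
    reported as 0.
    """
    counts = {"Hex": 0, "HexNAc": 0, "dHex": 0}
    nme = 0
    for node in tree.walk():
        counts[node.residue.mass_class] += 1
        nme += node.residue.methyl_count
    if tree.derivatization == "permethylated":
        nme = 0
    return Composition(
        counts["Hex"], counts["HexNAc"], counts["dHex"], nme, tree.derivatization
    )


def tree_mass(tree: GlycanTree, adduct: str = "Na") -> float:
    """Sodiated monoisotopic m/z of the intact (whole) glycan tree."""
    return composition_mass(tree_composition(tree), adduct)


def strip_methyls(comp: Composition) -> Composition:
    return replace(comp, nMe=0)
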