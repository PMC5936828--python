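"""B/Y fragment enumeration and glycomer deconvolution of MS/MS spectra.

Glycans of the core-galactofucosylated F1HnN2 series fragment preferentially
at the glycosidic bond between the two core GlcNAc residues (the chitobiose
bond).  Each isomer sharing a parent mass — a *glycomer* — therefore yields
one complementary B/Y ion pair: the B ion carries the mannosylated
non-reducing part (Hex_a HexNAc_1, a >= 2) and the Y ion the fucosylated
reducing part (Fuc_1 Hex_b HexNAc_1).  The number of hexoses on the core
fucose, b = 0..5, labels the glycomer form 'a' through 'f'.

A glycomer is called only when BOTH members of its pair are observed as
major ions; its relative fraction is its pair intensity divided by the
summed pair intensities of all called glycomers of that parent.  For a
permethylated precursor every complementary pair obeys
B + Y = parent[M+Na]+ + 22.9898 (the extra sodium of the second fragment).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from glycomer.glycan_model import (
    NA,
    Composition,
    GlycanError,
    GlycanTree,
    fragment_mass,
    tree_composition,
)
from glycomer.ms1_annotation import PeakList

__all__ = [
    "FragmentIon",
    "GlycomerCall",
    "FORM_LABELS",
    "enumerate_BY",
    "candidate_pairs",
    "call_glycomers",
    "relative_distribution",
]

FORM_LABELS = "abcdef"  # form letter = number of Hex on the core fucose (a=0..f=5)


@dataclass(frozen=True)
class FragmentIon:
    ion_type: str  # 'B' or 'Y'
    composition: Composition
    mz: float
    cleaved_edge: tuple[str, str]  # (parent residue identity, child residue identity)


@dataclass(frozen=True)
class GlycomerCall:
    form: str
    b_mz: float
    y_mz: float
    b_observed_mz: float
    y_observed_mz: float
    pair_intensity: float
    relative_fraction: Optional[float] = None


def enumerate_BY(
    tree: GlycanTree, two_ab_b_ions: bool = False, two_ab_b_end: Optional[float] = None
) -> list[FragmentIon]:
    """One complementary (B, Y) ion pair per glycosidic edge of the tree.

    Single-cleavage fragments only: the B ion is the subtree distal to the
    cleaved edge, the Y ion is the remainder containing the reducing end.
    For 2-AB trees only Y ions are emitted unless ``two_ab_b_ions`` is set
    (the 2-AB B-ion end group is not anchored by calibration data and must
    then be supplied via ``two_ab_b_end``).
    """
    if tree.derivatization == "native":
        raise GlycanError("B/Y enumeration supports permethylated or 2-AB trees only")
    parent_comp = tree_composition(tree)
    fragments: list[FragmentIon] = []

    def subtree_comp(node) -> Composition:
        sub = GlycanTree(node, tree.derivatization).copy()
        sub.root.residue = replace(sub.root.residue, linkage="none", anomericity="?")
        return tree_composition(sub)

    for node in tree.walk():
        for child in node.children:
            b_comp = subtree_comp(child)
            y_comp = Composition(
                parent_comp.nHex - b_comp.nHex,
                parent_comp.nHexNAc - b_comp.nHexNAc,
                parent_comp.ndHex - b_comp.ndHex,
                parent_comp.nMe - b_comp.nMe,
                tree.derivatization,
            )
            edge = (node.residue.identity, child.residue.identity)
            y_ion = FragmentIon("Y", y_comp, fragment_mass(y_comp, "Y"), edge)
            if tree.derivatization == "permethylated" or two_ab_b_ions:
                b_ion = FragmentIon(
                    "B",
                    b_comp,
                    fragment_mass(b_comp, "B", two_ab_b_end=two_ab_b_end),
                    edge,
                )
                fragments.append(b_ion)
            fragments.append(y_ion)
    return fragments


def candidate_pairs(
    parent_comp: Composition,
    parent_mz: Optional[float] = None,
    min_b_hex: int = 2,
) -> list[tuple[float, float, str]]:
    """Theoretical chitobiose-cleavage (B m/z, Y m/z, form) pairs of an
    F1HnN2 parent.

    Splits the parent as B = Hex_a HexNAc_1 (a >= ``min_b_hex``, the
    smallest observed B ion being the dimannosyl Hex2HexNAc1) and
    Y = Fuc_1 Hex_b HexNAc_1 with b = nHex - a in 0..5 (forms a-f).
    """
    if not (parent_comp.ndHex == 1 and parent_comp.nHexNAc == 2):
        raise GlycanError(
            f"{parent_comp.label()} is not in the F1HnN2 series "
            "(need ndHex=1, nHexNAc=2)"
        )
    deriv = parent_comp.derivatization
    pairs = []
    for b_hex in range(min_b_hex, parent_comp.nHex + 1):
        y_hex = parent_comp.nHex - b_hex
        if y_hex >= len(FORM_LABELS):
            continue
        b_comp = Composition(b_hex, 1, 0, 0, deriv)
        y_comp = Composition(y_hex, 1, 1, 0, deriv)
        pairs.append(
            (
                fragment_mass(b_comp, "B"),
                fragment_mass(y_comp, "Y"),
                FORM_LABELS[y_hex],
            )
        )
    return pairs


def _match_major_peak(
    msms: PeakList, target_mz: float, tolerance: float, min_intensity: float
) -> Optional[tuple[float, float]]:
    """(observed mz, intensity) of the best matching major peak, or None.

    Among peaks within tolerance the most intense wins (ties toward lower
    m/z); the match must reach the major-ion intensity floor.
    """
    mz = msms.mz
    inten = msms.intensity
    inside = np.flatnonzero(np.abs(mz - target_mz) <= tolerance)
    if inside.size == 0:
        return None
    best = inside[np.argmax(inten[inside])]
    if inten[best] < min_intensity:
        return None
    return float(mz[best]), float(inten[best])


def call_glycomers(
    msms: PeakList,
    parent_comp: Composition,
    tolerance: float = 0.5,
    major_ion_threshold: float = 0.05,
    min_b_hex: int = 2,
) -> list[GlycomerCall]:
    """Call glycomers of one F1HnN2 parent from its MS/MS spectrum.

    A form is called iff both its B and Y ions match observed peaks at or
    above ``major_ion_threshold`` x base peak; the pair intensity is the sum
    of the two matched peak intensities.  Relative fractions are filled by
    :func:`relative_distribution`.  An empty result is a diagnostic, not an
    error.
    """
    if msms.ms_level != 2 or msms.parent_mz is None:
        raise GlycanError("glycomer calling requires an MS/MS peak list with parent_mz")
    floor = major_ion_threshold * msms.base_peak_intensity()
    calls = []
    for b_mz, y_mz, form in candidate_pairs(parent_comp, msms.parent_mz, min_b_hex):
        b_hit = _match_major_peak(msms, b_mz, tolerance, floor)
        y_hit = _match_major_peak(msms, y_mz, tolerance, floor)
        if b_hit is None or y_hit is None:
            continue
        calls.append(
            GlycomerCall(
                form=form,
                b_mz=b_mz,
                y_mz=y_mz,
                b_observed_mz=b_hit[0],
                y_observed_mz=y_hit[0],
                pair_intensity=b_hit[1] + y_hit[1],
            )
        )
    return relative_distribution(calls) if calls else []


def relative_distribution(calls: list[GlycomerCall]) -> list[GlycomerCall]:
    """Fill each call's relative fraction: pair intensity over the summed
    pair intensities of all called glycomers of the parent."""
    if not calls:
        raise GlycanError("relative distribution of an empty call set is undefined")
    total = sum(c.pair_intensity for c in calls)
    if total <= 0:
        raise GlycanError("total pair intensity is zero; distribution undefined")
    return [replace(c, relative_fraction=c.pair_intensity / total) for c in calls]


def complementarity_constant() -> float:
    """B + Y minus parent [M+Na]+ for any permethylated complementary pair
    (the sodium carried by the second fragment)."""
    return NA
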