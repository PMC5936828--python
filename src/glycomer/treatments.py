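"""Exoglycosidase / chemical treatment simulation and linkage-constraint inference.

Each treatment is a specificity predicate over residues: which mass class or
identity it removes, the required anomeric configuration, the allowed
linkage positions, whether only chain-terminal residues are attacked, and
whether O-methylation of the attacked residue blocks hydrolysis (the
observed behavior of every glycosidase here: a single methyl on the terminal
residue renders it resistant).  Unknown anomericity or linkage never
matches — the simulation is conservative, removing a residue only when the
structure affirmatively satisfies the specificity.

Built-in specificities:

* hydrofluoric acid — cleaves alpha(1-2)- and alpha(1-3)-linked fucose,
  terminal or internal, chemically (not blocked by methylation);
* bovine-kidney alpha-fucosidase — terminal alpha-fucose, any position;
* Aspergillus oryzae beta(1-4)-galactosidase — terminal Gal, beta, 1-4;
* Xanthomonas manihotis beta(1-3/6)-galactosidase — terminal Gal, beta, 1-3/1-6;
* coffee-bean alpha-galactosidase — terminal Gal, alpha, any position;
* jack-bean alpha-mannosidase — terminal Man, alpha, any position, exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from glycomer.glycan_model import GlycanError, GlycanNode, GlycanTree, tree_mass

__all__ = [
    "TreatmentSpec",
    "ShiftReport",
    "BUILTIN_TREATMENTS",
    "apply_treatment",
    "predict_shift",
    "infer_constraints",
]


@dataclass(frozen=True)
class TreatmentSpec:
    """Specificity predicate of one chemical or enzymatic treatment."""

    name: str
    removes_identity: Optional[str] = None  # e.g. 'Gal', 'Man'; None = use class
    removes_class: Optional[str] = None  # 'Hex', 'HexNAc', 'dHex'
    required_anomericity: Optional[str] = None  # 'a', 'b' or None (any)
    allowed_linkages: Optional[frozenset] = None  # e.g. {'1-4'}; None = any
    requires_terminal: bool = True
    blocked_by_methylation: bool = True
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if self.removes_identity is None and self.removes_class is None:
            raise GlycanError(
                f"treatment {self.name!r} must state an identity or mass class"
            )

    def matches(self, node: GlycanNode) -> bool:
        res = node.residue
        if self.removes_identity is not None and res.identity != self.removes_identity:
            return False
        if self.removes_class is not None and res.mass_class != self.removes_class:
            return False
        if self.required_anomericity is not None:
            if res.anomericity != self.required_anomericity:  # '?' never matches
                return False
        if self.allowed_linkages is not None:
            if res.linkage not in self.allowed_linkages:  # unknown never matches
                return False
        if self.requires_terminal and node.children:
            return False
        if self.blocked_by_methylation and res.methyl_count >= 1:
            return False
        return True

    @classmethod
    def from_dict(cls, d: dict) -> "TreatmentSpec":
        d = dict(d)
        if "allowed_linkages" in d and d["allowed_linkages"] is not None:
            d["allowed_linkages"] = frozenset(d["allowed_linkages"])
        return cls(**d)


BUILTIN_TREATMENTS: dict[str, TreatmentSpec] = {
    "hf": TreatmentSpec(
        name="hydrofluoric acid",
        removes_class="dHex",
        required_anomericity="a",
        allowed_linkages=frozenset({"1-2", "1-3"}),
        requires_terminal=False,
        blocked_by_methylation=False,
        exhaustive=True,
    ),
    "afuc": TreatmentSpec(
        name="alpha-fucosidase (bovine kidney)",
        removes_class="dHex",
        required_anomericity="a",
        allowed_linkages=None,
        requires_terminal=True,
        blocked_by_methylation=True,
    ),
    "b14gal": TreatmentSpec(
        name="beta(1-4)-galactosidase (A. oryzae)",
        removes_identity="Gal",
        required_anomericity="b",
        allowed_linkages=frozenset({"1-4"}),
        requires_terminal=True,
        blocked_by_methylation=True,
    ),
    "b36gal": TreatmentSpec(
        name="beta(1-3/6)-galactosidase (X. manihotis)",
        removes_identity="Gal",
        required_anomericity="b",
        allowed_linkages=frozenset({"1-3", "1-6"}),
        requires_terminal=True,
        blocked_by_methylation=True,
    ),
    "agal": TreatmentSpec(
        name="alpha-galactosidase (coffee bean)",
        removes_identity="Gal",
        required_anomericity="a",
        allowed_linkages=None,
        requires_terminal=True,
        blocked_by_methylation=True,
    ),
    "aman": TreatmentSpec(
        name="alpha-mannosidase (jack bean)",
        removes_identity="Man",
        required_anomericity="a",
        allowed_linkages=None,
        requires_terminal=True,
        blocked_by_methylation=True,
        exhaustive=True,
    ),
}


def _prune(node: GlycanNode, spec: TreatmentSpec) -> bool:
    """Remove matching children of ``node`` (and recurse); returns True if
    anything was removed.  Removing an internal residue (HF) releases its
    whole subtree."""
    changed = False
    kept = []
    for child in node.children:
        if spec.matches(child):
            changed = True
            continue
        if _prune(child, spec):
            changed = True
        kept.append(child)
    node.children = kept
    return changed


def apply_treatment(tree: GlycanTree, spec: TreatmentSpec) -> GlycanTree:
    """Product structure after one treatment.

    Every residue matching the specificity is removed; under an exhaustive
    treatment, newly exposed termini become eligible within the same
    treatment and pruning iterates to a fixpoint.  The reducing-end residue
    itself is never removed.  A treatment with no matching site is a no-op.
    """
    product = tree.copy()
    while True:
        changed = _prune(product.root, spec)
        if not changed or not spec.exhaustive:
            break
    return product


@dataclass
class ShiftReport:
    """Predicted spectrum changes of a treatment on a structure mixture.

    ``status`` maps each original peak m/z to 'reduced', 'increased' or
    'unchanged'; ``products`` maps each original m/z to the product m/z list
    it converts into (identity mapping when unchanged).
    """

    treatment: str
    status: dict[float, str] = field(default_factory=dict)
    products: dict[float, list[float]] = field(default_factory=dict)

    def delta(self, original_mz: float) -> list[float]:
        return [original_mz - p for p in self.products.get(original_mz, [])]


def predict_shift(
    structures: Sequence[GlycanTree],
    abundances: Optional[Sequence[float]],
    spec: TreatmentSpec,
    round_to: int = 4,
) -> ShiftReport:
    """Predict which MS1 peaks a treatment reduces, increases, or leaves.

    Structures sharing a theoretical m/z are pooled.  A peak is 'reduced'
    when at least one of its structures is converted to a lighter product,
    'increased' when a product of some other peak lands on it (or it is a
    new mass), 'unchanged' otherwise.  Every mass delta is an integer
    combination of residue increments of the removed residues.
    """
    if not structures:
        return ShiftReport(spec.name)
    derivs = {t.derivatization for t in structures}
    if len(derivs) > 1:
        raise GlycanError("all structures in a shift prediction must share derivatization")
    report = ShiftReport(spec.name)
    original = [round(tree_mass(t), round_to) for t in structures]
    product_trees = [apply_treatment(t, spec) for t in structures]
    product = [round(tree_mass(t), round_to) for t in product_trees]
    original_set = set(original)
    gained: set[float] = set()
    for mz0, mz1 in zip(original, product):
        report.products.setdefault(mz0, [])
        if mz1 not in report.products[mz0]:
            report.products[mz0].append(mz1)
        if mz1 != mz0:
            report.status[mz0] = "reduced"
            gained.add(mz1)
    for mz0 in original:
        if mz0 not in report.status:
            report.status[mz0] = "increased" if mz0 in gained else "unchanged"
    for mz1 in sorted(gained):
        if mz1 not in original_set:
            report.status[mz1] = "increased"
            report.products.setdefault(mz1, [mz1])
    return report


# ---------------------------------------------------------------------------
# decision-table inference: observed susceptibility/resistance -> linkage
# constraints
# ---------------------------------------------------------------------------

KNOWN_TREATMENTS = ("hf", "afuc", "b14gal", "b36gal", "agal", "aman")


def infer_constraints(
    shift_table: Iterable[tuple[str, str, str]],
    has_dhex: Optional[dict] = None,
    pmaa_terminal_gal: Optional[dict] = None,
) -> dict[str, list[str]]:
    """Turn a susceptibility table into linkage constraints per species.

    ``shift_table`` holds (species, treatment key, 'susceptible'|'resistant')
    records; ``has_dhex`` flags species whose composition contains a fucose;
    ``pmaa_terminal_gal`` flags species for which PMAA analysis shows a
    terminal galactose despite galactosidase resistance.

    Rules (conjunction returned; never a unique structure):

    * resistant to HF and to alpha-fucosidase, with a fucose present
      -> the fucose is alpha(1-6)-linked to the core GlcNAc and capped;
    * susceptible to beta(1-4)-galactosidase (hexose-loss shift)
      -> a terminal unmethylated Gal beta(1-4) is present;
    * resistant to all tested galactosidases while PMAA shows terminal Gal
      -> the terminal Gal is methylated OR its anomer was untested
      (ambiguity carried, not resolved).

    A species recorded both susceptible and resistant to one treatment is a
    contradiction and raises.
    """
    table: dict[str, dict[str, str]] = {}
    for species, treatment, outcome in shift_table:
        if outcome not in ("susceptible", "resistant"):
            raise GlycanError(f"bad outcome {outcome!r} for {species}/{treatment}")
        prev = table.setdefault(species, {}).get(treatment)
        if prev is not None and prev != outcome:
            raise GlycanError(
                f"inconsistent table: {species} both {prev} and {outcome} "
                f"to {treatment}"
            )
        table[species][treatment] = outcome

    has_dhex = has_dhex or {}
    pmaa_terminal_gal = pmaa_terminal_gal or {}
    constraints: dict[str, list[str]] = {}
    for species, outcomes in table.items():
        cons: list[str] = []
        if (
            outcomes.get("hf") == "resistant"
            and outcomes.get("afuc") == "resistant"
            and has_dhex.get(species, False)
        ):
            cons.append("Fuc is alpha(1-6)-linked to core GlcNAc and capped by hexose")
        if outcomes.get("b14gal") == "susceptible":
            cons.append("terminal unmethylated Gal beta(1-4) present")
        gal_treatments = [t for t in ("b14gal", "b36gal", "agal") if t in outcomes]
        if (
            gal_treatments
            and all(outcomes[t] == "resistant" for t in gal_treatments)
            and pmaa_terminal_gal.get(species, False)
        ):
            cons.append(
                "terminal Gal methylated OR anomer/linkage untested (ambiguous)"
            )
        constraints[species] = cons
    return constraints
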