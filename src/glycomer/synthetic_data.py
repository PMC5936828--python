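"""Ground-truth structure mixtures and synthetic MS1 / MS/MS / treatment /
PMAA datasets.

The generator emulates the glycome organization the analysis assumes:
singly charged monosodiated MALDI spectra of permethylated or 2-AB-labeled
N-glycans drawn from a roster of paucimannose and high-mannose cores
(Man-1 to Man-9 on the chitobiose) crossed with core-chitobiose
modifications — an alpha(1-6) fucose on the proximal GlcNAc carrying zero to
five 4-linked galactoses (glycomer forms a-f).  The methylation policy
mirrors the observed selectivity: the single galactose of the
monogalactosylated form stays unmethylated, every further galactose of the
polygalactosylated forms carries one methyl, and terminal mannoses carry
zero to three methyls.

Abundances are Dirichlet-distributed with concentration elevated for the
di- and trihexosylated core-fucose forms (c/d), the predominant isomers of
the study system.  Noise: Gaussian m/z jitter (sd 0.02 Da, below matching
tolerances), multiplicative lognormal intensity noise (sigma 0.1), and a
Poisson number of spurious peaks at 1% of the base peak.  All randomness
flows from a single seeded generator per dataset, so outputs are
byte-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from glycomer.glycan_model import (
    Composition,
    GlycanError,
    GlycanTree,
    parse_structure,
    serialize_structure,
    tree_composition,
    tree_mass,
)
from glycomer.ms1_annotation import PeakList
from glycomer.msms_glycomers import FORM_LABELS, candidate_pairs
from glycomer.pmaa_linkage import REFERENCE_TABLE, PMAARecord
from glycomer.treatments import TreatmentSpec, apply_treatment

__all__ = [
    "MixtureSpec",
    "Mixture",
    "man_core",
    "ccm_structure",
    "generate_mixture",
    "synthesize_ms1",
    "synthesize_msms",
    "synthesize_treatment_pair",
    "synthesize_pmaa",
]

# mannose-arm layouts; {n} marks the chitobiose attachment point.  Built so
# every mannose carries one of the branching patterns (terminal, 2-, 3-, 6-,
# or 3,6-linked) seen in GC-MS linkage analysis of high-mannose glycans.
_MAN_ARMS = {
    0: "",
    1: "Man(b1-4)",
    2: "Man(a1-6)Man(b1-4)",
    3: "Man(a1-3)[Man(a1-6)]Man(b1-4)",
    4: "Man(a1-3)[Man(a1-6)]Man(a1-6)Man(b1-4)",
    5: "Man(a1-3)[Man(a1-3)[Man(a1-6)]Man(a1-6)]Man(b1-4)",
    6: "Man(a1-2)Man(a1-3)[Man(a1-3)[Man(a1-6)]Man(a1-6)]Man(b1-4)",
    7: "Man(a1-2)Man(a1-3)[Man(a1-2)Man(a1-3)[Man(a1-6)]Man(a1-6)]Man(b1-4)",
    8: "Man(a1-2)Man(a1-3)[Man(a1-2)Man(a1-3)[Man(a1-2)Man(a1-6)]Man(a1-6)]Man(b1-4)",
    9: "Man(a1-2)Man(a1-2)Man(a1-3)[Man(a1-2)Man(a1-3)[Man(a1-2)Man(a1-6)]Man(a1-6)]Man(b1-4)",
}


def man_core(
    n_man: int,
    derivatization: str = "permethylated",
    terminal_man_methyls: int = 0,
) -> GlycanTree:
    """Man-n N-glycan: n mannoses on the GlcNAc(b1-4)GlcNAc chitobiose.

    ``terminal_man_methyls`` places one methyl on each of that many terminal
    mannose residues (natural O-methylation of the mannose termini).
    """
    if n_man not in _MAN_ARMS:
        raise GlycanError(f"no Man-{n_man} layout defined (0..9)")
    text = _MAN_ARMS[n_man] + "GlcNAc(b1-4)GlcNAc"
    tree = parse_structure(text, derivatization)
    if terminal_man_methyls:
        _methylate_terminal_man(tree, terminal_man_methyls)
    return tree


def _methylate_terminal_man(tree: GlycanTree, count: int) -> None:
    from dataclasses import replace

    terminals = [
        node
        for node in tree.walk()
        if node.residue.identity == "Man" and not node.children
    ]
    if count > len(terminals):
        raise GlycanError(
            f"cannot place {count} methyls on {len(terminals)} terminal mannoses"
        )
    for node in terminals[:count]:
        node.residue = replace(node.residue, methyl_count=1)


def ccm_structure(
    n_man: int,
    n_gal: int,
    derivatization: str = "permethylated",
    terminal_man_methyls: int = 0,
    methylate_polygal: bool = True,
    polygal_anomericity: str = "?",
) -> GlycanTree:
    """Man-n core bearing the chitobiose modification Fuc(a1-6) with a
    chain of ``n_gal`` 4-linked galactoses.

    The first galactose is beta(1-4) and unmethylated; with
    ``methylate_polygal`` every further galactose carries one methyl (the
    selective-methylation pattern of the polygalactosylated forms).  The
    anomericity of galactoses beyond the first is not experimentally
    assignable and defaults to unknown.
    """
    if n_gal < 0:
        raise GlycanError("n_gal must be >= 0")
    chain = ""
    for i in range(n_gal, 0, -1):
        if i == 1:
            chain += "Gal(b1-4)"
        else:
            me = "{1Me}" if methylate_polygal else ""
            chain += f"Gal{me}({polygal_anomericity}1-4)"
    text = _MAN_ARMS[n_man] + "GlcNAc(b1-4)[" + chain + "Fuc(a1-6)]GlcNAc"
    tree = parse_structure(text, derivatization)
    if terminal_man_methyls:
        _methylate_terminal_man(tree, terminal_man_methyls)
    return tree


def ccm_form(tree: GlycanTree) -> Optional[str]:
    """Glycomer form letter (a-f) of a core-fucosylated tree: the number of
    hexoses on the core-fucose arm; None when the tree carries no core Fuc."""
    for child in tree.root.children:
        if child.residue.mass_class == "dHex":
            n_gal = 0
            node = child
            while node.children:
                node = node.children[0]
                n_gal += 1
            return FORM_LABELS[n_gal] if n_gal < len(FORM_LABELS) else None
    return None


@dataclass
class MixtureSpec:
    """Study conditions for one synthetic glycome mixture."""

    seed: int = 0
    derivatization: str = "permethylated"
    plain_man_range: tuple = (2, 9)  # paucimannose + high-mannose cores
    ccm_man_range: tuple = (2, 6)  # cores carrying the GalFuc modification
    forms: str = FORM_LABELS  # glycomer forms included per CCM core
    # Dirichlet concentration per form; c/d elevated (predominant isomers)
    form_alpha: dict = field(
        default_factory=lambda: {"a": 1.0, "b": 2.0, "c": 4.0, "d": 4.0, "e": 1.0, "f": 0.5}
    )
    plain_alpha: float = 2.0
    max_terminal_man_methyls: int = 3  # 2-AB rosters: 0..3 methyls on Man termini
    explicit_structures: Optional[list] = None
    explicit_abundances: Optional[list] = None
    # noise model
    mz_jitter_sd: float = 0.02  # Da; below matching tolerance
    intensity_sigma: float = 0.1  # lognormal sigma of multiplicative noise
    spurious_rate: float = 5.0  # Poisson mean spurious peaks per spectrum
    spurious_rel_intensity: float = 0.01  # fraction of base peak

    def noiseless(self) -> "MixtureSpec":
        from dataclasses import replace

        return replace(
            self, mz_jitter_sd=0.0, intensity_sigma=0.0, spurious_rate=0.0
        )


@dataclass
class Mixture:
    """Ground truth: structures with abundances summing to one."""

    structures: list[GlycanTree]
    abundances: np.ndarray
    spec: MixtureSpec

    def __post_init__(self) -> None:
        total = float(np.sum(self.abundances))
        if total <= 0:
            raise GlycanError("mixture abundances must sum to a positive value")
        self.abundances = np.asarray(self.abundances, dtype=float) / total

    @property
    def derivatization(self) -> str:
        return self.spec.derivatization

    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "structure": [serialize_structure(t) for t in self.structures],
                "composition": [tree_composition(t).label() for t in self.structures],
                "form": [ccm_form(t) for t in self.structures],
                "mz": [round(tree_mass(t), 4) for t in self.structures],
                "abundance": self.abundances,
            }
        )


def roster_from_grammar(spec: MixtureSpec) -> list[GlycanTree]:
    """Deterministic roster: plain Man-n cores plus CCM cores x forms, each
    crossed with the allowed terminal-mannose methylation states.

    Methylation states are distinct glycoforms even under permethylation
    (where they are mass-invisible and pool as isobars in MS1)."""
    deriv = spec.derivatization
    me_states = range(spec.max_terminal_man_methyls + 1)
    roster: list[GlycanTree] = []
    for n_man in range(spec.plain_man_range[0], spec.plain_man_range[1] + 1):
        for me in me_states:
            try:
                roster.append(man_core(n_man, deriv, me))
            except GlycanError:
                continue  # more methyls than terminal mannoses
    for n_man in range(spec.ccm_man_range[0], spec.ccm_man_range[1] + 1):
        for form in spec.forms:
            n_gal = FORM_LABELS.index(form)
            for me in me_states:
                try:
                    roster.append(ccm_structure(n_man, n_gal, deriv, me))
                except GlycanError:
                    continue
    return roster


def generate_mixture(spec: MixtureSpec) -> Mixture:
    """Ground-truth mixture: roster from the structure grammar plus a
    Dirichlet abundance draw (seeded, reproducible)."""
    if spec.explicit_structures is not None:
        structures = list(spec.explicit_structures)
        if spec.explicit_abundances is not None:
            abundances = np.asarray(spec.explicit_abundances, dtype=float)
            if len(abundances) != len(structures):
                raise GlycanError("abundance vector length mismatch")
        else:
            abundances = np.full(len(structures), 1.0 / len(structures))
        return Mixture(structures, abundances, spec)
    structures = roster_from_grammar(spec)
    if not structures:
        raise GlycanError("empty roster; check mixture spec ranges")
    rng = np.random.default_rng(spec.seed)
    alpha = np.array(
        [
            spec.form_alpha.get(ccm_form(t), spec.plain_alpha)
            if ccm_form(t) is not None
            else spec.plain_alpha
            for t in structures
        ]
    )
    abundances = rng.dirichlet(alpha)
    return Mixture(structures, abundances, spec)


def _theoretical_peaks(mixture: Mixture) -> tuple[np.ndarray, np.ndarray]:
    """Distinct theoretical m/z values with isobar-summed abundances."""
    table: dict[float, float] = {}
    for tree, ab in zip(mixture.structures, mixture.abundances):
        mz = round(tree_mass(tree), 6)
        table[mz] = table.get(mz, 0.0) + float(ab)
    mzs = np.array(sorted(table))
    return mzs, np.array([table[m] for m in mzs])


def _apply_noise(
    mzs: np.ndarray, intensities: np.ndarray, spec: MixtureSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    if spec.intensity_sigma > 0:
        intensities = intensities * rng.lognormal(0.0, spec.intensity_sigma, len(mzs))
    if spec.mz_jitter_sd > 0:
        mzs = mzs + rng.normal(0.0, spec.mz_jitter_sd, len(mzs))
    if spec.spurious_rate > 0 and len(mzs):
        n_spur = rng.poisson(spec.spurious_rate)
        if n_spur:
            lo, hi = float(mzs.min()) - 50.0, float(mzs.max()) + 50.0
            spur_mz = rng.uniform(lo, hi, n_spur)
            spur_int = np.full(n_spur, spec.spurious_rel_intensity * intensities.max())
            mzs = np.concatenate([mzs, spur_mz])
            intensities = np.concatenate([intensities, spur_int])
    return mzs, intensities


def synthesize_ms1(
    mixture: Mixture, rng: Optional[np.random.Generator] = None
) -> PeakList:
    """Synthetic MS1 spectrum: one peak per distinct theoretical mass
    (isobars pooled), with the mixture's noise model applied."""
    spec = mixture.spec
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    mzs, intensities = _theoretical_peaks(mixture)
    mzs, intensities = _apply_noise(mzs, intensities, spec, rng)
    return PeakList(
        pd.DataFrame({"mz": mzs, "intensity": intensities}),
        ms_level=1,
        derivatization=mixture.derivatization,
    )


def synthesize_msms(
    mixture: Mixture,
    parent_comp: Composition,
    rng: Optional[np.random.Generator] = None,
) -> PeakList:
    """Synthetic MS/MS spectrum of one F1HnN2 parent.

    Each glycomer of the parent contributes its chitobiose-cleavage B/Y
    pair, with B and Y intensities both equal to the glycomer's abundance
    share within the parent (before noise), matching the flat fragmentation
    model of the pair-intensity statistic.
    """
    spec = mixture.spec
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    shares: dict[str, float] = {}
    for tree, ab in zip(mixture.structures, mixture.abundances):
        comp = tree_composition(tree)
        if (comp.nHex, comp.nHexNAc, comp.ndHex) != (
            parent_comp.nHex,
            parent_comp.nHexNAc,
            parent_comp.ndHex,
        ):
            continue
        form = ccm_form(tree)
        if form is None:
            continue
        shares[form] = shares.get(form, 0.0) + float(ab)
    total = sum(shares.values())
    if total == 0:
        raise GlycanError(f"mixture contains no glycomer of {parent_comp.label()}")
    pairs = candidate_pairs(parent_comp)
    by_form = {form: (b, y) for b, y, form in pairs}
    mzs, intensities = [], []
    for form, share in sorted(shares.items()):
        if form not in by_form:
            continue
        b_mz, y_mz = by_form[form]
        mzs.extend([b_mz, y_mz])
        intensities.extend([share / total, share / total])
    mz_arr, int_arr = _apply_noise(
        np.array(mzs), np.array(intensities), spec, rng
    )
    parent_mz = composition_mass_of_parent(parent_comp)
    return PeakList(
        pd.DataFrame({"mz": mz_arr, "intensity": int_arr}),
        ms_level=2,
        parent_mz=parent_mz,
        derivatization=mixture.derivatization,
    )


def composition_mass_of_parent(parent_comp: Composition) -> float:
    from glycomer.glycan_model import composition_mass

    return composition_mass(parent_comp)


def synthesize_treatment_pair(
    mixture: Mixture, treatment: TreatmentSpec
) -> tuple[PeakList, PeakList]:
    """Before/after MS1 spectra for one treatment.

    Both spectra are drawn with generators seeded identically, so a
    treatment that matches nothing yields a byte-identical pair.
    """
    spec = mixture.spec
    before = synthesize_ms1(mixture, np.random.default_rng(spec.seed))
    treated = Mixture(
        [apply_treatment(t, treatment) for t in mixture.structures],
        mixture.abundances.copy(),
        spec,
    )
    after = synthesize_ms1(treated, np.random.default_rng(spec.seed))
    return before, after


# --- PMAA synthesis --------------------------------------------------------

_IDENTITY_NAME = {
    "Man": "mannose",
    "Gal": "galactose",
    "Glc": "glucose",
    "GlcNAc": "N-acetylglucosamine",
    "Fuc": "fucose",
}

_REFERENCE_BY_LABEL = {label: (rt, ions) for rt, ions, label in REFERENCE_TABLE}


def linkage_category(node) -> Optional[str]:
    """PMAA linkage category of one residue: which of its positions carry
    glycosidic substituents.  Terminal fucose returns None (undetected in
    the reference chemistry)."""
    name = _IDENTITY_NAME.get(node.residue.identity)
    if name is None:
        return None
    positions = sorted(
        {c.residue.linkage.split("-")[1] for c in node.children if c.residue.linkage != "none"}
    )
    if not positions:
        if node.residue.identity == "Fuc":
            return None  # terminal fucose is not recovered as a PMAA here
        return f"terminal {name}"
    return f"{','.join(positions)}-linked {name}"


def linkage_counts(mixture: Mixture) -> dict[str, float]:
    """Abundance-weighted residue count per linkage category over a mixture."""
    counts: dict[str, float] = {}
    for tree, ab in zip(mixture.structures, mixture.abundances):
        for node in tree.walk():
            category = linkage_category(node)
            if category is not None:
                counts[category] = counts.get(category, 0.0) + float(ab)
    return counts


def synthesize_pmaa(mixture: Mixture, scale: float = 100.0) -> list[PMAARecord]:
    """PMAA records of a mixture: one record per linkage category present,
    carrying the reference retention time and signature-ion set, with
    abundance proportional to the weighted residue count."""
    records = []
    for category, count in sorted(linkage_counts(mixture).items()):
        ref = _REFERENCE_BY_LABEL.get(category)
        if ref is None:
            continue  # category outside the reference chemistry
        rt, ions = ref
        records.append(PMAARecord(rt, ions, abundance=scale * count))
    return records
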