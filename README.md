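# glycomer

Mass-spectrometric annotation of invertebrate-style N-glycomes: the kind of
glycome dominated by paucimannose and high-mannose structures whose
chitobiose core carries an α(1–6) fucose extended by one or more 4-linked
galactoses (the GalFuc / poly-Gal-Fuc "core chitobiose modification"), with
extensive natural O-methylation.  The package is aimed at glycomics analysts
working from centroided MALDI-TOF peak lists of permethylated or
2-aminobenzamide (2-AB)-labeled N-glycans, where every ion is a singly
charged sodium adduct [M + Na]⁺.

## What it computes

**Mass model.**  Monoisotopic residue increments per derivatization
(permethylated Hex 204.0998 / HexNAc 245.1263 / dHex 174.0892; native and
2-AB Hex 162.0528 / HexNAc 203.0794 / dHex 146.0579) with end-group
constants for intact molecules and Domon–Costello B/Y fragments.  Glycan
structures are written in a condensed grammar,
e.g. `Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)GlcNAc` or
`Gal{1Me}(?1-4)Gal(b1-4)Fuc(a1-6)GlcNAc` for a methyl-carrying chain.

**MS1 annotation.**  Bounded exhaustive enumeration of
(Hex, HexNAc, dHex, Me) compositions matching a peak within tolerance,
classification into paucimannose / high-mannose / F1HnN2 /
complex–hybrid classes, and 14.0157-Da methyl-ladder profiling of 2-AB
spectra.

**Glycomer deconvolution.**  Isomers sharing one parent mass (glycomers)
fragment at the chitobiose bond into complementary B/Y pairs
(B = Hexₐ HexNAc₁, Y = Fuc₁ Hex_b HexNAc₁; b = 0–5 labels forms a–f).  A
glycomer is called when both ions of its pair are major peaks, and its
relative fraction is its pair intensity over the summed pair intensities —
for permethylated precursors every pair obeys B + Y = [M+Na]⁺ + 22.9898.

**Treatment simulation.**  Built-in specificity predicates for hydrofluoric
acid, α-fucosidase, β(1–4)-, β(1–3/6)- and α-galactosidase, and
α-mannosidase (all glycosidases blocked by O-methylation of the attacked
terminal residue), spectrum shift prediction, and decision-table inference
from susceptibility patterns to linkage constraints.

**PMAA linkage lookup.**  GC-MS partially-methylated-alditol-acetate records
(retention time + signature-ion set) matched to a ten-row reference table by
Jaccard similarity with retention-time tie-breaking, plus linkage-abundance
ratios such as terminal : 4-linked galactose.

**Synthetic data.**  A seeded generator produces ground-truth mixtures
(>60 glycoforms from the core × form × methylation grammar), MS1 and MS/MS
spectra with a realistic noise model, before/after treatment spectrum pairs,
and PMAA record sets — so the full pipeline is testable end to end.

## Worked example

```python
from glycomer import (
    Composition, composition_mass, parse_structure, tree_mass,
    apply_treatment, BUILTIN_TREATMENTS, call_glycomers,
)

# intact sodiated mass of the permethylated trimannosyl core
print(round(composition_mass(Composition(3, 2, 0, 0, "permethylated")), 1))
# 1171.6

# the monogalactosylated-core glycan loses its Gal to beta(1-4)-galactosidase
parent = parse_structure(
    "Man(a1-6)Man(b1-4)GlcNAc(b1-4)[Gal(b1-4)Fuc(a1-6)]GlcNAc"
)
product = apply_treatment(parent, BUILTIN_TREATMENTS["b14gal"])
print(round(tree_mass(parent), 1), "->", round(tree_mass(product), 1))
# 1345.7 -> 1141.6
```

The first number is the [M+Na]⁺ m/z of permethylated Hex₃HexNAc₂; the
second line shows the 204-Da hexose loss that identifies a terminal
unmethylated β(1–4) galactose on the core fucose.

A full simulated run from the shell:

```sh
glycomer simulate --seed 1 --outdir data/
glycomer annotate --ms1 data/ms1.csv --out assignments.csv
glycomer run --config config.yaml --out report.json   # config: "simulate: true"
```

## Layout

| module | contents |
| --- | --- |
| `glycomer.glycan_model` | residue/tree/composition types, grammar, mass conventions |
| `glycomer.ms1_annotation` | peak lists, composition enumeration, classes, methyl ladders |
| `glycomer.msms_glycomers` | B/Y enumeration, candidate pairs, glycomer calling, fractions |
| `glycomer.treatments` | treatment specs, digestion simulation, shift + constraint inference |
| `glycomer.pmaa_linkage` | PMAA reference table, linkage assignment, abundance ratios |
| `glycomer.synthetic_data` | mixture grammar, spectrum/PMAA synthesis, noise model |
| `glycomer.cli_pipeline` | `run_pipeline` orchestration and the `glycomer` CLI |

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
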