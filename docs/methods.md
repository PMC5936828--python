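# Methods

## Mass model

All masses are monoisotopic; all ions are singly charged sodium adducts
[M + Na]⁺ (Na 22.9898 Da), the acquisition convention of MALDI-TOF
glycomics of derivatized N-glycans.  Other adducts and charge states are
rejected rather than silently computed.

Residue increments (Da):

| class | native / 2-AB | permethylated |
| --- | --- | --- |
| Hex | 162.0528 | 204.0998 |
| HexNAc | 203.0794 | 245.1263 |
| dHex (Fuc) | 146.0579 | 174.0892 |

Permethylation adds one CH₂ (14.0157) per free hydroxyl/amide: three per
Hex or HexNAc residue, two per dHex.  End groups: an intact permethylated
molecule adds 46.0419 (H₂O + 2 CH₂); an intact 2-AB molecule adds 18.0106 +
120.0687 (water termini plus the net 2-aminobenzamide label, C₇H₈N₂).
Fragment end groups (Domon–Costello single glycosidic cleavages): the
permethylated B ion adds 14.0157, the permethylated Y ion 32.0262, and the
2-AB Y ion carries the same end groups as the intact labeled molecule.
These five constants are not independent assumptions: a least-squares fit
of the end-group constants against the full printed anchor set (intact
967.5–1579.8 and 1345.7; B 690/894; Y 474/678; 2-AB Y 364/672/848; 2-AB
intact 1419.5), with residue increments fixed, recovers each of them to the
precision the anchors allow (tested).  A direct corollary is the
complementarity identity for permethylated precursors,
B + Y = [M+Na]⁺ + 22.9898, which holds on every enumerated cleavage.

Natural O-methyl groups are mass-visible only for native and 2-AB
derivatizations (+14.0157 each).  Under permethylation a natural methyl is
indistinguishable from a derivatization methyl, so per-residue methyl
counts are ignored in permethylated masses and reported as zero in
tree-derived compositions.

The 2-AB **B-ion** end group is deliberately left unanchored: no consistent
Σresidues + constant convention reproduces the 2-AB B ions reported
alongside the other anchors, so the fragmenter emits 2-AB B ions only when
the caller supplies an explicit end-group constant behind an opt-in flag.
2-AB Y ions, which are fully anchored, are always emitted.

## Structure grammar

Condensed IUPAC-like strings, reducing end rightmost:
`residue := (Man|Gal|Glc|GlcNAc|Fuc|Hex|HexNAc|dHex) ['{nMe}'] ['(a|b|? 1-2|3|4|6|?)']`,
branches bracketed, e.g.
`Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)[Gal(b1-4)Fuc(a1-6)]GlcNAc`.
Unknown anomericity and position (`?`) are legal and are treated
conservatively everywhere (they never satisfy an enzyme specificity).
Serialization is canonical — children sorted by their serialized form, the
first in-line and the rest bracketed — and round-trips with the parser.

## MS1 annotation

Composition assignment is a bounded exhaustive enumeration over
(nHex ≤ 12, nHexNAc ≤ 6, ndHex ≤ 2, nMe ≤ 8), the methyl dimension searched
only where it is mass-visible.  Candidates within tolerance are ranked by
|Δm/z|, then fewest residues, then fewest methyls.  The default MS1
tolerance is 0.1 Da — looser than the instrument accuracy of the source
data (±0.05 Da) and five times the synthetic jitter, so both regimes match;
it is configurable everywhere.  Exceeding the enumeration budget raises
rather than truncating silently.

Classes partition every composition: HexNAc₂ without fucose is paucimannose
up to Hex₄ and high-mannose from Hex₅ (the boundary implied by the observed
series membership); HexNAc₂ with one fucose is the F1HnN2
(core-galactofucosylated) series; HexNAc ≥ 3 is a complex/hybrid candidate;
everything else is unassigned.  Note one quirk of the source literature:
the series is labeled Fuc₁Hex₂₋₉HexNAc₂ there, but the printed masses
compute to one hexose more (1345.7 is F1H3N2, 2162.0 is F1H7N2).  The
package trusts arithmetic and documents the discrepancy instead of
resolving it.

Methyl-ladder profiling matches peaks at base + k·14.0157 (k = 0..8),
nearest peak within tolerance, ties toward lower m/z.  A peak claimed by
several ladders is split equally among claimants with a warning — intensity
is conserved, never double-counted.  A brute-force scan confirms that no
two ladder points of distinct HexNAc₂-backbone bases collide within
0.05 Da inside the search bounds, so the split path is a safeguard, not a
routine code path.

## Glycomer calling

F1HnN2 precursors fragment preferentially at the bond between the two core
GlcNAc residues.  Candidate pairs split the parent into B = Hexₐ HexNAc₁
(a ≥ 2; the smallest observed B ion is the dimannosyl 690) and
Y = Fuc₁ Hex_b HexNAc₁ with b = 0–5 mapping to forms a–f.  A glycomer is
called only when both ions of its pair match observed peaks at ≥ 5% of the
base peak ("major" ions; the source reports no numeric threshold, 5% is the
package default).  MS/MS matching tolerance defaults to 0.5 Da because
fragment values are conventionally printed as integers (truncated, not
rounded — 1494.7 prints as 1494).  Within one parent the candidate B and Y
masses are pairwise distinct (asserted), so a peak supports at most one
pair; when two observed peaks fall within tolerance of one theoretical mass
the more intense wins.  Relative fractions divide each called pair's summed
B+Y intensity by the total over all called pairs.

## Treatment simulation

A treatment removes every residue satisfying its predicate — identity or
mass class, anomericity, linkage set, terminal-only flag, and
methylation-blocking flag (a single O-methyl on the attacked residue
blocks all the glycosidases modeled; methyls elsewhere are irrelevant).
Exhaustive treatments iterate to a fixpoint, so termini exposed by one
round become substrates in the next — this is what lets α-mannosidase chew
an unmethylated arm to the core while a methylated terminus protects
everything beneath it.  Hydrofluoric acid is the one chemical, non-terminal
treatment: it releases α(1–2)/α(1–3) fucose together with anything attached
to it.  Unknown anomericity or linkage never matches, keeping inference
conservative.  Order sensitivity is real and tested: galactosidase followed
by fucosidase strips the GalFuc arm, fucosidase alone removes nothing from
a capped fucose.

Constraint inference maps a susceptibility/resistance table to linkage
statements (fucose α(1–6)-linked and capped; terminal unmethylated
Galβ(1–4) present; or the explicitly ambiguous "methylated OR untested
anomer" when PMAA sees terminal Gal that no galactosidase removes).  The
α-vs-β ambiguity of the poly-Gal extension is carried, never resolved — the
engine returns constraint conjunctions, not unique structures.

## PMAA lookup

PMAA fragmentation chemistry is not simulated; the ten-row reference table
(retention time, EI signature ions, linkage label) is authoritative.
Matching maximizes Jaccard similarity of ion sets (cutoff 0.8) with
retention-time tie-breaking within ±0.3 min — needed because terminal
mannose and terminal galactose share an identical ion set and differ only
by elution.  Terminal fucose has no reference row (undetected in the source
chemistry) and is deliberately unassignable; the synthetic PMAA generator
likewise drops it.

## Synthetic data: what it emulates, what it does not

The generator's roster is the structure grammar of the study system: plain
Man-2..Man-9 cores (paucimannose + high-mannose) and Man-2..Man-6 cores
carrying Fuc(α1–6) with 0–5 galactoses (forms a–f), each crossed with 0–3
methyls on terminal mannoses — 124 glycoforms by default, satisfying the
">60 glycoforms" organization of the real glycome.  The methylation policy
mirrors the observed selectivity: the form-b galactose is unmethylated;
every added galactose of forms c–f carries one methyl (hence their
galactosidase resistance); poly-Gal anomericity beyond the first galactose
is unknown.  Abundances are Dirichlet draws with concentration elevated for
forms c and d (α = 4 vs 1–2 elsewhere), reflecting the predominance of di-
and trihexosylated core fucose; plain cores get α = 2.

Noise model: Gaussian m/z jitter (sd 0.02 Da, well under the matching
tolerances), multiplicative lognormal intensity noise (σ = 0.1, ≈10% CV),
and a Poisson number (mean 5) of spurious peaks at 1% of the base peak.
MS/MS synthesis gives each glycomer's B and Y ions intensity equal to its
abundance share — a deliberately flat fragmentation-efficiency model, so
fraction recovery tests the calling machinery, not an efficiency model.
Treatment pairs are drawn with identically seeded generators so a no-op
treatment yields a byte-identical before/after pair.

What passing these tests does **not** show about real data: no isotope
envelopes, charge states, in-source fragmentation, fragmentation-efficiency
variation between B and Y ions, chromatographic effects, or
methylation-dependent PMAA ion shifts (synthetic PMAA records ignore
natural methyls when binning linkage categories).  Recovery statistics on
this generator are a correctness floor for the algorithms, not an accuracy
claim for instruments.

## Numerical choices and problem sizes

Comparisons use absolute tolerances (report rounding to one decimal,
matching the field's printing style); ties in peak matching go to the lower
m/z (MS1) or higher intensity (MS/MS), making results order-independent.
The simulation studies in the test suite use 50 replicate spectra at 10%
intensity CV for fraction recovery (mean absolute error < 0.05 required)
and a 120-tree random corpus for grammar round-trip and fragment
complementarity properties; the full suite runs in a few seconds.

The 1:8 terminal:4-linked galactose ground-truth mixture used in tests is a
single nine-galactose core-fucose chain (1 chain-terminal, 8 internal
4-linked residues); chains of at most five galactoses (forms a–f) cannot
exceed 1:4, so reproducing the published ratio requires the longer chains
that the grammar permits beyond form f.

## Known limitations

* Single glycosidic cleavages only — no A/X cross-ring or C/Z ions, no
  double cleavages.
* O-glycans, glycopeptides, protonated or multiply charged species are out
  of scope.
* The 2-AB B-ion convention is user-supplied; downstream callers that need
  2-AB B ions must calibrate their own constant.
* Enzyme kinetics, partial digestion, and steric accessibility are not
  modeled; treatments are all-or-nothing predicates.
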