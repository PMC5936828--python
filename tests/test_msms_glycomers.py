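"""B/Y enumeration, complementarity, glycomer calling, and fraction recovery."""

import numpy as np
import pandas as pd
import pytest

from glycomer.glycan_model import (
    NA,
    Composition,
    GlycanError,
    parse_structure,
    tree_composition,
    tree_mass,
)
from glycomer.ms1_annotation import PeakList
from glycomer.msms_glycomers import (
    GlycomerCall,
    call_glycomers,
    candidate_pairs,
    enumerate_BY,
    relative_distribution,
)
from glycomer.synthetic_data import Mixture, MixtureSpec, ccm_structure, synthesize_msms

PERM = "permethylated"

F1H3N2_TREE = "Man(a1-6)Man(b1-4)GlcNAc(b1-4)[Gal(b1-4)Fuc(a1-6)]GlcNAc"


def msms_peaklist(pairs, parent_mz, derivatization=PERM):
    return PeakList(
        pd.DataFrame(pairs, columns=["mz", "intensity"]),
        ms_level=2,
        parent_mz=parent_mz,
        derivatization=derivatization,
    )


class TestEnumerateBY:
    def test_chitobiose_cleavage_of_f1h3n2_form_a(self):
        """The trimannosyl-core glycomer of the 1345.7 parent (bare core
        fucose) cleaves between the core GlcNAcs into B 894 (Hex3HexNAc1)
        and Y 474 (Fuc1HexNAc1)."""
        tree = parse_structure(
            "Man(a1-3)[Man(a1-6)]Man(b1-4)GlcNAc(b1-4)[Fuc(a1-6)]GlcNAc", PERM
        )
        fragments = enumerate_BY(tree)
        chitobiose = [
            f for f in fragments if f.cleaved_edge == ("GlcNAc", "GlcNAc")
        ]
        b = next(f for f in chitobiose if f.ion_type == "B")
        y = next(f for f in chitobiose if f.ion_type == "Y")
        assert b.mz == pytest.approx(894, abs=0.5)
        assert y.mz == pytest.approx(474, abs=0.5)

    def test_chitobiose_cleavage_of_f1h3n2_form_b(self):
        """The Man-2 + GalFuc glycomer of the same parent yields the
        complementary (690, 678) pair instead."""
        tree = parse_structure(F1H3N2_TREE, PERM)
        chitobiose = [
            f
            for f in enumerate_BY(tree)
            if f.cleaved_edge == ("GlcNAc", "GlcNAc")
        ]
        b = next(f for f in chitobiose if f.ion_type == "B")
        y = next(f for f in chitobiose if f.ion_type == "Y")
        assert b.mz == pytest.approx(690.3, abs=0.1)
        assert y.mz == pytest.approx(678.3, abs=0.1)

    def test_single_residue_no_edges(self):
        tree = parse_structure("GlcNAc", PERM)
        assert enumerate_BY(tree) == []

    def test_composition_conservation_on_every_cleavage(self, tree_corpus):
        # permethylated fragments come as adjacent (B, Y) pairs per edge
        for tree in tree_corpus:
            if tree.derivatization != PERM:
                continue
            parent = tree_composition(tree)
            fragments = enumerate_BY(tree)
            assert len(fragments) % 2 == 0
            for b, y in zip(fragments[::2], fragments[1::2]):
                assert (b.ion_type, y.ion_type) == ("B", "Y")
                assert b.cleaved_edge == y.cleaved_edge
                assert b.composition + y.composition == parent

    def test_permethylated_complementarity_constant(self, tree_corpus):
        """B + Y = intact [M+Na]+ + 22.9898 on every permethylated cleavage."""
        for tree in tree_corpus:
            if tree.derivatization != PERM:
                continue
            intact = tree_mass(tree)
            fragments = enumerate_BY(tree)
            for b, y in zip(fragments[::2], fragments[1::2]):
                assert b.mz + y.mz == pytest.approx(intact + NA, abs=1e-3)

    def test_two_ab_whole_galfuc_y_ion(self):
        """The GalFuc-GlcNAc reducing fragment of a larger 2-AB parent is the
        672.3 Y ion."""
        tree = parse_structure(F1H3N2_TREE, "twoAB")
        fragments = enumerate_BY(tree)
        y_672 = [f for f in fragments if f.ion_type == "Y" and abs(f.mz - 672.3) < 0.1]
        assert y_672, "GalFuc Y ion missing"
        comp = y_672[0].composition
        assert (comp.nHex, comp.nHexNAc, comp.ndHex) == (1, 1, 1)

    def test_two_ab_b_ions_only_behind_flag(self):
        tree = parse_structure(F1H3N2_TREE, "twoAB")
        assert all(f.ion_type == "Y" for f in enumerate_BY(tree))
        with_b = enumerate_BY(tree, two_ab_b_ions=True, two_ab_b_end=14.0157)
        assert any(f.ion_type == "B" for f in with_b)

    def test_native_unsupported(self):
        tree = parse_structure("Gal(b1-4)GlcNAc", "native")
        with pytest.raises(GlycanError):
            enumerate_BY(tree)


class TestCandidatePairs:
    def test_parent_2162_pairs(self):
        """The m/z 2162.0 parent (Fuc1Hex7HexNAc2 by arithmetic) offers the
        full printed B ladder 690-1506 paired against Y 1494-678."""
        parent = Composition(7, 2, 1, 0, PERM)
        pairs = candidate_pairs(parent)
        # printed fragment values are truncated integers (e.g. 1494.7 -> 1494)
        floored = {(int(b), int(y)) for b, y, _ in pairs}
        for expected in [(690, 1494), (894, 1290), (1098, 1086), (1302, 882), (1506, 678)]:
            assert expected in floored

    def test_f1h3n2_pairs(self):
        pairs = candidate_pairs(Composition(3, 2, 1, 0, PERM))
        rounded = sorted((round(b), round(y)) for b, y, _ in pairs)
        assert rounded == [(690, 678), (894, 474)]

    def test_complementarity_of_every_pair(self):
        from glycomer.glycan_model import composition_mass

        for n_hex in range(3, 10):
            parent = Composition(n_hex, 2, 1, 0, PERM)
            pmz = composition_mass(parent)
            for b, y, form in candidate_pairs(parent):
                assert b + y - pmz == pytest.approx(NA, abs=0.01)

    def test_form_label_tracks_y_hexoses(self):
        from glycomer.glycan_model import fragment_mass

        pairs = candidate_pairs(Composition(7, 2, 1, 0, PERM))
        for b, y, form in pairs:
            y_hex = "abcdef".index(form)
            expected_y = Composition(y_hex, 1, 1, 0, PERM)
            assert y == pytest.approx(fragment_mass(expected_y, "Y"), abs=1e-9)

    def test_pairs_never_share_a_theoretical_mz(self):
        for n_hex in range(3, 10):
            pairs = candidate_pairs(Composition(n_hex, 2, 1, 0, PERM))
            all_mz = [round(b, 3) for b, _, _ in pairs] + [round(y, 3) for _, y, _ in pairs]
            assert len(all_mz) == len(set(all_mz))

    def test_non_series_composition_rejected(self):
        with pytest.raises(GlycanError):
            candidate_pairs(Composition(5, 2, 0, 0, PERM))


class TestCallGlycomers:
    def test_four_glycomers_of_2162(self):
        parent = Composition(7, 2, 1, 0, PERM)
        pairs = {form: (b, y) for b, y, form in candidate_pairs(parent)}
        rows = []
        for form in "cdef":  # four forms present
            b, y = pairs[form]
            rows += [(b, 100.0), (y, 80.0)]
        msms = msms_peaklist(rows, parent_mz=2162.0)
        calls = call_glycomers(msms, parent)
        assert sorted(c.form for c in calls) == ["c", "d", "e", "f"]

    def test_unpaired_b_ion_is_not_called(self):
        parent = Composition(3, 2, 1, 0, PERM)
        msms = msms_peaklist([(894.43, 100.0)], parent_mz=1345.7)  # B alone, no Y 474
        assert call_glycomers(msms, parent) == []

    def test_below_threshold_ions_ignored(self):
        parent = Composition(3, 2, 1, 0, PERM)
        pairs = {form: (b, y) for b, y, form in candidate_pairs(parent)}
        b_a, y_a = pairs["a"]
        b_b, y_b = pairs["b"]
        msms = msms_peaklist(
            [(b_a, 100.0), (y_a, 90.0), (b_b, 1.0), (y_b, 1.0)], parent_mz=1345.7
        )
        calls = call_glycomers(msms, parent, major_ion_threshold=0.05)
        assert [c.form for c in calls] == ["a"]

    def test_synthetic_three_glycomer_truth(self):
        """Simulation round-trip: exactly the three seeded glycomers are
        called at the 5% threshold."""
        structures = [ccm_structure(5, 0), ccm_structure(4, 1), ccm_structure(3, 2)]
        spec = MixtureSpec(seed=5).noiseless()
        mix = Mixture(structures, np.array([0.2, 0.5, 0.3]), spec)
        parent = Composition(5, 2, 1, 0, PERM)
        msms = synthesize_msms(mix, parent)
        calls = call_glycomers(msms, parent, major_ion_threshold=0.05)
        assert sorted(c.form for c in calls) == ["a", "b", "c"]
        fractions = {c.form: c.relative_fraction for c in calls}
        assert fractions["a"] == pytest.approx(0.2, abs=1e-9)
        assert fractions["b"] == pytest.approx(0.5, abs=1e-9)
        assert fractions["c"] == pytest.approx(0.3, abs=1e-9)

    def test_requires_msms_metadata(self):
        parent = Composition(3, 2, 1, 0, PERM)
        ms1 = PeakList(pd.DataFrame({"mz": [894.4], "intensity": [1.0]}))
        with pytest.raises(GlycanError):
            call_glycomers(ms1, parent)


class TestRelativeDistribution:
    def test_two_calls(self):
        calls = [
            GlycomerCall("b", 894.0, 678.0, 894.0, 678.0, 300.0),
            GlycomerCall("c", 690.0, 882.0, 690.0, 882.0, 100.0),
        ]
        out = relative_distribution(calls)
        assert out[0].relative_fraction == pytest.approx(0.75)
        assert out[1].relative_fraction == pytest.approx(0.25)
        assert sum(c.relative_fraction for c in out) == pytest.approx(1.0, abs=1e-9)

    def test_single_call(self):
        (out,) = relative_distribution(
            [GlycomerCall("b", 894.0, 678.0, 894.0, 678.0, 50.0)]
        )
        assert out.relative_fraction == 1.0

    def test_zero_intensity_undefined(self):
        with pytest.raises(GlycanError):
            relative_distribution(
                [GlycomerCall("b", 894.0, 678.0, 894.0, 678.0, 0.0)]
            )
        with pytest.raises(GlycanError):
            relative_distribution([])

    def test_fraction_recovery_under_noise(self):
        """Parameter recovery: truth (0.1, 0.45, 0.35, 0.1), 10% intensity
        CV, 50 replicate spectra; mean recovered fractions within 0.05."""
        truth = np.array([0.1, 0.45, 0.35, 0.1])
        structures = [ccm_structure(5 - g, g) for g in range(4)]
        spec = MixtureSpec(
            seed=7, mz_jitter_sd=0.02, intensity_sigma=0.1, spurious_rate=0.0
        )
        mix = Mixture(structures, truth.copy(), spec)
        parent = Composition(5, 2, 1, 0, PERM)
        recovered = {form: [] for form in "abcd"}
        for i in range(50):
            msms = synthesize_msms(mix, parent, np.random.default_rng(1000 + i))
            calls = call_glycomers(msms, parent)
            got = {c.form: c.relative_fraction for c in calls}
            for form in "abcd":
                recovered[form].append(got.get(form, 0.0))
        for form, target in zip("abcd", truth):
            assert abs(np.mean(recovered[form]) - target) < 0.05
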