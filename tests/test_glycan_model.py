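"""Composition algebra, masses, fragments and delta decomposition."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pymass

import glycopop as gp
from glycopop.glycan_model import _signed_count_vectors

SYMBOLS = ("Hex", "HexNAc", "Fuc", "NeuAc", "NeuGc")

compositions = st.builds(
    gp.GlycanComposition,
    st.fixed_dictionaries({}, optional={s: st.integers(0, 6) for s in SYMBOLS}),
)


class TestParse:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("HexNAc(4)Hex(5)Fuc(1)NeuAc(1)", {"HexNAc": 4, "Hex": 5, "Fuc": 1, "NeuAc": 1}),
            ("", {}),
            ("  HexNAc(2) Hex(3) ", {"HexNAc": 2, "Hex": 3}),
            ("Hex(0)HexNAc(2)", {"HexNAc": 2}),
        ],
    )
    def test_parses_byonic_dialect(self, text, expected):
        assert dict(gp.parse_composition(text)) == expected

    def test_unknown_symbol_named_in_error(self):
        with pytest.raises(gp.GlycanParseError, match="Xyl"):
            gp.parse_composition("Xyl(1)")

    @pytest.mark.parametrize("bad", ["Hex(-1)", "Hex(1.5)", "Hex", "Hex(1"])
    def test_malformed_counts_rejected(self, bad):
        with pytest.raises(gp.GlycanParseError):
            gp.parse_composition(bad)

    @given(compositions)
    @settings(max_examples=200, deadline=None)
    def test_round_trip_through_formatting(self, comp):
        assert gp.parse_composition(gp.format_composition(comp)) == comp


class TestMass:
    def test_residue_masses_match_elemental_formulas(self, table):
        for sym, formula in [
            ("Hex", "C6H10O5"),
            ("HexNAc", "C8H13NO5"),
            ("Fuc", "C6H10O4"),
            ("NeuAc", "C11H17NO8"),
            ("NeuGc", "C11H17NO9"),
        ]:
            assert table.mass(sym) == pytest.approx(
                pymass.calculate_mass(formula=formula), abs=1e-4
            )

    @pytest.mark.parametrize(
        "text,expected",
        [
            ("Fuc(1)", 146.0579),
            ("", 0.0),
            ("HexNAc(4)Hex(5)Fuc(1)", 1768.6395),  # independent residue summation
        ],
    )
    def test_composition_mass(self, text, expected):
        assert gp.composition_mass(gp.parse_composition(text)) == pytest.approx(
            expected, abs=1e-3
        )

    def test_fucose_mass_prints_as_published_shift(self):
        assert round(gp.composition_mass(gp.parse_composition("Fuc(1)")), 3) == 146.058
        assert round(gp.composition_mass(gp.parse_composition("Hex(1)")), 3) == 162.053

    @given(compositions, compositions)
    @settings(max_examples=100, deadline=None)
    def test_mass_additivity(self, a, b):
        assert gp.composition_mass(a + b) == pytest.approx(
            gp.composition_mass(a) + gp.composition_mass(b), abs=1e-9
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            gp.GlycanComposition(Hex=1) - gp.GlycanComposition(Hex=2)


class TestOxonium:
    @pytest.mark.parametrize(
        "text,losses,expected",
        [
            ("HexNAc(1)", 0, 204.0867),
            ("NeuAc(1)", 0, 292.1027),
            ("Hex(1)", 0, 163.0601),
            ("Hex(1)", 1, 145.0495),
            ("Hex(1)HexNAc(1)", 0, 366.1395),
        ],
    )
    def test_diagnostic_ions(self, text, losses, expected):
        assert gp.oxonium_mz(gp.parse_composition(text), losses) == pytest.approx(
            expected, abs=2e-4
        )

    def test_empty_composition_rejected(self):
        with pytest.raises(ValueError):
            gp.oxonium_mz(gp.GlycanComposition())


class TestPeptide:
    def test_igg1_y1_ion(self, igg1_backbone):
        ion = gp.GlycopeptideIon(igg1_backbone, gp.parse_composition("HexNAc(1)"), charge=1)
        assert ion.mz() == pytest.approx(1392.5914, abs=2e-3)
        assert round(ion.mz(), 2) == 1392.59

    def test_mz_charge_relation(self, igg1_backbone):
        g = gp.parse_composition("HexNAc(4)Hex(5)Fuc(1)")
        for z in (1, 2, 3, 4):
            ion = gp.GlycopeptideIon(igg1_backbone, g, charge=z)
            assert ion.mz() == pytest.approx(
                (ion.neutral_mass() + z * gp.PROTON_MASS) / z, abs=1e-9
            )

    def test_carbamidomethyl_applied_per_cysteine(self):
        with_c = gp.peptide_mass("ACDK")
        without = gp.peptide_mass("ACDK", carbamidomethyl_cys=False)
        assert with_c - without == pytest.approx(gp.CARBAMIDOMETHYL, abs=1e-6)


class TestYLadder:
    def test_single_hexnac_glycan_yields_only_y1(self, igg1_backbone):
        ion = gp.GlycopeptideIon(igg1_backbone, gp.parse_composition("HexNAc(1)"), charge=2)
        ladder = gp.y_ion_ladder(ion, charges=(1,))
        assert len(ladder) == 1
        assert ladder[0].is_y1
        assert ladder[0].mz_by_charge[1] == pytest.approx(1392.5914, abs=2e-3)

    def test_lattice_matches_exhaustive_enumeration(self, igg1_backbone):
        # HexNAc(2)Hex(3): HexNAc 1-2 x Hex 0-3 minus the intact glycan = 7
        ion = gp.GlycopeptideIon(igg1_backbone, gp.parse_composition("HexNAc(2)Hex(3)"), charge=2)
        ladder = gp.y_ion_ladder(ion)
        expected = {
            gp.GlycanComposition(HexNAc=n, Hex=h)
            for n in (1, 2)
            for h in range(4)
        } - {gp.parse_composition("HexNAc(2)Hex(3)")}
        assert {y.composition for y in ladder} == expected
        assert len(ladder) == 7

    def test_ladder_requires_hexnac(self, igg1_backbone):
        ion = gp.GlycopeptideIon(igg1_backbone, gp.parse_composition("Hex(3)"), charge=2)
        with pytest.raises(ValueError):
            gp.y_ion_ladder(ion)

    def test_precursor_minus_y1_equals_glycan_minus_hexnac(self, igg1_backbone):
        g = gp.parse_composition("HexNAc(4)Hex(5)Fuc(1)NeuAc(1)")
        ion = gp.GlycopeptideIon(igg1_backbone, g, charge=2)
        y1 = [y for y in gp.y_ion_ladder(ion) if y.is_y1][0]
        lhs = ion.neutral_mass() - y1.neutral_mass
        rhs = gp.composition_mass(g) - gp.DEFAULT_TABLE.mass("HexNAc")
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_linear_policy_gives_single_path(self, igg1_backbone):
        g = gp.parse_composition("HexNAc(4)Hex(5)Fuc(1)NeuAc(1)")
        ion = gp.GlycopeptideIon(igg1_backbone, g, charge=2)
        linear = gp.y_ion_ladder(ion, policy="linear")
        assert len(linear) == g.total - 1  # one fragment per removal step
        lattice = {y.composition for y in gp.y_ion_ladder(ion, policy="lattice")}
        assert {y.composition for y in linear} <= lattice


def brute_force_deltas(delta, max_changes, tol, table=gp.DEFAULT_TABLE):
    """Independent enumeration over all signed residue combinations."""
    hits = set()
    syms = table.symbols
    for n in range(0, max_changes + 1):
        for combo in itertools.product(syms, repeat=n):
            for signs in itertools.product((-1, 1), repeat=n):
                counts = {}
                for s, sg in zip(combo, signs):
                    counts[s] = counts.get(s, 0) + sg
                net = sum(c * table.mass(s) for s, c in counts.items())
                if abs(net - delta) <= tol:
                    hits.add(tuple(sorted((s, c) for s, c in counts.items() if c)))
    return hits


class TestDeltaDecompositions:
    def test_fucose_hexose_swap(self):
        results = gp.delta_decompositions(15.995, max_changes=2, tol=0.1)
        assert {("Fuc", -1), ("Hex", 1)} in [set(d.counts) for d in results]

    def test_zero_delta_includes_identity(self):
        results = gp.delta_decompositions(0.0, max_changes=2, tol=0.1)
        assert any(d.n_changes == 0 for d in results)
        assert results[0].n_changes == 0  # sorted: fewest changes first

    def test_single_hexose_shift(self):
        results = gp.delta_decompositions(162.05, max_changes=2, tol=0.1)
        assert set(results[0].counts) == {("Hex", 1)}

    def test_hex_hexnac_shift_unique(self):
        results = gp.delta_decompositions(365.13, max_changes=2, tol=0.1)
        assert [set(d.counts) for d in results] == [{("Hex", 1), ("HexNAc", 1)}]

    @pytest.mark.parametrize("delta", [162.05, 291.10, 365.13, 656.23, 730.26, -146.06, 15.995, 40.0])
    def test_matches_brute_force_enumeration(self, delta):
        got = {d.counts for d in gp.delta_decompositions(delta, 2, 0.1)}
        assert got == brute_force_deltas(delta, 2, 0.1)

    def test_apply_rejects_negative_counts(self):
        d = [x for x in gp.delta_decompositions(15.995, 2, 0.1) if dict(x.counts).get("Fuc") == -1][0]
        assert d.apply(gp.GlycanComposition(HexNAc=2, Hex=3)) is None
        assert d.apply(gp.GlycanComposition(HexNAc=2, Hex=3, Fuc=1)) == gp.GlycanComposition(HexNAc=2, Hex=4)

    def test_signed_vectors_budget(self):
        vecs = list(_signed_count_vectors(("A", "B"), 2))
        assert all(sum(map(abs, v.values())) <= 2 for v in vecs)
        # L1-ball of radius 2 in Z^2: 13 lattice points
        assert len({tuple(sorted(v.items())) for v in vecs}) == 13


class TestMonosaccharideTable:
    def test_inconsistent_mass_rejected(self):
        with pytest.raises(ValueError):
            gp.MonosaccharideTable([gp.Monosaccharide("Hex", "C6H10O5", 162.06)])

    def test_extension_and_csv_round_trip(self, tmp_path):
        xyl = gp.Monosaccharide("Xyl", "C5H8O4", 132.0423)
        t = gp.MonosaccharideTable(
            [gp.Monosaccharide(s, f, gp.DEFAULT_TABLE[s].residue_mass)
             for s, f in [("Hex", "C6H10O5"), ("HexNAc", "C8H13NO5")]] + [xyl]
        )
        p = tmp_path / "residues.csv"
        t.to_csv(p)
        t2 = gp.MonosaccharideTable.from_csv(p)
        assert t2.symbols == t.symbols
        assert gp.parse_composition("Xyl(2)", t2)["Xyl"] == 2
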