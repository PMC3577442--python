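"""Mass model: independent elemental oracle, frozen values, invariants."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from biosurfkit.chem import (
    METHYLENE,
    PROTON,
    WATER,
    FattyAcidVariant,
    LipopeptideSpecies,
    ResidueMassTable,
    UnknownResidueError,
    adduct_mz,
    enumerate_fragments,
    homologue_series,
    neutral_mass,
    nominal_mz,
)

# --- independent oracle: elemental composition summation -------------------
# Residue formulas and NIST monoisotopic element masses, kept separate from
# the implementation's residue-mass table on purpose.

_EL = {"C": 12.0, "H": 1.0078250319, "N": 14.0030740052, "O": 15.9949146221}
_RESIDUE_FORMULA = {
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
}


def oracle_cyclic_mass(sequence: str, carbons: int) -> float:
    """Elemental sum for the cyclic acyl-peptide: residues + CnH2nO3 - H2O."""
    comp = {el: 0 for el in _EL}
    for code in sequence:
        for el, k in _RESIDUE_FORMULA[code].items():
            comp[el] += k
    comp["C"] += carbons
    comp["H"] += 2 * carbons
    comp["O"] += 3
    comp["H"] -= 2
    comp["O"] -= 1
    return sum(_EL[el] * k for el, k in comp.items())


class TestNeutralMass:
    def test_against_elemental_oracle(self):
        for carbons in range(13, 17):
            species = LipopeptideSpecies.surfactin(carbons)
            expected = oracle_cyclic_mass("ELLVDLL", carbons)
            assert neutral_mass(species) == pytest.approx(expected, abs=1e-4)

    def test_c15_value(self, c15):
        # frozen from the elemental oracle
        assert neutral_mass(c15) == pytest.approx(1035.683, abs=1e-3)

    def test_homologues_differ_by_methylene(self, c15):
        for n in range(4, 30):
            lo = neutral_mass(c15.with_carbons(n))
            hi = neutral_mass(c15.with_carbons(n + 1))
            assert hi - lo == pytest.approx(METHYLENE, abs=1e-9)

    def test_linear_acyl_is_cyclic_plus_water(self, c15):
        linear = LipopeptideSpecies(
            c15.sequence, c15.fatty_acid, topology="linear"
        )
        assert neutral_mass(linear) == pytest.approx(
            neutral_mass(c15) + WATER, abs=1e-9
        )

    def test_plain_peptide_without_fatty_acid(self):
        pep = LipopeptideSpecies("ELLVDLL", None, topology="linear")
        table = ResidueMassTable()
        assert neutral_mass(pep) == pytest.approx(
            table.peptide_residue_sum("ELLVDLL") + WATER, abs=1e-9
        )

    def test_unknown_residue_named_in_error(self):
        bad = LipopeptideSpecies("ELLXDLL", FattyAcidVariant(15), "cyclic-lactone")
        with pytest.raises(UnknownResidueError, match="X"):
            neutral_mass(bad)


class TestAdducts:
    @pytest.mark.parametrize(
        "carbons,negative,positive",
        [(13, 1007, 1009), (14, 1021, 1023), (15, 1035, 1037), (16, 1049, 1051)],
    )
    def test_printed_molecular_ions(self, c15, carbons, negative, positive):
        sp = c15.with_carbons(carbons)
        assert adduct_mz(sp, "negative").nominal == negative
        assert adduct_mz(sp, "positive").nominal == positive

    def test_polarity_gap_is_two_protons(self, c15):
        pos = adduct_mz(c15, "positive")
        neg = adduct_mz(c15, "negative")
        assert pos.mz - neg.mz == pytest.approx(2 * PROTON, abs=1e-9)
        assert pos.nominal - neg.nominal == 2

    def test_nominal_rounds_half_up(self):
        assert nominal_mz(100.5) == 101
        assert nominal_mz(100.4999) == 100


class TestFragments:
    @pytest.mark.parametrize(
        "label,expected",
        [
            ("y6", 685),  # C-terminal hexapeptide, common to every homologue
            ("internal(2-5)", 441),  # Leu-Leu-Val-Asp, common to every homologue
            ("b1", 370),
            ("b1-H2O", 352),
        ],
    )
    def test_printed_c15_fragments(self, c15, label, expected):
        frags = {f.label: f for f in enumerate_fragments(c15)}
        assert frags[label].nominal == expected

    def test_c16_b1_pair(self, c15):
        frags = {f.label: f for f in enumerate_fragments(c15.with_carbons(16))}
        assert frags["b1"].nominal == 384
        assert frags["b1-H2O"].nominal == 366

    def test_water_loss_satellite_offset(self, c15):
        frags = {f.label: f for f in enumerate_fragments(c15)}
        for k in range(1, 7):
            assert frags[f"b{k}"].mz - frags[f"b{k}-H2O"].mz == pytest.approx(
                WATER, abs=1e-9
            )

    def test_acyl_free_fragments_shared_across_homologues(self, c15):
        by_carbon = {
            n: {f.label: f.nominal for f in enumerate_fragments(c15.with_carbons(n))}
            for n in (13, 14, 15, 16)
        }
        for label in ("y6", "y4", "internal(2-5)", "internal(4-6)"):
            assert len({by_carbon[n][label] for n in by_carbon}) == 1

    def test_fragments_below_precursor(self, c15):
        mh = adduct_mz(c15, "positive").mz
        for f in enumerate_fragments(c15):
            assert f.mz < mh + 1.0

    def test_by_complementarity(self, c15):
        """b_k + y_(N-k) = [M+H]+ + proton for the linearized acyl-peptide."""
        linear = LipopeptideSpecies(c15.sequence, c15.fatty_acid, "linear")
        mh = adduct_mz(linear, "positive").mz
        frags = {f.label: f for f in enumerate_fragments(linear)}
        n = len(c15.sequence)
        for k in range(1, n):
            total = frags[f"b{k}"].mz + frags[f"y{n - k}"].mz
            assert total == pytest.approx(mh + PROTON, abs=1e-6)

    def test_plain_peptide_has_no_satellites(self):
        pep = LipopeptideSpecies("ELLVDLL", None, "linear")
        labels = [f.label for f in enumerate_fragments(pep)]
        assert not any("H2O" in l for l in labels)
        assert "b1" in labels and "y6" in labels


class TestHomologueSeries:
    def test_negative_ladder(self, c15, homologue_carbons):
        ladder = homologue_series(c15, homologue_carbons, "negative")
        assert [ion.nominal for _, ion in ladder] == [1007, 1021, 1035, 1049]

    def test_consecutive_spacing_exact(self, c15):
        ladder = homologue_series(c15, range(10, 20), "positive")
        for (_, a), (_, b) in zip(ladder, ladder[1:]):
            assert b.mz - a.mz == pytest.approx(METHYLENE, abs=1e-9)

    def test_positive_members_track_negative(self, c15, homologue_carbons):
        neg = homologue_series(c15, homologue_carbons, "negative")
        pos = homologue_series(c15, homologue_carbons, "positive")
        for (_, n), (_, p) in zip(neg, pos):
            assert p.mz - n.mz == pytest.approx(2 * PROTON, abs=1e-9)

    def test_single_member_and_bad_range(self, c15):
        assert len(homologue_series(c15, [15], "negative")) == 1
        with pytest.raises(ValueError):
            homologue_series(c15, [], "negative")
        with pytest.raises(ValueError):
            homologue_series(c15, [15, 14], "negative")


class TestDomainTypes:
    def test_constants_match_standard_values(self):
        assert METHYLENE == pytest.approx(14.01565, abs=1e-4)
        assert WATER == pytest.approx(18.01056, abs=1e-4)
        assert PROTON == pytest.approx(1.00728, abs=1e-4)

    @given(st.integers(min_value=4, max_value=30))
    @settings(derandomize=True, max_examples=27)
    def test_beta_hydroxy_formula(self, n):
        fa = FattyAcidVariant(n)
        assert fa.formula() == {"C": n, "H": 2 * n, "O": 3}

    def test_branching_never_changes_mass(self):
        masses = {
            FattyAcidVariant(15, branching=b).mass()
            for b in ("linear", "iso", "anteiso", "unknown")
        }
        assert len(masses) == 1

    def test_cyclic_requires_beta_hydroxy(self):
        with pytest.raises(ValueError):
            LipopeptideSpecies(
                "ELLVDLL", FattyAcidVariant(15, hydroxyl="alpha"), "cyclic-lactone"
            )
        with pytest.raises(ValueError):
            LipopeptideSpecies("ELLVDLL", None, "cyclic-lactone")
        with pytest.raises(ValueError):
            LipopeptideSpecies("", FattyAcidVariant(15), "cyclic-lactone")
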