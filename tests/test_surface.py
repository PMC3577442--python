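"""van Oss surface energetics: forward model, inversion, dGiwi, verdicts."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from biosurfkit.simulate import gen_contact_angles
from biosurfkit.surface import (
    DEFAULT_LIQUIDS,
    ETHYLENE_GLYCOL,
    FORMAMIDE,
    WATER,
    ContactAngleModel,
    ProbeLiquid,
    SurfaceComponents,
    classify_wettability,
    compute_deltaG_iwi,
    conditioning_delta,
    derive_ab_total,
    forward_contact_angle,
    invert_components,
    surface_energy,
)

#: Component triple of the magnitude of a real conditioned-steel surface.
STEEL_LIKE = SurfaceComponents(gamma_lw=42.02, gamma_plus=0.85, gamma_minus=2.68)
WATER_LIKE = SurfaceComponents(21.8, 25.5, 25.5)


def forward_angles(comp, liquids=DEFAULT_LIQUIDS):
    return {
        name: forward_contact_angle(comp, liq).theta_deg
        for name, liq in liquids.items()
    }


def random_admissible_components(rng):
    """Random triple for which all three probe angles are physical."""
    while True:
        comp = SurfaceComponents(
            gamma_lw=float(rng.uniform(15.0, 45.0)),
            gamma_plus=float(rng.uniform(0.0, 3.0)),
            gamma_minus=float(rng.uniform(0.0, 30.0)),
        )
        flags = [
            forward_contact_angle(comp, liq).flag for liq in DEFAULT_LIQUIDS.values()
        ]
        if all(f == "ok" for f in flags):
            return comp


class TestForwardModel:
    def test_water_on_waterlike_surface_wets_completely(self):
        out = forward_contact_angle(WATER_LIKE, WATER)
        assert out.theta_deg == 0.0
        assert out.flag in ("ok", "complete-wetting")
        assert out.cos_theta == pytest.approx(1.0, abs=1e-12)

    def test_apolar_surface_depends_only_on_lw(self):
        apolar = SurfaceComponents(30.0, 0.0, 0.0)
        for liq in (FORMAMIDE, ETHYLENE_GLYCOL):
            expected = math.degrees(
                math.acos(2.0 * math.sqrt(30.0 * liq.gamma_lw) / liq.gamma_tot - 1.0)
            )
            assert forward_contact_angle(apolar, liq).theta_deg == pytest.approx(
                expected, abs=1e-9
            )

    def test_roundtrip_recovers_components(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            comp = random_admissible_components(rng)
            rec, diag = invert_components(forward_angles(comp))
            assert rec.gamma_lw == pytest.approx(comp.gamma_lw, abs=1e-6)
            assert rec.gamma_plus == pytest.approx(comp.gamma_plus, abs=1e-6)
            assert rec.gamma_minus == pytest.approx(comp.gamma_minus, abs=1e-6)
            assert diag["negative_roots"] == ()


class TestInversion:
    def test_steel_like_components_recovered(self):
        rec, _ = invert_components(forward_angles(STEEL_LIKE))
        assert rec.gamma_lw == pytest.approx(42.02, abs=1e-6)
        assert rec.gamma_plus == pytest.approx(0.85, abs=1e-6)
        assert rec.gamma_minus == pytest.approx(2.68, abs=1e-6)

    def test_complete_wetting_water_like_definition(self):
        # all three liquids spread on a sufficiently high-energy surface
        angles = {name: 0.0 for name in DEFAULT_LIQUIDS}
        rec, _ = invert_components(angles)
        for liq in DEFAULT_LIQUIDS.values():
            assert forward_contact_angle(rec, liq).theta_deg == pytest.approx(
                0.0, abs=1e-6
            )

    def test_duplicated_liquids_rejected(self):
        liquids = {
            "water": WATER,
            "water2": ProbeLiquid("water2", 72.8, 21.8, 25.5, 25.5),
            "formamide": FORMAMIDE,
        }
        angles = {"water": 60.0, "water2": 60.0, "formamide": 50.0}
        with pytest.raises(ValueError, match="ill-conditioned"):
            invert_components(angles, liquids)

    def test_wrong_liquid_count_rejected(self):
        with pytest.raises(ValueError):
            invert_components({"water": 60.0, "formamide": 50.0})

    def test_negative_roots_clamped_and_flagged(self):
        # steep angles on water only: drives the donor root negative
        angles = {"water": 120.0, "formamide": 20.0, "ethylene glycol": 15.0}
        comp, diag = invert_components(angles)
        assert comp.gamma_lw >= 0 and comp.gamma_plus >= 0 and comp.gamma_minus >= 0
        assert len(diag["negative_roots"]) >= 1


class TestDerivedQuantities:
    def test_ab_total_values(self):
        gab, gtot = derive_ab_total(0.85, 2.68, 42.02)
        assert gab == pytest.approx(3.018, abs=1e-3)
        assert gtot == pytest.approx(45.04, abs=1e-2)

    def test_zero_acid_component_gives_apolar_total(self):
        gab, gtot = derive_ab_total(0.0, 17.3, 33.0)
        assert gab == 0.0
        assert gtot == 33.0

    def test_ab_symmetric_under_exchange(self):
        assert derive_ab_total(0.85, 2.68, 42.0)[0] == derive_ab_total(2.68, 0.85, 42.0)[0]

    def test_deltaG_zero_for_water_like_surface(self):
        assert compute_deltaG_iwi(WATER_LIKE) == 0.0

    def test_deltaG_apolar_closed_form(self):
        # purely apolar surface with water's gLW: only the water-cohesion
        # polar term survives: dG = -4 sqrt(gw+ gw-)
        comp = SurfaceComponents(WATER.gamma_lw, 0.0, 0.0)
        expected = -4.0 * math.sqrt(WATER.gamma_plus * WATER.gamma_minus)
        assert compute_deltaG_iwi(comp) == pytest.approx(expected, abs=1e-12)

    def test_steel_like_is_hydrophobic(self):
        dg = compute_deltaG_iwi(STEEL_LIKE)
        assert dg < 0
        assert classify_wettability(dg) == ("hydrophobic", False)

    def test_deltaG_invariant_under_exchange_in_water(self):
        a = SurfaceComponents(40.0, 1.3, 7.9)
        b = SurfaceComponents(40.0, 7.9, 1.3)
        assert compute_deltaG_iwi(a) == pytest.approx(compute_deltaG_iwi(b), abs=1e-9)

    @given(
        st.floats(min_value=0.0, max_value=60.0),
        st.floats(min_value=0.0, max_value=59.0),
    )
    @settings(derandomize=True, max_examples=60)
    def test_deltaG_monotone_in_electron_donor(self, gm, delta):
        lo = SurfaceComponents(35.0, 1.0, gm)
        hi = SurfaceComponents(35.0, 1.0, gm + delta + 0.001)
        assert compute_deltaG_iwi(hi) >= compute_deltaG_iwi(lo) - 1e-9


class TestClassification:
    @pytest.mark.parametrize(
        "dg,expected",
        [(-98.7, "hydrophobic"), (23.7, "hydrophilic"), (-0.001, "hydrophobic")],
    )
    def test_sign_rule(self, dg, expected):
        assert classify_wettability(dg)[0] == expected

    def test_zero_is_boundary_hydrophilic(self):
        assert classify_wettability(0.0) == ("hydrophilic", True)


class TestConditioningVerdicts:
    def test_less_hydrophobic_verdict(self):
        control = surface_energy(STEEL_LIKE)
        treated = surface_energy(SurfaceComponents(50.0, 5.0, 20.0))
        v = conditioning_delta(control, treated)
        assert v["hydrophobicity"] == "less hydrophobic"
        assert v["electron_donor"] == "more electron-donating"

    def test_identical_inputs_unchanged(self):
        e = surface_energy(STEEL_LIKE)
        v = conditioning_delta(e, e)
        assert v["hydrophobicity"] == "unchanged"
        assert v["electron_donor"] == "unchanged"
        assert not v["sign_change"]

    def test_sign_change_flagged(self):
        control = surface_energy(STEEL_LIKE)  # hydrophobic
        treated = surface_energy(SurfaceComponents(60.0, 2.0, 45.0))
        v = conditioning_delta(control, treated)
        assert treated.classification == "hydrophilic"
        assert v["sign_change"]


class TestContactAngleModel:
    def test_noiseless_table_recovers_truth(self):
        truth = {
            ("steel", "control"): STEEL_LIKE,
            ("steel", "conditioned"): SurfaceComponents(50.0, 5.0, 20.0),
        }
        df, _ = gen_contact_angles(truth, noise_sd=0.0, replicates=10, seed=0)
        results = ContactAngleModel(df).fit()
        e = results.energies[("steel", "control")]
        assert e.gamma_lw == pytest.approx(42.02, abs=1e-6)
        assert e.classification == "hydrophobic"
        summary = results.summary()
        assert set(summary["surface"]) == {"steel"}
        compare = results.compare(control_label="control")
        assert list(compare["hydrophobicity"]) == ["less hydrophobic"]

    def test_noisy_table_recovers_within_tolerance(self):
        truth = {("steel", "control"): STEEL_LIKE}
        df, _ = gen_contact_angles(truth, noise_sd=0.5, replicates=10, seed=1)
        e = ContactAngleModel(df).fit().energies[("steel", "control")]
        assert e.gamma_lw == pytest.approx(STEEL_LIKE.gamma_lw, rel=0.15)

    def test_out_of_range_angle_rejected(self):
        df = pd.DataFrame(
            {
                "surface": ["s"],
                "treatment": ["control"],
                "liquid": ["water"],
                "angle_deg": [190.0],
            }
        )
        with pytest.raises(ValueError, match="outside"):
            ContactAngleModel(df)
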