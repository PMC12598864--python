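"""Thermodynamic-cycle algebra against the tabulated experimental record."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pkasolv import cycles
from pkasolv.synthetic import make_gas_table
from pkasolv.thermochem import Quantity, ThermoConstants

TOL = 0.05  # kcal/mol or pKa units; absorbs two-decimal table rounding


class TestAutoprotolysisCorrection:
    @pytest.mark.parametrize(
        "pk, delta, expected",
        [(16.7, 2.30, 21.3), (14.0, 0.0, 14.0), (16.7, 2.25, 21.2)],
    )
    def test_correction(self, pk, delta, expected):
        out = cycles.correct_autoprotolysis(Quantity(pk), delta)
        assert out.value == pytest.approx(expected, abs=1e-9)

    def test_negative_delta_rejected(self):
        with pytest.raises(ValueError):
            cycles.correct_autoprotolysis(Quantity(14.0), -0.1)


class TestAcidityBasicity:
    @pytest.mark.parametrize(
        "pk, conc, expected",
        [
            (14.0, 55.5, 21.46),  # water
            (21.3, 24.5, 30.93),  # methanol, corrected constant
            (16.7, 24.5, 24.66),  # methanol, original constant
        ],
    )
    def test_solution_acidity(self, pk, conc, expected, const):
        out = cycles.solution_acidity(Quantity(pk), conc, const)
        assert out.value == pytest.approx(expected, abs=TOL)

    def test_acidity_log_of_one(self, const):
        # K_ap numerically equal to [SH]: the ratio is 1, dG vanishes
        conc = 2.0
        out = cycles.solution_acidity(Quantity(-math.log10(conc)), conc, const)
        assert out.value == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize(
        "conc, expected", [(55.5, -2.38), (24.5, -1.89), (1.0, 0.0)]
    )
    def test_solution_basicity(self, conc, expected, const):
        out = cycles.solution_basicity(conc, const)
        assert out.value == pytest.approx(expected, abs=TOL)

    @pytest.mark.parametrize(
        "pk, conc, expected", [(14.0, 55.5, 23.84), (21.3, 24.5, 32.85)]
    )
    def test_heterolytic(self, pk, conc, expected, const):
        out = cycles.heterolytic_dG(Quantity(pk), conc, const)
        assert out.value == pytest.approx(expected, abs=TOL)

    def test_heterolytic_log_of_one(self, const):
        conc = 3.0
        out = cycles.heterolytic_dG(Quantity(-2 * math.log10(conc)), conc, const)
        assert out.value == pytest.approx(0.0, abs=1e-12)

    def test_nonpositive_concentration_rejected(self, const):
        for fn in (
            lambda: cycles.solution_acidity(Quantity(14.0), 0.0, const),
            lambda: cycles.solution_basicity(-1.0, const),
            lambda: cycles.heterolytic_dG(Quantity(14.0), 0.0, const),
        ):
            with pytest.raises(ValueError):
                fn()

    @given(
        pk=st.floats(min_value=0, max_value=30),
        conc=st.floats(min_value=1, max_value=100),
    )
    @settings(max_examples=200, deadline=None)
    def test_acidity_minus_heterolytic_is_basicity(self, pk, conc, const):
        """dG(3) = dG(1) - dG(2) for any (pK_ap, [SH])."""
        dg1 = cycles.solution_acidity(Quantity(pk), conc, const)
        dg2 = cycles.heterolytic_dG(Quantity(pk), conc, const)
        dg3 = cycles.solution_basicity(conc, const)
        assert dg3.value == pytest.approx(dg1.value - dg2.value, abs=1e-9)


class TestPKa:
    @pytest.mark.parametrize(
        "dg, expected", [(21.46, 15.73), (30.93, 22.67), (0.0, 0.0)]
    )
    def test_pka_from_acidity(self, dg, expected, const):
        out = cycles.pKa_from_dG1(Quantity(dg, units="kcal/mol"), const)
        assert out.value == pytest.approx(expected, abs=TOL)

    @pytest.mark.parametrize(
        "dg, conc, expected", [(23.84, 55.5, 15.73), (32.85, 24.5, 22.69)]
    )
    def test_pka_from_heterolytic(self, dg, conc, expected, const):
        out = cycles.pKa_from_dG2(Quantity(dg, units="kcal/mol"), conc, const)
        assert out.value == pytest.approx(expected, abs=TOL)

    def test_pka2_algebraic_zero(self, const):
        conc = 10.0
        dg = const.ln10_RT * math.log10(conc)
        out = cycles.pKa_from_dG2(Quantity(dg, units="kcal/mol"), conc, const)
        assert out.value == pytest.approx(0.0, abs=1e-12)

    @given(
        pk=st.floats(min_value=0, max_value=30),
        conc=st.floats(min_value=1, max_value=100),
    )
    @settings(max_examples=200, deadline=None)
    def test_both_pka_routes_agree(self, pk, conc, const):
        """pKa(1) and pKa(2) both reduce to pK_ap + log10[SH]."""
        dg1 = cycles.solution_acidity(Quantity(pk), conc, const)
        dg2 = cycles.heterolytic_dG(Quantity(pk), conc, const)
        p1 = cycles.pKa_from_dG1(dg1, const)
        p2 = cycles.pKa_from_dG2(dg2, conc, const)
        assert p1.value == pytest.approx(p2.value, abs=1e-9)
        assert p1.value == pytest.approx(pk + math.log10(conc), abs=1e-9)


class TestIonSolvation:
    def test_hydroxide(self, water, const):
        dg1 = cycles.solution_acidity(water.pK_ap, water.conc_SH, const)
        out = cycles.anion_solvation(water, dg1)
        assert out.value == pytest.approx(-104.60, abs=TOL)
        assert out.sigma == pytest.approx(0.25, abs=0.01)

    def test_hydronium(self, water, const):
        dg3 = cycles.solution_basicity(water.conc_SH, const)
        out = cycles.cation_solvation(water, dg3)
        assert out.value == pytest.approx(-110.20, abs=TOL)
        assert out.sigma == pytest.approx(1.91, abs=0.01)

    def test_methoxide_both_conventions(self, methanol, const):
        pk_star = cycles.correct_autoprotolysis(methanol.pK_ap, methanol.delta.value)
        dg1 = cycles.solution_acidity(pk_star, methanol.conc_SH, const)
        out = cycles.anion_solvation(methanol, dg1)
        assert out.value == pytest.approx(-88.36, abs=TOL)
        assert out.sigma == pytest.approx(2.10, abs=0.01)
        dg1_orig = cycles.solution_acidity(methanol.pK_ap, methanol.conc_SH, const)
        orig = cycles.anion_solvation(methanol, dg1_orig)
        assert orig.value == pytest.approx(-94.63, abs=TOL)

    def test_methoxonium(self, methanol, const):
        dg3 = cycles.solution_basicity(methanol.conc_SH, const)
        out = cycles.cation_solvation(methanol, dg3)
        assert out.value == pytest.approx(-91.41, abs=TOL)
        assert out.sigma == pytest.approx(2.76, abs=0.01)

    @given(shift=st.floats(min_value=-5, max_value=5))
    @settings(max_examples=50, deadline=None)
    def test_anion_linear_in_acidity(self, water, shift):
        """Unit slope: shifting dG(1) by x shifts dG_sol*(S-) by x."""
        base = cycles.anion_solvation(water, Quantity(21.46, units="kcal/mol"))
        moved = cycles.anion_solvation(
            water, Quantity(21.46 + shift, units="kcal/mol")
        )
        assert moved.value - base.value == pytest.approx(shift, abs=1e-9)


class TestScaleShift:
    def test_methanol_shift(self, const):
        assert cycles.scale_shift(2.30, const) == pytest.approx(6.27, abs=TOL)
        assert cycles.scale_shift(0.0, const) == 0.0

    @given(
        delta=st.floats(min_value=0, max_value=5),
        pk=st.floats(min_value=0, max_value=30),
        conc=st.floats(min_value=1, max_value=100),
    )
    @settings(max_examples=100, deadline=None)
    def test_convention_gap_equals_shift(self, delta, pk, conc, const):
        """Corrected-minus-original acidity equals 2*delta*RT*ln10."""
        orig = cycles.solution_acidity(Quantity(pk), conc, const)
        corr = cycles.solution_acidity(
            cycles.correct_autoprotolysis(Quantity(pk), delta), conc, const
        )
        assert corr.value - orig.value == pytest.approx(
            cycles.scale_shift(delta, const), abs=1e-9
        )


class TestLandmarks:
    def test_methanol_landmarks(self, methanol):
        lm = cycles.ph_landmarks(methanol)
        assert lm.ph_neutral_app == pytest.approx(8.35, abs=TOL)
        assert lm.ph_neutral_star == pytest.approx(10.65, abs=TOL)
        assert lm.pKa_bulk == pytest.approx(18.1, abs=TOL)
        assert lm.pKa_bulk_star == pytest.approx(22.7, abs=TOL)

    def test_water_landmarks(self, water):
        lm = cycles.ph_landmarks(water)
        assert lm.ph_neutral_app == pytest.approx(7.0, abs=1e-9)
        assert lm.ph_neutral_star == pytest.approx(7.0, abs=1e-9)
        assert lm.pKa_bulk == pytest.approx(15.74, abs=TOL)


class TestGasPhase:
    @pytest.mark.parametrize(
        "solvent, expected", [("water", 226.4), ("methanol", 202.7)]
    )
    def test_heterolytic_bookkeeping(self, solvent, expected):
        out = cycles.gas_heterolytic(make_gas_table(solvent))
        assert out.value == pytest.approx(expected, abs=TOL)

    def test_equal_energies_cancel(self):
        from pkasolv.thermochem import GasSpecies

        g = Quantity(-100.0, units="kcal/mol")
        species = {lbl: GasSpecies(lbl, g) for lbl in ("SH", "SH2+", "S-")}
        assert cycles.gas_heterolytic(species).value == pytest.approx(0.0)

    def test_missing_species_rejected(self):
        species = make_gas_table("water")
        del species["S-"]
        with pytest.raises(ValueError, match="S-"):
            cycles.gas_heterolytic(species)

    @pytest.mark.parametrize(
        "solvent, acid, expected, sig",
        [("water", (385.64, 0.10), -6.04, 0.10), ("methanol", (377.93, 0.62), -5.91, None)],
    )
    def test_proton_energy(self, solvent, acid, expected, sig):
        tbl = make_gas_table(solvent)
        out = cycles.gas_proton_energy(
            Quantity(*acid, units="kcal/mol"),
            tbl["SH"].G_gas,
            tbl["S-"].G_gas,
        )
        assert out.value == pytest.approx(expected, abs=TOL)
        if sig is not None:
            assert out.sigma == pytest.approx(sig, abs=0.01)


class TestBuildReport:
    def test_water_report(self, water):
        r = cycles.build_report(water, "corrected")
        assert r.dG_sol_1.value == pytest.approx(21.46, abs=TOL)
        assert r.dG_sol_3.value == pytest.approx(-2.38, abs=TOL)
        assert r.pKa_1.value == pytest.approx(15.73, abs=TOL)
        assert r.dG_sol_anion.value == pytest.approx(-104.60, abs=TOL)
        assert r.dG_sol_cation.value == pytest.approx(-110.20, abs=TOL)

    def test_methanol_both_conventions(self, methanol):
        corr = cycles.build_report(methanol, "corrected")
        orig = cycles.build_report(methanol, "original")
        assert corr.dG_sol_1.value == pytest.approx(30.93, abs=TOL)
        assert orig.dG_sol_1.value == pytest.approx(24.66, abs=TOL)
        assert corr.dG_sol_anion.value == pytest.approx(-88.36, abs=TOL)
        assert orig.dG_sol_anion.value == pytest.approx(-94.63, abs=TOL)
        # basicity-derived quantities do not depend on the convention
        assert corr.dG_sol_cation.value == pytest.approx(orig.dG_sol_cation.value)

    def test_degenerate_solvent_all_zero(self):
        from pkasolv.thermochem import SolventSpec

        z = Quantity(0.0, units="kcal/mol")
        spec = SolventSpec(
            name="degenerate",
            conc_SH=1.0,
            pK_ap=Quantity(0.0),
            delta=Quantity(0.0),
            dG_gas_acid=z,
            dG_gas_base=z,
            dG_sol_SH=z,
            dG_sol_H=z,
        )
        r = cycles.build_report(spec)
        for qty in (r.dG_sol_1, r.dG_sol_2, r.dG_sol_3, r.pKa_1, r.pKa_2,
                    r.dG_sol_anion, r.dG_sol_cation):
            assert qty.value == pytest.approx(0.0, abs=1e-12)

    def test_unknown_convention_rejected(self, water):
        with pytest.raises(ValueError):
            cycles.build_report(water, "starred")
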