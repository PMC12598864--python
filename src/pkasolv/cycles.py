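"""Thermodynamic-cycle algebra for solvent autoprotolysis.

Three cycles connect measurable legs (gas-phase acidity/basicity, solvation
free energies of the neutral solvent SH and of the proton) to the solution
quantities that cannot be measured directly: the solvation free energies of
the solvent's own anion S- and cation SH2+, and the solvent's pKa in itself.

The algebra, for a solvent SH of molarity [SH] with autoprotolysis constant
K_ap = [SH2+][S-]:

    dG_sol(1) = -RT ln(K_ap / [SH])          (solution acidity, SH -> S- + H+)
    pKa(1)    =  dG_sol(1) / (RT ln 10)
    dG_sol(2) = -RT ln(K_ap / [SH]^2)        (heterolytic, 2 SH -> S- + SH2+)
    pKa(2)    =  dG_sol(2)/(RT ln10) - log10[SH]
    dG_sol(3) =  dG_sol(1) - dG_sol(2) = -RT ln[SH]   (solution basicity)

    dG_sol*(S-)   = -dG_gas(1) + dG_sol*(SH) - dG_sol*(H+) + dG_sol(1)
    dG_sol*(SH2+) =  dG_gas(3) + dG_sol*(SH) + dG_sol*(H+) - dG_sol(3)

For a nonaqueous solvent whose pH meter is calibrated on aqueous buffers,
the intrinsic scale is shifted by delta (pH* = pH_app + delta) and the
autoprotolysis constant used on the intrinsic scale is the corrected
K_ap* = 10^(-2 delta) K_ap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping

from .thermochem import (
    GasSpecies,
    Quantity,
    SolventSpec,
    ThermoConstants,
    propagate_quadrature,
    quantity_scale,
)

__all__ = [
    "Convention",
    "CycleReport",
    "PHLandmarks",
    "correct_autoprotolysis",
    "solution_acidity",
    "solution_basicity",
    "heterolytic_dG",
    "pKa_from_dG1",
    "pKa_from_dG2",
    "anion_solvation",
    "cation_solvation",
    "ph_landmarks",
    "scale_shift",
    "gas_heterolytic",
    "gas_proton_energy",
    "build_report",
]

Convention = Literal["original", "corrected"]


def correct_autoprotolysis(pK_ap: Quantity, delta: float) -> Quantity:
    """pK_ap* = pK_ap + 2*delta: autoprotolysis on the intrinsic pH* scale.

    ``delta`` is the solvent-specific offset between the intrinsic and the
    aqueous-calibrated (apparent) pH scales; it is 0 for water.
    """
    if delta < 0:
        raise ValueError(f"delta must be nonnegative, got {delta}")
    return Quantity(pK_ap.value + 2.0 * delta, pK_ap.sigma, pK_ap.units)


def solution_acidity(
    pK_ap: Quantity, conc_SH: float, const: ThermoConstants
) -> Quantity:
    """Solution acidity dG_sol(1) = -RT ln(K_ap/[SH]) in kcal/mol."""
    if conc_SH <= 0:
        raise ValueError(f"conc_SH must be positive, got {conc_SH}")
    value = const.ln10_RT * pK_ap.value + const.RT * math.log(conc_SH)
    sigma = None if pK_ap.sigma is None else const.ln10_RT * pK_ap.sigma
    return Quantity(value, sigma, "kcal/mol")


def solution_basicity(conc_SH: float, const: ThermoConstants) -> Quantity:
    """Solution basicity dG_sol(3) = -RT ln[SH] in kcal/mol."""
    if conc_SH <= 0:
        raise ValueError(f"conc_SH must be positive, got {conc_SH}")
    return Quantity(-const.RT * math.log(conc_SH), None, "kcal/mol")


def heterolytic_dG(
    pK_ap: Quantity, conc_SH: float, const: ThermoConstants
) -> Quantity:
    """Heterolytic free energy dG_sol(2) = -RT ln(K_ap/[SH]^2) in kcal/mol.

    Satisfies dG_sol(2) = dG_sol(1) - dG_sol(3) exactly.
    """
    if conc_SH <= 0:
        raise ValueError(f"conc_SH must be positive, got {conc_SH}")
    value = const.ln10_RT * pK_ap.value + 2.0 * const.RT * math.log(conc_SH)
    sigma = None if pK_ap.sigma is None else const.ln10_RT * pK_ap.sigma
    return Quantity(value, sigma, "kcal/mol")


def pKa_from_dG1(dG_sol_1: Quantity, const: ThermoConstants) -> Quantity:
    """pKa(1) = dG_sol(1) / (RT ln 10)."""
    return quantity_scale(dG_sol_1, 1.0 / const.ln10_RT).scaled(1.0, units="pKa")


def pKa_from_dG2(
    dG_sol_2: Quantity, conc_SH: float, const: ThermoConstants
) -> Quantity:
    """pKa(2) = dG_sol(2)/(RT ln 10) - log10[SH].

    Analytically equal to pKa(1) for the same solvent and convention; both
    reduce to pK_ap + log10[SH].
    """
    if conc_SH <= 0:
        raise ValueError(f"conc_SH must be positive, got {conc_SH}")
    scaled = quantity_scale(dG_sol_2, 1.0 / const.ln10_RT)
    return Quantity(scaled.value - math.log10(conc_SH), scaled.sigma, "pKa")


def anion_solvation(spec: SolventSpec, dG_sol_1: Quantity) -> Quantity:
    """Solvation free energy of the solvent anion S- (cycle 1).

    dG_sol*(S-) = -dG_gas(1) + dG_sol*(SH) - dG_sol*(H+) + dG_sol(1),
    with sigma from quadrature over the experimental terms (the solution
    acidity carries no stated uncertainty).
    """
    acidity = Quantity(dG_sol_1.value, None, "kcal/mol")
    return propagate_quadrature(
        [spec.dG_gas_acid, spec.dG_sol_SH, spec.dG_sol_H, acidity],
        [-1, 1, -1, 1],
    )


def cation_solvation(spec: SolventSpec, dG_sol_3: Quantity) -> Quantity:
    """Solvation free energy of the solvent cation SH2+ (cycle 3).

    dG_sol*(SH2+) = dG_gas(3) + dG_sol*(SH) + dG_sol*(H+) - dG_sol(3).
    """
    basicity = Quantity(dG_sol_3.value, None, "kcal/mol")
    return propagate_quadrature(
        [spec.dG_gas_base, spec.dG_sol_SH, spec.dG_sol_H, basicity],
        [1, 1, 1, -1],
    )


def scale_shift(delta: float, const: ThermoConstants) -> float:
    """Free-energy offset 2*delta*RT*ln10 between the apparent and intrinsic
    acidity scales, in kcal/mol (6.27 for delta = 2.30 at RT = 0.5926)."""
    if delta < 0:
        raise ValueError(f"delta must be nonnegative, got {delta}")
    return 2.0 * delta * const.ln10_RT


@dataclass(frozen=True)
class PHLandmarks:
    """pH-scale landmarks of a neat solvent.

    ``ph_neutral_app``: apparent pH of the neutral solution (pK_ap/2).
    ``ph_neutral_star``: same point on the intrinsic scale (+delta).
    ``pKa_bulk``: bulk-solvent pKa = pK_ap + log10[SH], original constant.
    ``pKa_bulk_star``: same with the corrected constant pK_ap*.
    """

    ph_neutral_app: float
    ph_neutral_star: float
    pKa_bulk: float
    pKa_bulk_star: float


def ph_landmarks(spec: SolventSpec) -> PHLandmarks:
    """Neutral-solution pH and bulk pKa on both scale conventions."""
    pk = spec.pK_ap.value
    delta = spec.delta.value
    pk_star = pk + 2.0 * delta
    log_c = math.log10(spec.conc_SH)
    return PHLandmarks(
        ph_neutral_app=pk / 2.0,
        ph_neutral_star=pk / 2.0 + delta,
        pKa_bulk=pk + log_c,
        pKa_bulk_star=pk_star + log_c,
    )


def gas_heterolytic(species: Mapping[str, GasSpecies]) -> Quantity:
    """Gas-phase heterolytic free energy 2 SH -> SH2+ + S-.

    dG_gas(2) = G(SH2+) + G(S-) - 2 G(SH) from absolute gas-phase free
    energies.
    """
    for label in ("SH", "SH2+", "S-"):
        if label not in species:
            raise ValueError(f"missing gas species {label!r}")
    return propagate_quadrature(
        [
            species["SH2+"].G_gas,
            species["S-"].G_gas,
            quantity_scale(species["SH"].G_gas, 2.0),
        ],
        [1, 1, -1],
    )


def gas_proton_energy(
    dG_gas_acid: Quantity, G_SH: Quantity, G_anion: Quantity
) -> Quantity:
    """Gas-phase proton free energy G(H+) = dG_gas(1) + G(SH) - G(S-)."""
    return propagate_quadrature([dG_gas_acid, G_SH, G_anion], [1, 1, -1])


@dataclass(frozen=True)
class CycleReport:
    """All cycle outputs for one solvent under one K_ap convention."""

    solvent: SolventSpec
    convention: Convention
    pK_ap_used: Quantity
    dG_sol_1: Quantity
    dG_sol_2: Quantity
    dG_sol_3: Quantity
    pKa_1: Quantity
    pKa_2: Quantity
    dG_sol_anion: Quantity
    dG_sol_cation: Quantity
    landmarks: PHLandmarks

    def __post_init__(self) -> None:
        if abs(self.dG_sol_3.value - (self.dG_sol_1.value - self.dG_sol_2.value)) > 1e-9:
            raise ValueError("dG_sol(3) != dG_sol(1) - dG_sol(2)")


def build_report(
    spec: SolventSpec,
    convention: Convention = "corrected",
    const: ThermoConstants | None = None,
) -> CycleReport:
    """Run the full cycle algebra for one solvent under one convention.

    ``corrected`` applies pK_ap* = pK_ap + 2*delta before the cycles
    (identical to ``original`` when delta = 0, i.e. for water).
    """
    if const is None:
        const = ThermoConstants(T=spec.T)
    if convention not in ("original", "corrected"):
        raise ValueError(f"unknown convention {convention!r}")
    if convention == "corrected":
        pk = correct_autoprotolysis(spec.pK_ap, spec.delta.value)
    else:
        pk = spec.pK_ap
    dg1 = solution_acidity(pk, spec.conc_SH, const)
    dg2 = heterolytic_dG(pk, spec.conc_SH, const)
    dg3 = solution_basicity(spec.conc_SH, const)
    return CycleReport(
        solvent=spec,
        convention=convention,
        pK_ap_used=pk,
        dG_sol_1=dg1,
        dG_sol_2=dg2,
        dG_sol_3=dg3,
        pKa_1=pKa_from_dG1(dg1, const),
        pKa_2=pKa_from_dG2(dg2, spec.conc_SH, const),
        dG_sol_anion=anion_solvation(spec, dg1),
        dG_sol_cation=cation_solvation(spec, dg3),
        landmarks=ph_landmarks(spec),
    )
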