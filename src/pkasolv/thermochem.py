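"""Core thermochemical data model and uncertainty propagation.

Every derived number in the cycle algebra is a :class:`Quantity`: a value
with an optional 1-sigma uncertainty in declared units.  Uncertainties are
propagated in independent quadrature (no covariances), which is how the
experimental error bars on ion solvation free energies are assembled from
the tabulated gas-phase and solvation inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "Quantity",
    "ThermoConstants",
    "SolventSpec",
    "GasSpecies",
    "UnitError",
    "propagate_quadrature",
    "quantity_scale",
    "DEFAULT_RT",
    "STD_STATE_FACTOR",
]

#: Thermal energy RT at 298.15 K in kcal/mol.
DEFAULT_RT = 0.5926

#: Molar volume ratio converting an ideal gas at 1 atm to 1 mol/L at 298.15 K.
STD_STATE_FACTOR = 24.46


class UnitError(ValueError):
    """Arithmetic attempted across mismatched units."""


@dataclass(frozen=True)
class Quantity:
    """A physical value with optional 1-sigma uncertainty.

    Parameters
    ----------
    value:
        Central value in ``units``.
    sigma:
        1-sigma uncertainty in the same units; ``None`` means the value is
        treated as exact (it contributes zero to any quadrature).
    units:
        Unit tag, e.g. ``"kcal/mol"``, ``"pKa"``, ``"mol/L"`` or ``""`` for
        dimensionless.  Immutable; mixing tags in arithmetic raises
        :class:`UnitError`.
    """

    value: float
    sigma: float | None = None
    units: str = ""

    def __post_init__(self) -> None:
        if self.sigma is not None and self.sigma < 0:
            raise ValueError(f"sigma must be nonnegative, got {self.sigma}")

    # -- helpers -----------------------------------------------------------

    @property
    def sigma_or_zero(self) -> float:
        return 0.0 if self.sigma is None else self.sigma

    def _check_units(self, other: "Quantity", op: str) -> None:
        if self.units != other.units:
            raise UnitError(
                f"cannot {op} quantities with units "
                f"{self.units!r} and {other.units!r}"
            )

    # -- arithmetic (independent quadrature) -------------------------------

    def __add__(self, other: "Quantity") -> "Quantity":
        self._check_units(other, "add")
        return propagate_quadrature([self, other], [1, 1])

    def __sub__(self, other: "Quantity") -> "Quantity":
        self._check_units(other, "subtract")
        return propagate_quadrature([self, other], [1, -1])

    def __neg__(self) -> "Quantity":
        return quantity_scale(self, -1.0)

    def scaled(self, k: float, units: str | None = None) -> "Quantity":
        q = quantity_scale(self, k)
        if units is not None:
            q = Quantity(q.value, q.sigma, units)
        return q

    def __format__(self, spec: str) -> str:
        if not spec:
            spec = ".2f"
        if self.sigma is None:
            return format(self.value, spec)
        return f"{self.value:{spec}} +- {self.sigma:{spec}}"


def propagate_quadrature(
    terms: Sequence[Quantity], signs: Sequence[int]
) -> Quantity:
    """Signed sum of quantities with 1-sigma combined in quadrature.

    ``value = sum(s_i * v_i)``, ``sigma = sqrt(sum(sigma_i**2))``.  Terms
    whose sigma is absent contribute zero uncertainty.  All terms must share
    a unit tag; the result carries it.
    """
    if len(terms) != len(signs):
        raise ValueError("terms and signs must have the same length")
    if not terms:
        raise ValueError("at least one term required")
    units = terms[0].units
    for t in terms[1:]:
        if t.units != units:
            raise UnitError(
                f"unit mismatch in quadrature: {units!r} vs {t.units!r}"
            )
    value = sum(s * t.value for s, t in zip(signs, terms))
    var = sum(t.sigma_or_zero**2 for t in terms)
    sigma = math.sqrt(var) if any(t.sigma is not None for t in terms) else None
    return Quantity(value, sigma, units)


def quantity_scale(q: Quantity, k: float) -> Quantity:
    """Scale a quantity by ``k``; sigma scales by ``|k|``."""
    if not math.isfinite(k):
        raise ValueError(f"scale factor must be finite, got {k}")
    sigma = None if q.sigma is None else abs(k) * q.sigma
    return Quantity(k * q.value, sigma, q.units)


@dataclass(frozen=True)
class ThermoConstants:
    """Temperature-dependent constants of the cycle algebra.

    ``RT`` defaults to 0.5926 kcal/mol at 298.15 K.  ``ln10_RT`` is
    RT*ln(10), the conversion between a free energy in kcal/mol and a pK
    unit.  ``std_state_factor`` (24.46) converts an ideal gas at 1 atm to
    the 1 mol/L standard state.
    """

    T: float = 298.15
    RT: float = DEFAULT_RT
    std_state_factor: float = STD_STATE_FACTOR

    def __post_init__(self) -> None:
        if self.RT <= 0:
            raise ValueError("RT must be positive")

    @property
    def ln10_RT(self) -> float:
        return self.RT * math.log(10.0)

    @property
    def std_state_term(self) -> float:
        """RT*ln(24.46), the gas 1 atm -> 1 mol/L correction in kcal/mol."""
        return self.RT * math.log(self.std_state_factor)


@dataclass(frozen=True)
class SolventSpec:
    """One solvent's complete thermochemical record.

    Fields mirror the experimental inputs the cycles consume: solvent
    molarity, autoprotolysis pK, the pH-scale offset delta between the
    solvent-intrinsic scale (pH*) and the aqueous-calibrated meter reading
    (pH_app), gas-phase acidity/basicity and the neutral-solvent and proton
    solvation free energies.
    """

    name: str
    conc_SH: float  # mol/L
    pK_ap: Quantity  # dimensionless
    delta: Quantity  # dimensionless, 0 for water
    dG_gas_acid: Quantity  # kcal/mol, SH -> S- + H+
    dG_gas_base: Quantity  # kcal/mol, SH2+ -> SH + H+
    dG_sol_SH: Quantity  # kcal/mol
    dG_sol_H: Quantity  # kcal/mol
    T: float = 298.15

    def __post_init__(self) -> None:
        if self.conc_SH <= 0:
            raise ValueError(f"conc_SH must be positive, got {self.conc_SH}")
        if self.delta.value < 0:
            raise ValueError(f"delta must be nonnegative, got {self.delta.value}")
        for fname in ("dG_gas_acid", "dG_gas_base", "dG_sol_SH", "dG_sol_H"):
            q: Quantity = getattr(self, fname)
            if q.units != "kcal/mol":
                raise UnitError(f"{fname} must be in kcal/mol, got {q.units!r}")


@dataclass(frozen=True)
class GasSpecies:
    """Gas-phase free energy of one species in a solvent's record.

    ``label`` is one of ``SH`` (neutral solvent), ``SH2+`` (protonated),
    ``S-`` (deprotonated) or ``H+``.
    """

    label: str
    G_gas: Quantity

    _ALLOWED = ("SH", "SH2+", "S-", "H+")

    def __post_init__(self) -> None:
        if self.label not in self._ALLOWED:
            raise ValueError(
                f"label must be one of {self._ALLOWED}, got {self.label!r}"
            )


def gas_table(species: Iterable[GasSpecies]) -> dict[str, GasSpecies]:
    """Index species by label, rejecting duplicates."""
    out: dict[str, GasSpecies] = {}
    for sp in species:
        if sp.label in out:
            raise ValueError(f"duplicate gas species label {sp.label!r}")
        out[sp.label] = sp
    return out
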