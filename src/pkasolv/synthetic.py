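"""Seeded generators for every input class the pipeline consumes.

Real inputs to the analysis are (a) experimental solvent thermochemistry
tables, (b) rigid-molecule force-field topologies, and (c) per-configuration
cluster energies from quantum-chemistry runs.  This module replaces them
with deterministic stand-ins: the canonical water/methanol records shipped
with the package, toy Lennard-Jones fluids with known analytic limits,
Gaussian energy streams with stated mean and spread, and an analytically
solvable harmonic free-energy case used as an estimator oracle.

All generators are pure functions of their parameters and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .convergence import EnergyStream
from .fepmc import (
    RigidMolecule,
    SimulationBox,
    SiteParams,
    System,
    fep_window,
)
from .thermochem import GasSpecies, Quantity, SolventSpec, ThermoConstants

__all__ = [
    "CANONICAL_SOLVENTS",
    "CANONICAL_GAS_PHASE",
    "CLUSTER_CALIBRATION",
    "DELTA_PRESETS",
    "make_solvent_table",
    "make_gas_table",
    "make_energy_stream",
    "make_toy_fluid",
    "ToyFluid",
    "make_harmonic_system",
    "HarmonicFEPCase",
    "spc_water",
    "opls_methanol",
]


def _kcal(value: float, sigma: float | None = None) -> Quantity:
    return Quantity(value, sigma, "kcal/mol")


#: Literature offsets between the intrinsic and apparent pH scales of
#: methanol; the default working value is their average.
DELTA_PRESETS = {"methanol_a": 2.34, "methanol_b": 2.25, "methanol": 2.30}

#: Canonical experimental records for the two solvents of interest.
CANONICAL_SOLVENTS: dict[str, SolventSpec] = {
    "water": SolventSpec(
        name="water",
        conc_SH=55.5,
        pK_ap=Quantity(14.0),
        delta=Quantity(0.0),
        dG_gas_acid=_kcal(385.64, 0.10),
        dG_gas_base=_kcal(159.64, 1.90),
        dG_sol_SH=_kcal(-6.32, 0.20),
        dG_sol_H=_kcal(-265.90, 0.10),
    ),
    "methanol": SolventSpec(
        name="methanol",
        conc_SH=24.5,
        pK_ap=Quantity(16.7),
        delta=Quantity(DELTA_PRESETS["methanol"]),
        dG_gas_acid=_kcal(377.93, 0.62),
        dG_gas_base=_kcal(175.06, 1.90),
        dG_sol_SH=_kcal(-4.86, 0.20),
        dG_sol_H=_kcal(-263.50, 2.00),
    ),
}

#: Absolute gas-phase free energies (kcal/mol) of SH, SH2+ and S-.
CANONICAL_GAS_PHASE: dict[str, dict[str, Quantity]] = {
    "water": {
        "SH": _kcal(-47857.37),
        "SH2+": _kcal(-48022.66),
        "S-": _kcal(-47465.69),
    },
    "methanol": {
        "SH": _kcal(-72444.89),
        "SH2+": _kcal(-72626.01),
        "S-": _kcal(-72061.05),
    },
}

#: Reported cluster-continuum averages (mean, SE of mean at n = 200) used to
#: shape synthetic energy streams; never recomputed by this package.
CLUSTER_CALIBRATION: dict[str, tuple[float, float]] = {
    "water_cation": (-110.50, 0.20),
    "water_anion": (-102.46, 1.72),
    "methanol_cation": (-91.36, 0.45),
    "methanol_anion": (-89.95, 0.50),
}

_PERTURB_FIELDS = ("dG_gas_acid", "dG_gas_base", "dG_sol_SH", "dG_sol_H")


def make_solvent_table(
    perturb_sd: float = 0.0, seed: int = 0
) -> dict[str, SolventSpec]:
    """Canonical water/methanol records, optionally Gaussian-perturbed.

    ``perturb_sd`` adds independent N(0, sd) noise to the central values of
    the four free-energy fields (sigmas and the exactly known [SH], pK_ap,
    delta stay fixed), producing reproducible variants for round-trip and
    robustness tests.
    """
    if perturb_sd < 0:
        raise ValueError("perturb_sd must be nonnegative")
    if perturb_sd == 0:
        return dict(CANONICAL_SOLVENTS)
    rng = np.random.default_rng(seed)
    out: dict[str, SolventSpec] = {}
    for name, spec in CANONICAL_SOLVENTS.items():
        kwargs = {}
        for fname in _PERTURB_FIELDS:
            q: Quantity = getattr(spec, fname)
            kwargs[fname] = Quantity(
                q.value + rng.normal(0.0, perturb_sd), q.sigma, q.units
            )
        out[name] = SolventSpec(
            name=spec.name,
            conc_SH=spec.conc_SH,
            pK_ap=spec.pK_ap,
            delta=spec.delta,
            T=spec.T,
            **kwargs,
        )
    return out


def make_gas_table(solvent: str) -> dict[str, GasSpecies]:
    """Canonical absolute gas-phase free energies for one solvent."""
    try:
        raw = CANONICAL_GAS_PHASE[solvent]
    except KeyError:
        raise ValueError(f"unknown solvent {solvent!r}") from None
    return {label: GasSpecies(label, q) for label, q in raw.items()}


def make_energy_stream(
    n: int, mu: float, sd: float, seed: int = 0, label: str = ""
) -> EnergyStream:
    """i.i.d. normal per-configuration energies with recorded truth.

    To emulate a reported cluster average of mu +- SE over n
    configurations, pass ``sd = SE * sqrt(n)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    rng = np.random.default_rng(seed)
    values = mu + sd * rng.standard_normal(n)
    return EnergyStream(values=values, label=label, truth=mu)


# ---------------------------------------------------------------------------
# Force-field fixtures
# ---------------------------------------------------------------------------


def spc_water() -> RigidMolecule:
    """Three-site SPC water: rigid, OH = 1.0 A, HOH = 109.47 deg."""
    half = math.radians(109.47 / 2.0)
    coords = np.array(
        [
            [0.0, 0.0, 0.0],
            [math.sin(half), 0.0, math.cos(half)],
            [-math.sin(half), 0.0, math.cos(half)],
        ]
    )
    sites = (
        SiteParams(epsilon=0.1554, sigma=3.165, charge=-0.82),
        SiteParams(epsilon=0.0, sigma=0.0, charge=0.41),
        SiteParams(epsilon=0.0, sigma=0.0, charge=0.41),
    )
    return RigidMolecule("SPC water", coords, sites)


def opls_methanol() -> RigidMolecule:
    """United-atom OPLS methanol (CH3, O, H) as a geometry placeholder.

    CO = 1.43 A, OH = 0.945 A, COH = 108.5 deg; methyl group is a single
    united site.
    """
    ang = math.radians(108.5)
    coords = np.array(
        [
            [1.43, 0.0, 0.0],  # CH3
            [0.0, 0.0, 0.0],  # O
            [0.945 * math.cos(ang), 0.945 * math.sin(ang), 0.0],  # H
        ]
    )
    sites = (
        SiteParams(epsilon=0.207, sigma=3.775, charge=0.265),
        SiteParams(epsilon=0.170, sigma=3.070, charge=-0.700),
        SiteParams(epsilon=0.0, sigma=0.0, charge=0.435),
    )
    return RigidMolecule("OPLS methanol", coords, sites)


@dataclass(frozen=True)
class ToyFluid:
    """A generated starting configuration for the Monte Carlo engine."""

    molecule: RigidMolecule
    box: SimulationBox
    positions: np.ndarray

    def system(
        self,
        solute: RigidMolecule | None = None,
        tail_on: bool = True,
    ) -> System:
        """Build a live system; if a solute is given it replaces molecule 0."""
        return System(
            solvent=self.molecule,
            box=self.box,
            positions=self.positions.copy(),
            solute=solute,
            tail_on=tail_on,
        )


def make_toy_fluid(
    n: int,
    density: float,
    epsilon: float = 0.2,
    sigma: float = 3.0,
    charge_pattern: str | tuple[float, ...] = "neutral",
    seed: int = 0,
    min_dist_factor: float = 0.85,
    max_tries: int = 20000,
) -> ToyFluid:
    """Non-overlapping monatomic fluid at a requested number density.

    ``density`` is in molecules/A^3 (box edge L = (n/density)^(1/3)).
    ``charge_pattern`` selects the molecule template: ``"neutral"``
    (single apolar LJ site), ``"dipolar"`` (LJ site carrying +0.25 e with a
    bare -0.25 e site 1 A away, giving the bath an electrostatic
    response), or a single float for a uniformly charged LJ site.  Initial
    positions come from minimum-distance rejection sampling at
    ``min_dist_factor * sigma``.
    """
    if n < 2:
        raise ValueError("need at least 2 molecules")
    if density <= 0:
        raise ValueError("density must be positive")
    L = (n / density) ** (1.0 / 3.0)
    min_dist = min_dist_factor * sigma
    rng = np.random.default_rng(seed)
    positions = np.empty((n, 3))
    placed = 0
    tries = 0
    while placed < n:
        if tries >= max_tries:
            raise ValueError(
                f"density {density} infeasible: could not place molecule "
                f"{placed + 1}/{n} after {max_tries} tries"
            )
        tries += 1
        cand = rng.uniform(0.0, L, 3)
        if placed:
            dr = positions[:placed] - cand
            dr -= L * np.round(dr / L)
            if (np.sum(dr**2, axis=1) < min_dist**2).any():
                continue
        positions[placed] = cand
        placed += 1

    if charge_pattern == "neutral":
        mol = RigidMolecule(
            "toy LJ",
            np.zeros((1, 3)),
            (SiteParams(epsilon=epsilon, sigma=sigma, charge=0.0),),
        )
    elif charge_pattern == "dipolar":
        mol = RigidMolecule(
            "toy dipolar LJ",
            np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]),
            (
                SiteParams(epsilon=epsilon, sigma=sigma, charge=0.25),
                SiteParams(epsilon=0.0, sigma=0.0, charge=-0.25),
            ),
        )
    else:
        mol = RigidMolecule(
            "toy charged LJ",
            np.zeros((1, 3)),
            (SiteParams(epsilon=epsilon, sigma=sigma, charge=float(charge_pattern)),),
        )
    box = SimulationBox(n_molecules=n, length=L)
    return ToyFluid(molecule=mol, box=box, positions=positions)


# ---------------------------------------------------------------------------
# Harmonic FEP oracle
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HarmonicFEPCase:
    """Analytic 1-D harmonic free-energy case.

    Changing the spring constant k -> k' of a 1-D harmonic oscillator has
    the closed-form free-energy difference dG = (RT/2) ln(k'/k), which a
    stepped-lambda exponential-averaging estimate must recover.  Sampling
    at spring constant k is exact: x ~ N(0, sqrt(RT/k)).
    """

    k_initial: float
    k_final: float
    n_windows: int
    const: ThermoConstants
    truth: float

    @property
    def ladder(self) -> np.ndarray:
        """Geometric spring-constant ladder, n_windows + 1 points."""
        return np.geomspace(self.k_initial, self.k_final, self.n_windows + 1)

    def sample(self, k: float, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.normal(0.0, math.sqrt(self.const.RT / k), n)

    @staticmethod
    def delta_u(x: np.ndarray, k_from: float, k_to: float) -> np.ndarray:
        return 0.5 * (k_to - k_from) * x**2

    def estimate(self, n_samples: int = 2000, seed: int = 0) -> tuple[float, float]:
        """Stepped-lambda FEP over the ladder: total dG and quadrature SE."""
        rng = np.random.default_rng(seed)
        total = 0.0
        var = 0.0
        ks = self.ladder
        for k_from, k_to in zip(ks, ks[1:]):
            x = self.sample(k_from, n_samples, rng)
            dG, se = fep_window(self.delta_u(x, k_from, k_to), self.const)
            total += dG
            var += se**2
        return total, math.sqrt(var)


def make_harmonic_system(
    k_initial: float,
    k_final: float,
    n_windows: int = 4,
    const: ThermoConstants | None = None,
) -> HarmonicFEPCase:
    """Build the harmonic oracle with its recorded closed-form truth."""
    if k_initial <= 0 or k_final <= 0:
        raise ValueError("spring constants must be positive")
    if n_windows < 1:
        raise ValueError("need at least one window")
    if const is None:
        const = ThermoConstants()
    truth = 0.5 * const.RT * math.log(k_final / k_initial)
    return HarmonicFEPCase(k_initial, k_final, n_windows, const, truth)
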