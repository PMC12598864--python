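"""Desk-scale rigid-molecule Metropolis Monte Carlo with FEP annihilation.

The engine samples rigid molecules interacting through a site-site
Lennard-Jones plus Coulomb potential with geometric-mean combination rules,

    u_ij(r) = 4 eps_ij [ (sig_ij/r)^12 - (sig_ij/r)^6 ] + C q_i q_j / r,
    eps_ij = sqrt(eps_i eps_j),  sig_ij = sqrt(sig_i sig_j),

in the isothermal-isobaric (NPT) ensemble with periodic boundary conditions,
minimum-image convention, a molecule-centre cutoff r_c = L/2 and the
standard isotropic LJ tail correction beyond the cutoff.  Electrostatics
use a plain cutoff (no Ewald); net-charged solutes therefore carry a
finite-size caveat at small N.

Solvation free energies are computed as the negative of the annihilation
free energy of the solute, staged as: (1) scale the solute charges to zero
(double-wide sampling), (2) scale the attractive r^-6 LJ term to zero
(double-wide), (3) scale the repulsive r^-12 term to zero (single
direction).  Each window uses the exponential-averaging (Zwanzig) estimator
dG = -RT ln <exp(-dU/RT)>.  The assembled standard-state solvation free
energy is

    dG_sol*(X) = -dG_ele(X) - dG_nonele(X) - RT ln(24.46) [+ polarization],

where the last constant converts the ideal gas at 1 atm to 1 mol/L.

Defaults throughout are desk-scale (tens of molecules, 1e3-1e5 sweeps);
production-scale protocols are expressible through the same interfaces.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .thermochem import Quantity, ThermoConstants

__all__ = [
    "COULOMB_CONST",
    "BOLTZMANN_KCAL",
    "PV_ATM_A3",
    "SiteParams",
    "RigidMolecule",
    "SimulationBox",
    "LambdaState",
    "LambdaSchedule",
    "default_lambda_schedules",
    "production_lambda_schedules",
    "WindowResult",
    "FEPResult",
    "System",
    "pair_energy",
    "tail_correction",
    "mc_sweep",
    "fep_window",
    "run_annihilation",
    "assemble_dG_sol",
]

#: Coulomb prefactor in kcal*A/(mol*e^2).
COULOMB_CONST = 332.06
#: Boltzmann constant in kcal/(mol*K).
BOLTZMANN_KCAL = 0.0019872041
#: 1 atm * 1 A^3 in kcal/mol.
PV_ATM_A3 = 1.458397e-5

Stage = Literal["charge", "lj_attractive", "lj_repulsive"]
STAGES: tuple[Stage, ...] = ("charge", "lj_attractive", "lj_repulsive")


@dataclass(frozen=True)
class SiteParams:
    """Lennard-Jones and Coulomb parameters of one interacting site."""

    epsilon: float  # kcal/mol
    sigma: float  # Angstrom
    charge: float  # e

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be nonnegative")
        if self.epsilon > 0 and self.sigma <= 0:
            raise ValueError("sigma must be positive when epsilon > 0")


@dataclass(frozen=True)
class RigidMolecule:
    """Fixed-geometry molecule: site coordinates (A) plus per-site params.

    Geometry is immutable during simulation; only rigid-body translation
    and rotation move the molecule.
    """

    name: str
    coords: np.ndarray  # (n_sites, 3), internal frame
    sites: tuple[SiteParams, ...]

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_sites, 3)")
        if coords.shape[0] != len(self.sites):
            raise ValueError("one SiteParams per coordinate row required")
        coords = coords - coords.mean(axis=0)  # centre at geometric centre
        coords.setflags(write=False)
        object.__setattr__(self, "coords", coords)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def net_charge(self) -> float:
        return float(sum(s.charge for s in self.sites))

    def param_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        eps = np.array([s.epsilon for s in self.sites])
        sig = np.array([s.sigma for s in self.sites])
        q = np.array([s.charge for s in self.sites])
        return eps, sig, q


@dataclass
class SimulationBox:
    """Cubic NPT box. Cutoff is tied to the edge: r_c = L/2."""

    n_molecules: int
    length: float  # A
    pressure: float = 1.0  # atm
    temperature: float = 298.15  # K

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("box length must be positive")
        if self.n_molecules < 1:
            raise ValueError("need at least one molecule")

    @property
    def cutoff(self) -> float:
        return self.length / 2.0

    @property
    def volume(self) -> float:
        return self.length**3

    @property
    def kT(self) -> float:
        return BOLTZMANN_KCAL * self.temperature


@dataclass(frozen=True)
class LambdaState:
    """Per-stage coupling of the solute to the bath, each in [0, 1]."""

    charge: float = 1.0
    lj_attractive: float = 1.0
    lj_repulsive: float = 1.0

    def with_stage(self, stage: Stage, lam: float) -> "LambdaState":
        return replace(self, **{stage: lam})

    def get(self, stage: Stage) -> float:
        return getattr(self, stage)


@dataclass(frozen=True)
class LambdaSchedule:
    """Ordered annihilation schedule for one stage.

    ``values`` decrease strictly from 1 to 0.  ``sim_points`` is the subset
    of values at which simulations are run; with ``double_wide`` each
    simulation point estimates both its backward (previous -> point) and
    forward (point -> next) window, otherwise only the forward window.
    The windows implied by the simulation points must tile the whole list.
    """

    stage: Stage
    values: tuple[float, ...]
    sim_points: tuple[float, ...]
    double_wide: bool

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if len(vals) < 2 or vals[0] != 1.0 or vals[-1] != 0.0:
            raise ValueError("schedule must run from 1.0 down to 0.0")
        if any(b >= a for a, b in zip(vals, vals[1:])):
            raise ValueError("lambda values must be strictly decreasing")
        object.__setattr__(self, "values", vals)
        sims = tuple(float(v) for v in self.sim_points)
        if not set(sims) <= set(vals):
            raise ValueError("sim_points must be a subset of values")
        object.__setattr__(self, "sim_points", sims)
        covered = set()
        for w_from, w_to, _ in self.windows():
            covered.add((w_from, w_to))
        needed = set(zip(vals, vals[1:]))
        if covered != needed:
            raise ValueError(
                f"simulation points do not tile the {self.stage} schedule: "
                f"missing windows {sorted(needed - covered)}"
            )

    def windows(self) -> list[tuple[float, float, float]]:
        """(lam_from, lam_to, lam_sim) for each window, annihilation order."""
        idx = {v: i for i, v in enumerate(self.values)}
        out: list[tuple[float, float, float]] = []
        for s in self.sim_points:
            i = idx[s]
            if self.double_wide:
                if i == 0 or i == len(self.values) - 1:
                    raise ValueError(
                        "double-wide simulation points need two neighbours"
                    )
                out.append((self.values[i - 1], s, s))
                out.append((s, self.values[i + 1], s))
            else:
                if i == len(self.values) - 1:
                    raise ValueError("cannot simulate forward from lambda=0")
                out.append((s, self.values[i + 1], s))
        return sorted(out, key=lambda w: -w[0])


def default_lambda_schedules() -> tuple[LambdaSchedule, ...]:
    """Desk-scale schedules: 2 double-wide charge simulations, 1 double-wide
    attractive-LJ simulation, 2 single-direction repulsive simulations."""
    return (
        LambdaSchedule("charge", (1.0, 0.75, 0.5, 0.25, 0.0), (0.75, 0.25), True),
        LambdaSchedule("lj_attractive", (1.0, 0.5, 0.0), (0.5,), True),
        LambdaSchedule("lj_repulsive", (1.0, 0.5, 0.0), (1.0, 0.5), False),
    )


def production_lambda_schedules() -> tuple[LambdaSchedule, ...]:
    """Production-scale schedules: a 25-value charge list spanned by 12
    double-wide simulations, a 9-value attractive list spanned by 4, and a
    5-value repulsive list spanned by 4 single-direction simulations."""
    charge_vals = (
        1.000, 0.975, 0.950, 0.925, 0.900, 0.875, 0.850, 0.825, 0.800,
        0.775, 0.750, 0.725, 0.700, 0.675, 0.650, 0.625, 0.600, 0.550,
        0.500, 0.450, 0.400, 0.350, 0.300, 0.200, 0.0,
    )
    charge_sims = charge_vals[1:-1:2]  # alternate interior points: 12 sims
    att_vals = (1.0, 0.875, 0.75, 0.625, 0.5, 0.375, 0.25, 0.125, 0.0)
    att_sims = att_vals[1:-1:2]  # 4 double-wide sims
    rep_vals = (1.0, 0.75, 0.5, 0.25, 0.0)
    return (
        LambdaSchedule("charge", charge_vals, charge_sims, True),
        LambdaSchedule("lj_attractive", att_vals, att_sims, True),
        LambdaSchedule("lj_repulsive", rep_vals, rep_vals[:-1], False),
    )


# ---------------------------------------------------------------------------
# Pairwise energies
# ---------------------------------------------------------------------------


def pair_energy(
    site_i: SiteParams,
    site_j: SiteParams,
    r: float,
    lam: LambdaState = LambdaState(),
) -> float:
    """Site-site LJ + Coulomb energy at separation r (A), in kcal/mol.

    Stage couplings scale the Coulomb, attractive (-r^-6) and repulsive
    (r^-12) terms independently.
    """
    if r <= 0:
        raise ValueError("site overlap: r must be positive")
    eps = math.sqrt(site_i.epsilon * site_j.epsilon)
    sig = math.sqrt(site_i.sigma * site_j.sigma)
    lj = 0.0
    if eps > 0:
        sr6 = (sig / r) ** 6
        lj = 4.0 * eps * (lam.lj_repulsive * sr6 * sr6 - lam.lj_attractive * sr6)
    coul = lam.charge * COULOMB_CONST * site_i.charge * site_j.charge / r
    return lj + coul


def tail_correction(
    box: SimulationBox,
    site_inventory: Sequence[tuple[int, SiteParams]],
) -> float:
    """Isotropic LJ tail correction beyond r_c for a homogeneous fluid.

    ``site_inventory`` lists (count in box, SiteParams) for every site type.
    Returns the total correction in kcal/mol:

        U_tail = (2 pi / V) sum_ab N_a N_b * 4 eps_ab
                 [ sig_ab^12 / (9 r_c^9) - sig_ab^6 / (3 r_c^3) ]

    assuming unit pair correlation beyond the cutoff.  The Coulomb
    beyond-cutoff contribution is excluded.
    """
    rc = box.cutoff
    V = box.volume
    total = 0.0
    for n_a, a in site_inventory:
        for n_b, b in site_inventory:
            eps = math.sqrt(a.epsilon * b.epsilon)
            if eps == 0:
                continue
            sig = math.sqrt(a.sigma * b.sigma)
            total += (
                n_a
                * n_b
                * 4.0
                * eps
                * (sig**12 / (9.0 * rc**9) - sig**6 / (3.0 * rc**3))
            )
    return 2.0 * math.pi * total / V


# ---------------------------------------------------------------------------
# System state
# ---------------------------------------------------------------------------


def _random_rotation_matrix(rng: np.random.Generator, max_angle: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-max_angle, max_angle)
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * (K @ K)


def _pair_tables(
    eps_a: np.ndarray, sig_a: np.ndarray, q_a: np.ndarray,
    eps_b: np.ndarray, sig_b: np.ndarray, q_b: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Precombined (eps_ij, sig_ij^6, q_i q_j) tables, geometric means."""
    eps = np.sqrt(np.outer(eps_a, eps_b))
    sig6 = np.outer(sig_a, sig_b) ** 3  # (sqrt(sig_a sig_b))^6
    qq = np.outer(q_a, q_b)
    return eps, sig6, qq


class System:
    """Configuration of a (possibly solute-containing) rigid-molecule box.

    Molecule 0 is the solute when ``solute`` is given, otherwise all
    molecules are solvent.  The lambda state couples only the solute to the
    bath; solvent-solvent interactions are never scaled.  Absolute site
    coordinates are cached per molecule and kept current through moves.
    """

    def __init__(
        self,
        solvent: RigidMolecule,
        box: SimulationBox,
        positions: np.ndarray,
        orientations: np.ndarray | None = None,
        solute: RigidMolecule | None = None,
        lam: LambdaState = LambdaState(),
        tail_on: bool = True,
    ):
        self.solvent = solvent
        self.solute = solute
        self.box = replace(box)  # own copy: volume moves mutate the length
        self.lam = lam
        self.tail_on = tail_on
        n = box.n_molecules
        positions = np.array(positions, dtype=float)
        if positions.shape != (n, 3):
            raise ValueError(f"positions must have shape ({n}, 3)")
        self.positions = positions  # molecular centres
        # reference volume fixing the default volume-move width; a width
        # tied to the *current* volume would make the proposal asymmetric
        # and bias <V> upward
        self.ref_volume = box.volume
        if orientations is None:
            orientations = np.tile(np.eye(3), (n, 1, 1))
        self.orientations = np.array(orientations, dtype=float)
        self._templates: list[RigidMolecule] = [
            (solute if (solute is not None and i == 0) else solvent)
            for i in range(n)
        ]
        s_eps, s_sig, s_q = solvent.param_arrays()
        self._solv_params = (s_eps, s_sig, s_q)
        self._tab_ss = _pair_tables(s_eps, s_sig, s_q, s_eps, s_sig, s_q)
        if solute is not None:
            u_eps, u_sig, u_q = solute.param_arrays()
            self._solu_params = (u_eps, u_sig, u_q)
            self._tab_us = _pair_tables(u_eps, u_sig, u_q, s_eps, s_sig, s_q)
        else:
            self._solu_params = None
            self._tab_us = None
        self._interacting = bool(
            (s_eps > 0).any() or (s_q != 0).any()
            or (
                solute is not None
                and ((self._solu_params[0] > 0).any() or (self._solu_params[2] != 0).any())
            )
        )
        self._rebuild_site_cache()
        self.energy = self.total_energy()

    # -- geometry ----------------------------------------------------------

    def _rebuild_site_cache(self) -> None:
        """Recompute absolute site positions: solvent stack + solute array."""
        n = self.box.n_molecules
        start = 1 if self.solute is not None else 0
        self._solv_sites = np.stack(
            [
                self.positions[i] + self.solvent.coords @ self.orientations[i].T
                for i in range(start, n)
            ]
        ) if n > start else np.zeros((0, self.solvent.n_sites, 3))
        if self.solute is not None:
            self._solu_sites = (
                self.positions[0] + self.solute.coords @ self.orientations[0].T
            )

    def site_coords(self, i: int) -> np.ndarray:
        if self.solute is not None and i == 0:
            return self._solu_sites
        start = 1 if self.solute is not None else 0
        return self._solv_sites[i - start]

    def _update_site_cache(self, i: int) -> None:
        sites = self.positions[i] + self._templates[i].coords @ self.orientations[i].T
        if self.solute is not None and i == 0:
            self._solu_sites = sites
        else:
            start = 1 if self.solute is not None else 0
            self._solv_sites[i - start] = sites

    def _min_image(self, dr: np.ndarray) -> np.ndarray:
        L = self.box.length
        return dr - L * np.round(dr / L)

    # -- energies ----------------------------------------------------------

    def _energy_vs_set(
        self,
        center_i: np.ndarray,
        sites_i: np.ndarray,
        centers: np.ndarray,
        sites: np.ndarray,
        tables: tuple[np.ndarray, np.ndarray, np.ndarray],
        lam: LambdaState,
    ) -> float:
        """Energy of one molecule against a stack of molecules.

        Minimum-image convention on molecular centres with the centre-centre
        cutoff r_c; returns +inf on site overlap.
        """
        if centers.shape[0] == 0:
            return 0.0
        dc = self._min_image(centers - center_i)
        mask = (dc**2).sum(axis=1) <= self.box.cutoff**2
        if not mask.any():
            return 0.0
        shift = (dc[mask] - (centers[mask] - center_i))[:, None, :]
        Y = sites[mask] + shift  # (k, mj, 3), nearest images
        dr = sites_i[None, :, None, :] - Y[:, None, :, :]
        r2 = (dr**2).sum(axis=3)  # (k, mi, mj)
        if (r2 < 1e-20).any():
            return math.inf
        eps, sig6, qq = tables
        e = 0.0
        if eps.any():
            sr6 = sig6[None, :, :] / r2**3
            lj = 4.0 * eps[None, :, :] * (
                lam.lj_repulsive * sr6**2 - lam.lj_attractive * sr6
            )
            e += float(lj.sum())
        if qq.any():
            e += float(
                lam.charge * COULOMB_CONST * (qq[None, :, :] / np.sqrt(r2)).sum()
            )
        return e

    def molecule_energy(self, i: int) -> float:
        """Interaction of molecule i with all others."""
        if not self._interacting:
            return 0.0
        has_solute = self.solute is not None
        start = 1 if has_solute else 0
        centers_solv = self.positions[start:]
        if has_solute and i == 0:
            return self._energy_vs_set(
                self.positions[0], self._solu_sites,
                centers_solv, self._solv_sites, self._tab_us, self.lam,
            )
        k = i - start
        keep = np.arange(centers_solv.shape[0]) != k
        e = self._energy_vs_set(
            self.positions[i], self._solv_sites[k],
            centers_solv[keep], self._solv_sites[keep],
            self._tab_ss, LambdaState(),
        )
        if has_solute:
            # symmetric: solvent molecule vs solute, solute tables transposed
            eps, sig6, qq = self._tab_us
            e += self._energy_vs_set(
                self.positions[i], self._solv_sites[k],
                self.positions[:1], self._solu_sites[None, :, :],
                (eps.T, sig6.T, qq.T), self.lam,
            )
        return e

    def pair_potential_energy(self) -> float:
        """Sum over molecule pairs inside the cutoff (no tail)."""
        if not self._interacting:
            return 0.0
        n = self.box.n_molecules
        total = sum(self.molecule_energy(i) for i in range(n))
        return total / 2.0

    def _site_inventory(self) -> list[tuple[int, SiteParams]]:
        inv: list[tuple[int, SiteParams]] = []
        n_solv = self.box.n_molecules - (1 if self.solute is not None else 0)
        for s in self.solvent.sites:
            inv.append((n_solv, s))
        if self.solute is not None:
            lam = self.lam
            for s in self.solute.sites:
                # tail sees the lambda-scaled attractive well only if both
                # LJ couplings are on; for partially coupled solutes the
                # solute tail term is scaled by the attractive lambda.
                inv.append(
                    (1, SiteParams(s.epsilon * lam.lj_attractive, s.sigma, s.charge))
                )
        return inv

    def tail_energy(self) -> float:
        if not self.tail_on or not self._interacting:
            return 0.0
        return tail_correction(self.box, self._site_inventory())

    def total_energy(self) -> float:
        """Full potential energy recomputed from scratch (pair + tail)."""
        return self.pair_potential_energy() + self.tail_energy()

    def solute_bath_energy(self, lam: LambdaState) -> float:
        """Solute-solvent interaction energy at an arbitrary lambda state."""
        if self.solute is None:
            raise ValueError("system has no solute")
        return self._energy_vs_set(
            self.positions[0], self._solu_sites,
            self.positions[1:], self._solv_sites, self._tab_us, lam,
        )

    def copy(self) -> "System":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Metropolis sweeps
# ---------------------------------------------------------------------------


@dataclass
class SweepStats:
    attempted: int = 0
    accepted: int = 0
    vol_attempted: int = 0
    vol_accepted: int = 0


def mc_sweep(
    system: System,
    rng: np.random.Generator,
    max_disp: float = 0.15,
    max_rot: float = 0.26,
    volume_moves: bool = True,
    max_dV: float | None = None,
    stats: SweepStats | None = None,
) -> SweepStats:
    """One Metropolis pass: a trial move per molecule plus one volume trial.

    Displacement moves propose a rigid translation (uniform in a cube of
    half-width ``max_disp`` A) combined with a rotation about a random axis
    (angle uniform within ``max_rot`` rad).  Volume trials rescale molecular
    centres and accept with the NPT weight
    exp(-beta(dU + P dV) + N ln(V'/V)).  The volume proposal is uniform in
    V with a fixed half-width (default 5% of the system's reference
    volume), keeping the proposal symmetric.  ``system.energy`` is kept
    current incrementally.
    """
    if stats is None:
        stats = SweepStats()
    n = system.box.n_molecules
    beta = 1.0 / system.box.kT
    for i in rng.permutation(n):
        e_old = system.molecule_energy(i)
        old_pos = system.positions[i].copy()
        old_rot = system.orientations[i].copy()
        system.positions[i] = old_pos + rng.uniform(-max_disp, max_disp, 3)
        if system._templates[i].n_sites > 1 and max_rot > 0:
            system.orientations[i] = (
                _random_rotation_matrix(rng, max_rot) @ old_rot
            )
        system._update_site_cache(i)
        e_new = system.molecule_energy(i)
        de = e_new - e_old
        stats.attempted += 1
        if de <= 0 or (math.isfinite(de) and rng.random() < math.exp(-beta * de)):
            system.energy += de
            stats.accepted += 1
        else:
            system.positions[i] = old_pos
            system.orientations[i] = old_rot
            system._update_site_cache(i)
    if volume_moves:
        stats.vol_attempted += 1
        if max_dV is None:
            max_dV = 0.05 * system.ref_volume
        V = system.box.volume
        V_new = V + rng.uniform(-max_dV, max_dV)
        if V_new > 0:
            old_energy = system.energy
            old_positions = system.positions.copy()
            old_L = system.box.length
            scale = (V_new / V) ** (1.0 / 3.0)
            system.positions = system.positions * scale
            system.box.length = old_L * scale
            system._rebuild_site_cache()
            e_new = system.total_energy()
            dU = e_new - old_energy
            arg = (
                -beta * (dU + system.box.pressure * PV_ATM_A3 * (V_new - V))
                + n * math.log(V_new / V)
            )
            if arg >= 0 or rng.random() < math.exp(arg):
                system.energy = e_new
                stats.vol_accepted += 1
            else:
                system.positions = old_positions
                system.box.length = old_L
                system._rebuild_site_cache()
    return stats


# ---------------------------------------------------------------------------
# Free-energy perturbation
# ---------------------------------------------------------------------------


def fep_window(
    delta_u: Sequence[float],
    const: ThermoConstants,
    n_blocks: int = 5,
) -> tuple[float, float]:
    """Zwanzig estimate dG = -RT ln <exp(-dU/RT)> with block-average SE.

    ``delta_u`` are potential-energy differences U(target) - U(reference)
    evaluated on configurations sampled at the reference state.  The SE is
    the spread of per-block estimates over ``n_blocks`` contiguous blocks.
    """
    du = np.asarray(delta_u, dtype=float)
    if du.size < 2:
        raise ValueError("need at least 2 samples for a FEP window")
    RT = const.RT
    # log-sum-exp for numerical safety
    def _zwanzig(x: np.ndarray) -> float:
        a = -x / RT
        m = a.max()
        return -RT * (m + math.log(np.mean(np.exp(a - m))))

    dG = _zwanzig(du)
    n_blocks = min(n_blocks, du.size)
    blocks = np.array_split(du, n_blocks)
    est = np.array([_zwanzig(b) for b in blocks])
    se = float(est.std(ddof=1) / math.sqrt(n_blocks)) if n_blocks > 1 else 0.0
    return float(dG), se


@dataclass(frozen=True)
class WindowResult:
    stage: Stage
    lam_from: float
    lam_to: float
    dG: float  # kcal/mol, annihilation direction
    se: float
    n_samples: int


@dataclass
class FEPResult:
    """Per-window increments and the assembled staged free energies.

    ``dG_ele`` and ``dG_nonele`` follow the solvation-assembly sign
    convention: the annihilation sum of a stage equals -dG_stage.
    """

    windows: list[WindowResult] = field(default_factory=list)
    polarization: float = 0.0  # kcal/mol, user-supplied correction

    def stage_sum(self, stage: Stage) -> tuple[float, float]:
        ws = [w for w in self.windows if w.stage == stage]
        dG = sum(w.dG for w in ws)
        se = math.sqrt(sum(w.se**2 for w in ws))
        return dG, se

    @property
    def dG_ele(self) -> float:
        return -self.stage_sum("charge")[0]

    @property
    def dG_nonele(self) -> float:
        return -(
            self.stage_sum("lj_attractive")[0] + self.stage_sum("lj_repulsive")[0]
        )

    @property
    def se_ele(self) -> float:
        return self.stage_sum("charge")[1]

    @property
    def se_nonele(self) -> float:
        return math.sqrt(
            self.stage_sum("lj_attractive")[1] ** 2
            + self.stage_sum("lj_repulsive")[1] ** 2
        )


def _run_window_set(
    system: System,
    schedule: LambdaSchedule,
    base_lam: LambdaState,
    const: ThermoConstants,
    rng: np.random.Generator,
    equil_sweeps: int,
    prod_sweeps: int,
    sample_interval: int,
    max_disp: float,
    max_rot: float,
    volume_moves: bool,
) -> list[WindowResult]:
    """Execute all simulations of one stage schedule on a live system."""
    results: list[WindowResult] = []
    stage = schedule.stage
    idx = {v: i for i, v in enumerate(schedule.values)}
    for lam_sim in schedule.sim_points:
        i = idx[lam_sim]
        system.lam = base_lam.with_stage(stage, lam_sim)
        for _ in range(equil_sweeps):
            mc_sweep(system, rng, max_disp, max_rot, volume_moves)
        targets: list[tuple[float, float, int]] = []  # (lam_from, lam_to, dir)
        if schedule.double_wide:
            targets.append((schedule.values[i - 1], lam_sim, -1))
            targets.append((lam_sim, schedule.values[i + 1], +1))
        else:
            targets.append((lam_sim, schedule.values[i + 1], +1))
        samples: dict[tuple[float, float], list[float]] = {
            (a, b): [] for a, b, _ in targets
        }
        e_ref = None
        for sweep in range(prod_sweeps):
            mc_sweep(system, rng, max_disp, max_rot, volume_moves)
            if (sweep + 1) % sample_interval == 0:
                e_ref = system.solute_bath_energy(system.lam)
                for a, b, direction in targets:
                    lam_other = a if direction < 0 else b
                    e_t = system.solute_bath_energy(
                        base_lam.with_stage(stage, lam_other)
                    )
                    samples[(a, b)].append(e_t - e_ref)
        for a, b, direction in targets:
            du = samples[(a, b)]
            dG, se = fep_window(du, const)
            if direction < 0:
                # sampled at b, perturbed to a: dG is G(a)-G(b); the window
                # in annihilation direction (a -> b) is its negative.
                dG = -dG
            results.append(WindowResult(stage, a, b, dG, se, len(du)))
    return results


def run_annihilation(
    system: System,
    schedules: Iterable[LambdaSchedule] = (),
    const: ThermoConstants | None = None,
    replicates: int = 3,
    equil_sweeps: int = 200,
    prod_sweeps: int = 600,
    sample_interval: int = 3,
    seed: int = 0,
    max_disp: float = 0.15,
    max_rot: float = 0.26,
    volume_moves: bool = True,
) -> FEPResult:
    """Two-stage annihilation of the solute of ``system``.

    Stages run in order: charges (double-wide), attractive LJ (double-wide),
    repulsive LJ (single direction), each schedule ending at lambda = 0.
    Each replicate re-runs the whole ladder from the same starting
    configuration with an independent RNG spawned from ``seed``; window
    uncertainties are standard errors over the replicate spread (falling
    back to within-run block SEs for a single replicate).
    """
    if system.solute is None:
        raise ValueError("run_annihilation needs a system with a solute")
    if const is None:
        const = ThermoConstants(T=system.box.temperature)
    schedules = tuple(schedules) or default_lambda_schedules()
    order = {s: k for k, s in enumerate(STAGES)}
    schedules = tuple(sorted(schedules, key=lambda s: order[s.stage]))
    for sched in schedules:
        if sched.values[-1] != 0.0:
            raise ValueError(f"{sched.stage} schedule must terminate at 0")

    seeds = np.random.SeedSequence(seed).spawn(replicates)
    per_rep: list[list[WindowResult]] = []
    for rep in range(replicates):
        rng = np.random.default_rng(seeds[rep])
        sys_rep = system.copy()
        base = LambdaState()
        windows: list[WindowResult] = []
        for sched in schedules:
            windows.extend(
                _run_window_set(
                    sys_rep, sched, base, const, rng,
                    equil_sweeps, prod_sweeps, sample_interval,
                    max_disp, max_rot, volume_moves,
                )
            )
            base = base.with_stage(sched.stage, 0.0)
            sys_rep.lam = base
        per_rep.append(windows)

    # combine replicates window-by-window
    combined: list[WindowResult] = []
    for k, w0 in enumerate(per_rep[0]):
        vals = np.array([per_rep[r][k].dG for r in range(replicates)])
        if replicates > 1:
            se = float(vals.std(ddof=1) / math.sqrt(replicates))
        else:
            se = per_rep[0][k].se
        combined.append(
            WindowResult(
                w0.stage, w0.lam_from, w0.lam_to, float(vals.mean()), se,
                sum(per_rep[r][k].n_samples for r in range(replicates)),
            )
        )
    return FEPResult(windows=combined)


def assemble_dG_sol(result: FEPResult, const: ThermoConstants) -> Quantity:
    """Standard-state solvation free energy from staged annihilation sums:

    dG_sol*(X) = -dG_ele - dG_nonele - RT ln(24.46) + polarization,
    sigma from quadrature of the two stage SEs.
    """
    value = (
        -result.dG_ele
        - result.dG_nonele
        - const.std_state_term
        + result.polarization
    )
    sigma = math.sqrt(result.se_ele**2 + result.se_nonele**2)
    return Quantity(value, sigma, "kcal/mol")
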