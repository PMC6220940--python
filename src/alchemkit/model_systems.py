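"""Coupling-parameter toy Hamiltonians with exact free-energy oracles.

This module defines the model systems on which the free-energy estimators
are exercised: an analytically solvable multivariate-Gaussian (quadratic)
family, and a four-state "growing side chain x restrained water" dimer that
reproduces, at desk scale, the steric-clash physics of perturbing a water
molecule that is distance-restrained to a simultaneously growing particle.

Two independent coupling axes are used: ``lam`` drives the first species
(the "grower", dummy at lam=0, fully interacting at lam=1) and ``kap``
drives the second (the water particle, dummy at kap=0, present at kap=1).
Pair interactions interpolate the interaction parameters themselves
(linearly for charges, linearly on the square roots of the Lennard-Jones
C12/C6 coefficients) and are softened with a Beutler-style soft-core
denominator so that every state strictly inside the unit square has finite
energies at zero inter-particle distance.

Units are kJ mol^-1, nm, e and K throughout. kB = 0.00831446 kJ mol^-1 K^-1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from scipy import integrate

__all__ = [
    "KB",
    "COULOMB_CONSTANT",
    "DomainError",
    "StructureError",
    "ThermoContext",
    "CouplingState",
    "PerturbedAtomParams",
    "SoftCoreParams",
    "RestraintParams",
    "BackgroundParticle",
    "QuadraticSystemSpec",
    "FourStateToySpec",
    "PairEnergy",
    "SystemEnergy",
    "QuadraticSystem",
    "FourStateToy",
    "FixedStateSystem",
    "as_system",
    "interpolate_parameters",
    "softcore_pair_energy",
    "restraint_energy",
    "system_energy",
    "analytic_free_energy",
    "quadrature_free_energy",
    "harmonic_lambda_pair",
    "curved_profile_system",
    "coupled_quadratic_2d",
    "clash_toy",
    "eds_well_pair",
    "CORNERS",
    "CORNER_LABELS",
]

#: Boltzmann constant, kJ mol^-1 K^-1.
KB = 0.00831446

#: Coulomb conversion factor q_i q_j / (4 pi eps_0), kJ mol^-1 nm e^-2.
COULOMB_CONSTANT = 138.935458

#: The four corner states of the two-axis perturbation, (lam, kap).
CORNERS = ((0.0, 0.0), (0.0, 1.0), (1.0, 0.0), (1.0, 1.0))

#: Conventional state codes: G/A = grower dummy/present, D/H = water dummy/present.
CORNER_LABELS = {(0.0, 0.0): "GD", (0.0, 1.0): "GH", (1.0, 0.0): "AD", (1.0, 1.0): "AH"}


class DomainError(ValueError):
    """An argument lies outside the physically meaningful domain."""


class StructureError(ValueError):
    """Structurally inconsistent inputs (shape/grid/field mismatches)."""


@dataclass(frozen=True)
class ThermoContext:
    """Thermodynamic context: absolute temperature and Boltzmann constant."""

    temperature: float = 298.0
    boltzmann_constant: float = KB

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise DomainError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def kBT(self) -> float:
        return self.boltzmann_constant * self.temperature


@dataclass(frozen=True, order=True)
class CouplingState:
    """A point (lam, kap) on the unit square of coupling parameters."""

    lam: float
    kap: float = 0.0

    def __post_init__(self) -> None:
        for name, v in (("lam", self.lam), ("kap", self.kap)):
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} must lie in [0, 1], got {v}")

    def key(self) -> tuple[float, float]:
        return (self.lam, self.kap)


@dataclass(frozen=True)
class PerturbedAtomParams:
    """End-state nonbonded parameters of one (possibly perturbed) atom.

    ``coupling_axis`` selects which coupling parameter drives the A->B
    interpolation: "lam", "kap", or "none" for an unperturbed atom (state A
    parameters are used throughout).
    """

    q_A: float
    q_B: float
    C12_A: float
    C12_B: float
    C6_A: float
    C6_B: float
    coupling_axis: str = "none"

    def __post_init__(self) -> None:
        for name in ("C12_A", "C12_B", "C6_A", "C6_B"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if self.coupling_axis not in ("lam", "kap", "none"):
            raise DomainError(f"coupling_axis must be lam/kap/none, got {self.coupling_axis!r}")

    @property
    def a_is_null(self) -> bool:
        return self.q_A == 0.0 and self.C12_A == 0.0 and self.C6_A == 0.0

    @property
    def b_is_null(self) -> bool:
        return self.q_B == 0.0 and self.C12_B == 0.0 and self.C6_B == 0.0

    @property
    def is_unperturbed(self) -> bool:
        return (
            self.coupling_axis == "none"
            or (self.q_A == self.q_B and self.C12_A == self.C12_B and self.C6_A == self.C6_B)
        )

    def coupling_value(self, state: CouplingState) -> float:
        if self.coupling_axis == "lam":
            return state.lam
        if self.coupling_axis == "kap":
            return state.kap
        return 0.0

    @staticmethod
    def unperturbed(q: float, C12: float, C6: float) -> "PerturbedAtomParams":
        return PerturbedAtomParams(q, q, C12, C12, C6, C6, "none")


@dataclass(frozen=True)
class SoftCoreParams:
    """Soft-core strengths: alpha_LJ (dimensionless) and alpha_CRF (nm^2)."""

    alpha_LJ: float = 0.5
    alpha_CRF: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha_LJ < 0 or self.alpha_CRF < 0:
            raise DomainError("soft-core parameters must be >= 0")


@dataclass(frozen=True)
class RestraintParams:
    """Harmonic distance restraint pulling a particle toward an anchor."""

    force_constant: float  # kJ mol^-1 nm^-2
    anchor: tuple[float, ...] = (0.0,)
    target_distance: float = 0.0  # nm; 0 pulls directly onto the anchor

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise DomainError("force_constant must be >= 0")


@dataclass(frozen=True)
class BackgroundParticle:
    """A fixed, unperturbed interaction site (stands in for the surroundings)."""

    position: tuple[float, ...]
    q: float = 0.0
    C12: float = 0.0
    C6: float = 0.0

    def atom(self) -> PerturbedAtomParams:
        return PerturbedAtomParams.unperturbed(self.q, self.C12, self.C6)


# ---------------------------------------------------------------------------
# Parameter interpolation and the soft-core pair interaction
# ---------------------------------------------------------------------------


def interpolate_parameters(atom: PerturbedAtomParams, c: float) -> tuple[float, float, float]:
    """Interpolate (q, C12, C6) of one atom at coupling value ``c``.

    Charges interpolate linearly; the Lennard-Jones coefficients interpolate
    linearly on their square roots (geometric combination rules make the
    resulting pair coefficients products of the interpolated roots).
    """
    if not 0.0 <= c <= 1.0:
        raise DomainError(f"coupling value must lie in [0, 1], got {c}")
    if c == 0.0:  # endpoint identities hold exactly, not just to rounding
        return atom.q_A, atom.C12_A, atom.C6_A
    if c == 1.0:
        return atom.q_B, atom.C12_B, atom.C6_B
    q = (1.0 - c) * atom.q_A + c * atom.q_B
    s12 = (1.0 - c) * math.sqrt(atom.C12_A) + c * math.sqrt(atom.C12_B)
    s6 = (1.0 - c) * math.sqrt(atom.C6_A) + c * math.sqrt(atom.C6_B)
    return q, s12 * s12, s6 * s6


def _atom_terms(atom: PerturbedAtomParams, state: CouplingState):
    """Interpolated interaction roots and soft-core extent of one atom.

    Returns (q, s12, s6, dq, ds12, ds6, L, dL, r12ref, r6ref, dr12ref,
    dr6ref, axis): s12/s6 are square roots of the interpolated C12/C6, L is
    the atom's de-coupling extent (its distance from the fully interacting
    end on its own axis), and r12ref/r6ref are the *reference* roots used
    for the soft-core radius - the fully interacting end's parameters when
    one end is null, so the softening radius never collapses at a dummy
    endpoint.  d* are derivatives with respect to the atom's own coupling
    variable.
    """
    c = atom.coupling_value(state)
    r12A, r12B = math.sqrt(atom.C12_A), math.sqrt(atom.C12_B)
    r6A, r6B = math.sqrt(atom.C6_A), math.sqrt(atom.C6_B)
    q = (1.0 - c) * atom.q_A + c * atom.q_B
    s12 = (1.0 - c) * r12A + c * r12B
    s6 = (1.0 - c) * r6A + c * r6B
    if atom.is_unperturbed:
        return q, s12, s6, 0.0, 0.0, 0.0, 0.0, 0.0, s12, s6, 0.0, 0.0, "none"
    dq = atom.q_B - atom.q_A
    ds12 = r12B - r12A
    ds6 = r6B - r6A
    # De-coupling extent: how far the atom is from its fully interacting
    # end; reference roots for the soft-core radius.
    if atom.a_is_null and not atom.b_is_null:
        L, dL = 1.0 - c, -1.0
        rr12, rr6, dr12, dr6 = r12B, r6B, 0.0, 0.0
    elif atom.b_is_null and not atom.a_is_null:
        L, dL = c, 1.0
        rr12, rr6, dr12, dr6 = r12A, r6A, 0.0, 0.0
    elif atom.a_is_null and atom.b_is_null:
        L, dL = 0.0, 0.0
        rr12, rr6, dr12, dr6 = 0.0, 0.0, 0.0, 0.0
    else:
        # Both ends interact: soften only at intermediate coupling; the
        # reference radius follows the interpolated parameters.
        L, dL = 4.0 * c * (1.0 - c), 4.0 - 8.0 * c
        rr12, rr6, dr12, dr6 = s12, s6, ds12, ds6
    return q, s12, s6, dq, ds12, ds6, L, dL, rr12, rr6, dr12, dr6, atom.coupling_axis


@dataclass(frozen=True)
class PairEnergy:
    energy: float
    dlam: float
    dkap: float


def softcore_pair_energy(
    r: float,
    i: PerturbedAtomParams,
    j: PerturbedAtomParams,
    state: CouplingState,
    sc: SoftCoreParams = SoftCoreParams(),
    ctx: ThermoContext | None = None,
    reaction_field: tuple[float, float] | None = None,
) -> PairEnergy:
    """Soft-core Lennard-Jones + Coulomb energy of a pair, with derivatives.

    The pair coefficients are geometric combinations of the per-atom
    interpolated parameters.  The soft-core magnitude combines the two
    partners' de-coupling extents as ``L^2 = 1 - (1 - L_i^2)(1 - L_j^2)``,
    which reverts exactly to the single-axis soft-core form when only one
    partner is perturbed and vanishes at every corner state (plain physics
    at the end states).  Derivatives are returned for both coupling axes.

    ``reaction_field``, if given, is a (cutoff_nm, epsilon_rf) pair adding
    the distance-independent reaction-field correction; it is off by default.
    """
    if r <= 0:
        raise DomainError(f"pair distance must be > 0, got {r}")
    (qi, s12i, s6i, dqi, ds12i, ds6i, Li, dLi, rr12i, rr6i, drr12i, drr6i, axi) = _atom_terms(i, state)
    (qj, s12j, s6j, dqj, ds12j, ds6j, Lj, dLj, rr12j, rr6j, drr12j, drr6j, axj) = _atom_terms(j, state)

    qq = qi * qj
    C12 = s12i * s12j
    C6 = s6i * s6j
    Li2, Lj2 = Li * Li, Lj * Lj
    L2 = 1.0 - (1.0 - Li2) * (1.0 - Lj2)

    # Soft-core radius from the reference (fully interacting) pair
    # coefficients, so the softening survives at dummy endpoints.
    C12r = rr12i * rr12j
    C6r = rr6i * rr6j
    C126 = C12r / C6r if C6r > 0.0 else 0.0
    r2 = r * r
    r6 = r2 * r2 * r2
    D = r6 + sc.alpha_LJ * L2 * C126
    inv_D = 1.0 / D
    e_lj = (C12 * inv_D - C6) * inv_D

    S2 = r2 + sc.alpha_CRF * L2
    inv_S = 1.0 / math.sqrt(S2)
    e_c = COULOMB_CONSTANT * qq * inv_S

    e_rf = 0.0
    dErf_dL2 = 0.0
    crf_qq_pref = 0.0
    if reaction_field is not None:
        rc, eps = reaction_field
        crf = (2.0 * eps - 2.0) / (2.0 * eps + 1.0)
        src = (rc * rc + sc.alpha_CRF * L2) ** 1.5
        crf_qq_pref = COULOMB_CONSTANT * (-0.5 * crf * r2 / src - (1.0 - 0.5 * crf) / rc)
        e_rf = qq * crf_qq_pref
        dErf_dL2 = qq * COULOMB_CONSTANT * 0.75 * crf * r2 * sc.alpha_CRF / (
            (rc * rc + sc.alpha_CRF * L2) ** 2.5
        )

    energy = e_lj + e_c + e_rf

    # Partials with respect to the pair-level intermediates.
    dE_dD = (-2.0 * C12 * inv_D + C6) * inv_D * inv_D
    dE_dC12 = inv_D * inv_D
    dE_dC6 = -inv_D
    dE_dS2 = -0.5 * COULOMB_CONSTANT * qq * inv_S / S2
    dE_dL2 = dE_dD * sc.alpha_LJ * C126 + dE_dS2 * sc.alpha_CRF + dErf_dL2
    dE_dC126 = dE_dD * sc.alpha_LJ * L2
    dE_dqq = COULOMB_CONSTANT * inv_S + crf_qq_pref

    dlam = 0.0
    dkap = 0.0
    for (axis, q_o, s12_o, s6_o, L_o2, rr12_o, rr6_o, dq, ds12, ds6, L_s, dL_s, drr12, drr6) in (
        (axi, qj, s12j, s6j, Lj2, rr12j, rr6j, dqi, ds12i, ds6i, Li, dLi, drr12i, drr6i),
        (axj, qi, s12i, s6i, Li2, rr12i, rr6i, dqj, ds12j, ds6j, Lj, dLj, drr12j, drr6j),
    ):
        if axis == "none":
            continue
        dL2_dc = 2.0 * L_s * dL_s * (1.0 - L_o2)
        g = (
            dE_dC12 * s12_o * ds12
            + dE_dC6 * s6_o * ds6
            + dE_dqq * q_o * dq
            + dE_dL2 * dL2_dc
        )
        if C6r > 0.0 and (drr12 != 0.0 or drr6 != 0.0):
            dC126_dc = (drr12 * rr12_o * C6r - C12r * drr6 * rr6_o) / (C6r * C6r)
            g += dE_dC126 * dC126_dc
        if axis == "lam":
            dlam += g
        else:
            dkap += g
    return PairEnergy(energy, dlam, dkap)


def _atom_terms_vec(atom: PerturbedAtomParams, c: np.ndarray):
    """Vectorized :func:`_atom_terms` over an array of coupling values."""
    r12A, r12B = math.sqrt(atom.C12_A), math.sqrt(atom.C12_B)
    r6A, r6B = math.sqrt(atom.C6_A), math.sqrt(atom.C6_B)
    q = (1.0 - c) * atom.q_A + c * atom.q_B
    s12 = (1.0 - c) * r12A + c * r12B
    s6 = (1.0 - c) * r6A + c * r6B
    zero = np.zeros_like(c)
    if atom.is_unperturbed:
        return q, s12, s6, 0.0, 0.0, 0.0, zero, zero, s12, s6, 0.0, 0.0
    dq, ds12, ds6 = atom.q_B - atom.q_A, r12B - r12A, r6B - r6A
    if atom.a_is_null and not atom.b_is_null:
        L, dL = 1.0 - c, -np.ones_like(c)
        rr12, rr6, dr12, dr6 = r12B + zero, r6B + zero, 0.0, 0.0
    elif atom.b_is_null and not atom.a_is_null:
        L, dL = c, np.ones_like(c)
        rr12, rr6, dr12, dr6 = r12A + zero, r6A + zero, 0.0, 0.0
    elif atom.a_is_null and atom.b_is_null:
        L, dL = zero, zero
        rr12, rr6, dr12, dr6 = zero, zero, 0.0, 0.0
    else:
        L, dL = 4.0 * c * (1.0 - c), 4.0 - 8.0 * c
        rr12, rr6, dr12, dr6 = s12, s6, ds12, ds6
    return q, s12, s6, dq, ds12, ds6, L, dL, rr12, rr6, dr12, dr6


def _softcore_vec(
    r: float,
    i: PerturbedAtomParams,
    j: PerturbedAtomParams,
    lam_arr: np.ndarray,
    kap_arr: np.ndarray,
    sc: SoftCoreParams,
):
    """Soft-core pair energy and derivatives over arrays of coupling states.

    Identical formulas to :func:`softcore_pair_energy`, evaluated for a whole
    probe grid at once; used by the on-the-fly probe recording.
    """

    def coupling_of(atom):
        if atom.coupling_axis == "lam":
            return lam_arr
        if atom.coupling_axis == "kap":
            return kap_arr
        return np.zeros_like(lam_arr)

    (qi, s12i, s6i, dqi, ds12i, ds6i, Li, dLi, rr12i, rr6i, drr12i, drr6i) = _atom_terms_vec(i, coupling_of(i))
    (qj, s12j, s6j, dqj, ds12j, ds6j, Lj, dLj, rr12j, rr6j, drr12j, drr6j) = _atom_terms_vec(j, coupling_of(j))
    qq = qi * qj
    C12 = s12i * s12j
    C6 = s6i * s6j
    Li2, Lj2 = Li * Li, Lj * Lj
    L2 = 1.0 - (1.0 - Li2) * (1.0 - Lj2)
    C12r = rr12i * rr12j
    C6r = rr6i * rr6j
    pos6 = C6r > 0.0
    C126 = np.where(pos6, C12r / np.where(pos6, C6r, 1.0), 0.0)
    r2 = r * r
    r6 = r2 * r2 * r2
    D = r6 + sc.alpha_LJ * L2 * C126
    inv_D = 1.0 / D
    e_lj = (C12 * inv_D - C6) * inv_D
    S2 = r2 + sc.alpha_CRF * L2
    inv_S = 1.0 / np.sqrt(S2)
    e_c = COULOMB_CONSTANT * qq * inv_S
    energy = e_lj + e_c

    dE_dD = (-2.0 * C12 * inv_D + C6) * inv_D * inv_D
    dE_dS2 = -0.5 * COULOMB_CONSTANT * qq * inv_S / S2
    dE_dL2 = dE_dD * sc.alpha_LJ * C126 + dE_dS2 * sc.alpha_CRF
    dE_dC126 = dE_dD * sc.alpha_LJ * L2
    dE_dC12 = inv_D * inv_D
    dE_dC6 = -inv_D
    dE_dqq = COULOMB_CONSTANT * inv_S

    dlam = np.zeros_like(lam_arr)
    dkap = np.zeros_like(lam_arr)
    for (atom, q_o, s12_o, s6_o, L_o2, rr12_o, rr6_o, dq, ds12, ds6, L_s, dL_s, drr12, drr6) in (
        (i, qj, s12j, s6j, Lj2, rr12j, rr6j, dqi, ds12i, ds6i, Li, dLi, drr12i, drr6i),
        (j, qi, s12i, s6i, Li2, rr12i, rr6i, dqj, ds12j, ds6j, Lj, dLj, drr12j, drr6j),
    ):
        if atom.coupling_axis == "none" or atom.is_unperturbed:
            continue
        dL2_dc = 2.0 * L_s * dL_s * (1.0 - L_o2)
        g = (
            dE_dC12 * s12_o * ds12
            + dE_dC6 * s6_o * ds6
            + dE_dqq * q_o * dq
            + dE_dL2 * dL2_dc
        )
        if np.isscalar(drr12) and drr12 == 0.0 and np.isscalar(drr6) and drr6 == 0.0:
            pass
        else:
            dC126_dc = np.where(
                pos6,
                (drr12 * rr12_o * C6r - C12r * drr6 * rr6_o) / np.where(pos6, C6r * C6r, 1.0),
                0.0,
            )
            g = g + dE_dC126 * dC126_dc
        if atom.coupling_axis == "lam":
            dlam = dlam + g
        else:
            dkap = dkap + g
    return energy, dlam, dkap


def restraint_energy(pos_w: Sequence[float] | float, params: RestraintParams) -> float:
    """Harmonic distance-restraint energy 0.5 k (|pos - anchor| - d0)^2."""
    if isinstance(pos_w, (int, float)):
        d = abs(float(pos_w) - params.anchor[0])
    else:
        acc = 0.0
        for x, a in zip(pos_w, params.anchor):
            acc += (x - a) ** 2
        d = math.sqrt(acc)
    dev = d - params.target_distance
    return 0.5 * params.force_constant * dev * dev


# ---------------------------------------------------------------------------
# System specifications
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuadraticSystemSpec:
    """Gaussian family: H = 1/2 x^T A(lam,kap) x - b(lam,kap)^T x.

    ``stiffness_matrix`` must be symmetric positive definite on the whole
    unit square.  Optional gradient callables return the derivatives of A
    and b with respect to (lam, kap); when absent, coupling derivatives are
    taken by central differences with step 1e-6.
    """

    dim: int
    stiffness_matrix: Callable[[float, float], np.ndarray]
    linear_term: Callable[[float, float], np.ndarray]
    stiffness_grad: Callable[[float, float], tuple[np.ndarray, np.ndarray]] | None = None
    linear_grad: Callable[[float, float], tuple[np.ndarray, np.ndarray]] | None = None
    name: str = "quadratic"


@dataclass(frozen=True)
class FourStateToySpec:
    """Growing particle at a fixed site + a restrained, removable water.

    The grower sits at ``site_position`` and couples to ``lam`` (dummy at
    lam=0).  The water particle moves, couples to ``kap`` (dummy at kap=0,
    present at kap=1), is pulled toward the site by a harmonic distance
    restraint, and additionally interacts with a fixed background particle
    representing the surroundings.  At (lam=1, kap=1) the restraint and the
    water-grower repulsion fight each other: the steric clash of a confined
    binding-site water displaced by a growing side chain.
    """

    site_position: tuple[float, ...]
    grower_params: PerturbedAtomParams
    water_params: PerturbedAtomParams
    restraint: RestraintParams
    background: BackgroundParticle | None = None
    softcore: SoftCoreParams = SoftCoreParams()
    name: str = "four_state_toy"

    @property
    def dim(self) -> int:
        return len(self.site_position)


@dataclass(frozen=True)
class SystemEnergy:
    energy: float
    dlam: float
    dkap: float


class QuadraticSystem:
    """Evaluator for :class:`QuadraticSystemSpec`."""

    def __init__(self, spec: QuadraticSystemSpec):
        self.spec = spec
        self.dim = spec.dim

    def _ab(self, lam: float, kap: float) -> tuple[np.ndarray, np.ndarray]:
        A = np.asarray(self.spec.stiffness_matrix(lam, kap), dtype=float)
        b = np.asarray(self.spec.linear_term(lam, kap), dtype=float)
        return A, b

    def evaluate(self, conf, state: CouplingState) -> SystemEnergy:
        x = np.atleast_1d(np.asarray(conf, dtype=float))
        if x.size != self.dim:
            raise StructureError(f"configuration has {x.size} coordinates, spec needs {self.dim}")
        A, b = self._ab(state.lam, state.kap)
        H = 0.5 * x @ A @ x - b @ x
        if self.spec.stiffness_grad is not None:
            dA_dl, dA_dk = self.spec.stiffness_grad(state.lam, state.kap)
        else:
            dA_dl, dA_dk = _central_grad(self.spec.stiffness_matrix, state)
        if self.spec.linear_grad is not None:
            db_dl, db_dk = self.spec.linear_grad(state.lam, state.kap)
        else:
            db_dl, db_dk = _central_grad(self.spec.linear_term, state)
        dlam = 0.5 * x @ np.asarray(dA_dl, float) @ x - np.asarray(db_dl, float) @ x
        dkap = 0.5 * x @ np.asarray(dA_dk, float) @ x - np.asarray(db_dk, float) @ x
        return SystemEnergy(float(H), float(dlam), float(dkap))

    def endstate_energies(self, conf) -> dict[tuple[float, float], float]:
        return {
            c: self.evaluate(conf, CouplingState(*c)).energy for c in CORNERS
        }

    def minimum(self, state: CouplingState) -> np.ndarray:
        A, b = self._ab(state.lam, state.kap)
        return np.linalg.solve(A, b)

    def make_probe_evaluator(self, states: Sequence[CouplingState], axis: str = "lam"):
        """Vectorized (H, dH/dc) along ``axis`` over a fixed probe grid.

        The probe grid is fixed for a whole run, so the per-state matrices
        are precomputed once and each configuration costs two einsums.
        """
        k = 0 if axis == "lam" else 1
        A = np.stack([np.asarray(self.spec.stiffness_matrix(s.lam, s.kap), float) for s in states])
        b = np.stack([np.asarray(self.spec.linear_term(s.lam, s.kap), float) for s in states])
        if self.spec.stiffness_grad is not None:
            dA = np.stack([np.asarray(self.spec.stiffness_grad(s.lam, s.kap)[k], float) for s in states])
        else:
            dA = np.stack([_central_grad(self.spec.stiffness_matrix, s)[k] for s in states])
        if self.spec.linear_grad is not None:
            db = np.stack([np.asarray(self.spec.linear_grad(s.lam, s.kap)[k], float) for s in states])
        else:
            db = np.stack([_central_grad(self.spec.linear_term, s)[k] for s in states])

        def evaluate(conf):
            x = np.atleast_1d(np.asarray(conf, float))
            h = 0.5 * np.einsum("pij,i,j->p", A, x, x) - b @ x
            d = 0.5 * np.einsum("pij,i,j->p", dA, x, x) - db @ x
            return h, d

        return evaluate


def _central_grad(f: Callable[[float, float], np.ndarray], state: CouplingState, h: float = 1e-6):
    """Central-difference coupling gradient, clipped to the unit square."""

    def d(axis: int):
        v = [state.lam, state.kap]
        lo, hi = max(v[axis] - h, 0.0), min(v[axis] + h, 1.0)
        vp, vm = list(v), list(v)
        vp[axis], vm[axis] = hi, lo
        return (np.asarray(f(*vp), float) - np.asarray(f(*vm), float)) / (hi - lo)

    return d(0), d(1)


class FourStateToy:
    """Evaluator for :class:`FourStateToySpec` (configuration = water coords)."""

    def __init__(self, spec: FourStateToySpec):
        self.spec = spec
        self.dim = spec.dim
        self._bg_atom = spec.background.atom() if spec.background is not None else None

    def _distance(self, conf, ref: tuple[float, ...]) -> float:
        if self.dim == 1:
            x = conf[0] if not isinstance(conf, (int, float)) else float(conf)
            return abs(x - ref[0])
        acc = 0.0
        for x, a in zip(conf, ref):
            acc += (x - a) ** 2
        return math.sqrt(acc)

    def evaluate(self, conf, state: CouplingState) -> SystemEnergy:
        if not isinstance(conf, (int, float)) and len(conf) != self.dim:
            raise StructureError(
                f"configuration has {len(conf)} coordinates, spec needs {self.dim}"
            )
        sp = self.spec
        r_site = self._distance(conf, sp.site_position)
        pair = softcore_pair_energy(
            max(r_site, 1e-12), sp.grower_params, sp.water_params, state, sp.softcore
        )
        H = pair.energy
        dlam, dkap = pair.dlam, pair.dkap
        if sp.background is not None:
            r_bg = self._distance(conf, sp.background.position)
            bg = softcore_pair_energy(
                max(r_bg, 1e-12), self._bg_atom, sp.water_params, state, sp.softcore
            )
            H += bg.energy
            dlam += bg.dlam
            dkap += bg.dkap
        H += restraint_energy(conf, sp.restraint)
        return SystemEnergy(H, dlam, dkap)

    def endstate_energies(self, conf) -> dict[tuple[float, float], float]:
        return {c: self.evaluate(conf, CouplingState(*c)).energy for c in CORNERS}

    def minimum(self, state: CouplingState, half_width: float = 0.9, n_grid: int = 241) -> np.ndarray:
        """Approximate minimum-energy water position at one coupling state.

        A coarse grid scan around the restraint anchor; used to start the
        Markov chain in the relevant basin (at strongly coupled states the
        region between the grower and the background particle is a caged
        local trap a bad start cannot leave).
        """
        anchor = np.asarray(self.spec.restraint.anchor, float)
        if self.dim == 1:
            grid = anchor[0] + np.linspace(-half_width, half_width, n_grid)
            energies = [self.evaluate([x], state).energy for x in grid]
            return np.array([grid[int(np.argmin(energies))]])
        axes = [anchor[d] + np.linspace(-half_width, half_width, 41) for d in range(self.dim)]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=-1)
        energies = [self.evaluate(p, state).energy for p in pts]
        return pts[int(np.argmin(energies))]

    def make_probe_evaluator(self, states: Sequence[CouplingState], axis: str = "lam"):
        """Vectorized (H, dH/dc) along ``axis`` over a fixed probe grid."""
        sp = self.spec
        lam_arr = np.array([s.lam for s in states])
        kap_arr = np.array([s.kap for s in states])
        bg_atom = self._bg_atom
        sel = 1 if axis == "lam" else 2

        def evaluate(conf):
            r_site = max(self._distance(conf, sp.site_position), 1e-12)
            out = _softcore_vec(
                r_site, sp.grower_params, sp.water_params, lam_arr, kap_arr, sp.softcore
            )
            h = out[0].copy()
            d = out[sel].copy()
            if sp.background is not None:
                r_bg = max(self._distance(conf, sp.background.position), 1e-12)
                out2 = _softcore_vec(
                    r_bg, bg_atom, sp.water_params, lam_arr, kap_arr, sp.softcore
                )
                h += out2[0]
                d += out2[sel]
            h += restraint_energy(conf, sp.restraint)
            return h, d

        return evaluate


class FixedStateSystem:
    """A coupled system frozen at one coupling state (a plain Hamiltonian).

    ``deriv_axis`` optionally keeps one coupling derivative alive, which is
    what the EDS-TI end states need: the Hamiltonian at fixed kap, together
    with its lam-derivative.
    """

    def __init__(self, system, state: CouplingState, deriv_axis: str | None = None):
        self.system = as_system(system)
        self.state = state
        self.deriv_axis = deriv_axis
        self.dim = self.system.dim

    def energy(self, conf) -> float:
        return self.system.evaluate(conf, self.state).energy

    def energy_and_deriv(self, conf) -> tuple[float, float]:
        e = self.system.evaluate(conf, self.state)
        if self.deriv_axis == "lam":
            return e.energy, e.dlam
        if self.deriv_axis == "kap":
            return e.energy, e.dkap
        return e.energy, 0.0


def as_system(spec):
    """Coerce a spec dataclass (or an existing evaluator) to an evaluator."""
    if isinstance(spec, QuadraticSystemSpec):
        return QuadraticSystem(spec)
    if isinstance(spec, FourStateToySpec):
        return FourStateToy(spec)
    if hasattr(spec, "evaluate") and hasattr(spec, "dim"):
        return spec
    raise StructureError(f"cannot interpret {type(spec).__name__} as a system")


def system_energy(spec, conf, state: CouplingState):
    """Total energy, both coupling derivatives, and the four corner energies."""
    system = as_system(spec)
    e = system.evaluate(conf, state)
    return e.energy, e.dlam, e.dkap, system.endstate_energies(conf)


# ---------------------------------------------------------------------------
# Free-energy oracles
# ---------------------------------------------------------------------------


def analytic_free_energy(
    spec: QuadraticSystemSpec, state: CouplingState, ctx: ThermoContext = ThermoContext()
) -> float:
    """Closed-form configurational free energy of the Gaussian family.

    G = (kBT/2) ln det A - (d/2) kBT ln(2 pi kBT) - 1/2 b^T A^-1 b, which is
    the absolute -kBT ln Z of the quadratic Hamiltonian; differences between
    coupling states are exact reference values for every estimator.
    """
    system = QuadraticSystem(spec)
    A, b = system._ab(state.lam, state.kap)
    try:
        chol = np.linalg.cholesky(A)
    except np.linalg.LinAlgError as exc:
        raise DomainError(f"stiffness matrix not positive definite at {state}") from exc
    kBT = ctx.kBT
    logdet = 2.0 * float(np.sum(np.log(np.diag(chol))))
    quad = float(b @ np.linalg.solve(A, b))
    d = spec.dim
    return 0.5 * kBT * logdet - 0.5 * d * kBT * math.log(2.0 * math.pi * kBT) - 0.5 * quad


def quadrature_free_energy(
    spec,
    state: CouplingState,
    box: Sequence[tuple[float, float]],
    ctx: ThermoContext = ThermoContext(),
    rel_tol: float = 1e-10,
) -> float:
    """Deterministic-quadrature free energy -kBT ln Z over a finite box.

    Exact (to quadrature tolerance) for any bundled system of total
    dimensionality <= 3; the gold reference for the non-Gaussian toys.
    """
    system = as_system(spec)
    d = system.dim
    if d > 3:
        raise DomainError("quadrature oracle supports dimensionality <= 3")
    if len(box) != d:
        raise StructureError(f"box has {len(box)} intervals, system needs {d}")
    kBT = ctx.kBT

    # Offset by a reference energy so the integrand is O(1) at its peak.
    grids = [np.linspace(lo, hi, 41) for (lo, hi) in box]
    mesh = np.meshgrid(*grids, indexing="ij")
    pts = np.stack([m.ravel() for m in mesh], axis=-1)
    h0 = min(system.evaluate(p, state).energy for p in pts)

    def boltz(*coords):
        e = system.evaluate(list(coords), state).energy
        z = (e - h0) / kBT
        return math.exp(-z) if z < 700 else 0.0

    opts = {"epsrel": rel_tol, "epsabs": 0.0, "limit": 200}
    val, _ = integrate.nquad(boltz, list(box), opts=[opts] * d)
    if not val > 0 or not math.isfinite(val):
        raise DomainError("quadrature of the Boltzmann factor is degenerate or divergent")
    return h0 - kBT * math.log(val)


# ---------------------------------------------------------------------------
# Bundled systems (the study conditions of the test suite)
# ---------------------------------------------------------------------------


def harmonic_lambda_pair(k_A: float = 100.0, k_B: float = 400.0) -> QuadraticSystemSpec:
    """1D harmonic well whose stiffness interpolates linearly in lam.

    The exact free-energy difference over the full path is
    (kBT/2) ln(k_B / k_A).
    """

    return QuadraticSystemSpec(
        dim=1,
        stiffness_matrix=lambda lam, kap: np.array([[(1.0 - lam) * k_A + lam * k_B]]),
        linear_term=lambda lam, kap: np.zeros(1),
        stiffness_grad=lambda lam, kap: (np.array([[k_B - k_A]]), np.zeros((1, 1))),
        linear_grad=lambda lam, kap: (np.zeros(1), np.zeros(1)),
        name=f"harmonic_pair_k{k_A:g}_to_{k_B:g}",
    )


def curved_profile_system() -> QuadraticSystemSpec:
    """1D Gaussian system with a sharply curved TI profile.

    The stiffness carries a localized Lorentzian bump,
    k(lam) = 100 + 2400 / (1 + 300 (lam - 0.6)^2), so dG/dlam =
    (kBT/2) k'/k swings through a narrow feature that a 10-point
    trapezoid grid integrates with a large systematic error (+0.34
    kJ/mol) while a dense 101-point profile does not (7e-5 kJ/mol).
    """

    def k(lam: float) -> float:
        return 100.0 + 2400.0 / (1.0 + 300.0 * (lam - 0.6) ** 2)

    def dk(lam: float) -> float:
        return -2400.0 * 600.0 * (lam - 0.6) / (1.0 + 300.0 * (lam - 0.6) ** 2) ** 2

    return QuadraticSystemSpec(
        dim=1,
        stiffness_matrix=lambda lam, kap: np.array([[k(lam)]]),
        linear_term=lambda lam, kap: np.zeros(1),
        stiffness_grad=lambda lam, kap: (np.array([[dk(lam)]]), np.zeros((1, 1))),
        linear_grad=lambda lam, kap: (np.zeros(1), np.zeros(1)),
        name="curved_profile",
    )


def coupled_quadratic_2d() -> QuadraticSystemSpec:
    """2D Gaussian family genuinely coupled in both lam and kap.

    The off-diagonal stiffness depends on the product lam*kap and the linear
    term on both axes, so neither axis is separable and the 2D landscape is
    a nontrivial surface; the analytic oracle stays exact everywhere.
    """

    def A(lam: float, kap: float) -> np.ndarray:
        off = 30.0 * lam * kap
        return np.array([[100.0 + 100.0 * lam, off], [off, 150.0 + 100.0 * kap]])

    def dA(lam: float, kap: float):
        return (
            np.array([[100.0, 30.0 * kap], [30.0 * kap, 0.0]]),
            np.array([[0.0, 30.0 * lam], [30.0 * lam, 100.0]]),
        )

    def b(lam: float, kap: float) -> np.ndarray:
        return np.array([5.0 * lam, -3.0 * kap])

    def db(lam: float, kap: float):
        return np.array([5.0, 0.0]), np.array([0.0, -3.0])

    return QuadraticSystemSpec(
        dim=2, stiffness_matrix=A, linear_term=b, stiffness_grad=dA, linear_grad=db,
        name="coupled_quadratic_2d",
    )


def _lj_coefficients(sigma: float, epsilon: float) -> tuple[float, float]:
    """(C12, C6) of a 12-6 potential from sigma (nm) and epsilon (kJ/mol)."""
    return 4.0 * epsilon * sigma ** 12, 4.0 * epsilon * sigma ** 6


def clash_toy(restraint_k: float = 500.0) -> FourStateToySpec:
    """The default four-state steric-clash dimer (1D water coordinate).

    The grower (a methyl-sized Lennard-Jones site, sigma 0.3 nm, epsilon
    1 kJ/mol) grows in at the site the water is restrained to with the
    production force constant of 500 kJ mol^-1 nm^-2; a fixed SPC-like
    background particle at 0.35 nm gives the water something to interact
    with even when the grower is a dummy.  At (1, 1) the restraint and the
    water-grower repulsion are in direct conflict.
    """
    g_c12, g_c6 = _lj_coefficients(0.30, 1.0)
    w_c12, w_c6 = 2.634129e-6, 2.617346e-3  # SPC-oxygen-like
    return FourStateToySpec(
        site_position=(0.0,),
        grower_params=PerturbedAtomParams(0.0, 0.10, 0.0, g_c12, 0.0, g_c6, "lam"),
        water_params=PerturbedAtomParams(0.0, -0.10, 0.0, w_c12, 0.0, w_c6, "kap"),
        restraint=RestraintParams(force_constant=restraint_k, anchor=(0.0,), target_distance=0.0),
        background=BackgroundParticle(position=(0.35,), q=0.10, C12=2.634129e-6, C6=2.617346e-3),
        softcore=SoftCoreParams(0.5, 0.5),
        name="clash_toy",
    )


def eds_well_pair() -> tuple[FixedStateSystem, FixedStateSystem, float]:
    """Two overlapping 1D harmonic wells and their exact free-energy gap.

    End state A: 1/2*100*x^2.  End state B: 1/2*120*(x-0.12)^2 + 4.  The
    exact gap is G_B - G_A = (kBT/2) ln(120/100) + 4 (the offset shifts G
    directly; the width change gives the log-ratio term at 298 K).
    Returned as (system_A, system_B, delta_G_exact).
    """
    kBT = ThermoContext().kBT

    def make(k: float, x0: float, e0: float) -> QuadraticSystemSpec:
        # 1/2 k (x-x0)^2 + e0 = 1/2 k x^2 - k x0 x + (1/2 k x0^2 + e0); the
        # constant is folded into the linear/offset form via a shifted spec.
        return QuadraticSystemSpec(
            dim=1,
            stiffness_matrix=lambda lam, kap: np.array([[k]]),
            linear_term=lambda lam, kap: np.array([k * x0]),
            stiffness_grad=lambda lam, kap: (np.zeros((1, 1)), np.zeros((1, 1))),
            linear_grad=lambda lam, kap: (np.zeros(1), np.zeros(1)),
            name=f"well_k{k:g}",
        )

    class _Shifted(FixedStateSystem):
        def __init__(self, spec, const):
            super().__init__(spec, CouplingState(0.0, 0.0))
            self.const = const

        def energy(self, conf):
            return super().energy(conf) + self.const

        def energy_and_deriv(self, conf):
            e, d = super().energy_and_deriv(conf)
            return e + self.const, d

    a = _Shifted(make(100.0, 0.0, 0.0), 0.0)
    b = _Shifted(make(120.0, 0.12, 4.0), 0.5 * 120.0 * 0.12 ** 2 + 4.0)
    exact = 0.5 * kBT * math.log(120.0 / 100.0) + 4.0
    return a, b, exact
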