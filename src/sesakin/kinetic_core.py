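"""Rate law and temperature models for the sesamin -> asarinin isomerization.

Sesamin (A) isomerizes reversibly to its epimer asarinin (B) over a solid
acid catalyst.  With quasi-equilibrated adsorption/desorption around a single
rate-determining surface step, the site balance yields a
Langmuir-Hinshelwood rate law

    R = k(T) * w_cat * ([A] - [B]/K(T)) / (1 + K1*[A] + K2*[B])

where k(T) is the lumped surface rate constant, K(T) the isomerization
equilibrium constant, K1 and K2 the adsorption constants of sesamin and
asarinin, and w_cat the catalyst amount per amount of oil.  Both temperature
dependencies are parameterized at a reference temperature T_ref so that the
pre-exponential factor and the activation energy decorrelate during fitting:

    k(T) = exp[ ln k_ref + (Ea/(R*T_ref)) * (1 - T_ref/T) ]
    K(T) = exp[ ln K_ref + (dH_r/(R*T_ref)) * (1 - T_ref/T) ]

Unit convention
---------------
All functions here are unit-agnostic: they evaluate the formulas on whatever
consistent unit system the caller adopts.  The package-wide convention,
applied at the I/O boundary, is: concentrations in mmol/L, time in minutes,
temperature in K, catalyst amount w_cat as a mass fraction (g catalyst per g
oil), K1/K2 in L/mmol, so k carries (g oil)/(g cat)/min.  Under this
convention the default parameter set reproduces the experimentally observed
time scale of the reaction (tens of minutes to hours at 70-90 degC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "R_GAS",
    "T_REF",
    "ArrheniusParams",
    "VantHoffParams",
    "KineticParameters",
    "ReactionConditions",
    "StateVector",
    "rate_constant",
    "equilibrium_constant",
    "reaction_rate",
    "ode_rhs",
    "conversion_percent",
    "closed_form_profile",
    "equilibrium_state",
    "reference_parameters",
]

#: Gas constant, J mol^-1 K^-1.
R_GAS = 8.314

#: Default reference temperature for the reparameterized temperature laws, K.
T_REF = 353.15


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ValueError(message)


@dataclass(frozen=True)
class ArrheniusParams:
    """Reference-temperature (modified) Arrhenius parameterization.

    ``ln_k_ref`` is the natural log of the rate constant at ``T_ref``;
    ``ea_over_RTref`` is the dimensionless activation-energy group
    Ea/(R*T_ref).  ``ln_k_ref = -inf`` is allowed and flags a dead catalyst
    (k identically zero).
    """

    ln_k_ref: float
    ea_over_RTref: float
    T_ref: float = T_REF

    def __post_init__(self) -> None:
        _require(self.T_ref > 0, f"T_ref must be positive, got {self.T_ref}")
        _require(math.isfinite(self.ea_over_RTref),
                 "ea_over_RTref must be finite")
        _require(not math.isnan(self.ln_k_ref), "ln_k_ref must not be NaN")

    @property
    def ea_joule_per_mol(self) -> float:
        """Activation energy in J/mol implied by the dimensionless group."""
        return self.ea_over_RTref * R_GAS * self.T_ref


@dataclass(frozen=True)
class VantHoffParams:
    """Van't Hoff temperature law for the isomerization equilibrium constant.

    ``K_ref`` is K at ``T_ref``; ``dH_r`` is the reaction enthalpy in J/mol
    (positive = endothermic, so K increases with temperature).
    """

    K_ref: float
    dH_r: float
    T_ref: float = T_REF

    def __post_init__(self) -> None:
        _require(self.K_ref > 0, f"K_ref must be positive, got {self.K_ref}")
        _require(self.T_ref > 0, f"T_ref must be positive, got {self.T_ref}")
        _require(math.isfinite(self.dH_r), "dH_r must be finite")

    @property
    def dh_over_RTref(self) -> float:
        """Dimensionless enthalpy group dH_r/(R*T_ref)."""
        return self.dH_r / (R_GAS * self.T_ref)


@dataclass(frozen=True)
class KineticParameters:
    """Full parameter vector of the isomerization model.

    ``K2`` defaults to ``K1`` (equal adsorption constants for the two
    epimers, which also makes the site-balance denominator a trajectory
    constant); pass ``K2`` explicitly to override.
    """

    arrhenius: ArrheniusParams
    vant_hoff: VantHoffParams
    K1: float
    K2: float | None = None

    def __post_init__(self) -> None:
        _require(self.K1 >= 0, f"K1 must be non-negative, got {self.K1}")
        if self.K2 is None:
            object.__setattr__(self, "K2", self.K1)
        _require(self.K2 >= 0, f"K2 must be non-negative, got {self.K2}")


@dataclass(frozen=True)
class ReactionConditions:
    """One experimental run's conditions.

    ``rpm`` is carried as metadata only: the model contains no mass-transfer
    term, consistent with the experimentally observed insensitivity of the
    kinetics to stirring speed.
    """

    T: float
    w_cat: float
    C_A0: float
    C_B0: float = 0.0
    rpm: float = 300.0
    run_id: str = ""

    def __post_init__(self) -> None:
        _require(self.T > 0, f"temperature must be positive, got {self.T}")
        _require(self.w_cat >= 0, "catalyst amount must be non-negative")
        _require(self.C_A0 >= 0, "initial sesamin concentration must be >= 0")
        _require(self.C_B0 >= 0, "initial asarinin concentration must be >= 0")


@dataclass(frozen=True)
class StateVector:
    """Instantaneous concentrations of sesamin (C_A) and asarinin (C_B)."""

    C_A: float
    C_B: float

    def __post_init__(self) -> None:
        _require(np.all(np.asarray(self.C_A) >= 0), "C_A must be >= 0")
        _require(np.all(np.asarray(self.C_B) >= 0), "C_B must be >= 0")


def rate_constant(T: float, arr: ArrheniusParams) -> float:
    """Rate constant k(T) from the reference-temperature Arrhenius form."""
    _require(T > 0, f"temperature must be positive, got {T}")
    return math.exp(arr.ln_k_ref + arr.ea_over_RTref * (1.0 - arr.T_ref / T))


def equilibrium_constant(T: float, vh: VantHoffParams) -> float:
    """Equilibrium constant K(T) from the Van't Hoff law."""
    _require(T > 0, f"temperature must be positive, got {T}")
    return math.exp(math.log(vh.K_ref)
                    + vh.dh_over_RTref * (1.0 - vh.T_ref / T))


def reaction_rate(state: StateVector, params: KineticParameters,
                  cond: ReactionConditions) -> float:
    """Net isomerization rate R at the given state.

    Zero exactly at chemical equilibrium [B] = K(T)*[A]; positive while
    sesamin is above its equilibrium share.
    """
    K = equilibrium_constant(cond.T, params.vant_hoff)
    if K == 0.0:
        raise ValueError("degenerate model: equilibrium constant is zero")
    k = rate_constant(cond.T, params.arrhenius)
    denom = 1.0 + params.K1 * state.C_A + params.K2 * state.C_B
    return k * cond.w_cat * (state.C_A - state.C_B / K) / denom


def ode_rhs(state: StateVector, params: KineticParameters,
            cond: ReactionConditions) -> tuple[float, float]:
    """Material balances (dC_A/dt, dC_B/dt) = (-R, +R)."""
    r = reaction_rate(state, params, cond)
    return (-r, r)


def conversion_percent(C_A: float, C_A0: float) -> float:
    """Sesamin conversion (1 - C_A/C_A0) * 100, in percent."""
    _require(C_A0 > 0, f"initial concentration must be positive, got {C_A0}")
    return (1.0 - np.asarray(C_A) / C_A0) * 100.0


def closed_form_profile(cond: ReactionConditions, params: KineticParameters,
                        t: float | np.ndarray) -> StateVector:
    """Exact solution of the batch isomerization when K1 == K2.

    Equal adsorption constants make the site-balance denominator
    1 + K1*(C_A + C_B) constant along a trajectory (total lignan is
    conserved), so the ODE is linear with a single relaxation rate:

        C_A(t) = A_eq + (C_A0 - A_eq) * exp(-lambda * t)

    with A_eq = C_tot / (1 + K), lambda = k_eff * (1 + 1/K) and
    k_eff = k(T) * w_cat / (1 + K1 * C_tot).  Serves as the analytic oracle
    for the numerical integrator.
    """
    if params.K1 != params.K2:
        raise ValueError(
            "closed-form solution requires K1 == K2 "
            f"(got K1={params.K1}, K2={params.K2})")
    t = np.asarray(t, dtype=float)
    _require(bool(np.all(t >= 0)), "time must be non-negative")
    C_tot = cond.C_A0 + cond.C_B0
    K = equilibrium_constant(cond.T, params.vant_hoff)
    k = rate_constant(cond.T, params.arrhenius)
    k_eff = k * cond.w_cat / (1.0 + params.K1 * C_tot)
    lam = k_eff * (1.0 + 1.0 / K)
    A_eq = C_tot / (1.0 + K)
    C_A = A_eq + (cond.C_A0 - A_eq) * np.exp(-lam * t)
    # rounding can leave C_tot - C_A at -1 ulp when C_B0 = 0
    return StateVector(C_A=C_A, C_B=np.clip(C_tot - C_A, 0.0, None))


def equilibrium_state(cond: ReactionConditions,
                      params: KineticParameters) -> StateVector:
    """Long-time limit: [B]/[A] = K(T) with total lignan conserved."""
    K = equilibrium_constant(cond.T, params.vant_hoff)
    _require(K > 0, "equilibrium constant must be positive")
    C_tot = cond.C_A0 + cond.C_B0
    A_eq = C_tot / (1.0 + K)
    return StateVector(C_A=A_eq, C_B=C_tot - A_eq)


def reference_parameters() -> KineticParameters:
    """Default parameter set for the sesamin/asarinin system at T_ref=353.15 K.

    ln k_ref = 9.74, Ea/(R*T_ref) = 21.4 (Ea ~ 62.8 kJ/mol), K1 = K2 =
    4029.99, K_ref = 0.536, dH_r = 34578 J/mol (endothermic).  These are the
    generating values used throughout the synthetic-data studies.
    """
    return KineticParameters(
        arrhenius=ArrheniusParams(ln_k_ref=9.74, ea_over_RTref=21.4),
        vant_hoff=VantHoffParams(K_ref=0.536, dH_r=34578.0),
        K1=4029.99,
    )
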