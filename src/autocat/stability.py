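"""Analytic steady states and stability of the single-intermediate cycle.

The model: one intermediate X, an autocatalytic reaction fa consuming one X
(plus the assimilated external metabolite A at fixed concentration) and
producing ``1 + delta`` X, and a branch reaction fb draining X out of the
cycle, both irreversible Michaelis-Menten.  The dynamics are

    dX/dt = delta * fa(X) + fi - fb(X)

with an optional constant input flux fi.  Everything here is closed-form:
the positive steady state, its stability, the four-quadrant phase-diagram
label, the parameter sensitivities of X*, and the constraints mapped onto
the bisubstrate parameterizations of fa.

Generalized stoichiometry (a 1:(1+delta) autocatalytic reaction) is handled
throughout by replacing Vmax,a with delta*Vmax,a.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Optional

import numpy as np

from .errors import DomainError, ValidationError
from .kinetics import (
    BisubstrateKinetics,
    MichaelisMentenKinetics,
    apparent_constants,
    mm_derivative,
    mm_flux,
)

__all__ = [
    "SimpleCycleSpec",
    "SteadyState",
    "SteadyStateReport",
    "ReversibleBranchSpec",
    "ReversibleBranchReport",
    "BisubstrateBounds",
    "steady_state_simple",
    "classify_domain",
    "steady_states_with_input",
    "sensitivity_signs",
    "bisubstrate_stable_region",
    "xstar_vs_A",
    "reversible_branch_analysis",
    "reversible_autocatalytic_min_Vmax",
]

#: Relative tolerance below which an inequality is reported as degenerate.
DEGENERACY_RTOL = 1e-12
#: Relative tolerance for analytic/numeric agreement of steady states.
STEADY_STATE_RTOL = 1e-9


@dataclass(frozen=True)
class SimpleCycleSpec:
    """Parameters of the one-intermediate autocatalytic cycle.

    ``delta`` is the autocatalytic gain per unit of X consumed (1 for the
    didactic 1:2 stoichiometry, 1/5 for a CBB-like 5:6 cycle); ``fi`` is a
    constant input flux into X from outside the cycle.
    """

    fa: MichaelisMentenKinetics
    fb: MichaelisMentenKinetics
    delta: float | Fraction = 1
    fi: float = 0.0

    def __post_init__(self):
        if not self.delta > 0:
            raise ValidationError(f"delta must be > 0, got {self.delta}")
        if self.fi < 0:
            raise ValidationError(f"fi must be >= 0, got {self.fi}")

    @property
    def va_eff(self) -> float:
        """delta-scaled autocatalytic Vmax."""
        return float(self.delta) * self.fa.Vmax

    def net_production(self, X: float) -> float:
        """dX/dt = delta*fa(X) + fi - fb(X)."""
        return float(self.delta) * mm_flux(self.fa, X) + self.fi - mm_flux(self.fb, X)

    def net_production_derivative(self, X: float) -> float:
        return float(self.delta) * mm_derivative(self.fa, X) - mm_derivative(self.fb, X)


@dataclass(frozen=True)
class SteadyState:
    X: float
    stable: bool
    flux: float  # branch flux fb(X*) at the state


@dataclass(frozen=True)
class SteadyStateReport:
    states: tuple[SteadyState, ...]
    zero_exists: bool
    zero_stable: bool
    domain: str
    divergent: bool = False

    @property
    def positive_stable(self) -> Optional[SteadyState]:
        for s in self.states:
            if s.stable and s.X > 0:
                return s
        return None


def _close(a: float, b: float, rtol: float = DEGENERACY_RTOL) -> bool:
    return abs(a - b) <= rtol * max(abs(a), abs(b), 1e-300)


def classify_domain(spec: SimpleCycleSpec, rtol: float = DEGENERACY_RTOL) -> str:
    """Phase-diagram quadrant of the no-input cycle.

    * I   -- Vb > d*Va and Vb/Kb < d*Va/Ka: positive stable state, zero unstable
    * II  -- Vb > d*Va and Vb/Kb > d*Va/Ka: zero stable, no positive state
    * III -- Vb < d*Va and Vb/Kb > d*Va/Ka: zero stable, positive unstable state
    * IV  -- Vb < d*Va and Vb/Kb < d*Va/Ka: zero unstable, divergent

    Equalities within ``rtol`` give ``"degenerate"``.
    """
    if spec.fi != 0:
        raise ValidationError("domain classification applies to the fi=0 cycle")
    va, ka = spec.va_eff, spec.fa.KM
    vb, kb = spec.fb.Vmax, spec.fb.KM
    if _close(vb, va, rtol) or _close(vb / kb, va / ka, rtol):
        return "degenerate"
    branch_dominates = vb > va
    zero_unstable = vb / kb < va / ka
    if branch_dominates:
        return "I" if zero_unstable else "II"
    return "IV" if zero_unstable else "III"


def steady_state_simple(spec: SimpleCycleSpec) -> SteadyStateReport:
    """Closed-form steady states of the fi=0 cycle.

    The positive candidate is X* = (Vb*Ka - d*Va*Kb) / (d*Va - Vb); it is
    reported only when positive, with stability from the sign of
    d(delta*fa - fb)/dX at X*.  X = 0 always is a steady state; it is stable
    iff the branch slope at zero exceeds the delta-scaled autocatalytic one.
    """
    if spec.fi != 0:
        raise ValidationError("steady_state_simple requires fi = 0; "
                              "use steady_states_with_input")
    va, ka = spec.va_eff, spec.fa.KM
    vb, kb = spec.fb.Vmax, spec.fb.KM
    domain = classify_domain(spec)
    zero_stable = vb / kb > va / ka
    states: list[SteadyState] = []
    if domain != "degenerate":
        xstar = (vb * ka - va * kb) / (va - vb)
        if xstar > 0:
            stable = spec.net_production_derivative(xstar) < 0
            states.append(SteadyState(xstar, stable, mm_flux(spec.fb, xstar)))
    divergent = domain == "IV"
    return SteadyStateReport(
        states=tuple(states),
        zero_exists=True,
        zero_stable=zero_stable,
        domain=domain,
        divergent=divergent,
    )


def steady_states_with_input(spec: SimpleCycleSpec) -> SteadyStateReport:
    """Steady states with a constant input flux fi > 0.

    Solves fi + delta*fa(X) = fb(X), a quadratic in X.  With
    Vb > fi + delta*Va there is exactly one positive state and it is stable;
    otherwise there are two positive states (the lower one stable) or none,
    in which case the cycle diverges.  Zero is never a steady state.
    """
    if not spec.fi > 0:
        raise ValidationError("steady_states_with_input requires fi > 0")
    va, ka = spec.va_eff, spec.fa.KM
    vb, kb = spec.fb.Vmax, spec.fb.KM
    fi = spec.fi
    # fi*(Ka+X)*(Kb+X) + va*X*(Kb+X) - vb*X*(Ka+X) = 0
    a2 = fi + va - vb
    a1 = fi * (ka + kb) + va * kb - vb * ka
    a0 = fi * ka * kb
    roots: list[float] = []
    if a2 == 0:
        if a1 < 0:
            roots = [-a0 / a1]
    else:
        disc = a1 * a1 - 4 * a2 * a0
        if disc >= 0:
            sq = math.sqrt(disc)
            roots = [(-a1 - sq) / (2 * a2), (-a1 + sq) / (2 * a2)]
    states = []
    for x in sorted(r for r in roots if r > 0):
        stable = spec.net_production_derivative(x) < 0
        states.append(SteadyState(x, stable, mm_flux(spec.fb, x)))
    return SteadyStateReport(
        states=tuple(states),
        zero_exists=False,
        zero_stable=False,
        domain="input",
        divergent=not states,
    )


def sensitivity_signs(spec: SimpleCycleSpec) -> dict[str, float]:
    """Closed-form derivatives of X* with respect to the four parameters.

    Valid in domain I (where the positive state is stable), giving
    dX*/dKM,a < 0, dX*/dKM,b > 0, dX*/dVmax,a > 0, dX*/dVmax,b < 0.
    """
    if classify_domain(spec) != "I":
        raise DomainError("sensitivities assume a domain-I (stable) cycle")
    d = float(spec.delta)
    va, ka = spec.va_eff, spec.fa.KM
    vb, kb = spec.fb.Vmax, spec.fb.KM
    diff = va - vb
    return {
        "KM_a": vb / diff,
        "KM_b": -va / diff,
        "Vmax_a": d * vb * (kb - ka) / diff**2,
        "Vmax_b": va * (ka - kb) / diff**2,
    }


# ---------------------------------------------------------------------------
# bisubstrate constraints


@dataclass(frozen=True)
class BisubstrateBounds:
    """Stability constraints of a bisubstrate autocatalytic reaction.

    ``A_lower`` is the assimilated-metabolite concentration below which no
    positive stable steady state exists (0 for the ping-pong scheme;
    ``inf`` with ``satisfiable=False`` when the defining inequality cannot
    be met by any finite A).  ``A_upper``, when finite, is the concentration
    at which the apparent autocatalytic Vmax reaches Vmax,b and X* runs off
    to infinity.  ``KM_b_lower`` is the scheme's absolute lower bound on the
    branch-reaction KM (``None`` when the scheme imposes none).
    """

    scheme: str
    A_lower: float
    A_upper: Optional[float]
    KM_b_lower: Optional[float]
    satisfiable: bool
    conditions: tuple[str, ...] = ()


def bisubstrate_stable_region(
    b: BisubstrateKinetics,
    branch: MichaelisMentenKinetics,
    delta: float = 1.0,
) -> BisubstrateBounds:
    """Map the existence/stability conditions onto a bisubstrate fa.

    The autocatalytic Vmax is delta-scaled throughout, so the conditions are
    stated for a general 1:(1+delta) stoichiometry.
    """
    V = delta * b.Vmax
    vb, kb = branch.Vmax, branch.KM
    scheme = b.scheme
    if scheme == "ping_pong":
        cond1 = f"Vmax_b > {V}*A/({b.KA}+A)"
        slope_ok = vb / kb < V / b.KX
        a_upper = b.KA * vb / (V - vb) if V > vb else None
        return BisubstrateBounds(
            scheme, 0.0, a_upper, None, satisfiable=slope_ok,
            conditions=(cond1, f"Vmax_b/KM_b < Vmax/KX ({'holds' if slope_ok else 'fails'})"),
        )
    if scheme in ("random_order", "ordered_A_first"):
        denom = kb * V / (vb * b.KX) - 1.0
        if denom <= 0:
            a_lower, satisfiable = math.inf, False
        else:
            a_lower, satisfiable = b.KiA / denom, True
        if scheme == "random_order":
            km_b_lower = b.KX / max(1.0, b.KA / b.KiA)
        else:
            km_b_lower = b.KX
            if V >= vb:
                satisfiable = False  # Vmax_b > Vmax must hold at every A
        a_upper = None
        if scheme == "random_order" and V > vb:
            a_upper = b.KA * vb / (V - vb)
        return BisubstrateBounds(scheme, a_lower, a_upper, km_b_lower, satisfiable)
    # ordered_X_first: no KM_b bound; stability achievable by rate tuning
    a_lower = vb * b.KiX * b.KA / (kb * V)
    a_upper = b.KA * vb / (V - vb) if V > vb else None
    return BisubstrateBounds(scheme, a_lower, a_upper, None, satisfiable=True)


def xstar_vs_A(
    b: BisubstrateKinetics,
    branch: MichaelisMentenKinetics,
    A: float,
    delta: float = 1.0,
) -> float:
    """Steady-state X* as a function of the assimilated concentration A.

    Evaluates the scheme-specific closed form (for the ping-pong scheme, the
    composition of the apparent-constant reduction with the simple-cycle
    solution, which is exact).  Returns 0 at the scheme's lower bound on A
    and raises :class:`DomainError` below it.
    """
    bounds = bisubstrate_stable_region(b, branch, delta)
    if not bounds.satisfiable:
        raise DomainError(f"{b.scheme}: no finite A satisfies stability")
    if A < bounds.A_lower and not _close(A, bounds.A_lower, 1e-12):
        raise DomainError(f"A={A} below the scheme lower bound {bounds.A_lower}")
    if _close(A, bounds.A_lower, 1e-12):
        return 0.0
    V = delta * b.Vmax
    vb, kb = branch.Vmax, branch.KM
    if b.scheme == "ping_pong":
        app = apparent_constants(b, A)
        report = steady_state_simple(SimpleCycleSpec(fa=app, fb=branch, delta=delta))
        for s in report.states:
            return s.X
        return 0.0
    if b.scheme == "random_order":
        vtilde = V * A / (b.KA + A)
        num = vtilde * kb - vb * (b.KiA + A) / (b.KA + A) * b.KX
        den = vb - vtilde
    elif b.scheme == "ordered_A_first":
        num = V * kb - vb * (b.KiA + A) / A * b.KX
        den = vb - V
    else:  # ordered_X_first
        vtilde = V * A / (b.KA + A)
        num = vtilde * kb - vb * b.KiX * b.KA / (b.KA + A)
        den = vb - vtilde
    if den <= 0:
        raise DomainError(
            f"{b.scheme}: apparent autocatalytic Vmax exceeds Vmax_b at A={A}; "
            "X* diverges"
        )
    return num / den


# ---------------------------------------------------------------------------
# reversible branch reaction


@dataclass(frozen=True)
class ReversibleBranchSpec:
    """Cycle with a reversible branch fb (product Y) and linear sink fc = D*Y.

    Y is measured in units of Keq*X, fixing the branch equilibrium constant
    to 1; KY is retained as a free parameter of the reversible MM law
    fb = Vmax_b*(X - Y)/(KX + X + (KX/KY)*Y).
    """

    fa: MichaelisMentenKinetics
    Vmax_b: float
    KX: float
    KY: float
    D: float

    def __post_init__(self):
        for name in ("Vmax_b", "KX", "KY", "D"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0")

    def fb(self, X: float, Y: float) -> float:
        return self.Vmax_b * (X - Y) / (self.KX + X + self.KX * Y / self.KY)

    def jacobian(self, X: float, Y: float) -> np.ndarray:
        alpha = mm_derivative(self.fa, X)
        denom = (self.KX + X + self.KX * Y / self.KY) ** 2
        beta_x = self.Vmax_b * (self.KX + Y * (1 + self.KX / self.KY)) / denom
        beta_y = -self.Vmax_b * (self.KX + X * (1 + self.KX / self.KY)) / denom
        return np.array([[alpha - beta_x, -beta_y], [beta_x, beta_y - self.D]])


@dataclass(frozen=True)
class ReversibleBranchReport:
    states: tuple[tuple[float, float, bool], ...]  # (X*, Y*, stable)
    regime: str  # "fast_sink" (irreversible-like) or "slow_sink"
    globally_stabilizable: bool


def reversible_branch_analysis(spec: ReversibleBranchSpec) -> ReversibleBranchReport:
    """Positive steady states of the reversible-branch cycle and their
    stability from the 2x2 Jacobian trace/determinant conditions.

    With Vmax_b <= Vmax_a no positive state can be globally stable (the
    branch cannot absorb fluxes near Vmax_a), which is flagged.  The regime
    label compares the sink rate D with the autocatalytic slope at zero:
    a fast sink keeps Y low and reproduces the irreversible analysis.
    """
    va, ka = spec.fa.Vmax, spec.fa.KM
    vb, kx, ky, D = spec.Vmax_b, spec.KX, spec.KY, spec.D
    globally_ok = vb > va
    regime = "fast_sink" if D > va / ka else "slow_sink"
    states: list[tuple[float, float, bool]] = []
    if vb != va:
        b1 = (2 * ka * vb - (ka + kx) * va - kx * va**2 / (ky * D) - va * vb / D) / (vb - va)
        c0 = ka * (vb * ka - va * kx - va * vb / D) / (vb - va)
        disc = b1 * b1 - 4 * c0
        if disc >= 0:
            sq = math.sqrt(disc)
            for x in sorted({(-b1 - sq) / 2, (-b1 + sq) / 2}):
                if x <= 0:
                    continue
                y = (va / D) * x / (ka + x)
                J = spec.jacobian(x, y)
                tr = J[0, 0] + J[1, 1]
                det = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
                states.append((x, y, bool(tr < 0 and det > 0)))
    return ReversibleBranchReport(
        states=tuple(states), regime=regime, globally_stabilizable=globally_ok
    )


def reversible_autocatalytic_min_Vmax(
    fa_slope_at_zero: float, branch: MichaelisMentenKinetics
) -> bool:
    """Sufficient condition for a positive steady state when the
    autocatalytic reaction itself is reversible: the slope of fa at X=0
    (at the fixed assimilated concentration) must strictly exceed the branch
    slope Vmax_b/KM_b.  Raising Vmax_a raises the slope, so a minimal
    Vmax_a always exists above which this holds."""
    if fa_slope_at_zero <= 0:
        raise ValidationError("slope must be positive")
    return fa_slope_at_zero > branch.Vmax / branch.KM
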