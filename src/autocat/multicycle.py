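"""Stability of n-reaction autocatalytic cycles.

The cycle is a chain X1 -> X2 -> ... -> Xn -> (1+delta) X1 of reactions
fa1..fan, with an optional branch reaction fbi draining each intermediate.
At a steady state the linearization is fully described by the derivatives
alpha_i = dfa_i/dXi and beta_i = dfb_i/dXi, collected in a
:class:`CycleLinearization`; the Jacobian has -(alpha_i + beta_i) on the
diagonal, alpha_i on the subdiagonal, and (1+delta)*alpha_n in the upper
right corner.

Stability can be settled numerically (:func:`eigen_stability`) or by the
sufficient condition that some branch is steeper than its cycle reaction
(beta_i > alpha_i), which also guarantees the characteristic-polynomial
product criterion prod(1 + beta_i/alpha_i) > 1 + delta.  The product
criterion and the chain balance inequalities are valid for autocatalytic
ratios up to 1:2 (delta <= 1); larger gains are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import prod
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .errors import NotSteadyStateError, ValidationError
from .kinetics import MichaelisMentenKinetics, mm_derivative, mm_flux

__all__ = [
    "CycleLinearization",
    "MultiCycleKineticSpec",
    "SufficiencyReport",
    "FluxOrderingReport",
    "build_jacobian",
    "eigen_stability",
    "sufficient_stability",
    "flux_ordering_check",
    "perturbation_response",
    "linearize",
    "solve_steady_state",
]

#: Eigenvalues with real part above -MARGINAL_TOL are treated as marginal.
MARGINAL_TOL = 1e-10


@dataclass(frozen=True)
class CycleLinearization:
    """Per-position derivatives of an n-reaction cycle at a steady state.

    ``autocatalytic_factor`` is 1 + delta, the corner amplification of the
    assimilating reaction; it must lie in (1, 2] (gains above 1:2 fall
    outside the validity range of the product criterion).
    """

    alphas: tuple[float, ...]
    betas: tuple[float, ...]
    autocatalytic_factor: float = 2.0

    def __post_init__(self):
        object.__setattr__(self, "alphas", tuple(float(a) for a in self.alphas))
        object.__setattr__(self, "betas", tuple(float(b) for b in self.betas))
        if len(self.alphas) != len(self.betas) or not self.alphas:
            raise ValidationError("alphas and betas must be equal-length, nonempty")
        if any(a <= 0 for a in self.alphas):
            raise ValidationError("all alpha_i must be > 0")
        if any(b < 0 for b in self.betas):
            raise ValidationError("all beta_i must be >= 0")
        if not 1.0 < self.autocatalytic_factor <= 2.0:
            raise ValidationError(
                "autocatalytic_factor must be in (1, 2]: the analysis is valid "
                "only up to a 1:2 autocatalytic ratio"
            )

    @property
    def n(self) -> int:
        return len(self.alphas)


def build_jacobian(lin: CycleLinearization) -> np.ndarray:
    """Jacobian of the linearized chain.

    For n = 1 the chain collapses to the simple model and the single entry
    is (factor - 1)*alpha_1 - beta_1, i.e. delta*fa' - fb'.
    """
    n = lin.n
    if n == 1:
        return np.array([[(lin.autocatalytic_factor - 1.0) * lin.alphas[0] - lin.betas[0]]])
    J = np.zeros((n, n))
    for i in range(n):
        J[i, i] = -(lin.alphas[i] + lin.betas[i])
        if i + 1 < n:
            J[i + 1, i] = lin.alphas[i]
    J[0, n - 1] = lin.autocatalytic_factor * lin.alphas[n - 1]
    return J


def eigen_stability(J: np.ndarray, tol: float = MARGINAL_TOL) -> bool:
    """True iff every eigenvalue has real part below ``-tol``."""
    J = np.asarray(J, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValidationError("J must be a square matrix")
    return bool(np.max(np.linalg.eigvals(J).real) < -tol)


def stability_verdict(J: np.ndarray, tol: float = MARGINAL_TOL) -> str:
    """"stable" / "marginal" / "unstable" by the leading eigenvalue."""
    lead = float(np.max(np.linalg.eigvals(np.asarray(J, dtype=float)).real))
    if lead < -tol:
        return "stable"
    if lead <= tol:
        return "marginal"
    return "unstable"


@dataclass(frozen=True)
class SufficiencyReport:
    sufficient: bool  # some beta_i > alpha_i
    product: float  # prod(1 + beta_i/alpha_i)
    threshold: float  # the autocatalytic factor
    product_exceeds: bool

    def __bool__(self) -> bool:
        return self.sufficient


def sufficient_stability(lin: CycleLinearization) -> SufficiencyReport:
    """The one-steep-branch sufficient condition and the product criterion.

    ``sufficient`` is True iff beta_i > alpha_i for some i, which implies
    stability.  The report also carries prod(1 + beta_i/alpha_i) and whether
    it exceeds the autocatalytic factor (the sharper criterion from the
    characteristic polynomial; equality is the marginal, zero-eigenvalue
    case)."""
    product = prod(1.0 + b / a for a, b in zip(lin.alphas, lin.betas))
    return SufficiencyReport(
        sufficient=any(b > a for a, b in zip(lin.alphas, lin.betas)),
        product=product,
        threshold=lin.autocatalytic_factor,
        product_exceeds=product > lin.autocatalytic_factor,
    )


def perturbation_response(
    lin: CycleLinearization, j: int, dXj: float
) -> np.ndarray:
    """First-order instantaneous response J.e_j*dXj to a deviation at
    position ``j`` (0-based).

    The self-damping component is -(alpha_j + beta_j)*dXj; the component
    passed to the next intermediate is alpha_j*dXj, amplified to
    factor*alpha_n*dXj when j is the assimilating position n-1."""
    if not 0 <= j < lin.n:
        raise ValidationError(f"position {j} outside 0..{lin.n - 1}")
    delta_vec = np.zeros(lin.n)
    delta_vec[j] = dXj
    return build_jacobian(lin) @ delta_vec


# ---------------------------------------------------------------------------
# kinetic cycle specifications


@dataclass(frozen=True)
class MultiCycleKineticSpec:
    """MM kinetics of an n-reaction cycle; ``branch_kinetics[i]`` may be
    ``None`` for positions with no branch (beta_i = 0).  The last cycle
    reaction assimilates with gain ``delta`` per unit consumed."""

    cycle_kinetics: tuple[MichaelisMentenKinetics, ...]
    branch_kinetics: tuple[Optional[MichaelisMentenKinetics], ...]
    delta: float | Fraction = 1

    def __post_init__(self):
        object.__setattr__(self, "cycle_kinetics", tuple(self.cycle_kinetics))
        object.__setattr__(self, "branch_kinetics", tuple(self.branch_kinetics))
        if len(self.cycle_kinetics) != len(self.branch_kinetics) or not self.cycle_kinetics:
            raise ValidationError("cycle and branch kinetics must be equal-length, nonempty")
        if not any(b is not None for b in self.branch_kinetics):
            raise ValidationError("at least one branch reaction is required")
        if not 0 < float(self.delta) <= 1:
            raise ValidationError(
                "delta must be in (0, 1]: the analysis is valid only up to a "
                "1:2 autocatalytic ratio"
            )

    @property
    def n(self) -> int:
        return len(self.cycle_kinetics)

    def fa(self, i: int, X: float) -> float:
        return mm_flux(self.cycle_kinetics[i], X)

    def fb(self, i: int, X: float) -> float:
        k = self.branch_kinetics[i]
        return 0.0 if k is None else mm_flux(k, X)

    def rhs(self, X: Sequence[float]) -> np.ndarray:
        """dXi/dt: X1 receives (1+delta)*fan, each Xi feeds fai + fbi."""
        n = self.n
        d = float(self.delta)
        fa = [self.fa(i, X[i]) for i in range(n)]
        fb = [self.fb(i, X[i]) for i in range(n)]
        out = np.empty(n)
        out[0] = (1.0 + d) * fa[n - 1] - fa[0] - fb[0]
        for i in range(1, n):
            out[i] = fa[i - 1] - fa[i] - fb[i]
        return out


def linearize(spec: MultiCycleKineticSpec, xstars: Sequence[float]) -> CycleLinearization:
    """Analytic derivatives alpha_i, beta_i at the supplied steady state."""
    if len(xstars) != spec.n:
        raise ValidationError("xstars length must match the cycle size")
    alphas = [mm_derivative(spec.cycle_kinetics[i], xstars[i]) for i in range(spec.n)]
    betas = [
        0.0 if spec.branch_kinetics[i] is None else mm_derivative(spec.branch_kinetics[i], xstars[i])
        for i in range(spec.n)
    ]
    return CycleLinearization(tuple(alphas), tuple(betas), 1.0 + float(spec.delta))


def solve_steady_state(
    spec: MultiCycleKineticSpec,
    x0: Sequence[float] | None = None,
    tol: float = 1e-12,
) -> Optional[np.ndarray]:
    """Numerically solve rhs(X) = 0 for a positive steady state.

    Returns the concentration vector or ``None`` if the solver does not find
    a strictly positive root.  Solved in log-concentrations so the iterates
    stay positive; roots that collapse onto the zero state are rejected.
    Without an explicit guess, several starting scales around the KM values
    are tried."""
    n = spec.n
    kms = np.array([spec.cycle_kinetics[i].KM for i in range(n)])
    if x0 is None:
        guesses = [c * kms for c in (1.0, 10.0, 100.0, 0.1, 1000.0)]
    else:
        x0 = np.asarray(x0, dtype=float)
        if np.any(x0 <= 0):
            raise ValidationError("initial guess must be strictly positive")
        guesses = [x0]
    vscale = max(k.Vmax for k in spec.cycle_kinetics)
    for guess in guesses:
        sol = optimize.root(
            lambda u: spec.rhs(np.exp(np.clip(u, -700.0, 700.0))),
            np.log(guess),
            method="hybr",
            options={"xtol": 1e-13},
        )
        x = np.exp(sol.x)
        if not sol.success or np.max(np.abs(spec.rhs(x))) > tol * vscale:
            continue
        if np.max(x) < 1e-9 * np.max(kms):
            continue  # found the zero state, not a positive one
        return x
    return None


@dataclass(frozen=True)
class FluxOrderingReport:
    ok: bool
    fa: tuple[float, ...]
    fb: tuple[float, ...]
    slack_lower: tuple[float, ...]  # fan - fbi >= 0
    slack_upper: tuple[float, ...]  # fai - fan >= 0
    balance_residual: float  # sum(fbi) - delta*fan


def flux_ordering_check(
    spec: MultiCycleKineticSpec,
    xstars: Sequence[float],
    rtol: float = 1e-9,
) -> FluxOrderingReport:
    """Verify the chain balance at a steady state: fbi <= fan <= fai for all
    i and sum(fbi) = delta*fan.

    The supplied state is first validated by substitution into the ODE
    right-hand side; a residual above tolerance raises
    :class:`NotSteadyStateError`."""
    n = spec.n
    scale = max(k.Vmax for k in spec.cycle_kinetics)
    resid = np.max(np.abs(spec.rhs(xstars)))
    if resid > rtol * scale:
        raise NotSteadyStateError(
            f"substitution residual {resid:.3e} exceeds {rtol * scale:.3e}: "
            "not a steady state"
        )
    fa = tuple(spec.fa(i, xstars[i]) for i in range(n))
    fb = tuple(spec.fb(i, xstars[i]) for i in range(n))
    fan = fa[n - 1]
    slack_lower = tuple(fan - v for v in fb)
    slack_upper = tuple(v - fan for v in fa)
    balance = sum(fb) - float(spec.delta) * fan
    tol = rtol * scale
    ok = bool(
        all(s >= -tol for s in slack_lower)
        and all(s >= -tol for s in slack_upper)
        and abs(balance) <= tol
    )
    return FluxOrderingReport(ok, fa, fb, slack_lower, slack_upper, balance)
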