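"""ODE integration of the cycle models.

A thin layer over :func:`scipy.integrate.solve_ivp` (LSODA, stiff-capable)
that integrates the simple one-intermediate cycle or an n-reaction chain,
classifies the outcome (converged to a positive state, collapsed to zero,
diverged, or undecided within the horizon), and measures convergence times.

Numerical conventions: relative tolerance 1e-9, absolute 1e-12; divergence
is declared when any concentration exceeds 1e3 times the largest KM (every
Michaelis-Menten flux is then saturated to better than 0.1%, so no further
structure exists beyond the cap; a far larger cap would make slowly escaping
trajectories undecidable within any reasonable horizon); convergence when
|dX/dt| drops below 1e-10 times the Vmax scale.  The default horizon is 1e4
characteristic times KM_a/Vmax_a.  Both are overridable per call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DomainError, ValidationError
from .multicycle import MultiCycleKineticSpec
from .stability import SimpleCycleSpec

__all__ = ["Trajectory", "simulate_simple", "simulate_multi", "convergence_time"]

RTOL = 1e-9
ATOL = 1e-12
DIVERGENCE_FACTOR = 1e3
CONVERGENCE_FACTOR = 1e-10
DEFAULT_HORIZON_CHARTIMES = 1e4


@dataclass(frozen=True)
class Trajectory:
    times: np.ndarray  # strictly increasing
    states: np.ndarray  # (len(times), n_intermediates)
    outcome: str  # converged_positive | converged_zero | diverged | undecided
    final_state: np.ndarray

    @property
    def initial_state(self) -> np.ndarray:
        return self.states[0]


def _integrate(rhs, x0, t_max, x_cap, v_scale, zero_scale):
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    if np.any(x0 < 0):
        raise DomainError("initial concentrations must be >= 0")

    def diverged_event(t, x):
        return np.max(x) - x_cap

    diverged_event.terminal = True
    diverged_event.direction = 1

    def converged_event(t, x):
        return np.max(np.abs(rhs(t, x))) - CONVERGENCE_FACTOR * v_scale

    converged_event.terminal = True
    converged_event.direction = -1

    sol = solve_ivp(
        rhs,
        (0.0, t_max),
        x0,
        method="LSODA",
        rtol=RTOL,
        atol=ATOL,
        events=[diverged_event, converged_event],
        dense_output=False,
    )
    states = sol.y.T
    if np.min(states) < -1e-12:
        import warnings

        warnings.warn("integrator produced slightly negative concentrations; clipped")
    states = np.clip(states, 0.0, None)
    final = states[-1]
    if sol.status == 1 and len(sol.t_events[0]):
        outcome = "diverged"
    elif sol.status == 1 and len(sol.t_events[1]):
        outcome = "converged_zero" if np.max(final) < zero_scale else "converged_positive"
    elif sol.status == 0:
        # horizon reached without triggering an event
        if np.max(np.abs(rhs(sol.t[-1], final))) < 10 * CONVERGENCE_FACTOR * v_scale:
            outcome = "converged_zero" if np.max(final) < zero_scale else "converged_positive"
        else:
            outcome = "undecided"
    else:
        outcome = "undecided"
    return Trajectory(sol.t, states, outcome, final)


def simulate_simple(
    spec: SimpleCycleSpec, X0: float, T: float | None = None, x_cap: float | None = None
) -> Trajectory:
    """Integrate dX/dt = delta*fa(X) + fi - fb(X) from X0."""
    if T is None:
        T = DEFAULT_HORIZON_CHARTIMES * spec.fa.KM / spec.fa.Vmax
    if T <= 0:
        raise ValidationError("T must be > 0")
    k_scale = max(spec.fa.KM, spec.fb.KM)
    v_scale = max(spec.va_eff, spec.fb.Vmax, spec.fi)
    if x_cap is None:
        x_cap = DIVERGENCE_FACTOR * max(k_scale, X0)
    # clip: the integrator may probe infinitesimally negative states
    return _integrate(
        lambda t, x: np.array([spec.net_production(max(float(x[0]), 0.0))]),
        [X0],
        T,
        x_cap,
        v_scale,
        zero_scale=1e-6 * k_scale,
    )


def simulate_multi(
    spec: MultiCycleKineticSpec,
    X0: Sequence[float],
    T: float | None = None,
    x_cap: float | None = None,
) -> Trajectory:
    """Integrate the n-reaction chain from the concentration vector X0."""
    if T is None:
        k = spec.cycle_kinetics[0]
        T = DEFAULT_HORIZON_CHARTIMES * k.KM / k.Vmax
    if T <= 0:
        raise ValidationError("T must be > 0")
    kms = [k.KM for k in spec.cycle_kinetics] + [
        b.KM for b in spec.branch_kinetics if b is not None
    ]
    vscale = max(k.Vmax for k in spec.cycle_kinetics)
    if x_cap is None:
        x_cap = DIVERGENCE_FACTOR * max(max(kms), np.max(np.atleast_1d(X0)))
    return _integrate(
        lambda t, x: spec.rhs(np.clip(x, 0.0, None)),
        X0,
        T,
        x_cap,
        vscale,
        zero_scale=1e-6 * max(kms),
    )


def convergence_time(traj: Trajectory, fraction: float) -> float:
    """First time the deviation from the final state falls below
    ``fraction`` of the initial deviation and stays below.

    Only defined for converged trajectories; ``fraction=1`` gives 0.
    """
    if traj.outcome not in ("converged_positive", "converged_zero"):
        raise ValidationError(f"trajectory outcome is {traj.outcome!r}, not converged")
    if not 0 < fraction <= 1:
        raise ValidationError("fraction must be in (0, 1]")
    dev = np.linalg.norm(traj.states - traj.final_state, axis=1)
    initial = dev[0]
    if initial == 0 or fraction == 1:
        return 0.0
    threshold = fraction * initial
    above = np.nonzero(dev > threshold)[0]
    if len(above) == 0:
        return 0.0
    last_above = above[-1]
    if last_above + 1 >= len(traj.times):
        raise ValidationError("deviation never settles below the threshold")
    return float(traj.times[last_above + 1])
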