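"""Flux laws: irreversible Michaelis-Menten and bisubstrate mechanisms.

The central objects are :class:`MichaelisMentenKinetics` (a ``Vmax``/``KM``
bundle) and :class:`BisubstrateKinetics`, which covers the four classic
irreversible bisubstrate schemes (substituted-enzyme "ping pong", random
binding order, and the two ordered ternary-complex variants).  When the
assimilated co-substrate A is held at a constant concentration every scheme
collapses to an apparent Michaelis-Menten law in the cycle intermediate X;
:func:`apparent_constants` returns that reduction exactly.

Concentrations and rates are unit-agnostic positive reals; unit consistency
is the caller's contract.  Negative concentrations raise
:class:`~autocat.errors.DomainError` rather than being clipped, because the
downstream stability analysis is sign-sensitive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

from .errors import DomainError, ValidationError

__all__ = [
    "MichaelisMentenKinetics",
    "BisubstrateKinetics",
    "AssimilatedContext",
    "BISUBSTRATE_SCHEMES",
    "mm_flux",
    "mm_derivative",
    "saturation",
    "elasticity",
    "apparent_constants",
    "bisubstrate_flux",
    "load_kinetics_config",
]

BISUBSTRATE_SCHEMES = ("ping_pong", "random_order", "ordered_A_first", "ordered_X_first")


@dataclass(frozen=True)
class MichaelisMentenKinetics:
    """Irreversible Michaelis-Menten parameters: f(X) = Vmax*X/(KM+X)."""

    Vmax: float
    KM: float

    def __post_init__(self):
        if not self.Vmax > 0:
            raise ValidationError(f"Vmax must be > 0, got {self.Vmax}")
        if not self.KM > 0:
            raise ValidationError(f"KM must be > 0, got {self.KM}")

    def flux(self, X: float) -> float:
        return mm_flux(self, X)

    def derivative(self, X: float) -> float:
        return mm_derivative(self, X)

    @property
    def slope_at_zero(self) -> float:
        """Vmax/KM, the first-order rate constant at vanishing substrate."""
        return self.Vmax / self.KM


@dataclass(frozen=True)
class AssimilatedContext:
    """Concentration of the assimilated external metabolite, held constant."""

    A: float

    def __post_init__(self):
        if self.A < 0:
            raise ValidationError(f"A must be >= 0, got {self.A}")


@dataclass(frozen=True)
class BisubstrateKinetics:
    """Parameters of an irreversible bisubstrate reaction f(A, X).

    ``scheme`` selects the mechanism; constants that a scheme does not use
    must be left ``None``:

    ==================  ==========================
    scheme              constants
    ==================  ==========================
    ping_pong           Vmax, KA, KX
    random_order        Vmax, KA, KX, KiA
    ordered_A_first     Vmax, KX, KiA
    ordered_X_first     Vmax, KA, KiX
    ==================  ==========================
    """

    scheme: str
    Vmax: float
    KA: Optional[float] = None
    KX: Optional[float] = None
    KiA: Optional[float] = None
    KiX: Optional[float] = None

    _REQUIRED = {
        "ping_pong": ("KA", "KX"),
        "random_order": ("KA", "KX", "KiA"),
        "ordered_A_first": ("KX", "KiA"),
        "ordered_X_first": ("KA", "KiX"),
    }

    def __post_init__(self):
        if self.scheme not in BISUBSTRATE_SCHEMES:
            raise ValidationError(f"unknown bisubstrate scheme {self.scheme!r}")
        if not self.Vmax > 0:
            raise ValidationError(f"Vmax must be > 0, got {self.Vmax}")
        required = self._REQUIRED[self.scheme]
        for name in ("KA", "KX", "KiA", "KiX"):
            value = getattr(self, name)
            if name in required:
                if value is None or not value > 0:
                    raise ValidationError(f"scheme {self.scheme!r} needs {name} > 0")
            elif value is not None:
                raise ValidationError(f"scheme {self.scheme!r} does not use {name}")

    def flux(self, X: float, A: float) -> float:
        return bisubstrate_flux(self, X, A)


# ---------------------------------------------------------------------------
# single-substrate operations


def _check_nonneg(X: float) -> None:
    if X < 0:
        raise DomainError(f"concentration must be >= 0, got {X}")


def mm_flux(k: MichaelisMentenKinetics, X: float) -> float:
    """Vmax*X/(KM+X): zero at X=0, strictly increasing, bounded by Vmax."""
    _check_nonneg(X)
    return k.Vmax * X / (k.KM + X)


def mm_derivative(k: MichaelisMentenKinetics, X: float) -> float:
    """df/dX = Vmax*KM/(KM+X)^2; equals Vmax/KM at X=0."""
    _check_nonneg(X)
    return k.Vmax * k.KM / (k.KM + X) ** 2


def saturation(k: MichaelisMentenKinetics, X: float) -> float:
    """S = f/Vmax = X/(KM+X), the fraction of capacity in use."""
    _check_nonneg(X)
    return X / (k.KM + X)


def elasticity(k: MichaelisMentenKinetics, X: float) -> float:
    """Normalized sensitivity (df/dX)*(X/f) = KM/(KM+X) for MM kinetics."""
    if X <= 0:
        raise DomainError(f"elasticity requires X > 0, got {X}")
    return k.KM / (k.KM + X)


# ---------------------------------------------------------------------------
# bisubstrate reduction


def bisubstrate_flux(b: BisubstrateKinetics, X: float, A: float) -> float:
    """Direct evaluation of the scheme's full rate law."""
    _check_nonneg(X)
    _check_nonneg(A)
    if b.scheme == "ping_pong":
        denom = b.KX * A + b.KA * X + A * X
    elif b.scheme == "random_order":
        denom = b.KiA * b.KX + b.KX * A + b.KA * X + A * X
    elif b.scheme == "ordered_A_first":
        denom = b.KiA * b.KX + b.KX * A + A * X
    else:  # ordered_X_first
        denom = b.KiX * b.KA + b.KA * X + A * X
    if denom == 0:
        return 0.0
    return b.Vmax * A * X / denom


def apparent_constants(
    b: BisubstrateKinetics, ctx: AssimilatedContext | float
) -> MichaelisMentenKinetics:
    """Apparent (Vmax, KM) of the reduction at fixed A.

    The reductions are exact: ``mm_flux(apparent_constants(b, A), X)``
    reproduces ``bisubstrate_flux(b, X, A)`` for every X.
    """
    A = ctx.A if isinstance(ctx, AssimilatedContext) else float(ctx)
    if A <= 0:
        raise DomainError(f"apparent constants require A > 0, got {A}")
    if b.scheme == "ping_pong":
        vmax = b.Vmax * A / (b.KA + A)
        km = b.KX * A / (b.KA + A)
    elif b.scheme == "random_order":
        vmax = b.Vmax * A / (b.KA + A)
        km = b.KX * (b.KiA + A) / (b.KA + A)
    elif b.scheme == "ordered_A_first":
        vmax = b.Vmax
        km = b.KX * (b.KiA + A) / A
    else:  # ordered_X_first
        vmax = b.Vmax * A / (b.KA + A)
        km = b.KiX * b.KA / (b.KA + A)
    return MichaelisMentenKinetics(Vmax=vmax, KM=km)


# ---------------------------------------------------------------------------
# configuration I/O


def load_kinetics_config(path):
    """Read a kinetic parameter bundle from JSON.

    ``{"type": "michaelis_menten", "Vmax": ..., "KM": ...}`` or
    ``{"type": "bisubstrate", "scheme": ..., <constants>}``.
    """
    data = json.loads(Path(path).read_text())
    kind = data.pop("type", None)
    if kind == "michaelis_menten":
        return MichaelisMentenKinetics(**data)
    if kind == "bisubstrate":
        return BisubstrateKinetics(**data)
    raise ValidationError(f"unknown kinetics config type {kind!r}")
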