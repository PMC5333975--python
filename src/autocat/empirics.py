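"""Saturation audits of branch points from flux and enzyme tables.

The stability theory predicts that, at an operating autocatalytic cycle,
the branch reaction at one or more branch points must be less saturated
than the corresponding cycle reaction.  This module estimates saturations
from tabular data the way the in-vivo analysis does:

* the maximal in-vivo catalytic rate of a reaction is the maximum across
  conditions of flux per unit enzyme (a *lower bound* on the true turnover
  capability, since no condition need run the enzyme at full saturation);
* capacity under a condition is that rate times the enzyme amount, and
  saturation is flux divided by capacity.

A synthetic-table generator produces flux/enzyme tables from a kinetic
cycle model whose steady states are solved and eigenvalue-checked, so every
audit is testable against known ground truth without external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .kinetics import MichaelisMentenKinetics, mm_flux, saturation
from .multicycle import (
    MultiCycleKineticSpec,
    eigen_stability,
    build_jacobian,
    linearize,
    solve_steady_state,
)

__all__ = [
    "FluxTable",
    "EnzymeTable",
    "BranchPointSpec",
    "SaturationAuditRow",
    "RegulationEdge",
    "SyntheticGroundTruth",
    "max_in_vivo_rate",
    "capacity_and_saturation",
    "audit_branch_points",
    "expected_regulation",
    "audit_regulation",
    "generate_synthetic_tables",
]


class _ReactionConditionTable:
    """Reaction x condition matrix of non-negative values."""

    value_name = "value"

    def __init__(self, values: pd.DataFrame):
        if values.empty or values.shape[1] == 0:
            raise ValidationError("table needs at least one reaction and condition")
        if (values.to_numpy() < 0).any():
            raise ValidationError(f"{self.value_name} values must be >= 0")
        self.values = values.astype(float)

    @property
    def reactions(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.values.columns)

    def get(self, reaction: str, condition: str) -> float:
        try:
            return float(self.values.at[reaction, condition])
        except KeyError:
            raise ValidationError(
                f"no entry for reaction {reaction!r}, condition {condition!r}"
            ) from None

    @classmethod
    def from_long(cls, df: pd.DataFrame):
        cols = {"reaction", "condition", cls.value_name}
        if not cols.issubset(df.columns):
            raise ValidationError(f"long table needs columns {sorted(cols)}")
        wide = df.pivot(index="reaction", columns="condition", values=cls.value_name)
        if wide.isna().any().any():
            raise ValidationError("table has missing (reaction, condition) entries")
        return cls(wide)

    @classmethod
    def read_tsv(cls, path):
        return cls.from_long(pd.read_csv(path, sep="\t"))

    def to_long(self) -> pd.DataFrame:
        long = self.values.stack().rename(self.value_name).reset_index()
        long.columns = ["reaction", "condition", self.value_name]
        return long

    def write_tsv(self, path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)


class FluxTable(_ReactionConditionTable):
    """Fluxes (direction pre-resolved to non-negative magnitudes)."""

    value_name = "flux"


class EnzymeTable(_ReactionConditionTable):
    """Enzyme abundances in arbitrary consistent units."""

    value_name = "abundance"


@dataclass(frozen=True)
class BranchPointSpec:
    """A metabolite consumed by a cycle reaction and by a branch reaction."""

    metabolite: str
    cycle_reaction: str
    branch_reaction: str

    def __post_init__(self):
        if self.cycle_reaction == self.branch_reaction:
            raise ValidationError("cycle and branch reactions must differ")


@dataclass(frozen=True)
class SaturationAuditRow:
    branch_point: BranchPointSpec
    condition: str
    S_branch: float
    S_cycle: float
    verdict: str  # branch_less_saturated | similar | branch_more_saturated


# ---------------------------------------------------------------------------
# capacity estimation


def max_in_vivo_rate(flux: FluxTable, enzyme: EnzymeTable, reaction: str) -> float:
    """max over conditions of flux/enzyme: a lower bound on the enzyme's
    true maximal catalytic rate.

    Conditions with zero enzyme and zero flux are skipped; zero enzyme with
    positive flux is inconsistent data and raises."""
    ratios = []
    conditions = [c for c in flux.conditions if c in set(enzyme.conditions)]
    for c in conditions:
        f = flux.get(reaction, c)
        e = enzyme.get(reaction, c)
        if e == 0:
            if f > 0:
                raise ValidationError(
                    f"reaction {reaction!r}, condition {c!r}: flux {f} with zero enzyme"
                )
            continue
        ratios.append(f / e)
    usable = [r for r in ratios if r > 0]
    if not usable:
        raise ValidationError(f"reaction {reaction!r}: no usable condition")
    return max(usable)


def capacity_and_saturation(
    flux: FluxTable, enzyme: EnzymeTable, reaction: str, condition: str
) -> tuple[float, float]:
    """Estimated maximal flux capacity and the saturation flux/capacity.

    Saturations above 1 (possible under measurement noise, since capacity is
    a lower bound) are capped at 1 with a warning."""
    rate = max_in_vivo_rate(flux, enzyme, reaction)
    capacity = rate * enzyme.get(reaction, condition)
    if capacity == 0:
        raise ValidationError(
            f"reaction {reaction!r}: zero capacity under condition {condition!r}"
        )
    sat = flux.get(reaction, condition) / capacity
    if sat > 1.0:
        warnings.warn(
            f"saturation {sat:.3f} > 1 for {reaction!r}@{condition!r}; capped at 1"
        )
        sat = 1.0
    return capacity, sat


def audit_branch_points(
    flux: FluxTable,
    enzyme: EnzymeTable,
    branch_points: Sequence[BranchPointSpec],
    condition: str,
    similar_band: float = 0.1,
) -> tuple[list[SaturationAuditRow], dict[str, int]]:
    """Compare branch vs cycle saturation at each branch point.

    Verdicts use a relative "similar" band: branch_less_saturated when
    S_branch < S_cycle*(1 - band), branch_more_saturated when
    S_cycle < S_branch*(1 - band), otherwise similar.
    """
    rows = []
    counts = {"branch_less_saturated": 0, "similar": 0, "branch_more_saturated": 0}
    for bp in branch_points:
        _, s_cycle = capacity_and_saturation(flux, enzyme, bp.cycle_reaction, condition)
        _, s_branch = capacity_and_saturation(flux, enzyme, bp.branch_reaction, condition)
        if s_branch < s_cycle * (1.0 - similar_band):
            verdict = "branch_less_saturated"
        elif s_cycle < s_branch * (1.0 - similar_band):
            verdict = "branch_more_saturated"
        else:
            verdict = "similar"
        counts[verdict] += 1
        rows.append(SaturationAuditRow(bp, condition, s_branch, s_cycle, verdict))
    return rows, counts


# ---------------------------------------------------------------------------
# allosteric-regulation rule table

REGULATOR_CLASSES = ("cycle_intermediate", "assimilated_metabolite", "branch_product")
TARGET_CLASSES = ("cycle_reaction", "branch_reaction", "reverse_branch_reaction")


@dataclass(frozen=True)
class RegulationEdge:
    regulator_class: str
    target_class: str
    sign: str  # "activation" | "inhibition"
    regulator: str = ""
    target: str = ""

    def __post_init__(self):
        if self.regulator_class not in REGULATOR_CLASSES:
            raise ValidationError(f"unknown regulator class {self.regulator_class!r}")
        if self.target_class not in TARGET_CLASSES:
            raise ValidationError(f"unknown target class {self.target_class!r}")
        if self.sign not in ("activation", "inhibition"):
            raise ValidationError(f"unknown sign {self.sign!r}")


def expected_regulation(regulator_class: str, target_class: str) -> str:
    """Regulation direction that supports stable, fast-converging cycles.

    Every regulator class (cycle intermediate, assimilated metabolite,
    branch product) should inhibit cycle reactions and activate branch
    reactions; reactions running opposite to a branch (feeding the cycle
    from branch products) are mirror images of branches and get the flipped
    sign."""
    if regulator_class not in REGULATOR_CLASSES:
        raise ValidationError(f"unknown regulator class {regulator_class!r}")
    if target_class == "cycle_reaction":
        return "inhibition"
    if target_class == "branch_reaction":
        return "activation"
    if target_class == "reverse_branch_reaction":
        return "inhibition"  # flip of the branch expectation
    raise ValidationError(f"unknown target class {target_class!r}")


def audit_regulation(
    edges: Iterable[RegulationEdge],
) -> tuple[int, int, list[tuple[RegulationEdge, bool]]]:
    """Count edges (in)consistent with the expected rule table."""
    verdicts = []
    n_ok = 0
    for e in edges:
        ok = e.sign == expected_regulation(e.regulator_class, e.target_class)
        verdicts.append((e, ok))
        n_ok += ok
    return n_ok, len(verdicts) - n_ok, verdicts


# ---------------------------------------------------------------------------
# synthetic-table generator


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """What the generator knows that the tables alone do not."""

    steady_states: np.ndarray  # (n_conditions, n_intermediates)
    true_saturation: pd.DataFrame  # reaction x condition
    estimable_saturation: pd.DataFrame  # true / per-reaction best-condition max
    kcat: dict[str, float]  # base Vmax per enzyme unit
    argmax_condition: dict[str, str]
    branch_points: tuple[BranchPointSpec, ...]
    branch_scales: np.ndarray  # per-condition scaling of branch enzymes


def default_demo_cycle() -> MultiCycleKineticSpec:
    """A two-reaction 1:2 cycle used as the generator's default subject.

    The parameters are balanced so that the two existence-threshold
    conditions (1+delta)*Va2 = Va1 + s*Vb1 and Va1 = Va2 + s*Vb2 share the
    same critical branch scale s* = 0.4: lowering branch expression toward
    s* drives both intermediates jointly toward saturation, emulating a
    cycle operated across conditions from comfortable excess branch
    capacity down to near its stability boundary.  Branch KMs exceed the
    cycle KMs, as stability requires.
    """
    return MultiCycleKineticSpec(
        cycle_kinetics=(
            MichaelisMentenKinetics(1.2, 1.0),
            MichaelisMentenKinetics(1.0, 1.0),
        ),
        branch_kinetics=(
            MichaelisMentenKinetics(2.0, 8.0),
            MichaelisMentenKinetics(0.5, 4.0),
        ),
        delta=1,
    )


def _scaled_spec(spec: MultiCycleKineticSpec, s: float) -> MultiCycleKineticSpec:
    return MultiCycleKineticSpec(
        cycle_kinetics=spec.cycle_kinetics,
        branch_kinetics=tuple(
            None if b is None else MichaelisMentenKinetics(s * b.Vmax, b.KM)
            for b in spec.branch_kinetics
        ),
        delta=spec.delta,
    )


def generate_synthetic_tables(
    kinetics: MultiCycleKineticSpec,
    n_conditions: int,
    noise_cv: float,
    seed: int,
    net=None,
    cycle=None,
    x_target_factor: float = 1e4,
) -> tuple[FluxTable, EnzymeTable, SyntheticGroundTruth]:
    """Emit flux and enzyme tables for a cycle operating across conditions.

    Conditions differ in the expression of the branch enzymes: their common
    scale factor is swept log-uniformly from 1 down toward the existence
    threshold of the positive steady state (where X* grows without bound),
    so that the most extreme condition runs every reaction near full
    saturation (X* about ``x_target_factor`` times KM).  Cycle enzymes stay
    at unit abundance; base Vmax values play the role of kcat.  Each steady
    state is solved numerically and eigenvalue-checked; an unstable or
    missing state aborts generation.

    Measurement noise is multiplicative lognormal with coefficient of
    variation ``noise_cv`` (mean 1), applied independently to every flux and
    enzyme entry.  Fully reproducible from ``seed``.

    ``net``/``cycle`` may carry a network context for reaction naming but
    are not needed: reactions are named a1..an (cycle) and b1..bn (branch),
    metabolites X1..Xn.
    """
    if n_conditions < 1:
        raise ValidationError("n_conditions must be >= 1")
    if noise_cv < 0:
        raise ValidationError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    n = kinetics.n

    # walk the branch scale down with solution continuation until the steady
    # state is deep in saturation, to place the near-critical condition
    x = solve_steady_state(kinetics)
    if x is None or not eigen_stability(build_jacobian(linearize(kinetics, x))):
        raise ValidationError("base kinetics has no stable positive steady state")
    km_all = [k.KM for k in kinetics.cycle_kinetics] + [
        b.KM for b in kinetics.branch_kinetics if b is not None
    ]
    km_max = max(km_all)
    s_lo = 1.0
    x_walk = x.copy()
    factor = 0.93
    for _ in range(5000):
        if np.min(x_walk) >= x_target_factor * km_max or factor > 1 - 1e-9:
            break
        s_try = s_lo * factor
        x_try = solve_steady_state(_scaled_spec(kinetics, s_try), x0=x_walk)
        if x_try is None or np.min(x_try) < np.min(x_walk):
            factor = (1.0 + factor) / 2.0  # gentler step near the threshold
        else:
            s_lo, x_walk = s_try, x_try

    scales = np.geomspace(s_lo, 1.0, n_conditions)
    conditions = [f"c{i + 1}" for i in range(n_conditions)]
    cycle_ids = [f"a{i + 1}" for i in range(n)]
    branch_ids = {
        i: f"b{i + 1}" for i in range(n) if kinetics.branch_kinetics[i] is not None
    }

    states = np.empty((n_conditions, n))
    flux_rows, enz_rows, sat_rows = {}, {}, {}
    all_ids = cycle_ids + [branch_ids[i] for i in sorted(branch_ids)]
    for rid in all_ids:
        flux_rows[rid], enz_rows[rid], sat_rows[rid] = (
            np.empty(n_conditions),
            np.empty(n_conditions),
            np.empty(n_conditions),
        )

    def _continue_to(s_from, x_from, s_to, depth=0):
        xs = solve_steady_state(_scaled_spec(kinetics, s_to), x0=x_from)
        if xs is not None:
            return xs
        if depth >= 40:
            return None
        s_mid = float(np.sqrt(s_from * s_to))
        x_mid = _continue_to(s_from, x_from, s_mid, depth + 1)
        if x_mid is None:
            return None
        return _continue_to(s_mid, x_mid, s_to, depth + 1)

    s_prev, x_prev = 1.0, x
    for ci in np.argsort(scales)[::-1]:  # descending scale, from the s=1 state
        s_c = scales[ci]
        scaled = _scaled_spec(kinetics, s_c)
        xs = _continue_to(s_prev, x_prev, s_c)
        if xs is None:
            raise ValidationError(f"no steady state at branch scale {s_c:.4g}")
        s_prev = s_c
        lin = linearize(scaled, xs)
        lead = float(np.max(np.linalg.eigvals(build_jacobian(lin)).real))
        # near the existence threshold all derivatives shrink like 1/X*^2,
        # so judge instability relative to the local rate scale
        if lead > 1e-9 * max(a + b for a, b in zip(lin.alphas, lin.betas)):
            raise ValidationError(f"unstable steady state at branch scale {s_c:.4g}")
        x_prev = xs
        states[ci] = xs
        for i in range(n):
            k = kinetics.cycle_kinetics[i]
            flux_rows[cycle_ids[i]][ci] = mm_flux(k, xs[i])
            enz_rows[cycle_ids[i]][ci] = 1.0
            sat_rows[cycle_ids[i]][ci] = saturation(k, xs[i])
            if i in branch_ids:
                b = kinetics.branch_kinetics[i]
                flux_rows[branch_ids[i]][ci] = s_c * mm_flux(b, xs[i])
                enz_rows[branch_ids[i]][ci] = s_c
                sat_rows[branch_ids[i]][ci] = saturation(b, xs[i])

    flux_df = pd.DataFrame(flux_rows, index=conditions).T
    enz_df = pd.DataFrame(enz_rows, index=conditions).T
    sat_df = pd.DataFrame(sat_rows, index=conditions).T

    sigma = float(np.sqrt(np.log1p(noise_cv**2)))
    def _noisy(df: pd.DataFrame) -> pd.DataFrame:
        if sigma == 0:
            return df.copy()
        noise = rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=df.shape)
        return df * noise

    kcat = {rid: kinetics.cycle_kinetics[i].Vmax for i, rid in enumerate(cycle_ids)}
    kcat.update(
        {branch_ids[i]: kinetics.branch_kinetics[i].Vmax for i in branch_ids}
    )
    argmax = {rid: sat_df.loc[rid].idxmax() for rid in sat_df.index}
    estimable = sat_df.div(sat_df.max(axis=1), axis=0)
    branch_points = tuple(
        BranchPointSpec(f"X{i + 1}", cycle_ids[i], branch_ids[i]) for i in sorted(branch_ids)
    )
    truth = SyntheticGroundTruth(
        steady_states=states,
        true_saturation=sat_df,
        estimable_saturation=estimable,
        kcat=kcat,
        argmax_condition=argmax,
        branch_points=branch_points,
        branch_scales=scales,
    )
    return FluxTable(_noisy(flux_df)), EnzymeTable(_noisy(enz_df)), truth
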