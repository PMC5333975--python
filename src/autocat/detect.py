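"""Autocatalytic-cycle detection.

Two complementary routes are implemented:

1. a graph algorithm: the network becomes a bipartite directed graph
   (metabolite -> reaction edges for substrates, reaction -> metabolite for
   products), simple cycles are enumerated, and each is classified by three
   rules -- reject cycles whose reactions drain more than one intermediate,
   accept cycles with a reaction producing two intermediates, accept cycles
   whose external branch product can return to every intermediate without
   touching the cycle;

2. a formal verifier: a search for positive integer multipliers of the
   reaction set whose combined reaction vector is non-negative on every
   cycle intermediate and strictly positive on at least one, together with
   the sign conditions on the stoichiometric submatrix and minimality with
   respect to proper reaction subsets (which excludes unions of disjoint
   cycles).

The graph route assumes every reaction consumes/produces single molecules of
each species; cycles violating that assumption are handled by the verifier
alone.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .errors import ValidationError
from .netmodel import MetabolicNetwork, ReactionVector, net_reaction_vector, strip_cofactors

__all__ = [
    "ReactionGraph",
    "CycleCandidate",
    "AutocatalyticCycle",
    "UNDECIDED",
    "build_reaction_graph",
    "enumerate_cycles",
    "classify_cycle",
    "verify_autocatalytic",
    "find_autocatalytic_cycles",
]

logger = logging.getLogger(__name__)

#: Exhaustive-search budget for the multiplier search; larger spaces use MILP.
_BRUTE_CAP = 200_000

REVERSE_SUFFIX = "__rev"


class Undecided:
    """Sentinel: the bounded search could not settle the question."""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "UNDECIDED"

    def __bool__(self) -> bool:
        return False


UNDECIDED = Undecided()


# ---------------------------------------------------------------------------
# graph construction and cycle enumeration

ReactionGraph = nx.DiGraph


def build_reaction_graph(net: MetabolicNetwork) -> ReactionGraph:
    """Bipartite substrate/product graph over internal metabolites.

    External metabolites are not cycle-intermediate candidates and are left
    out of the graph entirely.
    """
    g = nx.DiGraph()
    internal = set(net.internal_metabolite_ids)
    for m in internal:
        g.add_node(m, kind="metabolite")
    for r in net.reactions:
        g.add_node(r.id, kind="reaction")
        for m in r.substrates:
            if m in internal:
                g.add_edge(m, r.id)
        for m in r.products:
            if m in internal:
                g.add_edge(r.id, m)
    return g


@dataclass(frozen=True)
class CycleCandidate:
    """A simple cycle in the reaction graph, stored as an alternating node
    sequence starting from its lexicographically smallest metabolite."""

    nodes: tuple[str, ...]
    reaction_ids: tuple[str, ...]
    metabolite_ids: tuple[str, ...]

    @classmethod
    def from_node_list(cls, nodes: Sequence[str], g: ReactionGraph) -> "CycleCandidate":
        kinds = [g.nodes[n]["kind"] for n in nodes]
        mets = [n for n, k in zip(nodes, kinds) if k == "metabolite"]
        rxns = [n for n, k in zip(nodes, kinds) if k == "reaction"]
        if not mets or not rxns:
            raise ValidationError("a cycle must alternate metabolites and reactions")
        # canonical rotation: start at the smallest metabolite node
        start = nodes.index(min(mets))
        rot = tuple(nodes[start:]) + tuple(nodes[:start])
        return cls(rot, tuple(n for n in rot if g.nodes[n]["kind"] == "reaction"),
                   tuple(n for n in rot if g.nodes[n]["kind"] == "metabolite"))

    def __len__(self) -> int:
        return len(self.reaction_ids)


def enumerate_cycles(g: ReactionGraph, max_len: int = 12) -> list[CycleCandidate]:
    """All simple cycles with at most ``max_len`` reaction nodes.

    Deduplicated up to rotation (guaranteed by the enumeration) and returned
    in a deterministic order.
    """
    if max_len < 1:
        raise ValidationError("max_len must be >= 1")
    out = []
    for nodes in nx.simple_cycles(g, length_bound=2 * max_len):
        cand = CycleCandidate.from_node_list(nodes, g)
        if len(cand) <= max_len:
            out.append(cand)
    out.sort(key=lambda c: (len(c.nodes), c.nodes))
    return out


# ---------------------------------------------------------------------------
# classification (the three-way rule)


def classify_cycle(
    net: MetabolicNetwork,
    c: CycleCandidate,
    g: ReactionGraph | None = None,
    return_path_mode: str = "any",
) -> Optional[str]:
    """Classify a cycle candidate; ``None`` means rejected.

    Rules, applied in order:

    * reject if any cycle reaction consumes more than one distinct cycle
      intermediate (the cycle would drain itself);
    * ``"multi_product"`` if some cycle reaction produces more than one
      cycle intermediate (direct stoichiometric gain);
    * ``"branch_product_path"`` if some cycle reaction has a product outside
      the cycle from which a cycle intermediate can be regenerated by a path
      avoiding the cycle's reactions and any reaction consuming a cycle
      intermediate (re-entry at one intermediate suffices: the cycle's own
      reactions then redistribute the gain; ``return_path_mode="all"``
      instead demands a bypass to every intermediate).
    """
    if g is None:
        g = build_reaction_graph(net)
    intermediates = set(c.metabolite_ids)
    cycle_rxns = set(c.reaction_ids)
    for rid in c.reaction_ids:
        r = net.reaction(rid)
        if len(set(r.substrates) & intermediates) > 1:
            return None
    for rid in c.reaction_ids:
        r = net.reaction(rid)
        if len(set(r.products) & intermediates) > 1:
            return "multi_product"
    # candidate external products of the cycle (internal metabolites only:
    # boundary species cannot seed a return path inside the system)
    internal = set(net.internal_metabolite_ids)
    candidates = []
    for rid in c.reaction_ids:
        for m in net.reaction(rid).products:
            if m in internal and m not in intermediates:
                candidates.append(m)
    if not candidates:
        return None
    # forbidden nodes: the cycle's reactions and every reaction that consumes
    # a cycle intermediate
    forbidden = set(cycle_rxns)
    for r in net.reactions:
        if set(r.substrates) & intermediates:
            forbidden.add(r.id)
    if return_path_mode not in ("any", "all"):
        raise ValidationError(f"unknown return_path_mode {return_path_mode!r}")
    quantifier = any if return_path_mode == "any" else all
    h = g.subgraph(n for n in g.nodes if n not in forbidden)
    for me in candidates:
        if me not in h:
            continue
        if quantifier(nx.has_path(h, me, mi) for mi in intermediates):
            return "branch_product_path"
    return None


# ---------------------------------------------------------------------------
# formal verifier


@dataclass(frozen=True)
class AutocatalyticCycle:
    """A verified (or classified) autocatalytic cycle.

    ``multipliers``/``net``/``delta`` form the formal certificate and are
    ``None`` for graph-classified cycles whose gain returns through an
    external branch path rather than through the cycle reactions alone.
    """

    reactions: Optional[Mapping[str, int]]
    intermediates: frozenset[str]
    net: Optional[Mapping[str, Fraction]]
    delta: Optional[Fraction]
    classification: str = "formal_only"
    minimality_verified: bool = True

    @property
    def has_certificate(self) -> bool:
        return self.reactions is not None


def _submatrix(
    net: MetabolicNetwork, reaction_ids: Sequence[str], intermediates: Sequence[str]
) -> list[list[Fraction]]:
    cols = [net.stoich_column(rid) for rid in reaction_ids]
    return [[col.get(m, Fraction(0)) for col in cols] for m in intermediates]


def _sign_conditions_hold(A: Sequence[Sequence[Fraction]]) -> bool:
    """Every row and column of the cycle submatrix must mix signs."""
    if not A or not A[0]:
        return False
    for row in A:
        if not (any(v > 0 for v in row) and any(v < 0 for v in row)):
            return False
    ncols = len(A[0])
    for j in range(ncols):
        col = [row[j] for row in A]
        if not (any(v > 0 for v in col) and any(v < 0 for v in col)):
            return False
    return True


def _integer_matrix(A: Sequence[Sequence[Fraction]]) -> np.ndarray:
    """Scale each row by its denominators' lcm; signs and zero pattern of the
    constraints are unchanged."""
    rows = []
    for row in A:
        scale = math.lcm(*(v.denominator for v in row)) if row else 1
        rows.append([int(v * scale) for v in row])
    return np.array(rows, dtype=np.int64)


def _brute_force_search(A: np.ndarray, max_multiplier: int, gain_rows=None):
    """Exhaustive bounded search; returns the (sum, lex)-minimal multiplier
    vector or ``None``.  Columns are assumed id-sorted so tuple order is the
    lexicographic tie-break.  ``gain_rows`` restricts where the strict gain
    may occur (default: anywhere)."""
    k = A.shape[1]
    rows = range(A.shape[0]) if gain_rows is None else gain_rows
    best = None
    for vec in itertools.product(range(1, max_multiplier + 1), repeat=k):
        x = np.asarray(vec, dtype=np.int64)
        net = A @ x
        if np.all(net >= 0) and any(net[r] > 0 for r in rows):
            key = (int(x.sum()), vec)
            if best is None or key < best:
                best = key
    return None if best is None else np.asarray(best[1], dtype=np.int64)


def _milp_search(A: np.ndarray, max_multiplier: int, gain_rows=None):
    """MILP route for large spaces: minimize total multiplier with a tiny
    lexicographic preference for earlier (id-smaller) reactions."""
    from scipy.optimize import LinearConstraint, milp, Bounds

    n_int, k = A.shape
    weights = 1.0 + 1e-7 * np.arange(k)[::-1]
    best = None
    for t in (range(n_int) if gain_rows is None else gain_rows):
        lb = np.zeros(n_int)
        lb[t] = 1.0
        con = LinearConstraint(A.astype(float), lb=lb, ub=np.inf)
        res = milp(
            c=weights,
            constraints=[con],
            integrality=np.ones(k),
            bounds=Bounds(lb=1, ub=max_multiplier),
        )
        if res.status == 0 and res.x is not None:
            x = np.round(res.x).astype(np.int64)
            net = A @ x
            if np.all(net >= 0) and net[t] > 0:
                key = (int(x.sum()), tuple(int(v) for v in x))
                if best is None or key < best:
                    best = key
        elif res.status not in (0, 2):  # not optimal, not infeasible
            return UNDECIDED
    return None if best is None else np.asarray(best[1], dtype=np.int64)


def _solution_exists(A: np.ndarray, max_multiplier: int) -> bool:
    k = A.shape[1]
    if max_multiplier**k <= _BRUTE_CAP:
        return _brute_force_search(A, max_multiplier) is not None
    res = _milp_search(A, max_multiplier)
    return res is not UNDECIDED and res is not None


def default_intermediates(
    net: MetabolicNetwork, reaction_ids: Iterable[str]
) -> tuple[str, ...]:
    """Internal metabolites both consumed and produced by the reaction set."""
    consumed, produced = set(), set()
    for rid in reaction_ids:
        r = net.reaction(rid)
        consumed |= set(r.substrates)
        produced |= set(r.products)
    internal = set(net.internal_metabolite_ids)
    return tuple(m for m in net.metabolite_ids if m in consumed & produced & internal)


def verify_autocatalytic(
    net: MetabolicNetwork,
    reaction_ids: Iterable[str],
    intermediates: Iterable[str] | None = None,
    max_multiplier: int = 12,
    method: str = "auto",
    check_minimality: bool = True,
    subset_limit: int = 12,
    require_gain_on: Iterable[str] | None = None,
):
    """Search for a positive-integer multiplier certificate of autocatalysis.

    Returns an :class:`AutocatalyticCycle` (minimizing the total multiplier,
    ties broken lexicographically by reaction id), ``None`` when no bounded
    assignment exists or a condition fails, or :data:`UNDECIDED` when the
    bounded search could not be completed.

    The minimality condition -- no proper nonempty reaction subset admits a
    certificate of its own -- is checked by subset enumeration for up to
    ``subset_limit`` reactions; beyond that the result is returned with
    ``minimality_verified=False``.

    ``require_gain_on`` restricts the strictly-positive coordinate of the
    net vector to the given intermediates (e.g. ask specifically for an
    ATP-autocatalytic certificate); non-negativity is still required on all
    intermediates.
    """
    rids = sorted(set(reaction_ids))
    if not rids:
        raise ValidationError("reaction_ids must be nonempty")
    if max_multiplier < 1:
        raise ValidationError("max_multiplier must be >= 1")
    if intermediates is None:
        inter = default_intermediates(net, rids)
    else:
        inter = tuple(intermediates)
        unknown = set(inter) - set(net.metabolite_ids)
        if unknown:
            raise ValidationError(f"unknown intermediates: {sorted(unknown)}")
    if not inter:
        return None

    A_frac = _submatrix(net, rids, inter)
    if not _sign_conditions_hold(A_frac):
        return None
    A = _integer_matrix(A_frac)
    gain_rows = None
    if require_gain_on is not None:
        targets = set(require_gain_on)
        unknown = targets - set(inter)
        if unknown:
            raise ValidationError(f"gain targets not intermediates: {sorted(unknown)}")
        gain_rows = [i for i, m in enumerate(inter) if m in targets]

    k = len(rids)
    space = max_multiplier**k
    if method == "brute" or (method == "auto" and space <= _BRUTE_CAP):
        if space > _BRUTE_CAP and method == "brute":
            return UNDECIDED
        x = _brute_force_search(A, max_multiplier, gain_rows)
    elif method in ("auto", "milp"):
        x = _milp_search(A, max_multiplier, gain_rows)
        if x is UNDECIDED:
            return UNDECIDED
    else:
        raise ValidationError(f"unknown method {method!r}")
    if x is None:
        return None

    minimality_verified = True
    if check_minimality and k > 1:
        if k <= subset_limit:
            for size in range(1, k):
                for subset in itertools.combinations(range(k), size):
                    if _solution_exists(A[:, list(subset)], max_multiplier):
                        return None  # a proper subset already suffices
        else:
            minimality_verified = False

    multipliers = {rid: int(v) for rid, v in zip(rids, x)}
    net_vec = net_reaction_vector(net, multipliers)
    net_on_inter = net_vec.restricted(inter)
    # delta: gain per unit consumed, relative to the maximal-gain intermediate
    ref_pool = inter if require_gain_on is None else [m for m in inter if m in set(require_gain_on)]
    ref = max(ref_pool, key=lambda m: net_on_inter[m])
    consumed = sum(
        multipliers[rid] * net.reaction(rid).substrates.get(ref, Fraction(0)) for rid in rids
    )
    delta = net_on_inter[ref] / consumed if consumed > 0 else None
    return AutocatalyticCycle(
        reactions=multipliers,
        intermediates=frozenset(inter),
        net=net_on_inter,
        delta=delta,
        classification="formal_only",
        minimality_verified=minimality_verified,
    )


# ---------------------------------------------------------------------------
# end-to-end search


def _base_id(rid: str) -> str:
    return rid[: -len(REVERSE_SUFFIX)] if rid.endswith(REVERSE_SUFFIX) else rid


def find_autocatalytic_cycles(
    net: MetabolicNetwork,
    max_len: int = 12,
    max_multiplier: int = 12,
    cofactor_ids: Iterable[str] | None = None,
) -> list[AutocatalyticCycle]:
    """Enumerate, classify and formally verify autocatalytic cycles.

    Reversible reactions are split into their two directions beforehand; a
    cycle may use at most one direction of each.  Cycles whose reactions
    have non-unit stoichiometry bypass the (unit-stoichiometry) graph
    classification and are kept only with a formal certificate.
    """
    if cofactor_ids is not None:
        net = strip_cofactors(net, cofactor_ids)
    split = net.split_reversible(REVERSE_SUFFIX)
    g = build_reaction_graph(split)
    hits: list[AutocatalyticCycle] = []
    seen: set[frozenset[str]] = set()
    for cand in enumerate_cycles(g, max_len=max_len):
        bases = [_base_id(r) for r in cand.reaction_ids]
        if len(set(bases)) < len(bases):
            continue  # both directions of one reversible reaction
        key = frozenset(cand.reaction_ids)
        if key in seen:
            continue
        unit = all(split.reaction(r).has_unit_stoichiometry() for r in cand.reaction_ids)
        classification = classify_cycle(split, cand, g) if unit else None
        if not unit:
            logger.info(
                "cycle %s has non-unit stoichiometry; graph classification skipped",
                cand.reaction_ids,
            )
        cert = verify_autocatalytic(
            split,
            cand.reaction_ids,
            intermediates=cand.metabolite_ids,
            max_multiplier=max_multiplier,
        )
        if cert is UNDECIDED:
            raise ValidationError(
                f"multiplier search undecided within bound for cycle {cand.reaction_ids}"
            )
        if classification is None and cert is None:
            continue
        seen.add(key)
        if cert is not None:
            hits.append(
                AutocatalyticCycle(
                    reactions=cert.reactions,
                    intermediates=cert.intermediates,
                    net=cert.net,
                    delta=cert.delta,
                    classification=classification or "formal_only",
                    minimality_verified=cert.minimality_verified,
                )
            )
        else:
            hits.append(
                AutocatalyticCycle(
                    reactions=None,
                    intermediates=frozenset(cand.metabolite_ids),
                    net=None,
                    delta=None,
                    classification=classification,
                )
            )
    return hits
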