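"""Random test networks with planted, ground-truth autocatalytic cycles.

The background is a random directed acyclic reaction chain (edges only run
from lower- to higher-numbered metabolites, so it contributes no cycles);
the planted cycle is a chain X1 -> ... -> Xm closed by an assimilating
reaction Xm + A_ext -> 2*X1.  The generator records the planted reaction
ids so detection tests can check exact recovery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .netmodel import MetabolicNetwork, Metabolite, Reaction

__all__ = ["PlantedNetwork", "planted_cycle_network", "planted_loops_graph_network"]


@dataclass(frozen=True)
class PlantedNetwork:
    network: MetabolicNetwork
    cycle_reactions: tuple[str, ...]
    cycle_intermediates: tuple[str, ...]


def planted_cycle_network(
    rng: np.random.Generator,
    cycle_len: int = 3,
    n_background_metabolites: int = 10,
    n_background_reactions: int = 15,
) -> PlantedNetwork:
    """One autocatalytic cycle of ``cycle_len`` reactions inside a random
    acyclic background.

    Background reactions convert a lower-indexed metabolite to a
    higher-indexed one (possibly tapping a cycle intermediate as a branch),
    which keeps the background loop-free by construction.
    """
    if cycle_len < 2:
        # a single autocatalytic reaction would need its intermediate on both
        # sides, which the reaction model forbids
        raise ValueError("cycle_len must be >= 2")
    mets = [Metabolite(f"x{i + 1}") for i in range(cycle_len)]
    mets.append(Metabolite("assim", is_external=True))
    reactions = []
    for i in range(cycle_len - 1):
        reactions.append(Reaction(f"cyc{i + 1}", {f"x{i + 1}": 1}, {f"x{i + 2}": 1}))
    reactions.append(
        Reaction(f"cyc{cycle_len}", {f"x{cycle_len}": 1, "assim": 1}, {"x1": 2})
    )
    cycle_rids = tuple(r.id for r in reactions)

    bg_ids = [f"m{i + 1}" for i in range(n_background_metabolites)]
    mets.extend(Metabolite(m) for m in bg_ids)
    # ordering: cycle intermediates rank below every background metabolite,
    # and background edges go strictly upward in index -> no new cycles
    rank = {f"x{i + 1}": -cycle_len + i for i in range(cycle_len)}
    rank.update({m: i for i, m in enumerate(bg_ids)})
    sources = [f"x{i + 1}" for i in range(cycle_len)] + bg_ids
    for j in range(n_background_reactions):
        while True:
            a = sources[rng.integers(len(sources))]
            b = bg_ids[rng.integers(len(bg_ids))]
            if rank[a] < rank[b]:
                break
        reactions.append(Reaction(f"bg{j + 1}", {a: 1}, {b: 1}))
    return PlantedNetwork(
        MetabolicNetwork(mets, reactions),
        cycle_rids,
        tuple(f"x{i + 1}" for i in range(cycle_len)),
    )


def planted_loops_graph_network(k: int, loop_len: int = 2) -> PlantedNetwork:
    """``k`` node-disjoint simple loops (futile cycles), no autocatalysis.

    Used to check that cycle enumeration finds exactly the planted loops.
    """
    mets, reactions = [], []
    for li in range(k):
        ids = [f"l{li}_x{j}" for j in range(loop_len)]
        mets.extend(Metabolite(m) for m in ids)
        for j in range(loop_len):
            reactions.append(
                Reaction(f"l{li}_r{j}", {ids[j]: 1}, {ids[(j + 1) % loop_len]: 1})
            )
    return PlantedNetwork(MetabolicNetwork(mets, reactions), tuple(), tuple())


def random_network(
    rng: np.random.Generator,
    n_metabolites: int = 6,
    n_reactions: int = 5,
    p_external: float = 0.2,
    max_coeff: int = 2,
) -> MetabolicNetwork:
    """Small random network (cycles allowed) for oracle-equivalence tests."""
    mets = [
        Metabolite(f"m{i}", is_external=bool(rng.random() < p_external))
        for i in range(n_metabolites)
    ]
    reactions = []
    for j in range(n_reactions):
        ids = rng.permutation(n_metabolites)
        n_sub = int(rng.integers(1, 3))
        n_prod = int(rng.integers(1, 3))
        subs = {f"m{i}": int(rng.integers(1, max_coeff + 1)) for i in ids[:n_sub]}
        prods = {
            f"m{i}": int(rng.integers(1, max_coeff + 1))
            for i in ids[n_sub : n_sub + n_prod]
        }
        reactions.append(Reaction(f"r{j}", subs, prods))
    return MetabolicNetwork(mets, reactions)
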