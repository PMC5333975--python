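"""Cycle detection: graph construction, enumeration, classification, and the
formal multiplier verifier (with its brute-force oracle)."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from autocat.detect import (
    UNDECIDED,
    AutocatalyticCycle,
    build_reaction_graph,
    classify_cycle,
    enumerate_cycles,
    find_autocatalytic_cycles,
    verify_autocatalytic,
)
from autocat.errors import ValidationError
from autocat.netmodel import MetabolicNetwork, Metabolite, Reaction, net_reaction_vector
from autocat.synth import planted_cycle_network, planted_loops_graph_network, random_network


def mk(mets, rxns):
    return MetabolicNetwork(mets, rxns)


class TestGraph:
    def test_single_reaction_counts(self):
        net = mk([Metabolite("a"), Metabolite("b")], [Reaction("r", {"a": 1}, {"b": 1})])
        g = build_reaction_graph(net)
        assert set(g.nodes) == {"a", "b", "r"}
        assert set(g.edges) == {("a", "r"), ("r", "b")}

    def test_glyoxylate_graph_excludes_external(self, glyoxylate):
        g = build_reaction_graph(glyoxylate)
        assert set(g.nodes) == {"mal", "icit", "mal_to_icit", "icit_split"}
        assert g.number_of_edges() == 4

    def test_empty_network(self):
        g = build_reaction_graph(mk([], []))
        assert g.number_of_nodes() == 0


class TestEnumerate:
    def test_two_reaction_loop(self, pts):
        cycles = enumerate_cycles(build_reaction_graph(pts))
        assert len(cycles) == 1
        assert set(cycles[0].reaction_ids) == {"pts", "glycolysis"}

    def test_acyclic_chain_has_no_cycles(self):
        net = mk(
            [Metabolite(m) for m in "abc"],
            [Reaction("r1", {"a": 1}, {"b": 1}), Reaction("r2", {"b": 1}, {"c": 1})],
        )
        assert enumerate_cycles(build_reaction_graph(net)) == []

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_planted_disjoint_loops_found_exactly(self, k):
        planted = planted_loops_graph_network(k, loop_len=3)
        cycles = enumerate_cycles(build_reaction_graph(planted.network))
        assert len(cycles) == k

    def test_max_len_bound_respected(self):
        planted = planted_loops_graph_network(1, loop_len=4)
        g = build_reaction_graph(planted.network)
        assert enumerate_cycles(g, max_len=3) == []
        assert len(enumerate_cycles(g, max_len=4)) == 1


class TestClassify:
    def branchy_net(self):
        # S + X1 -> X2 ; X2 -> X1 + X3 ; X3 -> X1 (return path)
        return mk(
            [
                Metabolite("S", is_external=True),
                Metabolite("X1"),
                Metabolite("X2"),
                Metabolite("X3"),
            ],
            [
                Reaction("R1", {"S": 1, "X1": 1}, {"X2": 1}),
                Reaction("R2", {"X2": 1}, {"X1": 1, "X3": 1}),
                Reaction("R3", {"X3": 1}, {"X1": 1}),
            ],
        )

    def _cycle(self, net, rids):
        g = build_reaction_graph(net)
        for c in enumerate_cycles(g):
            if set(c.reaction_ids) == set(rids):
                return c, g
        raise AssertionError(f"cycle {rids} not enumerated")

    def test_branch_product_path_accepted(self):
        net = self.branchy_net()
        c, g = self._cycle(net, {"R1", "R2"})
        assert classify_cycle(net, c, g) == "branch_product_path"

    def test_multi_product_accepted(self):
        net = self.branchy_net()
        c, g = self._cycle(net, {"R1", "R2", "R3"})
        # R2 produces two intermediates of the longer cycle (X1, X3)
        assert classify_cycle(net, c, g) == "multi_product"

    def test_futile_loop_rejected(self):
        net = mk(
            [Metabolite("X1"), Metabolite("X2")],
            [Reaction("f", {"X1": 1}, {"X2": 1}), Reaction("b", {"X2": 1}, {"X1": 1})],
        )
        c, g = self._cycle(net, {"f", "b"})
        assert classify_cycle(net, c, g) is None

    def test_double_intermediate_consumption_rejected(self):
        net = mk(
            [Metabolite("X1"), Metabolite("X2"), Metabolite("X3")],
            [
                Reaction("r1", {"X1": 1, "X2": 1}, {"X3": 1}),
                Reaction("r2", {"X3": 1}, {"X1": 1, "X2": 1}),
            ],
        )
        c, g = self._cycle(net, {"r1", "r2"})
        assert classify_cycle(net, c, g) is None


class TestVerifier:
    def test_glyoxylate_certificate(self, glyoxylate):
        cert = verify_autocatalytic(glyoxylate, glyoxylate.reaction_ids)
        assert cert.reactions == {"mal_to_icit": 1, "icit_split": 1}
        assert cert.net["mal"] == 1
        assert cert.delta == 1

    def test_cbb_certificate_fractional_delta(self, cbb):
        cert = verify_autocatalytic(cbb, cbb.reaction_ids)
        assert cert.reactions == {"carboxylation": 1, "regeneration": 1}
        assert cert.net["c5"] == 1
        assert cert.delta == Fraction(1, 5)

    def test_glycolysis_atp_gain(self, glycolysis_atp):
        cert = verify_autocatalytic(
            glycolysis_atp, glycolysis_atp.reaction_ids, require_gain_on={"atp"}
        )
        assert cert.reactions == {"priming": 1, "payoff": 2}
        assert cert.net["atp"] == 2

    def test_set_needing_zero_multiplier_gives_none(self, glyoxylate):
        # add a pure drain to the glyoxylate pair: any positive multiplier on
        # it breaks the sign/non-negativity conditions, so the only
        # "solution" would put 0 on a member -- the set is not a cycle
        net = mk(
            list(glyoxylate.metabolites) + [Metabolite("waste", is_external=True)],
            list(glyoxylate.reactions) + [Reaction("drain", {"mal": 1}, {"waste": 1})],
        )
        assert (
            verify_autocatalytic(
                net, net.reaction_ids, intermediates=("mal", "icit")
            )
            is None
        )

    def test_disjoint_union_rejected_by_minimality(self, pts, glyoxylate):
        # union of two independent autocatalytic cycles: each proper subset
        # (either cycle alone) already admits a certificate
        mets = list(pts.metabolites) + list(glyoxylate.metabolites)
        rxns = list(pts.reactions) + list(glyoxylate.reactions)
        union = mk(mets, rxns)
        assert verify_autocatalytic(union, union.reaction_ids) is None
        # each half alone is verified
        assert verify_autocatalytic(union, pts.reaction_ids) is not None
        assert verify_autocatalytic(union, glyoxylate.reaction_ids) is not None

    def test_undecided_when_brute_space_exceeded(self, glyoxylate):
        res = verify_autocatalytic(
            glyoxylate,
            glyoxylate.reaction_ids,
            max_multiplier=10**6,
            method="brute",
        )
        assert res is UNDECIDED

    def test_milp_route_matches_brute(self, glyoxylate, glycolysis_atp):
        for net in (glyoxylate, glycolysis_atp):
            a = verify_autocatalytic(net, net.reaction_ids, method="brute")
            b = verify_autocatalytic(net, net.reaction_ids, method="milp")
            assert a.reactions == b.reactions


def _oracle_verify(net, rids, intermediates, max_multiplier):
    """Independent re-statement of the formal definition by full enumeration."""
    rids = sorted(rids)
    cols = {r: net.stoich_column(r) for r in rids}
    A = [[cols[r].get(m, Fraction(0)) for r in rids] for m in intermediates]
    if not A or not A[0]:
        return None
    rows_ok = all(any(v > 0 for v in row) and any(v < 0 for v in row) for row in A)
    cols_ok = all(
        any(A[i][j] > 0 for i in range(len(A))) and any(A[i][j] < 0 for i in range(len(A)))
        for j in range(len(rids))
    )
    if not (rows_ok and cols_ok):
        return None

    def admits(active):
        for vec in itertools.product(range(1, max_multiplier + 1), repeat=len(active)):
            full = dict(zip(active, vec))
            net_v = [
                sum(full.get(r, 0) * cols[r].get(m, Fraction(0)) for r in rids)
                for m in intermediates
            ]
            if all(v >= 0 for v in net_v) and any(v > 0 for v in net_v):
                return vec
        return None

    best = None
    for vec in itertools.product(range(1, max_multiplier + 1), repeat=len(rids)):
        net_v = [sum(v * cols[r].get(m, Fraction(0)) for v, r in zip(vec, rids)) for m in intermediates]
        if all(v >= 0 for v in net_v) and any(v > 0 for v in net_v):
            key = (sum(vec), vec)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    for size in range(1, len(rids)):
        for sub in itertools.combinations(rids, size):
            if admits(sub) is not None:
                return None
    return dict(zip(rids, best[1]))


class TestOracleEquivalence:
    def test_random_networks_match_enumeration_oracle(self, rng):
        checked = 0
        for _ in range(40):
            net = random_network(
                rng,
                n_metabolites=int(rng.integers(3, 6)),
                n_reactions=int(rng.integers(2, 5)),
            )
            from autocat.detect import default_intermediates

            inter = default_intermediates(net, net.reaction_ids)
            if not inter:
                continue
            expected = _oracle_verify(net, net.reaction_ids, inter, max_multiplier=3)
            got = verify_autocatalytic(
                net, net.reaction_ids, intermediates=inter, max_multiplier=3,
                method="milp",
            )
            if expected is None:
                assert got is None
            else:
                assert got is not None and got is not UNDECIDED
                assert dict(got.reactions) == expected
            checked += 1
        assert checked >= 20

    def test_returned_cycles_satisfy_type_invariants(self, glyoxylate, cbb, pts):
        for net in (glyoxylate, cbb, pts):
            cert = verify_autocatalytic(net, net.reaction_ids)
            # re-check independently of the verifier's own arithmetic
            vec = net_reaction_vector(net, cert.reactions)
            assert all(vec[m] >= 0 for m in cert.intermediates)
            assert any(vec[m] > 0 for m in cert.intermediates)
            assert cert.delta > 0


class TestEndToEnd:
    def test_pts_cycle_found(self, pts):
        hits = find_autocatalytic_cycles(pts)
        assert len(hits) == 1
        assert hits[0].delta == 1
        assert hits[0].intermediates == frozenset({"pep", "g6p"})

    def test_glycolysis_atp_cycle_found(self, glycolysis_atp):
        hits = find_autocatalytic_cycles(glycolysis_atp)
        assert any(h.reactions and set(h.reactions) == {"priming", "payoff"} for h in hits)

    def test_random_acyclic_network_empty(self, rng):
        net = mk(
            [Metabolite(f"m{i}") for i in range(6)],
            [Reaction(f"r{i}", {f"m{i}": 1}, {f"m{i+1}": 1}) for i in range(5)],
        )
        assert find_autocatalytic_cycles(net) == []

    def test_reversible_reactions_do_not_create_futile_hits(self):
        net = mk(
            [Metabolite("a"), Metabolite("b")],
            [Reaction("r", {"a": 1}, {"b": 1}, reversible=True)],
        )
        assert find_autocatalytic_cycles(net) == []

    @pytest.mark.parametrize("cycle_len", [2, 3, 4])
    def test_planted_cycle_recovered(self, cycle_len, rng):
        for _ in range(10):
            planted = planted_cycle_network(
                rng,
                cycle_len=cycle_len,
                n_background_metabolites=8,
                n_background_reactions=12,
            )
            hits = find_autocatalytic_cycles(planted.network, max_len=cycle_len + 2)
            assert any(
                h.reactions and set(h.reactions) == set(planted.cycle_reactions)
                for h in hits
            )
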