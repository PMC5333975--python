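"""Analytic steady states of the simple cycle: domains, input flux,
sensitivities, bisubstrate bounds, and the reversible-branch extension."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from autocat.errors import DomainError, ValidationError
from autocat.kinetics import (
    BisubstrateKinetics,
    MichaelisMentenKinetics as MM,
    apparent_constants,
    mm_flux,
)
from autocat.stability import (
    ReversibleBranchSpec,
    SimpleCycleSpec,
    bisubstrate_stable_region,
    classify_domain,
    reversible_autocatalytic_min_Vmax,
    reversible_branch_analysis,
    sensitivity_signs,
    steady_state_simple,
    steady_states_with_input,
    xstar_vs_A,
)

DOMAIN_I = SimpleCycleSpec(MM(1, 1), MM(2, 4))
DOMAIN_II = SimpleCycleSpec(MM(1, 1), MM(2, 1))
DOMAIN_III = SimpleCycleSpec(MM(2, 4), MM(1, 1))


class TestSimpleSteadyState:
    def test_domain_I_stable_positive_state(self):
        r = steady_state_simple(DOMAIN_I)
        (s,) = r.states
        assert s.X == pytest.approx(2.0)
        assert s.stable and not r.zero_stable and r.domain == "I"
        # substitution oracle: fa(X*) == fb(X*) == 2/3
        assert mm_flux(DOMAIN_I.fa, s.X) == pytest.approx(2 / 3)
        assert mm_flux(DOMAIN_I.fb, s.X) == pytest.approx(2 / 3)

    def test_domain_III_unstable_positive_state(self):
        r = steady_state_simple(DOMAIN_III)
        (s,) = r.states
        assert s.X == pytest.approx(2.0)
        assert not s.stable and r.zero_stable and r.domain == "III"

    def test_domain_II_zero_only(self):
        r = steady_state_simple(DOMAIN_II)
        assert r.states == () and r.zero_stable and r.domain == "II"

    def test_domain_IV_divergent(self):
        r = steady_state_simple(SimpleCycleSpec(MM(2, 1), MM(1, 2)))
        assert r.domain == "IV" and r.divergent and not r.zero_stable

    def test_degenerate_equal_parameters(self):
        r = steady_state_simple(SimpleCycleSpec(MM(1, 1), MM(1, 1)))
        assert r.domain == "degenerate"

    def test_delta_generalization_matches_scaled_vmax(self):
        # a 5:6 cycle behaves like delta*Vmax_a in all formulas
        spec = SimpleCycleSpec(MM(5, 1), MM(2, 4), delta=0.2)
        scaled = SimpleCycleSpec(MM(1, 1), MM(2, 4), delta=1)
        ra, rb = steady_state_simple(spec), steady_state_simple(scaled)
        assert ra.domain == rb.domain == "I"
        assert ra.states[0].X == pytest.approx(rb.states[0].X)

    def test_swapping_fa_fb_reclassifies(self):
        assert classify_domain(DOMAIN_I) == "I"
        swapped = SimpleCycleSpec(DOMAIN_I.fb, DOMAIN_I.fa)
        assert classify_domain(swapped) == "III"


class TestExistenceIffConditions:
    def test_iff_over_1e5_draws(self, rng):
        """Stable positive state <=> Vb > d*Va and Vb/Kb < d*Va/Ka, and every
        stable draw has KM_b > KM_a; X* solves delta*fa = fb by substitution."""
        n = 100_000
        va, vb = rng.lognormal(0, 1, n), rng.lognormal(0, 1, n)
        ka, kb = rng.lognormal(0, 1, n), rng.lognormal(0, 1, n)
        delta = np.where(rng.random(n) < 0.5, 1.0, 0.25)
        vae = delta * va
        cond = (vb > vae) & (vb / kb < vae / ka)
        xstar = (vb * ka - vae * kb) / (vae - vb)
        exists_stable = cond
        # closed form positive exactly on the condition set
        assert np.all(xstar[cond] > 0)
        assert np.all(kb[cond] > ka[cond])
        # substitution residual
        resid = vae * xstar / (ka + xstar) - vb * xstar / (kb + xstar)
        assert np.max(np.abs(resid[cond]) / vb[cond]) < 1e-9
        # draws violating either inequality never give a stable positive root
        bad = ~cond & (xstar > 0)
        # where a positive root exists outside the condition set, it must be
        # unstable: d(delta*fa - fb)/dX > 0 there
        dslope = (
            vae[bad] * ka[bad] / (ka[bad] + xstar[bad]) ** 2
            - vb[bad] * kb[bad] / (kb[bad] + xstar[bad]) ** 2
        )
        assert np.all(dslope > 0)

    def test_domain_I_root_matches_bisection(self, rng):
        found = 0
        while found < 50:
            va, vb = rng.lognormal(0, 1), rng.lognormal(0, 1)
            ka, kb = rng.lognormal(0, 1), rng.lognormal(0, 1)
            spec = SimpleCycleSpec(MM(va, ka), MM(vb, kb))
            if classify_domain(spec) != "I":
                continue
            x_analytic = steady_state_simple(spec).states[0].X
            root = brentq(spec.net_production, 1e-12 * ka, 1e6 * (ka + kb + x_analytic))
            assert x_analytic == pytest.approx(root, rel=1e-9)
            found += 1


class TestInputFlux:
    def test_single_stable_state_example(self):
        spec = SimpleCycleSpec(MM(1, 1), MM(3, 1), fi=0.5)
        r = steady_states_with_input(spec)
        (s,) = r.states
        assert s.X == pytest.approx(1 / 3)
        assert s.stable and not r.zero_exists

    def test_branch_smaller_than_input_diverges(self):
        r = steady_states_with_input(SimpleCycleSpec(MM(1, 1), MM(0.4, 1), fi=0.5))
        assert r.divergent and r.states == ()

    def test_two_state_case_lower_is_stable(self):
        # Vb < fi + Va but steep branch slope: two crossings
        spec = SimpleCycleSpec(MM(2, 1), MM(1.5, 0.05), fi=0.01)
        r = steady_states_with_input(spec)
        assert len(r.states) == 2
        low, high = r.states
        assert low.X < high.X and low.stable and not high.stable

    def test_fi_to_zero_limit_recovers_simple(self):
        base = steady_state_simple(DOMAIN_I).states[0].X
        withfi = steady_states_with_input(
            SimpleCycleSpec(DOMAIN_I.fa, DOMAIN_I.fb, fi=1e-9)
        )
        stable_xs = [s.X for s in withfi.states if s.stable]
        assert min(abs(x - base) for x in stable_xs) < 1e-6


class TestSensitivities:
    def test_closed_form_example(self):
        sens = sensitivity_signs(DOMAIN_I)
        assert sens["KM_a"] == pytest.approx(-2.0)
        assert sens["KM_a"] < 0 and sens["KM_b"] > 0
        assert sens["Vmax_a"] > 0 and sens["Vmax_b"] < 0

    @pytest.mark.parametrize("param,field", [
        ("KM_a", "fa"), ("KM_b", "fb"), ("Vmax_a", "fa"), ("Vmax_b", "fb"),
    ])
    def test_matches_finite_difference(self, param, field):
        spec = DOMAIN_I
        sens = sensitivity_signs(spec)
        h = 1e-7

        def xstar(s):
            return steady_state_simple(s).states[0].X

        fa, fb = spec.fa, spec.fb
        if param == "KM_a":
            pert = SimpleCycleSpec(MM(fa.Vmax, fa.KM + h), fb)
        elif param == "KM_b":
            pert = SimpleCycleSpec(fa, MM(fb.Vmax, fb.KM + h))
        elif param == "Vmax_a":
            pert = SimpleCycleSpec(MM(fa.Vmax + h, fa.KM), fb)
        else:
            pert = SimpleCycleSpec(fa, MM(fb.Vmax + h, fb.KM))
        fd = (xstar(pert) - xstar(spec)) / h
        assert sens[param] == pytest.approx(fd, rel=1e-5)

    def test_uniform_vmax_scaling_leaves_xstar_unchanged(self):
        spec = DOMAIN_I
        scaled = SimpleCycleSpec(MM(3 * spec.fa.Vmax, spec.fa.KM), MM(3 * spec.fb.Vmax, spec.fb.KM))
        assert steady_state_simple(scaled).states[0].X == pytest.approx(
            steady_state_simple(spec).states[0].X
        )

    def test_outside_domain_I_raises(self):
        with pytest.raises(DomainError):
            sensitivity_signs(DOMAIN_III)


class TestBisubstrateBounds:
    def test_random_order_A_bound_example(self):
        b = BisubstrateKinetics("random_order", Vmax=2, KA=1, KX=2, KiA=1)
        bounds = bisubstrate_stable_region(b, MM(1, 4))
        assert bounds.A_lower == pytest.approx(1 / 3)
        assert bounds.KM_b_lower == pytest.approx(2 / max(1, 1 / 1))

    def test_ordered_A_first_km_bound_is_KX(self, rng):
        for _ in range(20):
            b = BisubstrateKinetics(
                "ordered_A_first",
                Vmax=float(rng.lognormal(0, 1)),
                KX=float(rng.lognormal(0, 1)),
                KiA=float(rng.lognormal(0, 1)),
            )
            branch = MM(float(rng.lognormal(0, 1)), float(rng.lognormal(0, 1)))
            assert bisubstrate_stable_region(b, branch).KM_b_lower == b.KX

    def test_ordered_X_first_has_no_km_bound(self):
        b = BisubstrateKinetics("ordered_X_first", Vmax=2, KA=1, KiX=3)
        bounds = bisubstrate_stable_region(b, MM(1, 4))
        assert bounds.KM_b_lower is None
        assert bounds.A_lower == pytest.approx(1 * 3 * 1 / (4 * 2))
        assert bounds.satisfiable

    def test_unsatisfiable_A_bound_flagged(self):
        # KM_b*Vmax <= Vmax_b*KX makes the A inequality unsatisfiable
        b = BisubstrateKinetics("random_order", Vmax=1, KA=1, KX=5, KiA=1)
        bounds = bisubstrate_stable_region(b, MM(2, 1))
        assert math.isinf(bounds.A_lower) and not bounds.satisfiable

    def test_xstar_zero_at_bound_and_small_above(self):
        b = BisubstrateKinetics("random_order", Vmax=2, KA=1, KX=2, KiA=1)
        branch = MM(1, 4)
        a_lo = bisubstrate_stable_region(b, branch).A_lower
        assert xstar_vs_A(b, branch, a_lo) == 0.0
        assert 0 < xstar_vs_A(b, branch, a_lo * 1.001) < 0.05
        with pytest.raises(DomainError):
            xstar_vs_A(b, branch, a_lo * 0.5)

    def test_xstar_diverges_near_upper_bound(self):
        b = BisubstrateKinetics("random_order", Vmax=2, KA=1, KX=2, KiA=1)
        branch = MM(1, 4)
        a_hi = bisubstrate_stable_region(b, branch).A_upper
        assert xstar_vs_A(b, branch, a_hi * 0.999) > 100
        with pytest.raises(DomainError):
            xstar_vs_A(b, branch, a_hi * 1.1)

    def test_xstar_composition_oracle_all_schemes(self, rng):
        """Closed-form X*(A) equals the apparent-constants + simple-cycle
        pipeline on random stable draws of every scheme."""
        checked = {s: 0 for s in ("random_order", "ordered_A_first", "ordered_X_first", "ping_pong")}
        trials = 0
        while min(checked.values()) < 25 and trials < 20000:
            trials += 1
            scheme = list(checked)[trials % 4]
            kwargs = {"scheme": scheme, "Vmax": float(rng.lognormal(0, 0.7))}
            for name in BisubstrateKinetics._REQUIRED[scheme]:
                kwargs[name] = float(rng.lognormal(0, 0.7))
            b = BisubstrateKinetics(**kwargs)
            branch = MM(float(rng.lognormal(0, 0.7)), float(rng.lognormal(0, 0.7)))
            bounds = bisubstrate_stable_region(b, branch)
            if not bounds.satisfiable:
                continue
            hi = bounds.A_upper if bounds.A_upper is not None else max(bounds.A_lower, 1.0) * 10
            lo = bounds.A_lower
            if hi <= lo:
                continue
            A = lo + 0.5 * (hi - lo) if lo > 0 else 0.5 * hi
            if A <= 0:
                continue
            try:
                x_closed = xstar_vs_A(b, branch, A)
            except DomainError:
                continue
            app = apparent_constants(b, A)
            report = steady_state_simple(SimpleCycleSpec(app, branch))
            if not report.states:
                assert x_closed == pytest.approx(0.0, abs=1e-9)
                continue
            assert x_closed == pytest.approx(report.states[0].X, rel=1e-9)
            checked[scheme] += 1
        assert min(checked.values()) >= 25


class TestReversibleBranch:
    def test_large_D_matches_irreversible(self):
        # same MM shape as DOMAIN_I with the branch KX playing KM_b
        spec = ReversibleBranchSpec(fa=MM(1, 1), Vmax_b=2, KX=4, KY=1, D=1000.0)
        rep = reversible_branch_analysis(spec)
        assert rep.regime == "fast_sink"
        xs = [x for x, _, stable in rep.states if stable]
        assert xs and xs[0] == pytest.approx(2.0, rel=0.01)

    def test_vmaxb_to_infinity_limit(self):
        D = 0.2
        spec = ReversibleBranchSpec(fa=MM(1, 1), Vmax_b=1e8, KX=4, KY=1, D=D)
        rep = reversible_branch_analysis(spec)
        xs = [x for x, _, stable in rep.states if stable]
        assert xs and xs[0] == pytest.approx(1 / D - 1, rel=1e-4)

    def test_vmaxb_below_vmaxa_not_globally_stabilizable(self):
        spec = ReversibleBranchSpec(fa=MM(2, 1), Vmax_b=1, KX=4, KY=1, D=1.0)
        assert not reversible_branch_analysis(spec).globally_stabilizable

    def test_stability_verdict_matches_numeric_eigenvalues(self, rng):
        checked = 0
        while checked < 100:
            spec = ReversibleBranchSpec(
                fa=MM(float(rng.lognormal(0, 0.5)), float(rng.lognormal(0, 0.5))),
                Vmax_b=float(rng.lognormal(0.5, 0.5)),
                KX=float(rng.lognormal(0, 0.5)),
                KY=float(rng.lognormal(0, 0.5)),
                D=float(rng.lognormal(0, 1)),
            )
            rep = reversible_branch_analysis(spec)
            for x, y, stable in rep.states:
                eigs = np.linalg.eigvals(spec.jacobian(x, y))
                if abs(np.max(eigs.real)) < 1e-9:
                    continue  # marginal: skip knife-edge draws
                assert stable == bool(np.max(eigs.real) < 0)
                checked += 1


class TestReversibleAutocatalytic:
    def test_slope_above_branch_slope(self):
        assert reversible_autocatalytic_min_Vmax(2.0, MM(1, 1))

    def test_boundary_is_strict(self):
        assert not reversible_autocatalytic_min_Vmax(1.0, MM(1, 1))

    def test_sweep_flips_once(self):
        branch = MM(3, 2)
        verdicts = [
            reversible_autocatalytic_min_Vmax(s, branch) for s in np.linspace(0.1, 4, 200)
        ]
        flips = sum(a != b for a, b in zip(verdicts, verdicts[1:]))
        assert flips == 1 and not verdicts[0] and verdicts[-1]
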