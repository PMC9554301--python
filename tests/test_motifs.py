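"""Motif library: each builder's circuit reproduces its reaction scheme."""

import dataclasses

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import brentq

import circuitkinetics as ck
from circuitkinetics import (
    BiBiRates,
    Circuit,
    InhibitionParameters,
    MMParameters,
    build_inhibition,
    build_mm_exact,
    build_mm_qssa,
    build_product_feedback,
    build_reversible_bibi,
    build_two_substrate,
    build_txtl,
    compile_circuit,
    simulate,
)
from circuitkinetics.motifs import bibi_step_net_fluxes


def _all_motif_circuits(inhibition_base, bibi_rates, txtl_params):
    mm = MMParameters(K_m=0.167e-3, k_cat=2903.0, E0=0.3e-9, S0=1.2e-3)
    exact = MMParameters(k_cat=500.0, E0=1e-8, S0=2e-3, k_f=1e7, k_r=2e-3 * 1e7 - 500.0)
    yield "mm_qssa", build_mm_qssa(mm)
    yield "mm_exact", build_mm_exact(exact)
    for t, extra in [
        ("competitive", {}),
        ("noncompetitive", {}),
        ("uncompetitive", {}),
        ("mixed", dict(K_m2=4e-3, K_i2=6e-3)),
    ]:
        yield f"inhibition_{t}", build_inhibition(
            InhibitionParameters(inhibition_type=t, **inhibition_base, **extra)
        )
    yield "product_feedback", build_product_feedback(
        InhibitionParameters(
            K_m=0.167e-3, k_cat=2903.0, K_i=13.7e-3, E0=0.7e-9, S0=1e-3,
            I0=0.0, inhibition_type="competitive",
        ),
        Gal0=40e-3,
    )
    for order in ("random", "A_first", "B_first"):
        yield f"two_substrate_{order}", build_two_substrate(
            1e-3, 2e-3, 500.0, order, 2e-3, 2e-3, 1e-8
        )
    yield "reversible_bibi", build_reversible_bibi(bibi_rates)
    yield "txtl", build_txtl(txtl_params)


def test_every_motif_validates_clean(inhibition_base, bibi_rates, txtl_params):
    for name, circuit in _all_motif_circuits(inhibition_base, bibi_rates, txtl_params):
        assert circuit.validate() == [], name


class TestMMExact:
    def test_no_enzyme_means_no_product(self):
        p = MMParameters(k_cat=500.0, E0=0.0, S0=2e-3, k_f=1e6, k_r=1500.0)
        traj = simulate(build_mm_exact(p), 100.0)
        assert np.all(traj.values["P"] == 0.0)

    def test_initial_complex_formation_rate(self):
        # d[ES]/dt at t=0 with ES=0 is k_f*S0*E0
        p = MMParameters(k_cat=500.0, E0=1e-8, S0=2e-3, k_f=1e6, k_r=1500.0)
        system = compile_circuit(build_mm_exact(p))
        rhs = system.rhs(system.y0, np.empty(0))
        i_es = system.dynamic_layout.index("ES")
        assert rhs[i_es] == pytest.approx(p.k_f * p.S0 * p.E0, rel=1e-12)

    def test_fast_binding_matches_qssa_product_curve(self):
        K_m, k_cat, E0, S0 = 0.167e-3, 2903.0, 0.3e-9, 1.2e-3
        k_f = 1e8
        exact = simulate(
            build_mm_exact(
                MMParameters(k_cat=k_cat, E0=E0, S0=S0, k_f=k_f, k_r=K_m * k_f - k_cat)
            ),
            1800.0,
        )
        qssa = simulate(
            build_mm_qssa(MMParameters(K_m=K_m, k_cat=k_cat, E0=E0, S0=S0)), 1800.0
        )
        # compare after the fast complex-formation transient
        late = exact.times > 5.0
        np.testing.assert_allclose(
            exact.values["P"][late], qssa.values["P"][late], rtol=0.01
        )

    def test_inconsistent_grouped_constants_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            MMParameters(k_cat=500.0, E0=1e-8, S0=2e-3, K_m=1e-3, k_f=1e6, k_r=1500.0)

    def test_missing_elementary_constants_redirect_to_qssa(self):
        p = MMParameters(K_m=1e-3, k_cat=500.0, E0=1e-8, S0=2e-3)
        with pytest.raises(ValueError, match="build_mm_qssa"):
            build_mm_exact(p)


class TestMMQssa:
    def test_resistor_is_reciprocal_km(self, betagal_params):
        circuit = build_mm_qssa(betagal_params)
        assert circuit.fluxes["I_km"].resistance == pytest.approx(1.0 / 0.167e-3)
        assert round(circuit.metadata["R_ohm"]) == 5988

    def test_initial_rate_closed_form(self, betagal_params):
        p = betagal_params
        traj = simulate(build_mm_qssa(p), 60.0)
        v0 = stats.linregress(traj.times[:50], traj.values["P"][:50]).slope
        expected = p.k_cat * p.E0 * p.S0 / (p.K_m + p.S0)
        assert v0 == pytest.approx(expected, rel=0.02)

    def test_tight_binding_uses_quadratic_not_hyperbola(self):
        # E0 = S0 = K_m: free-ligand hyperbola is wrong; circuit matches the
        # conservation-coupled quadratic root.
        E0 = S0 = K_m = 1e-6
        system = compile_circuit(
            build_mm_qssa(MMParameters(K_m=K_m, k_cat=10.0, E0=E0, S0=S0))
        )
        es = system.solve_algebraic(np.array([0.0]))[0]
        oracle = brentq(lambda x: (S0 - x) * (E0 - x) - x * K_m, 0.0, min(E0, S0))
        hyperbola = E0 * S0 / (K_m + S0)
        assert es == pytest.approx(oracle, rel=1e-9)
        assert abs(es - hyperbola) / hyperbola > 0.2  # regimes genuinely differ


class TestInhibition:
    def test_type_constant_consistency_enforced(self, inhibition_base):
        with pytest.raises(ValueError, match="K_m2 = K_m"):
            InhibitionParameters(
                inhibition_type="noncompetitive", K_m2=4e-3, **inhibition_base
            )
        with pytest.raises(ValueError, match="no ESI branch"):
            InhibitionParameters(
                inhibition_type="competitive", K_i2=6e-3, **inhibition_base
            )
        with pytest.raises(ValueError, match="independent K_m2 and K_i2"):
            InhibitionParameters(inhibition_type="mixed", **inhibition_base)

    def test_mixed_with_equal_constants_is_noncompetitive(self, inhibition_base):
        """Reduction lattice: mixed with K_m2=K_m, K_i2=K_i equals the
        independently built noncompetitive circuit, trajectory for trajectory."""
        mixed = build_inhibition(
            InhibitionParameters(
                inhibition_type="mixed",
                K_m2=inhibition_base["K_m"], K_i2=inhibition_base["K_i"],
                **inhibition_base,
            )
        )
        noncomp = build_inhibition(
            InhibitionParameters(inhibition_type="noncompetitive", **inhibition_base)
        )
        t1 = simulate(mixed, 600.0)
        t2 = simulate(noncomp, 600.0)
        np.testing.assert_allclose(t1.values["P"], t2.values["P"], rtol=1e-9)

    def test_mixed_with_huge_ternary_constants_approaches_competitive(
        self, inhibition_base
    ):
        """Reduction lattice: K_m2, K_i2 -> infinity starves the ESI branch."""
        mixed = build_inhibition(
            InhibitionParameters(
                inhibition_type="mixed", K_m2=1e6, K_i2=1e6, **inhibition_base
            )
        )
        comp = build_inhibition(
            InhibitionParameters(inhibition_type="competitive", **inhibition_base)
        )
        t1 = simulate(mixed, 600.0)
        t2 = simulate(comp, 600.0)
        np.testing.assert_allclose(t1.values["P"], t2.values["P"], rtol=1e-4)

    def test_uncompetitive_matches_hand_built_circuit(self, inhibition_base):
        """The library's uncompetitive motif equals a circuit assembled from
        raw primitives following the scheme (ES + I <-> ESI, no EI branch)."""
        b = inhibition_base
        hand = Circuit("hand_uncompetitive")
        hand.add_species("ES", "algebraic")
        hand.add_species("ESI", "algebraic")
        hand.add_species("P", "dynamic")
        hand.add_pool("E_free", b["E0"], [("ES", 1.0), ("ESI", 1.0)])
        hand.add_pool("S_free", b["S0"], [("ES", 1.0), ("ESI", 1.0), ("P", 1.0)])
        hand.add_pool("I_free", b["I0"], [("ESI", 1.0)])
        hand.add_transconductor("f1", 1.0, ["E_free", "S_free"], "ES")
        hand.add_decay("r1", "ES", 1.0 / b["K_m"])
        hand.add_transconductor("f2", 1.0, ["ES", "I_free"], "ESI")
        hand.add_decay("r2", "ESI", 1.0 / b["K_i"])
        hand.add_transconductor("cat", b["k_cat"], ["ES"], "P")
        lib = build_inhibition(
            InhibitionParameters(inhibition_type="uncompetitive", **b)
        )
        t1 = simulate(hand, 600.0)
        t2 = simulate(lib, 600.0)
        np.testing.assert_allclose(t1.values["P"], t2.values["P"], rtol=1e-9)

    def test_no_inhibitor_reduces_to_plain_mm(self, inhibition_base):
        b = dict(inhibition_base, I0=0.0)
        inhib = build_inhibition(
            InhibitionParameters(inhibition_type="noncompetitive", **b)
        )
        mm = build_mm_qssa(
            MMParameters(K_m=b["K_m"], k_cat=b["k_cat"], E0=b["E0"], S0=b["S0"])
        )
        t1 = simulate(inhib, 600.0)
        t2 = simulate(mm, 600.0)
        np.testing.assert_allclose(t1.values["P"], t2.values["P"], rtol=1e-8)

    @pytest.mark.parametrize(
        "itype, extra, alpha, alpha_prime",
        [
            ("competitive", {}, 2.0, 1.0),
            ("noncompetitive", {}, 2.0, 2.0),
            ("uncompetitive", {}, 1.0, 2.0),
            ("mixed", dict(K_m2=4e-3, K_i2=6e-3), 2.0, 1.5),
        ],
    )
    def test_initial_rates_match_closed_forms(
        self, inhibition_base, itype, extra, alpha, alpha_prime
    ):
        """V0(S) = V_max*S/(K_m*alpha + S*alpha') with the classic
        (alpha, alpha') per mechanism, at trace enzyme."""
        b = inhibition_base
        v_max = b["k_cat"] * b["E0"]
        grid = np.geomspace(0.5e-3, 20e-3, 16)
        for s0 in grid[::5]:
            circuit = build_inhibition(
                InhibitionParameters(inhibition_type=itype, **{**b, "S0": s0}, **extra)
            )
            traj = simulate(circuit, 5.0)
            v0 = stats.linregress(traj.times[:25], traj.values["P"][:25]).slope
            expected = v_max * s0 / (b["K_m"] * alpha + s0 * alpha_prime)
            assert v0 == pytest.approx(expected, rel=0.005), (itype, s0)


class TestProductFeedback:
    def test_disabled_feedback_reduces_to_plain_mm(self):
        p = InhibitionParameters(
            K_m=0.167e-3, k_cat=2903.0, K_i=1e6, E0=0.7e-9, S0=1e-3,
            I0=0.0, inhibition_type="competitive",
        )
        fb = simulate(build_product_feedback(p, Gal0=0.0), 3600.0)
        mm = simulate(
            build_mm_qssa(MMParameters(K_m=p.K_m, k_cat=p.k_cat, E0=p.E0, S0=p.S0)),
            3600.0,
        )
        np.testing.assert_allclose(fb.values["P"], mm.values["P"], rtol=1e-6)

    def test_added_product_slows_reaction_at_every_time(self):
        p = InhibitionParameters(
            K_m=0.167e-3, k_cat=2903.0, K_i=13.7e-3, E0=0.7e-9, S0=1e-3,
            I0=0.0, inhibition_type="competitive",
        )
        with_gal = simulate(build_product_feedback(p, Gal0=40e-3), 7200.0)
        without = simulate(build_product_feedback(p, Gal0=0.0), 7200.0)
        assert np.all(with_gal.values["P"][1:] <= without.values["P"][1:] * (1 + 1e-9))
        assert with_gal.values["P"][-1] < without.values["P"][-1]

    def test_substrate_still_fully_consumed(self):
        # inhibition slows but does not consume substrate
        p = InhibitionParameters(
            K_m=0.167e-3, k_cat=2903.0, K_i=13.7e-3, E0=0.7e-9, S0=0.5e-3,
            I0=0.0, inhibition_type="competitive",
        )
        traj = simulate(build_product_feedback(p, Gal0=20e-3), 3e4)
        assert traj.values["P"][-1] == pytest.approx(0.5e-3, rel=1e-3)


class TestTwoSubstrate:
    def test_symmetric_orders_identical(self):
        a = simulate(build_two_substrate(1e-3, 1e-3, 500.0, "A_first", 2e-3, 2e-3, 1e-8), 500.0)
        b = simulate(build_two_substrate(1e-3, 1e-3, 500.0, "B_first", 2e-3, 2e-3, 1e-8), 500.0)
        np.testing.assert_allclose(a.values["P"], b.values["P"], rtol=1e-10)

    def test_unknown_order_rejected(self):
        with pytest.raises(ValueError, match="unknown binding order"):
            build_two_substrate(1e-3, 1e-3, 500.0, "C_first", 2e-3, 2e-3, 1e-8)

    def test_zero_kcat_still_equilibrates_binding(self):
        traj = simulate(build_two_substrate(1e-3, 1e-3, 0.0, "random", 2e-3, 2e-3, 1e-8), 100.0)
        assert np.all(traj.values["P"] == 0.0)
        assert traj.values["EAB"][-1] > 0.0

    @pytest.mark.parametrize(
        "A0, B0, KdA, KdB",
        [
            (1e-3, 4e-3, 1e-3, 1e-3),   # A has smaller S/Kd via concentration
            (2e-3, 2e-3, 2e-3, 0.5e-3), # A has smaller S/Kd via larger Kd
            (1e-3, 2e-3, 1e-3, 1e-3),
        ],
    )
    def test_binding_smaller_s_over_kd_first_is_never_slower(self, A0, B0, KdA, KdB):
        """Time to half-completion for the order that binds the smaller-S/Kd
        substrate first is <= the opposite order."""
        assert A0 / KdA < B0 / KdB
        def t_half(order):
            traj = simulate(build_two_substrate(KdA, KdB, 500.0, order, A0, B0, 1e-8), 4000.0)
            target = min(A0, B0) / 2
            idx = np.searchsorted(traj.values["P"], target)
            assert idx < len(traj.times), "did not reach half-completion"
            return traj.times[idx]
        assert t_half("A_first") <= t_half("B_first")


class TestReversibleBiBi:
    def test_irreversible_limit_converts_limiting_pool(self):
        rates = BiBiRates(
            k1=1e6, km1=0.0, k2=1e5, km2=0.0, k3=300.0, km3=0.0,
            k4=500.0, km4=0.0, k5=200.0, km5=0.0,
            E0=3.9e-9, NAD0=4e-3, S0=10e-3,
        )
        traj = simulate(build_reversible_bibi(rates), 5e4)
        assert traj.values["P"][-1] == pytest.approx(min(rates.S0, rates.NAD0), rel=1e-3)

    def test_detailed_balance_at_equilibrium(self, bibi_rates):
        traj = simulate(build_reversible_bibi(bibi_rates), 2e5)
        final = traj.state_at(len(traj.times) - 1)
        nets = bibi_step_net_fluxes(bibi_rates, final)
        scale = bibi_rates.k1 * bibi_rates.E0 * bibi_rates.NAD0
        for step, net in enumerate(nets, start=1):
            assert abs(net) / scale < 1e-6, f"step {step} not balanced"

    def test_nad_moiety_conserved_throughout(self, bibi_rates):
        """NAD0 = [NAD+] + [E-NAD] + [E-NAD-S] + [E-NADH-P] + [E-NADH] + [NADH]
        at every output time, the free-NAD term assembled via the pool."""
        circuit = build_reversible_bibi(bibi_rates)
        traj = simulate(circuit, 2e5)
        bound = sum(
            traj.values[n] for n in ("E_NAD", "E_NAD_S", "E_NADH_P", "E_NADH", "NADH")
        )
        free = np.array(
            [circuit.free_value("NAD_free", traj.state_at(k)) for k in range(len(traj.times))]
        )
        np.testing.assert_allclose(free + bound, bibi_rates.NAD0, rtol=1e-12)
        assert np.all(free >= -1e-12)

    def test_missing_rate_constant_rejected(self):
        with pytest.raises(ValueError):
            BiBiRates(k1=-1.0, km1=0, k2=0, km2=0, k3=0, km3=0, k4=0, km4=0, k5=0, km5=0)


class TestTxtl:
    def test_sequestration_multiplier_arithmetic(self, txtl_params):
        # k_TX = 0.05/s, Lm = 1000 nt, Cm = 50 nt/s -> 1 + 1 = 2
        assert ck.rnap_multiplier(txtl_params) == pytest.approx(2.0)
        circuit = build_txtl(txtl_params)
        assert circuit.metadata["rnap_multiplier"] == pytest.approx(2.0)
        rnap_pool = circuit.pools["RNAP_free"]
        assert dict(rnap_pool.deductions)["DNA_RNAP"] == pytest.approx(2.0)

    def test_no_repressor_reduces_to_uninhibited(self, txtl_params):
        traj = simulate(build_txtl(txtl_params), 4000.0)
        assert np.all(traj.values["DNA_TetR"] == 0.0)
        assert np.all(traj.values["DNA_RNAP_TetR"] == 0.0)
        assert traj.values["GFP"][-1] > 0.0

    def test_repression_monotone_in_tetr(self, txtl_params):
        def steady_production_rate(tetr0):
            p = dataclasses.replace(txtl_params, TetR0=tetr0)
            traj = simulate(build_txtl(p), 4000.0)
            total = traj.values["GFP"] + traj.values["GFP_dark"]
            late = traj.times > 2000.0
            return stats.linregress(traj.times[late], total[late]).slope
        rates = [steady_production_rate(t) for t in (0.0, 5e-9, 20e-9, 100e-9)]
        assert all(a > b for a, b in zip(rates, rates[1:]))

    def test_template_doubling_doubles_output_in_linear_regime(self, txtl_params):
        base = dataclasses.replace(txtl_params, DNA0=1e-9, RNAP0=2000e-9)
        doubled = dataclasses.replace(base, DNA0=2e-9)
        def steady_rate(p):
            traj = simulate(build_txtl(p), 4000.0)
            total = traj.values["GFP"] + traj.values["GFP_dark"]
            late = traj.times > 2000.0
            return stats.linregress(traj.times[late], total[late]).slope
        ratio = steady_rate(doubled) / steady_rate(base)
        assert ratio == pytest.approx(2.0, rel=0.05)
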