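"""Behaviour of the individual circuit designs under the deterministic semantics."""

import numpy as np
import pytest

import crnasync as ca

HI = 10.0


def ode(circuit, horizon=2.0, **extra):
    crs = circuit.with_initial(extra).crs if extra else circuit.crs
    return ca.simulate_ode(crs, horizon)


class TestStructure:
    def test_motif_counts(self):
        m = ca.build_motif()
        assert len(m.crs.reactions) == 2 and len(m.crs.names) == 4

    def test_am_counts(self):
        am = ca.build_am()
        assert len(am.reactions) == 4 and len(am.names) == 3

    @pytest.mark.parametrize("name", list(ca.COMPONENTS))
    def test_all_reactions_bimolecular_catalytic(self, name):
        built = ca.COMPONENTS[name]()
        crs = built.crs if isinstance(built, ca.DualRailCircuit) else built
        for rxn in crs.reactions:
            assert rxn.order == 2
            assert sum(c for _, c in rxn.products) == 2
            # 2->2 reactions conserve the grand total
            assert sum(rxn.net().values()) == 0
            assert rxn.rate == 1.0  # uniform rates throughout


class TestAm:
    def test_majority_wins(self):
        crs = ca.build_am().with_initial({"X": 8, "Y": 2})
        traj = ca.simulate_ode(crs, 5.0)
        assert traj.value("X", 5.0) > 9.5 and traj.value("Y", 5.0) < 0.5

    def test_symmetric_start_stays_symmetric(self):
        crs = ca.build_am().with_initial({"X": 5, "Y": 5})
        traj = ca.simulate_ode(crs, 2.0)
        assert np.allclose(traj["X"], traj["Y"], atol=1e-7)

    def test_total_conserved(self):
        crs = ca.build_am().with_initial({"X": 6, "Y": 3, "lam": 1})
        traj = ca.simulate_ode(crs, 2.0)
        assert np.max(np.abs(traj["X"] + traj["Y"] + traj["lam"] - 10)) < 1e-6


class TestDualRailAm:
    def test_consensus_to_low(self, dual_rail_am_lowlow):
        traj = ca.simulate_ode(dual_rail_am_lowlow.crs, 1.0)
        assert traj.value("Zlo", 0.5) > 9.5
        assert traj.value("Zhi", 0.5) < 0.5

    def test_reference_failure_mode_values(self, dual_rail_am_mixed):
        """Mixed input leaves Z_hi at ~6 and lam at ~4: below the 8-molecule bar."""
        traj = ca.simulate_ode(dual_rail_am_mixed.crs, 1.0)
        assert traj.value("Zhi", 0.3) == pytest.approx(6.0, abs=0.5)
        assert traj.value("lam", 0.3) == pytest.approx(4.0, abs=0.5)
        # analytic steady state of the mixed configuration
        assert traj.value("Zhi", 1.0) == pytest.approx((math_sqrt500 - 10) / 2, abs=1e-3)

    def test_output_pool_conserved(self, dual_rail_am_mixed):
        traj = ca.simulate_ode(dual_rail_am_mixed.crs, 1.0)
        assert np.max(np.abs(traj["Zhi"] + traj["Zlo"] + traj["lam"] - 10)) < 1e-6


math_sqrt500 = 500.0 ** 0.5


class TestArbiter:
    def test_present_input_promoted(self):
        arb = ca.build_arbiter(initial_output=None).with_initial({"Xhi": 5})
        traj = ca.simulate_ode(arb.crs, 1.0)
        assert traj.value("Yhi", 0.4) > 9.5

    def test_rail_swap_symmetry(self):
        a = ca.build_arbiter(initial_output=None).with_initial({"Xhi": 5})
        b = ca.build_arbiter(initial_output=None).with_initial({"Xlo": 5})
        ta, tb = ca.simulate_ode(a.crs, 1.0), ca.simulate_ode(b.crs, 1.0)
        assert np.allclose(ta["Yhi"], tb["Ylo"], atol=1e-7)

    def test_no_input_no_motion(self):
        arb = ca.build_arbiter(initial_output=None)
        traj = ca.simulate_ode(arb.crs, 1.0)
        assert np.all(traj["lam"] == 10.0)


class TestCElement:
    def test_both_low_flips_to_low_within_1s(self):
        c = ca.build_c_element(initial_output=1).with_input_assignment({"X": 0, "Y": 0})
        traj = ca.simulate_ode(c.crs, 2.0)
        assert traj.value("Zlo", 1.0) > 9.5

    def test_both_high_flips_to_high_within_1s(self):
        c = ca.build_c_element(initial_output=0).with_input_assignment({"X": 1, "Y": 1})
        traj = ca.simulate_ode(c.crs, 2.0)
        assert traj.value("Zhi", 1.0) > 9.5

    @pytest.mark.parametrize("state", [0, 1])
    @pytest.mark.parametrize("bits", [(0, 1), (1, 0)])
    def test_mixed_inputs_leave_output_unchanged(self, state, bits):
        """The C-element contract's 'unchanged' rows: the held rail never drops below 9.5."""
        c = ca.build_c_element(initial_output=state).with_input_assignment(
            {"X": bits[0], "Y": bits[1]}
        )
        traj = ca.simulate_ode(c.crs, 5.0)
        rail = "Zhi" if state == 1 else "Zlo"
        assert float(traj[rail].min()) > HI - 0.5

    def test_single_am_candidate_violates_unchanged(self, dual_rail_am_mixed):
        """The flaw the two-stage design fixes: the single AM drops to ~6."""
        traj = ca.simulate_ode(dual_rail_am_mixed.crs, 5.0)
        assert float(traj["Zhi"].min()) < 8.0

    def test_weak_inputs_boosted_to_full_output(self):
        c = ca.build_c_element(initial_output=None).with_initial({"Xhi": 6, "Yhi": 4})
        traj = ca.simulate_ode(c.crs, 2.0)
        assert traj.value("Zhi", 2.0) > 9.5

    def test_reusable_after_input_swap(self):
        """After converging high, injected input inversion flips the output."""
        c = ca.build_c_element(initial_output=0).with_input_assignment({"X": 1, "Y": 1})
        events = [
            ca.InjectionEvent.make(2.0, [
                ca.Reaction.make(["Xhi"], ["Xlo"]),
                ca.Reaction.make(["Yhi"], ["Ylo"]),
            ])
        ]
        traj = ca.simulate_ode(c.crs, 8.0, schedule=events)
        assert traj.value("Zhi", 2.0) > 9.5  # converged high before the swap
        assert traj.value("Zlo", 8.0) > 9.5  # flipped low after it


class TestLatches:
    def test_both_designs_follow_input(self):
        for kind in ("simple", "with_reset"):
            latch = ca.build_latch(kind).with_initial({"Xhi": HI, "Ylo": HI})
            traj = ca.simulate_ode(latch.crs, 1.0)
            assert traj.value("Yhi", 1.0) > 9.5, kind

    def test_faster_design_timing(self):
        """The faster of the two reaches ~8.7 at 0.2 s, full value by 0.5 s."""
        best = {}
        for kind in ("simple", "with_reset"):
            latch = ca.build_latch(kind).with_initial({"Xhi": HI, "Ylo": HI})
            traj = ca.simulate_ode(latch.crs, 1.0)
            best[kind] = traj.value("Yhi", 0.2)
        faster = max(best.values())
        assert faster == pytest.approx(10 * (1 - np.exp(-2.0)), abs=0.01)
        assert best["simple"] > best["with_reset"]

    def test_simple_latch_holds_with_input_removed(self):
        latch = ca.build_latch("simple").with_initial({"Yhi": HI, "Ylo": 0})
        traj = ca.simulate_ode(latch.crs, 2.0)
        assert traj.value("Yhi", 2.0) > 9.5

    def test_reset_returns_to_neutral(self):
        latch = ca.build_latch("with_reset").with_initial({"Yhi": HI, "Ylo": 0, "Rhi": HI})
        traj = ca.simulate_ode(latch.crs, 3.0)
        assert traj.value("Yhi", 3.0) < 0.5
        assert traj.value("Ylo", 3.0) < 0.5
        assert traj.value("lam", 3.0) > 9.0


class TestForkJoin:
    def test_fork_splits_signal(self):
        f = ca.build_fork().with_input_assignment({"X": 1})
        traj = ca.simulate_ode(f.crs, 2.0)
        assert traj.value("Y1hi", 2.0) > 9.5 and traj.value("Y2hi", 2.0) > 9.5

    def test_fork_branches_isochronous(self):
        """Equal rates and initial rails: both branches identical for all t."""
        f = ca.build_fork().with_input_assignment({"X": 1})
        traj = ca.simulate_ode(f.crs, 2.0)
        assert np.allclose(traj["Y1hi"], traj["Y2hi"], atol=1e-9)

    def test_join_requires_both_inputs(self):
        j = ca.build_join().with_initial({"X1hi": HI})
        traj = ca.simulate_ode(j.crs, 5.0)
        assert float(traj["Yhi"].max()) < 8.0

    def test_join_truth_table(self):
        assert ca.sweep_truth_table(ca.build_join()).ok


class TestGates:
    @pytest.mark.parametrize("kind", ["NOT", "AND", "OR", "NAND", "NOR", "XOR"])
    def test_truth_table_ode(self, kind):
        assert ca.sweep_truth_table(ca.build_gate(kind)).ok

    def test_and_first_passage_near_0p8(self):
        g = ca.build_gate("AND").with_input_assignment({"X": 1, "Y": 1})
        traj = ca.simulate_ode(g.crs, 3.0)
        t = ca.first_passage(traj, "Zhi", 8.0)
        assert t == pytest.approx(0.8, rel=0.25)

    def test_xor_low_output_timing(self):
        g = ca.build_gate("XOR").with_input_assignment({"X": 0, "Y": 0})
        traj = ca.simulate_ode(g.crs, 1.0)
        assert traj.value("Zlo", 0.4) > 9.5

    def test_not_inverts(self):
        g = ca.build_gate("NOT").with_input_assignment({"X": 1})
        traj = ca.simulate_ode(g.crs, 2.0)
        assert traj.value("Ylo", 2.0) > 9.5 and traj.value("Yhi", 2.0) < 0.5

    @pytest.mark.parametrize("kind", ["AND", "OR", "NAND", "NOR", "XOR"])
    def test_dual_rail_exclusivity_at_convergence(self, kind):
        """At most one output rail above its high threshold, every assignment."""
        import itertools

        circ = ca.build_gate(kind)
        groups = ca.conserved_totals(circ.crs, max_weighted_species=0)
        for bits in itertools.product((0, 1), repeat=2):
            inst = circ.with_input_assignment(dict(zip("XY", bits)))
            traj = ca.simulate_ode(inst.crs, 5.0)
            highs = 0
            for rail in ("Zhi", "Zlo"):
                m = ca.rail_group_total(inst.crs, rail, groups)
                if ca.is_high(traj, rail, 5.0, m):
                    highs += 1
            assert highs <= 1


class TestLambdaSink:
    def test_outputs_absorbed_without_input(self):
        s = ca.build_lambda_sink().with_initial({"Yhi": 5})
        traj = ca.simulate_ode(s.crs, 5.0)
        assert traj.value("Yhi", 5.0) < 0.01
        assert traj.value("lam", 5.0) == pytest.approx(10.0, abs=0.01)

    def test_input_converts_lam_to_output(self):
        s = ca.build_lambda_sink().with_initial({"Xhi": HI, "lam": HI, "Yhi": 0})
        traj = ca.simulate_ode(s.crs, 5.0)
        assert traj.value("Yhi", 5.0) > 1.0  # mix: production vs resorption

    def test_deadlock_without_lam(self):
        s = ca.build_lambda_sink().with_initial({"lam": 0, "Yhi": HI})
        path = ca.simulate_ssa(s.crs, 2.0, seed=0)
        assert path.n_jumps == 0
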