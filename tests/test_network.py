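"""Transfer functions, gate algebra, and the assembled logic-based ODE system."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import toy_chain_spec
from glomfen import network
from glomfen.network import (
    Event,
    ReactionSpec,
    SpeciesSpec,
    and_gate,
    assemble_rhs,
    edge_transfer,
    hill_constants,
    normalized_hill,
    or_fold,
    simulate,
)


class TestNormalizedHill:
    @pytest.mark.parametrize("n,ec50", [(1.4, 0.5), (2.0, 0.3), (1.0, 0.6), (3.7, 0.45)])
    def test_pinned_points(self, n, ec50):
        """f(0)=0, f(EC50)=1/2, f(1)=1 for any admissible (n, EC50)."""
        assert normalized_hill(0.0, n, ec50) == pytest.approx(0.0, abs=1e-12)
        assert normalized_hill(ec50, n, ec50) == pytest.approx(0.5, abs=1e-12)
        assert normalized_hill(1.0, n, ec50) == pytest.approx(1.0, abs=1e-12)

    def test_quarter_activity_value(self):
        # independent arithmetic oracle for the closed form at x=0.25
        n, ec50, x = 1.4, 0.5, 0.25
        b = (ec50**n - 1.0) / (2.0 * ec50**n - 1.0)
        expected = b * x**n / ((b - 1.0) + x**n)
        assert normalized_hill(0.25) == pytest.approx(expected, rel=1e-14)
        assert expected == pytest.approx(0.21556, abs=1e-5)

    @given(
        x1=st.floats(0.0, 1.0),
        x2=st.floats(0.0, 1.0),
        n=st.floats(1.0, 4.0),
        ec50=st.floats(0.1, 0.9),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_increasing(self, x1, x2, n, ec50):
        if abs(2.0 * ec50**n - 1.0) < 1e-6:
            return
        lo, hi = sorted((x1, x2))
        assert normalized_hill(lo, n, ec50) <= normalized_hill(hi, n, ec50) + 1e-12

    def test_undefined_constants_rejected(self):
        # 2*EC50^n = 1 exactly when n=1, EC50=0.5
        with pytest.raises(ValueError):
            hill_constants(1.0, 0.5)
        with pytest.raises(ValueError):
            ReactionSpec(id=1, inputs=(("A", "activating"),), target="B", n=1.0, ec50=0.5)

    def test_negative_activity_rejected(self):
        with pytest.raises(ValueError):
            normalized_hill(-0.1)


class TestGates:
    def test_edge_transfer_inhibition(self):
        assert edge_transfer(1.0, "inhibiting") == pytest.approx(0.0, abs=1e-12)
        assert edge_transfer(0.0, "inhibiting") == pytest.approx(1.0, abs=1e-12)
        assert edge_transfer(0.5, "inhibiting") == pytest.approx(0.5, abs=1e-12)

    def test_gate_identities(self):
        assert and_gate([0.5, 0.5]) == pytest.approx(0.25)
        assert or_fold([0.5, 0.5]) == pytest.approx(0.75)
        for x in (0.0, 0.3, 1.0):
            assert or_fold([x, 0.0]) == pytest.approx(x)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=6))
    @settings(max_examples=200, deadline=None)
    def test_or_fold_bounded_and_dominates_inputs(self, drives):
        out = or_fold(drives)
        assert -1e-12 <= out <= 1.0 + 1e-12
        assert out >= max(drives) - 1e-12

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=5))
    @settings(max_examples=100, deadline=None)
    def test_or_fold_permutation_invariant(self, drives):
        rev = or_fold(list(reversed(drives)))
        assert or_fold(drives) == pytest.approx(rev, abs=1e-9)


class TestAssembledRHS:
    def test_oracle_equivalence_on_toy_network(self):
        """Hand-written edge/gate evaluation matches the compiled RHS."""
        spec = toy_chain_spec()
        rhs = assemble_rhs(spec, lambda t: 0.7)
        rng = np.random.default_rng(0)
        for _ in range(100):
            y = rng.uniform(0.0, 1.0, size=3)
            # brute force: species order GLU, A, B
            d_glu = (1.0 * 0.7 - y[0]) / 1.0
            f_a = 0.9 * normalized_hill(y[0], 1.4, 0.5)
            d_a = (min(max(f_a, 0.0), 1.0) - y[1]) / 1.0
            r3 = normalized_hill(y[1], 2.0, 0.4) * (1.0 - normalized_hill(y[0], 2.0, 0.4))
            r4 = 0.5 * normalized_hill(y[0], 1.4, 0.5)
            r3 = min(max(r3, 0.0), 1.0)
            r4 = min(max(r4, 0.0), 1.0)
            drive_b = r3 + r4 - r3 * r4
            d_b = (0.8 * drive_b - y[2]) / 1.0
            expected = np.array([d_glu, d_a, d_b])
            assert np.allclose(rhs(0.0, y), expected, atol=1e-12)

    def test_species_without_inputs_decays(self):
        spec = toy_chain_spec()
        rhs = assemble_rhs(spec, lambda t: 0.0)
        y = np.array([0.4, 0.0, 0.0])
        assert rhs(0.0, y)[0] == pytest.approx(-0.4)

    def test_glu_fixed_point(self):
        spec = toy_chain_spec()
        rhs = assemble_rhs(spec, lambda t: 1.0)
        d = rhs(0.0, np.array([1.0, 0.0, 0.0]))
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_single_edge_relaxes_to_ymax(self):
        species = [SpeciesSpec(id="GLU"), SpeciesSpec(id="T", ymax=0.9)]
        reactions = [
            ReactionSpec(id=1, inputs=(), target="GLU"),
            ReactionSpec(id=2, inputs=(("GLU", "activating"),), target="T"),
        ]
        spec = network.NetworkSpec(species=species, reactions=reactions)
        traj = simulate(spec, lambda t: 1.0, t_span=(0.0, 50.0), grid_h=1.0)
        assert traj.activity("T")[-1] == pytest.approx(0.9, abs=1e-4)


class TestSimulation:
    def test_zero_stimulus_stays_at_basal_state(self, spec):
        """Without glucose nothing activates; only the constitutive nodes
        (phosphatase/kinase with purely inhibitory inputs) hold basal drive."""
        basal = {"MLCK", "MLCP"}
        traj = simulate(spec, lambda t: 0.0, t_span=(336.0, 600.0), grid_h=6.0)
        for s in spec.species:
            y = traj.activity(s.id)
            if s.id in basal:
                assert y[-1] == pytest.approx(s.ymax, abs=1e-5)
            else:
                assert np.max(np.abs(y)) < 1e-5, s.id

    def test_boundedness(self, spec, disease_traj):
        """0 <= y_i <= ymax_i within solver tolerance for all non-stimulus species."""
        tol = 1e-5
        for s in spec.species:
            y = disease_traj.activity(s.id)
            if s.id == "GLU":
                continue  # stimulus may exceed 1 by design
            assert y.min() >= -tol, s.id
            assert y.max() <= s.ymax + tol, s.id

    def test_sustained_stimulus_reaches_near_maximal_activation(self, spec):
        traj = simulate(spec, lambda t: 1.0, t_span=(336.0, 3360.0), grid_h=6.0)
        for sid in ("AGE", "NFkB", "IL1b", "VEGFA", "RhoRock", "pMLC", "Actin_s"):
            assert traj.activity(sid)[-1] > 0.97, sid

    def test_event_split_consistency(self, spec, schedule):
        whole = simulate(spec, schedule, t_span=(336.0, 1344.0), grid_h=6.0)
        noop = simulate(
            spec,
            schedule,
            t_span=(336.0, 1344.0),
            grid_h=6.0,
            events=[Event(time=840.0, kind="ymax", target="RhoRock", scale=1.0)],
        )
        assert np.max(np.abs(whole.y - noop.y)) < 1e-4

    def test_event_time_outside_span_rejected(self, spec, schedule):
        with pytest.raises(ValueError):
            simulate(
                spec,
                schedule,
                t_span=(336.0, 1000.0),
                events=[Event(time=2000.0, kind="ymax", target="Ca", scale=0.5)],
            )

    def test_repeated_events_scale_pristine_value(self, spec, schedule):
        """Two successive 50% events leave the parameter at 0.5x, not 0.25x."""
        once = simulate(
            spec,
            schedule,
            t_span=(336.0, 1500.0),
            grid_h=6.0,
            events=[Event(840.0, "ymax", "RhoRock", 0.5)],
        )
        twice = simulate(
            spec,
            schedule,
            t_span=(336.0, 1500.0),
            grid_h=6.0,
            events=[
                Event(840.0, "ymax", "RhoRock", 0.5),
                Event(1000.0, "ymax", "RhoRock", 0.5),
            ],
        )
        assert np.max(np.abs(once.y - twice.y)) < 1e-4

    def test_stimulus_monotonicity_of_chain_steady_state(self, spec):
        """Raising the held glucose weight never lowers the GLU->AGE->RAGEec chain."""
        finals = []
        for w in (0.3, 0.6, 1.0):
            traj = simulate(spec, lambda t, w=w: w, t_span=(336.0, 1500.0), grid_h=12.0)
            finals.append([traj.activity(s)[-1] for s in ("GLU", "AGE", "RAGEec")])
        finals = np.array(finals)
        assert np.all(np.diff(finals, axis=0) >= -1e-6)

    def test_variant_flips_single_edge(self, spec):
        healthy = spec.with_variant("healthy")
        r20_d = spec.get_reaction(20)
        r20_h = healthy.get_reaction(20)
        assert r20_d.inputs == (("RhoRock", "inhibiting"),)
        assert r20_h.inputs == (("RhoRock", "activating"),)
        same = [
            (a, b)
            for a, b in zip(spec.reactions, healthy.reactions)
            if a.id != 20
        ]
        assert all(a == b for a, b in same)
        assert healthy.with_variant("disease").get_reaction(20).inputs == r20_d.inputs

    def test_variant_changes_actin_balance(self, disease_traj, healthy_traj):
        # relaxed fibers are inactive in disease, near-maximal in health
        assert disease_traj.activity("Actin_r")[-1] < 0.05
        assert healthy_traj.activity("Actin_r")[-1] > 0.9

    def test_subnetwork_resimulation_matches_full(self, spec, schedule, disease_traj):
        """Frozen-input re-integration of the pMLC subsystem equals a full rerun."""
        tau = 520.0
        reduced = network.resimulate_subnetwork(
            spec, disease_traj, changed={"pMLC"}, tau={"pMLC": tau}
        )
        full = simulate(
            spec.with_overrides(tau={"pMLC": tau}),
            schedule,
            t_span=(336.0, 3360.0),
            grid_h=6.0,
        )
        err = np.max(np.abs(reduced.activity("pMLC") - full.activity("pMLC")))
        assert err < 1e-4


class TestValidation:
    def test_duplicate_species_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            network.NetworkSpec(
                species=[SpeciesSpec(id="A"), SpeciesSpec(id="A")],
                reactions=[ReactionSpec(id=1, inputs=(), target="A")],
            )

    def test_unknown_target_rejected(self):
        with pytest.raises(ValueError, match="unknown target"):
            network.NetworkSpec(
                species=[SpeciesSpec(id="A")],
                reactions=[
                    ReactionSpec(id=1, inputs=(), target="A"),
                    ReactionSpec(id=2, inputs=(("A", "activating"),), target="B"),
                ],
            )

    def test_tau_class_mismatch_rejected(self):
        with pytest.raises(ValueError, match="tau"):
            SpeciesSpec(id="X", tau=5.0, tau_class="ligand-receptor")

    def test_shipped_model_counts(self, spec):
        assert len(spec.species) == 34
        assert spec.stimulus_species == "GLU"
        assert spec.get_reaction(7).target == "PI3K"
        assert spec.get_reaction(7).inputs == (("IL1R", "activating"),)
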