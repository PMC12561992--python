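"""Sensitivity indices, intervention plans, and group statistics."""

import numpy as np
import pytest

from glomfen import network, perturb
from glomfen.glucose import sample_population
from glomfen.network import NetworkSpec, ReactionSpec, SpeciesSpec
from glomfen.perturb import (
    AGENT_TARGETS,
    InterventionPlan,
    apply_intervention,
    relative_change_from_baseline,
    run_intervention,
    run_model,
    screen_all,
    sensitivity_index,
    significance_stars,
    ttest_from_stats,
    two_sample_ttest,
)


class TestSensitivityIndex:
    def test_complete_knockdown_arithmetic(self):
        # Y 4 -> 6 under dP = -P: S = -100 * dY / Y
        assert sensitivity_index(4.0, 6.0, 1.0, -1.0) == pytest.approx(-50.0)

    def test_null_perturbation_zero(self):
        assert sensitivity_index(5.0, 5.0, 1.0, -1.0) == 0.0

    def test_sign_convention(self):
        # inhibition that lowers the output gives a positive index
        assert sensitivity_index(10.0, 8.0, 1.0, -1.0) > 0.0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ZeroDivisionError):
            sensitivity_index(0.0, 1.0, 1.0, -1.0)
        with pytest.raises(ZeroDivisionError):
            sensitivity_index(1.0, 2.0, 1.0, 0.0)


def actin_toy_spec():
    """GLU -> X -> Actin_s plus a parallel GLU -> Actin_s edge."""
    species = [
        SpeciesSpec(id="GLU"),
        SpeciesSpec(id="X"),
        SpeciesSpec(id="Actin_s"),
        SpeciesSpec(id="Actin_r"),
        SpeciesSpec(id="pMLC"),
    ]
    reactions = [
        ReactionSpec(id=1, inputs=(), target="GLU"),
        ReactionSpec(id=2, inputs=(("GLU", "activating"),), target="X"),
        ReactionSpec(id=3, inputs=(("X", "activating"),), target="Actin_s"),
        ReactionSpec(id=4, inputs=(("GLU", "activating"),), target="Actin_s", W=0.6),
    ]
    return NetworkSpec(species=species, reactions=reactions, variant_edge=("X", "Actin_s"))


class TestScreen:
    def test_unreachable_species_has_zero_index(self, spec, schedule, params):
        """TLR4 has no ligand in vivo and no path to the structural outputs."""
        tab = screen_all(
            spec, schedule, params, t_span=(336.0, 1500.0), species=["TLR4"], reactions=[]
        )
        assert np.allclose(tab["S_percent"], 0.0, atol=1e-3)
        assert not tab["sensitive"].any()

    def test_species_knockdown_dominates_single_reaction(self, params):
        """On a two-input target, species knockdown outweighs one-edge inhibition."""
        toy = actin_toy_spec()
        tab = screen_all(
            toy,
            lambda t: 1.0,
            params,
            t_span=(336.0, 3360.0),
            species=["Actin_s"],
            reactions=[3],
        )
        s_species = tab[(tab.kind == "species") & (tab.output == "number")]["S_percent"].iloc[0]
        s_reaction = tab[(tab.kind == "reaction") & (tab.output == "number")]["S_percent"].iloc[0]
        assert abs(s_species) >= abs(s_reaction) - 1e-9
        assert abs(s_species) > 1.5  # stressed-actin removal is sensitive

    def test_classification_partitions_all_rows(self, spec, schedule, params):
        tab = screen_all(
            spec,
            schedule,
            params,
            t_span=(336.0, 1500.0),
            species=["RhoRock", "TLR4"],
            reactions=[18],
        )
        assert tab["sensitive"].dtype == bool
        assert ((tab["S_percent"].abs() > 1.5) == tab["sensitive"]).all()


class TestInterventions:
    def test_scale_one_is_identity(self, spec, schedule, params):
        base_net, base = run_model(spec, schedule, params, (336.0, 1500.0))
        plan = InterventionPlan(
            kind="species_knockdown", target="RhoRock", scale=1.0, t_apply=336.0, t_end=1500.0
        )
        _, traj = run_intervention(spec, schedule, params, plan)
        assert np.max(np.abs(traj.number - base.number)) < 1e-4
        assert np.max(np.abs(traj.diameter - base.diameter)) < 1e-2

    def test_glucose_control_at_start_prevents_all_activation(self, spec, schedule, params):
        plan = InterventionPlan(kind="glucose_control", t_apply=336.0, t_end=1500.0)
        net, traj = run_intervention(spec, schedule, params, plan)
        quiet = [s.id for s in spec.species if s.id not in ("MLCK", "MLCP")]
        for sid in quiet:
            assert np.max(np.abs(net.activity(sid))) < 1e-5, sid
        assert np.allclose(traj.number, params.yNumber_ss1, atol=1e-6)
        assert np.allclose(traj.diameter, params.yDiameter0, atol=1e-4)

    def test_agent_mapping(self, spec, schedule):
        plan = InterventionPlan(kind="chemical_agent", target="Y27632", t_apply=336.0)
        _, _, events = apply_intervention(spec, schedule, plan)
        assert events[0].target == "RhoRock" and events[0].scale == 0.0
        assert AGENT_TARGETS["cytochalasinB"] == "Actin_s"

    def test_unknown_agent_rejected(self, spec, schedule):
        with pytest.raises(KeyError):
            apply_intervention(
                spec, schedule, InterventionPlan(kind="chemical_agent", target="aspirin")
            )

    def test_unknown_species_rejected(self, spec, schedule):
        with pytest.raises(KeyError):
            apply_intervention(
                spec, schedule, InterventionPlan(kind="species_knockdown", target="FOO")
            )

    def test_invalid_plan_rejected(self):
        with pytest.raises(ValueError):
            InterventionPlan(kind="banana")
        with pytest.raises(ValueError):
            InterventionPlan(kind="species_knockdown", target="Ca", scale=1.5)

    def test_late_glucose_control_fails_to_revert(self, spec, schedule, params):
        """The autocrine loop self-sustains: late glycemic control cannot restore
        the fenestration number, early control can."""
        early = run_intervention(
            spec,
            schedule,
            params,
            InterventionPlan(kind="glucose_control", t_apply=3.0 * 168, t_end=3360.0),
        )[1]
        late = run_intervention(
            spec,
            schedule,
            params,
            InterventionPlan(kind="glucose_control", t_apply=10.0 * 168, t_end=3360.0),
        )[1]
        assert early.number[-1] == pytest.approx(params.yNumber_ss1, abs=0.05)
        assert late.number[-1] == pytest.approx(params.yNumber_ss2, abs=0.1)


class TestStatistics:
    def test_identical_groups(self):
        t, p = two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1e-3, 6)
        b = 1.0 + rng.normal(0.0, 1e-3, 6)
        _, p = two_sample_ttest(a, b)
        assert p < 1e-6

    def test_summary_statistics_match_raw(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1.5, 9)
        t_raw, p_raw = two_sample_ttest(a, b)
        t_sum, p_sum = ttest_from_stats(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
        )
        assert t_raw == pytest.approx(t_sum, rel=1e-12)
        assert p_raw == pytest.approx(p_sum, rel=1e-12)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            two_sample_ttest([1.0], [1.0, 2.0])

    def test_stars(self):
        assert significance_stars(0.2) == "ns"
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(5e-4) == "***"
        assert significance_stars(5e-5) == "****"


class TestRelativeChange:
    def test_zero_at_reference_time(self, disease_traj):
        change = relative_change_from_baseline(disease_traj, 1000.0, 1000.0)
        assert (change.abs() < 1e-12).all()

    def test_monotone_species_positive(self, disease_traj):
        change = relative_change_from_baseline(disease_traj, 336.0, 3360.0)
        assert change["pMLC"] > 0.9

    def test_out_of_span_rejected(self, disease_traj):
        with pytest.raises(ValueError):
            relative_change_from_baseline(disease_traj, 0.0, 1000.0)


class TestAgentsBattery:
    def test_rho_rock_and_actin_agents_restore_number(self, spec, glucose_stats, params):
        pop = sample_population(glucose_stats, n=3, seed=0)
        tab = perturb.agents_battery(
            spec, pop, params, agents=("Y27632", "cytochalasinB", "calyculinA")
        )
        tab = tab.set_index("group")
        assert tab.loc["no_treatment", "number_mean"] == pytest.approx(4.05, abs=0.1)
        assert tab.loc["Y27632", "number_mean"] == pytest.approx(7.0, abs=0.1)
        assert tab.loc["cytochalasinB", "number_mean"] == pytest.approx(7.0, abs=0.1)
        # Rho/Rock inhibition also restores the diameter; the others do not
        assert tab.loc["Y27632", "diameter_mean"] < 50.0
        assert tab.loc["calyculinA", "diameter_mean"] > 75.0
        assert tab.loc["Y27632", "number_p_vs_none"] < 1e-4
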