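"""Label propagation: forced outcomes, oracle agreement, invariants."""

import numpy as np
import pytest
from scipy.stats import binom

from isotrace.atom_network import (
    AtomMap,
    Metabolite,
    NetworkConfigError,
    Reaction,
    ReactionNetwork,
    TracerSpec,
    glucose_12_13c,
    glutamine_13c5_15n2,
)
from isotrace.label_sim import (
    brute_force_isotopomers,
    predict_isotopomer_table,
    simulate_labeling,
)

from conftest import make_linear_net, random_toy_network

GLYCOLYSIS_ONLY = {"pyruvate": {"pk": 1.0}, "lactate": {"ldh_f": 1.0}, "alanine": {"alt_f": 1.0}}


class TestForcedOutcomes:
    def test_half_of_pyruvate_is_m2_from_12_glucose(self, canonical):
        """One of the two trioses per glucose carries both tracer carbons."""
        state = simulate_labeling(canonical, glucose_12_13c(), GLYCOLYSIS_ONLY)
        assert state.converged
        np.testing.assert_allclose(state.mid("pyruvate"), [0.5, 0.0, 0.5, 0.0], atol=1e-9)

    def test_unlabeled_tracer_leaves_everything_m0(self, canonical):
        state = simulate_labeling(canonical, glucose_12_13c(enrichment=0.0), GLYCOLYSIS_ONLY)
        for met in canonical.metabolites:
            mid = state.mid(met, "C") if canonical.metabolites[met].n_carbon else state.mid(met, "N")
            assert mid[0] == pytest.approx(1.0, abs=1e-12)

    def test_pure_reductive_carboxylation_gives_m5_citrate(self, canonical):
        state = simulate_labeling(
            canonical,
            glutamine_13c5_15n2(),
            {"glutamate": {"gls": 1.0}, "akg": {"alt_f": 1.0}, "citrate": {"rc": 1.0}},
        )
        assert state.mid("citrate")[5] == pytest.approx(1.0, abs=1e-9)

    def test_oxidative_turn_gives_m4_succinate_and_m4_oaa(self, canonical):
        state = simulate_labeling(
            canonical,
            glutamine_13c5_15n2(),
            {"glutamate": {"gls": 1.0}, "akg": {"alt_f": 1.0}, "pyruvate": {"pk": 1.0}},
        )
        assert state.mid("succinate")[4] == pytest.approx(1.0, abs=1e-9)
        assert state.mid("oaa")[4] == pytest.approx(1.0, abs=1e-9)

    def test_glutaminase_glutamate_is_c5_n1(self, canonical):
        state = simulate_labeling(canonical, glutamine_13c5_15n2(), {"glutamate": {"gls": 1.0}})
        grid = state.joint_mid("glutamate")
        assert grid[5, 1] == pytest.approx(1.0, abs=1e-9)

    def test_lactate_and_alanine_mirror_pyruvate(self, canonical):
        """No carbon loss in LDH or transaminase: carbon MIDs are identical."""
        state = simulate_labeling(canonical, glucose_12_13c(0.8, 0.97), GLYCOLYSIS_ONLY)
        np.testing.assert_allclose(state.mid("lactate"), state.mid("pyruvate"), atol=1e-12)
        np.testing.assert_allclose(state.mid("alanine"), state.mid("pyruvate"), atol=1e-12)


class TestSimulatorMechanics:
    def test_identity_reaction_preserves_mid(self, linear_net):
        tracer = TracerSpec("src", {"C": (1, 3)}, 0.6, 0.95)
        state = simulate_labeling(linear_net, tracer)
        np.testing.assert_allclose(state.mid("b"), state.mid("src"), atol=1e-12)

    def test_bad_fractions_rejected(self, canonical):
        with pytest.raises(NetworkConfigError, match="sum to"):
            simulate_labeling(canonical, glucose_12_13c(), {"pyruvate": {"pk": 0.5}})
        with pytest.raises(NetworkConfigError, match="do not produce"):
            simulate_labeling(canonical, glucose_12_13c(), {"pyruvate": {"oxppp": 1.0}})

    def test_unreachable_metabolite_reported_all_m0(self):
        net = make_linear_net()
        net.add_metabolite(Metabolite("orphan", "C2H2"))
        tracer = TracerSpec("src", {"C": (1,)})
        state = simulate_labeling(net, tracer)
        assert "orphan" in state.unreachable
        assert state.mid("orphan")[0] == 1.0

    def test_mids_sum_to_one_everywhere(self, canonical):
        state = simulate_labeling(canonical, glutamine_13c5_15n2(0.73, 0.94))
        for met in canonical.metabolites.values():
            for el in ("C", "N"):
                if met.n_atoms(el):
                    assert state.mid(met.id, el).sum() == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_enrichment_fraction(self, canonical):
        """Downstream labeled fraction never decreases as tracer enrichment grows."""
        prev = -1.0
        for e in (0.0, 0.25, 0.5, 0.75, 1.0):
            state = simulate_labeling(canonical, glucose_12_13c(enrichment=e), GLYCOLYSIS_ONLY)
            frac = state.labeled_fraction("lactate")
            assert frac >= prev - 1e-12
            prev = frac

    def test_purity_matches_binomial_on_linear_chain(self):
        """Per-atom purity: end-of-chain MID is the binomial over labeled atoms."""
        net = make_linear_net(n_atoms=3)
        p = 0.93
        state = simulate_labeling(net, TracerSpec("src", {"C": (1, 2, 3)}, 1.0, p))
        expected = binom.pmf(np.arange(4), 3, p)
        np.testing.assert_allclose(state.mid("b"), expected, atol=1e-12)


class TestBruteForceOracle:
    def test_identical_on_glycolysis_chain(self, canonical):
        fr = GLYCOLYSIS_ONLY
        sim = simulate_labeling(canonical, glucose_12_13c(0.9, 0.98), fr)
        bf = brute_force_isotopomers(canonical, glucose_12_13c(0.9, 0.98), fr)
        for met in canonical.metabolites:
            np.testing.assert_allclose(
                sim.distributions[met], bf.distributions[met], atol=1e-9
            )

    @pytest.mark.parametrize("seed", range(12))
    def test_random_toy_networks_agree(self, seed):
        net, tracer, fractions = random_toy_network(seed)
        sim = simulate_labeling(net, tracer, fractions, tol=1e-12)
        bf = brute_force_isotopomers(net, tracer, fractions)
        assert sim.converged and bf.converged
        for met in net.metabolites:
            np.testing.assert_allclose(
                sim.distributions[met], bf.distributions[met], atol=1e-9
            )

    def test_size_guard(self):
        net = ReactionNetwork(sources=("big",))
        net.add_metabolite(Metabolite("big", "C9H20"))
        with pytest.raises(Exception, match="mapped atoms"):
            brute_force_isotopomers(net, TracerSpec("big", {"C": (1,)}))


class TestExpectationTable:
    def test_succinate_reachable_m4_from_glutamine(self, canonical):
        table = predict_isotopomer_table(canonical, "glutamine")
        sub = table.query(
            "route == 'tca_oxidative' and metabolite == 'succinate' and element == 'C'"
        )
        assert 4 in set(sub["mass_shift"])

    def test_oxidative_vs_reductive_citrate_distinguished(self, canonical):
        table = predict_isotopomer_table(canonical, "glutamine")
        ox = table.query("route == 'tca_oxidative' and metabolite == 'citrate'")
        red = table.query("route == 'reductive_carboxylation' and metabolite == 'citrate'")
        assert 4 in set(ox["mass_shift"]) and 5 not in set(ox["mass_shift"])
        assert 5 in set(red["mass_shift"]) and 4 not in set(red["mass_shift"])

    def test_glucose_routes_distinguish_ppp_branches(self, canonical):
        table = predict_isotopomer_table(canonical, "glucose")
        ox = table.query("route == 'oxidative_ppp' and metabolite == 'r5p'")
        nonox = table.query("route == 'nonoxidative_ppp' and metabolite == 'r5p'")
        assert set(ox["mass_shift"]) == {1}
        # non-oxidative ribose carries an even label count (2 from F6P C1/C2,
        # plus 2 more when the triose partner is labeled), never the M+1
        # signature of the oxidative branch
        assert 2 in set(nonox["mass_shift"])
        assert set(nonox["mass_shift"]) <= {0, 2, 4}
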