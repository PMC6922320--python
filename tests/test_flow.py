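"""Cascade engine: hand-traced examples, mass balance, operator oracle."""

import numpy as np
import pytest

from gutflow import (
    CommunitySample,
    CrossFeedingNetwork,
    FlowParameters,
    IntakeProfile,
    build_secretion_matrix,
    build_uptake_matrix,
    flow_summary,
    predict_profiles,
    run_cascade,
)
from gutflow.flow import cascade_operators

from conftest import random_instance


class TestUptakeMatrix:
    def test_single_consumer_gets_everything(self, single_species_net):
        up = build_uptake_matrix(
            single_species_net, CommunitySample("x", {"A": 1.0}), FlowParameters()
        )
        assert up.matrix[0, 0] == 1.0

    def test_split_proportional_to_abundance(self):
        net = CrossFeedingNetwork(
            ["A", "B"], ["m"], [("A", "m"), ("B", "m")], []
        )
        up = build_uptake_matrix(
            net, CommunitySample("x", {"A": 0.75, "B": 0.25}), FlowParameters()
        )
        np.testing.assert_allclose(up.matrix[:, 0], [0.75, 0.25])

    def test_rates_weight_the_split(self):
        net = CrossFeedingNetwork(["A", "B"], ["m"], [("A", "m"), ("B", "m")], [])
        params = FlowParameters(uptake_rates={("A", "m"): 2.0, ("B", "m"): 1.0})
        up = build_uptake_matrix(net, CommunitySample("x", {"A": 0.5, "B": 0.5}), params)
        np.testing.assert_allclose(up.matrix[:, 0], [2 / 3, 1 / 3])

    def test_zero_abundance_consumer_leaves_column_unconsumable(self, chain_net):
        up = build_uptake_matrix(
            chain_net, CommunitySample("x", {"A": 1.0}), FlowParameters()
        )
        # B is absent, so m1's column is all-zero and flagged
        i = chain_net.metabolite_index["m1"]
        assert not up.consumable[i]
        assert np.all(up.matrix[:, i] == 0)

    def test_columns_sum_to_one_or_zero(self):
        rng = np.random.default_rng(7)
        net, sample, _, params = random_instance(rng)
        up = build_uptake_matrix(net, sample, params)
        sums = up.matrix.sum(axis=0)
        assert np.all((np.abs(sums - 1) < 1e-12) | (sums == 0))


class TestSecretionMatrix:
    def test_equal_split(self):
        net = CrossFeedingNetwork(
            ["A"], ["a", "b", "c", "d"], [], [("A", x) for x in "abcd"]
        )
        out = build_secretion_matrix(net, FlowParameters())
        np.testing.assert_allclose(out.matrix[:, 0], 0.25)

    def test_single_byproduct(self, single_species_net):
        out = build_secretion_matrix(single_species_net, FlowParameters())
        assert out.matrix[1, 0] == 1.0

    def test_no_byproducts_zero_column(self):
        net = CrossFeedingNetwork(["A"], ["m"], [("A", "m")], [])
        out = build_secretion_matrix(net, FlowParameters())
        assert out.n_out[0] == 0
        assert np.all(out.matrix[:, 0] == 0)

    def test_negative_explicit_weights_rejected(self, single_species_net):
        params = FlowParameters(
            secretion_mode="explicit", secretion_weights={("A", "m1"): -1.0}
        )
        with pytest.raises(ValueError):
            build_secretion_matrix(single_species_net, params)


class TestCascade:
    def test_single_species_splits_intake(self, single_species_net):
        """1 unit in: 1-f becomes biomass, f exits as inedible byproduct."""
        flow = run_cascade(
            single_species_net,
            CommunitySample("x", {"A": 1.0}),
            IntakeProfile({"m0": 1.0}),
            FlowParameters(f=0.9, n_levels=3),
        )
        assert flow.total_biomass.sum() == pytest.approx(0.1)
        assert flow.metabolome.sum() == pytest.approx(0.9)

    def test_two_step_chain_hand_trace(self, chain_net, chain_sample, chain_intake):
        flow = run_cascade(
            chain_net, chain_sample, chain_intake, FlowParameters(f=0.9, n_levels=2)
        )
        b = flow.biomass_series()
        assert b["A"] == pytest.approx(0.1)
        assert b["B"] == pytest.approx(0.09)
        assert flow.metabolome_series()["m2"] == pytest.approx(0.81)
        assert flow.mass_balance_error() < 1e-12

    @pytest.mark.parametrize("f,n", [(0.9, 4), (0.5, 3), (0.25, 7)])
    def test_fully_consumable_closed_form(self, f, n):
        """Every byproduct consumable => total biomass = 1 - f^n."""
        from gutflow import generate_network, generate_cohort

        net, intake_mets = generate_network(
            20, 30, 2, 2, 5, seed=3, ensure_all_consumable=True
        )
        rng = np.random.default_rng(4)
        sample = CommunitySample(
            "x", dict(zip(net.species, rng.dirichlet(np.ones(net.n_species))))
        )
        amounts = rng.dirichlet(np.ones(len(intake_mets)))
        flow = run_cascade(
            net,
            sample,
            IntakeProfile(dict(zip(intake_mets, map(float, amounts)))),
            FlowParameters(f=f, n_levels=n),
        )
        assert flow.total_biomass.sum() == pytest.approx(1 - f**n, rel=1e-12)

    def test_mass_conservation_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(40):
            net, sample, intake, params = random_instance(rng)
            flow = run_cascade(net, sample, intake, params)
            assert flow.mass_balance_error() < 1e-9
            assert np.all(flow.biomass_by_level >= 0)
            assert np.all(flow.unconsumed_by_level >= 0)

    def test_unconsumable_annihilated_by_uptake(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            net, sample, intake, params = random_instance(rng)
            flow = run_cascade(net, sample, intake, params)
            A_in = flow.uptake.matrix
            M = A_in.shape[1]
            for l in range(flow.n_levels):
                assert np.all(A_in @ flow.unconsumed_by_level[l, :M] == 0)

    def test_operator_form_matches_recursion(self):
        """Sum_l (1-f) f^(l-1) A_in (A_out A_in)^(l-1) c equals the recursion
        on networks where no species lacks byproducts."""
        rng = np.random.default_rng(17)
        for _ in range(15):
            net, sample, intake, params = random_instance(rng, allow_sink=False)
            flow = run_cascade(net, sample, intake, params)
            A_in = flow.uptake.matrix
            A_out = flow.secretion.matrix
            c = flow.intake[: net.n_metabolites]
            f = params.f
            B = np.zeros(net.n_species)
            step = np.eye(net.n_metabolites)
            for l in range(1, params.n_levels + 1):
                B += (1 - f) * f ** (l - 1) * (A_in @ step @ c)
                step = (A_out @ A_in) @ step
            denom = np.maximum(np.abs(flow.total_biomass), 1e-300)
            mask = flow.total_biomass > 0
            assert np.max(np.abs(B - flow.total_biomass)[mask] / denom[mask]) < 1e-10

    def test_scale_invariance_of_profiles(self, chain_net, chain_sample):
        p1 = predict_profiles(
            run_cascade(
                chain_net,
                chain_sample,
                IntakeProfile({"m0": 1.0}),
                FlowParameters(f=0.7, n_levels=2),
            )
        )
        p2 = predict_profiles(
            run_cascade(
                chain_net,
                chain_sample,
                IntakeProfile({"m0": 17.3}),
                FlowParameters(f=0.7, n_levels=2),
            )
        )
        np.testing.assert_allclose(p1[0].values, p2[0].values)
        np.testing.assert_allclose(p1[1].values, p2[1].values)

    def test_biomass_monotone_in_levels(self):
        rng = np.random.default_rng(19)
        net, sample, intake, _ = random_instance(rng)
        totals = [
            run_cascade(net, sample, intake, FlowParameters(f=0.8, n_levels=n))
            .total_biomass.sum()
            for n in range(1, 8)
        ]
        assert all(b2 >= b1 - 1e-12 for b1, b2 in zip(totals, totals[1:]))

    def test_all_zero_intake_rejected(self, chain_net, chain_sample):
        with pytest.raises(ValueError):
            IntakeProfile({"m0": 0.0})

    def test_unknown_intake_metabolite_passes_through(self, chain_net, chain_sample):
        flow = run_cascade(
            chain_net,
            chain_sample,
            IntakeProfile({"m0": 0.6, "vitamin_x": 0.4}),
            FlowParameters(f=0.9, n_levels=2),
        )
        assert flow.metabolome_series()["vitamin_x"] == pytest.approx(0.4)
        assert flow.mass_balance_error() < 1e-12

    def test_sink_accounting(self):
        """Species without byproducts route their f-fraction to the sink."""
        net = CrossFeedingNetwork(["A"], ["m0"], [("A", "m0")], [])
        flow = run_cascade(
            net,
            CommunitySample("x", {"A": 1.0}),
            IntakeProfile({"m0": 1.0}),
            FlowParameters(f=0.9, n_levels=2),
        )
        assert flow.sink_mass == pytest.approx(0.9)
        assert flow.metabolome.sum() == pytest.approx(0.0)
        assert flow.mass_balance_error() < 1e-12


class TestFlowSummary:
    def test_chain_fractions(self, chain_net, chain_sample, chain_intake):
        flow = run_cascade(
            chain_net, chain_sample, chain_intake, FlowParameters(f=0.9, n_levels=2)
        )
        s = flow_summary(flow).set_index("level")
        assert s.loc[1, "biomass_fraction"] == pytest.approx(0.1)
        assert s.loc[2, "biomass_fraction"] == pytest.approx(0.09)
        assert s.loc[2, "passed_on_fraction"] == pytest.approx(0.81)

    def test_fully_unconsumable_intake(self, chain_net):
        flow = run_cascade(
            chain_net,
            CommunitySample("x", {"B": 1.0}),  # nobody present eats m0
            IntakeProfile({"m0": 1.0}),
            FlowParameters(f=0.9, n_levels=2),
        )
        s = flow_summary(flow).set_index("level")
        assert s.loc[1, "unconsumable_fraction"] == pytest.approx(1.0)
        assert s.loc[1, "biomass_fraction"] == 0.0

    def test_geometric_biomass_sequence_fully_connected(self):
        from gutflow import generate_network

        net, intake_mets = generate_network(
            15, 20, 2, 2, 4, seed=5, ensure_all_consumable=True
        )
        rng = np.random.default_rng(6)
        sample = CommunitySample(
            "x", dict(zip(net.species, rng.dirichlet(np.ones(net.n_species))))
        )
        flow = run_cascade(
            net,
            sample,
            IntakeProfile({m: 1.0 / len(intake_mets) for m in intake_mets}),
            FlowParameters(f=0.9, n_levels=4),
        )
        s = flow_summary(flow)
        np.testing.assert_allclose(
            s["biomass_fraction"].values, [0.1 * 0.9**l for l in range(4)], rtol=1e-10
        )


def test_predict_profiles_normalization(chain_net, chain_sample, chain_intake):
    flow = run_cascade(
        chain_net, chain_sample, chain_intake, FlowParameters(f=0.9, n_levels=2)
    )
    p, m = predict_profiles(flow)
    assert p.sum() == pytest.approx(1.0)
    assert m.sum() == pytest.approx(1.0)
    assert p["A"] == pytest.approx(10 / 19)
    assert p["B"] == pytest.approx(9 / 19)


def test_cascade_operators_match_run(chain_net, chain_sample):
    params = FlowParameters(f=0.85, n_levels=3)
    L_b, L_m, species, mets = cascade_operators(chain_net, chain_sample, params)
    c = np.array([0.3, 0.0, 0.0])
    flow = run_cascade(chain_net, chain_sample, IntakeProfile({"m0": 0.3}), params)
    np.testing.assert_allclose(L_b @ c, flow.total_biomass, atol=1e-15)
    np.testing.assert_allclose(L_m @ c, flow.metabolome, atol=1e-15)
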