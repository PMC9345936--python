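"""Network parsing, FBA/FVA against vertex enumeration, sampling, quartiles."""

import json

import numpy as np
import pytest

from endoflux import netcore
from endoflux.netcore import (
    MetabolicNetwork,
    fba,
    fva,
    read_network,
    sample_fluxes,
    transport_quartiles,
    write_network_json,
)

from _oracles import vertex_optimum
from conftest import branch_network, chain_network

CHAIN_JSON = {
    "metabolites": [{"id": "A"}, {"id": "B"}],
    "reactions": [
        {"id": "EX_A", "stoichiometry": {"A": -1}, "lb": -5, "ub": 0,
         "is_transport": True},
        {"id": "R_AB", "stoichiometry": {"A": -1, "B": 1}, "lb": 0, "ub": 1000},
        {"id": "EX_B", "stoichiometry": {"B": -1}, "lb": 0, "ub": 1000,
         "is_transport": True},
    ],
    "objective": "EX_B",
}


class TestReadNetwork:
    def test_json_chain_parses(self, tmp_path):
        path = tmp_path / "chain.json"
        path.write_text(json.dumps(CHAIN_JSON))
        net = read_network(str(path), format="json")
        assert net.n_reactions == 3
        assert net.n_metabolites == 2
        assert net.transport_ids == ["EX_A", "EX_B"]
        assert net.objective == "EX_B"
        np.testing.assert_allclose(net.lb, [-5, 0, 0])

    def test_json_roundtrip_preserves_structure(self, tmp_path, toy_net):
        path = tmp_path / "toy.json"
        write_network_json(toy_net, str(path))
        back = read_network(str(path), format="json")
        assert back.reaction_ids == toy_net.reaction_ids
        assert back.metabolite_ids == toy_net.metabolite_ids
        np.testing.assert_allclose(back.S, toy_net.S)
        np.testing.assert_allclose(back.lb, toy_net.lb)
        np.testing.assert_allclose(back.ub, toy_net.ub)
        assert back.transport_ids == toy_net.transport_ids

    def test_sbml_roundtrip_identical(self, tmp_path, chain_net):
        cobra = pytest.importorskip("cobra")
        model = netcore.to_cobra(chain_net)
        path = tmp_path / "chain.xml"
        cobra.io.write_sbml_model(model, str(path))
        back = read_network(str(path), format="sbml")
        assert back.reaction_ids == chain_net.reaction_ids
        np.testing.assert_allclose(back.S, chain_net.S)
        np.testing.assert_allclose(back.lb, chain_net.lb)
        np.testing.assert_allclose(back.ub, chain_net.ub)

    def test_undeclared_metabolite_rejected(self, tmp_path):
        doc = json.loads(json.dumps(CHAIN_JSON))
        doc["reactions"][1]["stoichiometry"]["ghost"] = 1
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="ghost"):
            read_network(str(path), format="json")

    def test_duplicate_reaction_id_rejected(self, tmp_path):
        doc = json.loads(json.dumps(CHAIN_JSON))
        doc["reactions"].append(dict(doc["reactions"][0]))
        path = tmp_path / "dup.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="duplicate"):
            read_network(str(path), format="json")

    def test_malformed_json_names_problem(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text("{not json")
        with pytest.raises(ValueError, match="malformed"):
            read_network(str(path), format="json")

    def test_unbalanced_internal_reaction_rejected(self):
        with pytest.raises(ValueError, match="not mass balanced"):
            MetabolicNetwork(
                metabolite_ids=["A", "B"],
                reaction_ids=["R1", "R2"],
                S=np.array([[-1.0, 0.0], [2.0, -1.0]]),  # A -> 2B, carbon broken
                lb=np.zeros(2),
                ub=np.full(2, 1000.0),
                formulas={"A": "C3", "B": "C3"},
            )


class TestFBA:
    def test_chain_bottleneck(self, chain_net):
        sol = fba(chain_net, "EX_B", "max")
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(5.0)

    def test_uncapped_chain_saturates_at_default_bound(self):
        net = chain_network(uptake_cap=1000.0)
        assert fba(net, "EX_B", "max").objective_value == pytest.approx(1000.0)

    def test_solution_satisfies_constraints(self, branch_net):
        sol = fba(branch_net, "EX_C", "max")
        v = sol.flux_vector
        assert np.abs(branch_net.S @ v).max() <= 1e-6
        assert np.all(v >= branch_net.lb - 1e-6)
        assert np.all(v <= branch_net.ub + 1e-6)

    @pytest.mark.parametrize("direction", ["max", "min"])
    @pytest.mark.parametrize("factory", [chain_network, branch_network])
    def test_optimum_matches_vertex_enumeration(self, factory, direction):
        net = factory()
        for rxn in net.reaction_ids:
            lp = fba(net, rxn, direction).objective_value
            assert lp == pytest.approx(
                vertex_optimum(net, rxn, direction), abs=1e-7
            )

    def test_positive_homogeneity_in_bounds(self, branch_net):
        lam = 3.5
        scaled = branch_net.copy()
        scaled.lb *= lam
        scaled.ub *= lam
        for rxn in branch_net.reaction_ids:
            assert fba(scaled, rxn, "max").objective_value == pytest.approx(
                lam * fba(branch_net, rxn, "max").objective_value
            )

    def test_unknown_objective_rejected(self, chain_net):
        with pytest.raises(KeyError):
            fba(chain_net, "nope", "max")

    def test_infeasible_bounds_reported(self, chain_net):
        net = chain_net.with_bounds({"EX_A": (0.0, 0.0), "EX_B": (1.0, 10.0)})
        assert fba(net, "EX_B", "max").status == "infeasible"


class TestFVA:
    def test_blocked_reaction_is_zero(self):
        # B has no exit: all fluxes forced to 0
        S = np.array([[-1.0, -1.0], [0.0, 1.0]])
        net = MetabolicNetwork(
            ["A", "B"], ["EX_A", "R_AB"], S,
            lb=np.array([-5.0, 0.0]), ub=np.array([0.0, 1000.0]),
            transport_ids=["EX_A"],
        )
        assert fva(net, "R_AB") == pytest.approx((0.0, 0.0))

    def test_linear_pathway_coupling(self, chain_net):
        for rxn in ["R_AB", "EX_B"]:
            assert fva(chain_net, rxn) == pytest.approx((0.0, 5.0))

    def test_branch_matches_vertex_enumeration(self, branch_net):
        for rxn in branch_net.reaction_ids:
            lo, hi = fva(branch_net, rxn)
            assert lo == pytest.approx(vertex_optimum(branch_net, rxn, "min"), abs=1e-7)
            assert hi == pytest.approx(vertex_optimum(branch_net, rxn, "max"), abs=1e-7)

    def test_cobrapy_cross_check(self, chain_net):
        """Independent solver route: cobrapy FBA on the same fixture."""
        cobra = pytest.importorskip("cobra")
        model = netcore.to_cobra(chain_net)
        model.objective = "EX_B"
        assert model.optimize().objective_value == pytest.approx(
            fba(chain_net, "EX_B", "max").objective_value
        )


class TestSampling:
    def test_rows_satisfy_constraints(self, chain_net):
        s = sample_fluxes(chain_net, n=200, seed=7)
        assert s.matrix.shape == (200, 3)
        assert np.abs(chain_net.S @ s.matrix.T).max() <= 1e-6
        assert np.all(s.matrix >= chain_net.lb - 1e-6)
        assert np.all(s.matrix <= chain_net.ub + 1e-6)

    def test_1d_polytope_uniform_mean(self, chain_net):
        # single pathway: common flux t in [0, 5]; uniform mean 2.5
        s = sample_fluxes(chain_net, n=5000, seed=11)
        assert s.matrix[:, 1].mean() == pytest.approx(2.5, abs=0.15)

    def test_convergence_rate_consistent_with_sqrt_n(self, chain_net):
        errs = []
        for n in (200, 3200):
            s = sample_fluxes(chain_net, n=n, seed=3)
            errs.append(abs(s.matrix[:, 1].mean() - 2.5))
        # 16x the samples: error should shrink noticeably (not 4x strictly,
        # single realisation), and both stay within a loose envelope
        assert errs[1] <= max(errs[0], 3.0 / np.sqrt(3200))

    def test_seed_determinism(self, chain_net):
        a = sample_fluxes(chain_net, n=50, seed=42)
        b = sample_fluxes(chain_net, n=50, seed=42)
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_within_fva_envelope(self, branch_net):
        s = sample_fluxes(branch_net, n=300, seed=5)
        for j, rxn in enumerate(branch_net.reaction_ids):
            lo, hi = fva(branch_net, rxn)
            assert s.matrix[:, j].min() >= lo - 1e-6
            assert s.matrix[:, j].max() <= hi + 1e-6

    def test_infeasible_polytope_errors_before_sampling(self, chain_net):
        net = chain_net.with_bounds({"EX_A": (0.0, 0.0), "EX_B": (1.0, 2.0)})
        with pytest.raises(ValueError, match="empty"):
            sample_fluxes(net, n=10, seed=0)


class TestTransportQuartiles:
    def _sample_from(self, columns):
        mat = np.column_stack(columns)
        return netcore.FluxSample(
            mat, [f"r{i}" for i in range(mat.shape[1])], 0, 0, 1
        )

    def test_type7_hand_value(self):
        s = self._sample_from([np.array([1.0, 2.0, 3.0, 4.0])])
        q = transport_quartiles(s, ["r0"])
        assert q.q1["r0"] == pytest.approx(1.75)
        assert q.q3["r0"] == pytest.approx(3.25)

    def test_constant_marginal(self):
        s = self._sample_from([np.full(8, 3.3)])
        q = transport_quartiles(s, ["r0"])
        assert q.q1["r0"] == q.q3["r0"] == pytest.approx(3.3)

    def test_symmetric_marginal(self):
        x = np.array([-4.0, -2.0, -1.0, 1.0, 2.0, 4.0])
        q = transport_quartiles(self._sample_from([x]), ["r0"])
        assert q.q1["r0"] == pytest.approx(-q.q3["r0"])

    def test_missing_reaction_listed(self):
        s = self._sample_from([np.arange(4.0)])
        with pytest.raises(KeyError, match="ghost"):
            transport_quartiles(s, ["ghost"])
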