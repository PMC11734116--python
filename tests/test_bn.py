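"""Core network representation, validation and exact inference."""

import numpy as np
import pytest

import seabed_era as se
from seabed_era.bn import _min_fill_order
from seabed_era.synthetic import random_cpts, random_dag


def tiny_net(table_b):
    variables = {
        "A": se.Variable("A", ("a1", "a2")),
        "B": se.Variable("B", ("b1", "b2")),
    }
    cpts = {
        "A": se.Cpt("A", (), np.array([[0.3, 0.7]])),
        "B": se.Cpt("B", ("A",), np.asarray(table_b, dtype=float)),
    }
    return se.Network(variables=variables, cpts=cpts)


class TestValidation:
    def test_valid_chain_has_no_violations(self, chain_net):
        assert se.validate_network(chain_net) == []

    def test_denormalized_column_names_child(self):
        net = tiny_net([[0.6, 0.3], [0.5, 0.5]])  # first row sums to 0.9
        problems = se.validate_network(net)
        assert len(problems) == 1 and "'B'" in problems[0]

    def test_slightly_off_column_is_renormalized(self):
        net = tiny_net([[0.9 + 4e-7, 0.1], [0.5, 0.5]])
        assert se.validate_network(net) == []
        np.testing.assert_allclose(net.cpts["B"].table.sum(axis=1), 1.0, atol=1e-12)

    def test_cycle_detected(self):
        variables = {
            "A": se.Variable("A", ("a1", "a2")),
            "B": se.Variable("B", ("b1", "b2")),
        }
        cpts = {
            "A": se.Cpt("A", ("B",), np.array([[0.5, 0.5], [0.5, 0.5]])),
            "B": se.Cpt("B", ("A",), np.array([[0.5, 0.5], [0.5, 0.5]])),
        }
        problems = se.validate_network(se.Network(variables=variables, cpts=cpts))
        assert any("cycle" in p for p in problems)

    def test_decision_variable_with_cpt_flagged(self):
        variables = {"D": se.Variable("D", ("x", "y"), role="decision")}
        cpts = {"D": se.Cpt("D", (), np.array([[0.5, 0.5]]))}
        problems = se.validate_network(se.Network(variables=variables, cpts=cpts))
        assert any("decision" in p for p in problems)


class TestJointProbability:
    def test_product_rule(self, chain_net):
        assert se.joint_probability(chain_net, {"A": "a1", "B": "b1"}) == pytest.approx(0.27)

    def test_point_mass_network_gives_one(self):
        net = tiny_net([[1.0, 0.0], [0.0, 1.0]])
        net.cpts["A"].table = np.array([[1.0, 0.0]])
        assert se.joint_probability(net, {"A": "a1", "B": "b1"}) == 1.0

    def test_zero_entry_gives_zero(self):
        net = tiny_net([[1.0, 0.0], [0.5, 0.5]])
        assert se.joint_probability(net, {"A": "a1", "B": "b2"}) == 0.0

    def test_incomplete_assignment_raises(self, chain_net):
        with pytest.raises(se.IncompleteAssignmentError):
            se.joint_probability(chain_net, {"A": "a1"})

    def test_matches_enumerated_joint_exactly(self, chain_net):
        joint = se.enumerate_joint(chain_net, order=["A", "B"])
        for i, a in enumerate(("a1", "a2")):
            for j, b in enumerate(("b1", "b2")):
                assert joint.values[i, j] == se.joint_probability(
                    chain_net, {"A": a, "B": b}
                )


class TestQuery:
    def test_marginal_by_total_probability(self, chain_net):
        post = se.query(chain_net, ["B"], {})
        np.testing.assert_allclose(post["B"], [0.62, 0.38], atol=1e-12)

    def test_bayes_rule(self, chain_net):
        post = se.query(chain_net, ["A"], {"B": "b1"})
        np.testing.assert_allclose(post["A"], [0.27 / 0.62, 0.35 / 0.62], atol=1e-12)

    def test_evidence_consistency(self, chain_net):
        # P(X = x | X = x) = 1 via posterior_all on the other variable
        for var, state in (("A", "a2"), ("B", "b1")):
            post = se.posterior_all(chain_net, {var: state})
            assert var not in post
            for vec in post.values():
                assert vec.sum() == pytest.approx(1.0)

    def test_zero_probability_evidence_raises(self):
        net = tiny_net([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(se.ZeroProbabilityEvidenceError):
            se.query(net, ["A"], {"B": "b2"})

    def test_targets_overlapping_evidence_rejected(self, chain_net):
        with pytest.raises(ValueError):
            se.query(chain_net, ["B"], {"B": "b1"})


class TestPosteriorAll:
    def test_no_evidence_roots_keep_priors(self, chain_net):
        post = se.posterior_all(chain_net, {})
        np.testing.assert_allclose(post["A"], [0.3, 0.7], atol=1e-12)

    def test_all_but_one_observed_recovers_cpt_row(self, chain_net):
        post = se.posterior_all(chain_net, {"A": "a1"})
        np.testing.assert_allclose(post["B"], [0.9, 0.1], atol=1e-12)

    def test_agrees_with_per_variable_query(self):
        net = random_cpts(random_dag(6, 3, seed=11), 3, 1.0, seed=11, n_nodes=6)
        evidence = {"v0": "s1"}
        post = se.posterior_all(net, evidence)
        for var, vec in post.items():
            np.testing.assert_array_equal(vec, se.query(net, [var], evidence)[var])


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(0, 50, 7))
    def test_ve_matches_enumeration(self, seed):
        net = random_cpts(random_dag(8, 3, seed), 3, 1.0, seed, n_nodes=8)
        joint = se.enumerate_joint(net)
        for v in net.variables:
            exact = joint.marginal(v)
            exact = exact / exact.sum()
            np.testing.assert_allclose(se.query(net, [v], {})[v], exact, atol=1e-9)

    def test_ve_matches_enumeration_with_evidence(self):
        net = random_cpts(random_dag(7, 3, seed=3), 2, 0.7, seed=3, n_nodes=7)
        joint = se.enumerate_joint(net)
        ev_var, ev_state = "v2", "s0"
        idx = joint.scope.index(ev_var)
        sliced = np.take(joint.values, 0, axis=idx)
        scope = tuple(v for v in joint.scope if v != ev_var)
        cond = se.Factor(scope, sliced / sliced.sum())
        for v in scope:
            exact = cond.marginal(v)
            np.testing.assert_allclose(
                se.query(net, [v], {ev_var: ev_state})[v], exact, atol=1e-9
            )


class TestEnumeration:
    def test_chain_joint_entries(self, chain_net):
        joint = se.enumerate_joint(chain_net, order=["A", "B"])
        np.testing.assert_allclose(
            joint.values, [[0.27, 0.03], [0.35, 0.35]], atol=1e-12
        )
        assert joint.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_root_returns_prior(self):
        variables = {"X": se.Variable("X", ("x1", "x2", "x3"))}
        cpts = {"X": se.Cpt("X", (), np.array([[0.2, 0.5, 0.3]]))}
        joint = se.enumerate_joint(se.Network(variables=variables, cpts=cpts))
        np.testing.assert_allclose(joint.values, [0.2, 0.5, 0.3])

    def test_state_space_guard(self):
        net = random_cpts(random_dag(21, 2, seed=0), 3, 1.0, seed=0, n_nodes=21)
        with pytest.raises(se.StateSpaceTooLargeError):
            se.enumerate_joint(net)


class TestForwardSample:
    def test_point_mass_network_all_samples_identical(self):
        net = tiny_net([[1.0, 0.0], [0.0, 1.0]])
        net.cpts["A"].table = np.array([[0.0, 1.0]])
        table = se.forward_sample(net, 50, seed=4)
        assert (table["A"] == "a2").all() and (table["B"] == "b2").all()

    def test_zero_samples_gives_empty_table(self, chain_net):
        assert len(se.forward_sample(chain_net, 0, seed=0)) == 0

    def test_empirical_marginal_near_exact(self, chain_net):
        table = se.forward_sample(chain_net, 100_000, seed=1)
        assert abs((table["B"] == "b1").mean() - 0.62) < 0.01

    def test_deterministic_per_seed(self, chain_net):
        a = se.forward_sample(chain_net, 200, seed=9)
        b = se.forward_sample(chain_net, 200, seed=9)
        assert a.equals(b)

    def test_unfixed_decision_variable_raises(self):
        variables = {
            "D": se.Variable("D", ("x", "y"), role="decision"),
            "B": se.Variable("B", ("b1", "b2")),
        }
        cpts = {"B": se.Cpt("B", ("D",), np.array([[0.9, 0.1], [0.5, 0.5]]))}
        net = se.Network(variables=variables, cpts=cpts)
        with pytest.raises(se.MissingDecisionError):
            se.forward_sample(net, 10, seed=0)
        table = se.forward_sample(net, 10, seed=0, evidence={"D": "x"})
        assert (table["D"] == "x").all()


def test_min_fill_order_is_deterministic():
    net = random_cpts(random_dag(9, 3, seed=5), 3, 1.0, seed=5, n_nodes=9)
    factors = [net._cpt_factor(c) for c in net.cpts.values()]
    eliminate = set(net.variables) - {"v0"}
    orders = {tuple(_min_fill_order(net, factors, set(eliminate))) for _ in range(5)}
    assert len(orders) == 1
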