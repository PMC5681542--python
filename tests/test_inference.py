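"""Logic sampling, conditional queries, the exact Gaussian oracle, and
do-style interventions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import cephbn as cb
from conftest import chain_net, mediator_net


class TestLogicSample:
    def test_parentless_node_obeys_law_of_large_numbers(self):
        net = cb.build_network(("X",), [cb.LocalModel("X", (), 3.0, (), 2.0)])
        sample = cb.logic_sample(net, 100_000, seed=0)
        assert abs(sample["X"].mean() - 3.0) <= 3 * 2.0 / np.sqrt(100_000)

    def test_chain_regression_recovers_coefficient(self):
        sample = cb.logic_sample(chain_net(beta=2.0), 50_000, seed=1)
        slope = np.cov(sample["A"], sample["B"])[0, 1] / sample["A"].var()
        assert slope == pytest.approx(2.0, abs=0.05)

    def test_same_seed_reproduces_table(self):
        net = cb.study_truth()
        a = cb.logic_sample(net, 500, seed=7)
        b = cb.logic_sample(net, 500, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_given_overrides_node_values(self):
        net = chain_net()
        fixed = np.full(100, 1.5)
        sample = cb.logic_sample(net, 100, seed=2, given={"A": fixed})
        assert np.array_equal(sample["A"].to_numpy(), fixed)
        assert sample["B"].mean() == pytest.approx(2.0 + 2.0 * 1.5, abs=0.5)


class TestConditionalQuery:
    def test_trivial_event_normalises_to_one(self):
        q = cb.QuerySpec(event={"A": (None, None)}, n_samples=1000)
        res = cb.conditional_query(chain_net(), q, seed=0)
        assert res.estimate == 1.0

    def test_symmetric_halfline_is_half(self):
        net = cb.build_network(("X",), [cb.LocalModel("X", (), 0.0, (), 1.0)])
        q = cb.QuerySpec(event={"X": (0.0, None)}, n_samples=1_000_000)
        res = cb.conditional_query(net, q, seed=3)
        assert abs(res.estimate - 0.5) <= 3 * res.mc_se

    def test_interval_evidence_matches_gaussian_oracle(self):
        """P(B > 1 | A in [0.9, 1.1]) against the closed-form bivariate
        normal rectangle probability."""
        net = cb.build_network(("A", "B"), [
            cb.LocalModel("A", (), 0.0, (), 1.0),
            cb.LocalModel("B", ("A",), 0.0, (1.0,), 1.0),
        ])
        q = cb.QuerySpec(event={"B": (1.0, None)},
                         evidence={"A": (0.9, 1.1)}, n_samples=200_000)
        res = cb.conditional_query(net, q, seed=4)
        moments = cb.implied_moments(net)
        mvn = stats.multivariate_normal(moments.mean, moments.cov)
        big = 50.0

        def rect(alo, ahi, blo, bhi):
            return (mvn.cdf([ahi, bhi]) - mvn.cdf([alo, bhi])
                    - mvn.cdf([ahi, blo]) + mvn.cdf([alo, blo]))

        p_exact = (rect(0.9, 1.1, 1.0, big) / rect(0.9, 1.1, -big, big))
        assert abs(res.estimate - p_exact) <= 3 * res.mc_se

    def test_no_matching_evidence_is_explicit(self):
        q = cb.QuerySpec(event={"B": (0, 1)}, evidence={"A": (90.0, 91.0)},
                         n_samples=1000)
        res = cb.conditional_query(chain_net(), q, seed=5)
        assert res.no_match
        assert res.estimate is None and res.mc_se is None

    def test_posterior_mean_query(self):
        q = cb.QuerySpec(event="B", evidence={"A": (0.9, 1.1)}, n_samples=50_000)
        res = cb.conditional_query(chain_net(beta=2.0), q, seed=6)
        assert res.estimate == pytest.approx(2.0 + 2.0 * 1.0, abs=4 * res.mc_se)

    def test_query_document_roundtrip(self):
        doc = {"event": {"B": [1.0, None]}, "evidence": {"A": [0.5, 1.5]},
               "n_samples": 5000}
        q = cb.QuerySpec.from_document(doc)
        res = cb.conditional_query(chain_net(), q, seed=11)
        out = res.to_dict()
        assert out["n_samples"] == 5000
        assert 0.0 <= out["estimate"] <= 1.0

    def test_binary_nodes_thresholded(self):
        net = mediator_net()
        q = cb.QuerySpec(event={"Growth": 1}, evidence={"Treatment": 1},
                         n_samples=20_000)
        res = cb.conditional_query(net, q, seed=7)
        assert 0.0 <= res.estimate <= 1.0
        assert res.n_matched_evidence > 0

    def test_unbiased_over_repetitions(self):
        """The rejection estimate averages to the exact value over seeds."""
        net = cb.build_network(("X",), [cb.LocalModel("X", (), 0.0, (), 1.0)])
        q = cb.QuerySpec(event={"X": (0.5, None)}, n_samples=2000)
        estimates = [cb.conditional_query(net, q, seed=s).estimate
                     for s in range(100)]
        exact = 1 - stats.norm.cdf(0.5)
        sd = np.std(estimates, ddof=1)
        assert abs(np.mean(estimates) - exact) <= 3 * sd / np.sqrt(100)


class TestExactConditional:
    def test_chain_implied_moments_by_hand(self):
        net = cb.build_network(("A", "B"), [
            cb.LocalModel("A", (), 0.0, (), 1.0),
            cb.LocalModel("B", ("A",), 2.0, (3.0,), 1.0),
        ])
        moments = cb.implied_moments(net)
        i, j = moments.nodes.index("A"), moments.nodes.index("B")
        assert moments.mean[j] == pytest.approx(2.0)
        assert moments.cov[j, j] == pytest.approx(10.0)   # 9*1 + 1
        assert moments.cov[i, j] == pytest.approx(3.0)

    def test_empty_evidence_returns_joint(self):
        net = cb.study_truth()
        joint = cb.implied_moments(net)
        cond = cb.exact_conditional(net, {})
        assert cond.nodes == joint.nodes
        assert np.allclose(cond.cov, joint.cov)

    def test_leaf_conditional_mean_equals_local_prediction(self):
        net = cb.study_truth()
        evidence = {v: 1.0 for v in net.dag.nodes if v != "dIMPA"}
        cond = cb.exact_conditional(net, evidence)
        lm = net.locals["dIMPA"]
        expected = lm.intercept + sum(b * evidence[p]
                                      for p, b in zip(lm.parents, lm.coefficients))
        assert cond.mean[0] == pytest.approx(expected)
        assert cond.cov[0, 0] == pytest.approx(lm.residual_sd**2)

    def test_sampled_moments_match_implied_moments(self):
        """Logic-sample means agree with the implied joint normal on random
        networks (4 MC standard errors per node)."""
        n = 20_000
        for seed in range(10):
            net = cb.make_truth(seed, noise_scale=1.0)
            sample = cb.logic_sample(net, n, seed=seed + 100)
            moments = cb.implied_moments(net)
            for i, v in enumerate(moments.nodes):
                se = np.sqrt(moments.cov[i, i] / n)
                assert abs(sample[v].mean() - moments.mean[i]) <= 4 * se


class TestInterveneFix:
    def test_fixed_node_is_constant(self):
        net = cb.intervene_fix(cb.study_truth(), "dANB", 0.0)
        sample = cb.logic_sample(net, 1000, seed=0)
        assert np.all(np.abs(sample["dANB"]) <= 5 * cb.SD_FLOOR)

    def test_former_parents_lose_influence(self):
        net = cb.intervene_fix(chain_net(beta=2.0), "B", 7.0)
        q = cb.QuerySpec(event="B", evidence={"A": (3.0, 6.0)}, n_samples=20_000)
        res = cb.conditional_query(net, q, seed=1)
        assert res.estimate == pytest.approx(7.0, abs=1e-4)

    def test_dseparation_after_fixing_mediator(self):
        """With every Treatment -> Growth path through dANB, fixing dANB
        makes the prognosis independent of treatment."""
        net = mediator_net()

        def prognosis(network, t, seed):
            q = cb.QuerySpec(event={"Growth": 1}, evidence={"Treatment": t},
                             n_samples=100_000)
            return cb.conditional_query(network, q, seed=seed)

        before_t, before_u = prognosis(net, 1, 0), prognosis(net, 0, 1)
        gap = abs(before_t.estimate - before_u.estimate)
        assert gap > 3 * np.hypot(before_t.mc_se, before_u.mc_se)

        cut = cb.intervene_fix(net, "dANB", 0.0)
        after_t, after_u = prognosis(cut, 1, 2), prognosis(cut, 0, 3)
        gap = abs(after_t.estimate - after_u.estimate)
        assert gap <= 3 * np.hypot(after_t.mc_se, after_u.mc_se)

    def test_idempotent_and_commutative(self):
        net = cb.study_truth()
        once = cb.intervene_fix(net, "dANB", 0.0)
        twice = cb.intervene_fix(once, "dANB", 0.0)
        assert once.dag.arcs == twice.dag.arcs
        ab = cb.intervene_fix(cb.intervene_fix(net, "dANB", 0.0), "dGoPg", 1.0)
        ba = cb.intervene_fix(cb.intervene_fix(net, "dGoPg", 1.0), "dANB", 0.0)
        assert ab.dag.arcs == ba.dag.arcs
        for v in net.dag.nodes:
            assert ab.locals[v] == ba.locals[v]
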