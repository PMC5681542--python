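"""BIC scoring, constrained hill-climbing, and OLS parameter learning."""

import numpy as np
import pandas as pd
import pytest

import cephbn as cb
from cephbn.errors import ConstraintError, FittingError, ScoringError
from conftest import random_4node_dataset, simulate_linear


class TestBicLocal:
    def test_network_score_decomposes(self, rate_table):
        dag = cb.hill_climb(rate_table, cb.default_constraints(rate_table.columns))
        total = sum(cb.bic_local(v, dag.parents(v), rate_table) for v in dag.nodes)
        assert cb.network_score(dag, rate_table) == pytest.approx(total)

    def test_noise_parent_usually_lowers_score(self):
        """The BIC penalty dominates the ~chi-square likelihood gain of an
        independent parent."""
        worse = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            frame = pd.DataFrame({"Y": rng.normal(size=1000),
                                  "Z": rng.normal(size=1000)})
            worse += (cb.bic_local("Y", ["Z"], frame)
                      < cb.bic_local("Y", [], frame))
        assert worse >= 95

    def test_duplicated_parent_is_singular(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        frame = pd.DataFrame({"Y": rng.normal(size=100), "X1": x, "X2": x})
        with pytest.raises(ScoringError):
            cb.bic_local("Y", ["X1", "X2"], frame)


class TestHillClimb:
    def test_full_blacklist_returns_whitelist_only(self, rate_table):
        nodes = rate_table.columns
        white = frozenset({("dT", "Growth")})
        black = frozenset((p, c) for p in nodes for c in nodes if p != c) - white
        dag = cb.hill_climb(rate_table, cb.ConstraintSet(white, black))
        assert dag.arcs == white

    def test_whitelist_arcs_forced_present(self, rate_table):
        constraints = cb.default_constraints(rate_table.columns)
        dag = cb.hill_climb(rate_table, constraints)
        assert constraints.whitelist <= dag.arcs
        assert not (constraints.blacklist & dag.arcs)

    def test_chain_matches_exhaustive_oracle(self):
        frame = simulate_linear([("A", "B"), ("B", "C")], n=1000, seed=7,
                                beta_range=(5.0, 5.0), nodes=("A", "B", "C"))
        dag = cb.hill_climb(frame)
        _, best_score = cb.exhaustive_search(frame)
        assert cb.network_score(dag, frame) == pytest.approx(best_score)
        assert dag.skeleton() == frozenset(
            {frozenset({"A", "B"}), frozenset({"B", "C"})})

    @pytest.mark.parametrize("seed", range(5))
    def test_output_respects_constraints_and_acyclicity(self, seed):
        frame = random_4node_dataset(seed)
        cs = cb.ConstraintSet(frozenset({("A", "B")}), frozenset({("D", "A")}))
        dag = cb.hill_climb(frame, cs)
        dag.topological_order()  # raises if cyclic
        assert ("A", "B") in dag.arcs
        assert ("D", "A") not in dag.arcs

    def test_never_scores_below_start_graph(self, rate_table):
        cs = cb.default_constraints(rate_table.columns)
        start = cb.Dag(tuple(rate_table.columns), frozenset(cs.whitelist))
        dag = cb.hill_climb(rate_table, cs)
        assert (cb.network_score(dag, rate_table)
                >= cb.network_score(start, rate_table))

    def test_score_equivalent_orientations_tie(self):
        """On data from A -> B the two single-arc DAGs receive equal BIC."""
        frame = simulate_linear([("A", "B")], n=500, seed=3, nodes=("A", "B"))
        ab = cb.Dag(("A", "B"), frozenset({("A", "B")}))
        ba = cb.Dag(("A", "B"), frozenset({("B", "A")}))
        assert abs(cb.network_score(ab, frame)
                   - cb.network_score(ba, frame)) <= 1e-9

    def test_cyclic_whitelist_rejected(self):
        with pytest.raises(ConstraintError):
            cb.ConstraintSet(frozenset({("A", "B"), ("B", "A")}))
        with pytest.raises(ConstraintError):
            cb.ConstraintSet(frozenset({("A", "B")}), frozenset({("A", "B")}))

    def test_deterministic_given_inputs(self, rate_table):
        cs = cb.default_constraints(rate_table.columns)
        assert cb.hill_climb(rate_table, cs).arcs == cb.hill_climb(rate_table, cs).arcs


class TestFitOls:
    def test_parentless_node_gets_mean_and_ml_sd(self):
        rng = np.random.default_rng(0)
        y = rng.normal(3.0, 2.0, size=400)
        frame = pd.DataFrame({"Y": y})
        net = cb.fit_ols(cb.Dag(("Y",), frozenset()), frame)
        lm = net.locals["Y"]
        assert lm.intercept == pytest.approx(y.mean())
        assert lm.residual_sd == pytest.approx(y.std(ddof=0))

    def test_noiseless_child_is_exact_with_floored_sd(self):
        x = np.linspace(-2, 2, 50)
        frame = pd.DataFrame({"X": x, "Y": 2.0 + 3.0 * x})
        net = cb.fit_ols(cb.Dag(("X", "Y"), frozenset({("X", "Y")})), frame)
        lm = net.locals["Y"]
        assert lm.intercept == pytest.approx(2.0, abs=1e-8)
        assert lm.coefficients[0] == pytest.approx(3.0, abs=1e-8)
        assert lm.residual_sd == cb.SD_FLOOR

    def test_coefficients_recovered_at_large_n(self):
        rng = np.random.default_rng(5)
        n = 10_000
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        y = 1.0 + 1.5 * x1 - 0.8 * x2 + rng.normal(0, 0.5, size=n)
        frame = pd.DataFrame({"X1": x1, "X2": x2, "Y": y})
        dag = cb.Dag(("X1", "X2", "Y"), frozenset({("X1", "Y"), ("X2", "Y")}))
        lm = cb.fit_ols(dag, frame).locals["Y"]
        assert lm.coefficients == pytest.approx((1.5, -0.8), abs=0.05)

    def test_singular_design_names_node(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        frame = pd.DataFrame({"A": x, "B": x, "Y": rng.normal(size=50)})
        dag = cb.Dag(("A", "B", "Y"), frozenset({("A", "Y"), ("B", "Y")}))
        with pytest.raises(FittingError, match="Y"):
            cb.fit_ols(dag, frame)


class TestSerialisation:
    def test_dag_tsv_roundtrip(self, tmp_path):
        dag = cb.Dag(("A", "B", "C"), frozenset({("A", "B"), ("B", "C")}))
        dag.to_tsv(tmp_path / "dag.tsv")
        again = cb.Dag.from_tsv(tmp_path / "dag.tsv", dag.nodes)
        assert again.arcs == dag.arcs

    def test_dot_mentions_every_arc(self):
        dag = cb.Dag(("A", "B"), frozenset({("A", "B")}))
        assert '"A" -> "B"' in dag.to_dot()

    def test_fitted_network_json_roundtrip(self, tmp_path):
        net = cb.study_truth()
        path = tmp_path / "net.json"
        net.to_json(path)
        again = cb.FittedNetwork.from_json(path)
        assert again.dag.arcs == net.dag.arcs
        for v in net.dag.nodes:
            assert again.locals[v].coefficients == pytest.approx(
                net.locals[v].coefficients)

    def test_skeleton_shd(self):
        a = cb.Dag(("A", "B", "C"), frozenset({("A", "B")}))
        b = cb.Dag(("A", "B", "C"), frozenset({("B", "A"), ("B", "C")}))
        assert cb.skeleton_shd(a, b) == 1  # orientation ignored, one extra pair
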