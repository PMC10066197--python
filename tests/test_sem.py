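import itertools

import numpy as np
import pandas as pd
import pytest

from divstab.sem import (
    Claim,
    DagError,
    DagSpec,
    PiecewiseSEM,
    basis_set,
    dsep_pvalues,
    fishers_c,
    fit_sem,
    multigroup_sem,
)
from divstab.simulate import simulate_dag_data


def _brute_force_claim_count(dag: DagSpec) -> int:
    """Count non-adjacent pairs directly (independent of basis_set's walk)."""
    adjacent = set()
    for a, b in dag.edges:
        adjacent.add(frozenset((a, b)))
    for pair in dag.correlated:
        adjacent.add(pair)
    count = 0
    for a, b in itertools.combinations(dag.nodes, 2):
        if frozenset((a, b)) not in adjacent:
            count += 1
    return count


class TestDagSpec:
    def test_parse_round_trip(self):
        text = """
        # comment
        group: site_id
        a -> b
        b -> c
        a ~~ d
        nodes: e
        """
        dag = DagSpec.from_text(text)
        assert set(dag.nodes) == {"a", "b", "c", "d", "e"}
        assert dag.edges == (("a", "b"), ("b", "c"))
        assert dag.correlated == (frozenset(("a", "d")),)
        assert dag.parents("c") == ("b",)
        assert set(dag.exogenous) == {"a", "d", "e"}

    def test_cycle_raises(self):
        with pytest.raises(DagError, match="cycle"):
            DagSpec(nodes=("a", "b"), edges=(("a", "b"), ("b", "a")))

    def test_correlated_pair_cannot_be_edge(self):
        with pytest.raises(DagError, match="directed"):
            DagSpec(nodes=("a", "b"), edges=(("a", "b"),), correlated=(frozenset(("a", "b")),))

    def test_undeclared_node_raises(self):
        with pytest.raises(DagError, match="undeclared"):
            DagSpec(nodes=("a",), edges=(("a", "b"),))


class TestBasisSet:
    def test_chain_single_claim(self):
        dag = DagSpec(nodes=("x", "y", "z"), edges=(("x", "y"), ("y", "z")))
        assert basis_set(dag) == [Claim(x="x", y="z", given=("y",))]

    def test_fully_connected_empty(self):
        dag = DagSpec(
            nodes=("a", "b", "c"), edges=(("a", "b"), ("a", "c"), ("b", "c"))
        )
        assert basis_set(dag) == []

    def test_correlated_pairs_excluded(self):
        dag = DagSpec(
            nodes=("a", "b", "c"), edges=(("a", "c"), ("b", "c")),
            correlated=(frozenset(("a", "b")),),
        )
        assert basis_set(dag) == []

    def test_random_sparse_dags_match_enumeration(self, rng):
        nodes = tuple("abcdef")
        for _ in range(30):
            edges = []
            for i, a in enumerate(nodes):
                for b in nodes[i + 1 :]:
                    if rng.random() < 0.3:
                        edges.append((a, b))
            dag = DagSpec(nodes=nodes, edges=tuple(edges))
            assert len(basis_set(dag)) == _brute_force_claim_count(dag)


class TestFishersC:
    def test_empty_set_vacuous(self):
        assert fishers_c([]) == (0.0, 0, 1.0)

    def test_closed_form_two_halves(self):
        c, df, p = fishers_c([0.5, 0.5])
        assert c == pytest.approx(-2 * np.log(0.25), abs=1e-10)
        assert df == 4
        # chi2_4 survival has the closed form e^{-C/2} (1 + C/2)
        assert p == pytest.approx(np.exp(-c / 2) * (1 + c / 2), abs=1e-12)

    def test_monotone_in_each_p(self, rng):
        ps = list(rng.uniform(0.05, 0.95, 5))
        c0, _, _ = fishers_c(ps)
        ps[2] *= 0.5
        c1, _, _ = fishers_c(ps)
        assert c1 > c0

    def test_permutation_invariant(self, rng):
        ps = rng.uniform(0.01, 1.0, 6)
        assert fishers_c(ps)[0] == pytest.approx(fishers_c(ps[::-1])[0])

    def test_zero_p_rejected(self):
        with pytest.raises(ValueError):
            fishers_c([0.0, 0.5])
        with pytest.raises(ValueError):
            fishers_c([1.5])


CHAIN = DagSpec(nodes=("w", "x", "y", "z"), edges=(("w", "x"), ("x", "y"), ("y", "z")))


class TestDsep:
    def test_constant_variable_flagged(self):
        df = pd.DataFrame(
            {
                "site_id": ["a"] * 10 + ["b"] * 10,
                "x": 1.0,
                "y": np.random.default_rng(0).normal(size=20),
            }
        )
        tests = dsep_pvalues([Claim("x", "y", ())], df, "site_id")
        assert tests[0].flagged and np.isnan(tests[0].p)

    def test_violated_independence_detected(self):
        # z depends directly on w, violating the chain's w ⟂ z | y claim
        coefs = {("w", "x"): 0.7, ("x", "y"): 0.7, ("y", "z"): 0.5, ("w", "z"): 0.6}
        dag_true = DagSpec(nodes=CHAIN.nodes, edges=CHAIN.edges + (("w", "z"),))
        hits = 0
        for seed in range(20):
            df = simulate_dag_data(dag_true, coefs, n_sites=30, n_blocks_per_site=10, seed=seed)
            tests = dsep_pvalues(basis_set(CHAIN), df, "site_id")
            claim_p = {t.claim: t.p for t in tests}
            wz = [p for c, p in claim_p.items() if {c.x, c.y} == {"w", "z"}]
            hits += wz[0] < 0.05
        assert hits >= 18


class TestFitSem:
    def test_near_noiseless_marginal_r2_approaches_one(self, rng):
        n = 120
        sites = np.repeat([f"s{i}" for i in range(30)], 4)
        x = rng.normal(size=n)
        df = pd.DataFrame({"site_id": sites, "x": x, "y": 2.0 * x + rng.normal(0, 1e-3, n)})
        dag = DagSpec(nodes=("x", "y"), edges=(("x", "y"),))
        res = fit_sem(dag, df)
        marginal, conditional = res.r2["y"]
        assert marginal > 0.999
        assert marginal <= conditional <= 1.0

    def test_standardized_paths_invariant_to_affine_rescaling(self):
        coefs = {("w", "x"): 0.7, ("x", "y"): 0.7, ("y", "z"): 0.5}
        df = simulate_dag_data(CHAIN, coefs, n_sites=40, seed=3)
        res1 = fit_sem(CHAIN, df)
        scaled = df.copy()
        scaled["x"] = 100.0 * scaled["x"] + 7.0
        scaled["z"] = 0.01 * scaled["z"] - 3.0
        res2 = fit_sem(CHAIN, scaled)
        np.testing.assert_allclose(
            res1.path_table["std_estimate"], res2.path_table["std_estimate"], atol=1e-8
        )

    def test_simplification_removes_spurious_edge(self):
        coefs = {("w", "x"): 0.7, ("x", "y"): 0.7, ("y", "z"): 0.5}
        spurious = DagSpec(nodes=CHAIN.nodes, edges=CHAIN.edges + (("w", "z"),))
        removed = 0
        for seed in range(5):
            df = simulate_dag_data(CHAIN, coefs, n_sites=40, seed=seed)
            res = fit_sem(spurious, df, simplify=True)
            removed += ("w", "z") not in res.dag.edges
            # audit: dropped + retained equals the initial edge count
            assert len(res.dropped_paths) + len(res.dag.edges) == len(spurious.edges)
        assert removed >= 4

    def test_estimator_interface(self):
        coefs = {("w", "x"): 0.7, ("x", "y"): 0.7, ("y", "z"): 0.5}
        df = simulate_dag_data(CHAIN, coefs, n_sites=30, seed=1)
        est = PiecewiseSEM(dag=CHAIN).fit(df)
        assert est.get_params()["simplify"] is False
        assert est.fisher_c_ >= 0 and est.dsep_df_ % 2 == 0
        assert set(est.r2_) == {"x", "y", "z"}
        for marginal, conditional in est.r2_.values():
            assert 0 <= marginal <= conditional <= 1

    def test_too_few_complete_cases(self):
        df = pd.DataFrame(
            {"site_id": ["a", "b"] * 3, "x": [1.0, 2, 3, np.nan] + [np.nan] * 2,
             "y": [1.0] * 6}
        )
        dag = DagSpec(nodes=("x", "y"), edges=(("x", "y"),))
        with pytest.raises(DagError, match="complete-case"):
            fit_sem(dag, df)


class TestMultigroup:
    def test_identical_phases_all_constrained(self):
        coefs = {("w", "x"): 0.7, ("x", "y"): 0.7, ("y", "z"): 0.5}
        df = simulate_dag_data(CHAIN, coefs, n_sites=30, seed=5)
        res = multigroup_sem(CHAIN, df, df.copy())
        assert (res.paths["status"] == "constrained").all()
        # constrained estimates equal across phases by construction
        np.testing.assert_allclose(res.paths["est_pre"], res.paths["est_post"])

    def test_changed_path_goes_free(self):
        pre_coefs = {("w", "x"): 0.6, ("x", "y"): 0.6, ("y", "z"): 0.5}
        post_coefs = {**pre_coefs, ("x", "y"): -0.4}
        stacked = simulate_dag_data(
            CHAIN, pre_coefs, n_sites=40, seed=9, coefficients_post=post_coefs
        )
        pre = stacked[stacked["phase"] == 0.0]
        post = stacked[stacked["phase"] == 1.0]
        res = multigroup_sem(CHAIN, pre, post)
        status = dict(zip(zip(res.paths["predictor"], res.paths["response"]), res.paths["status"]))
        assert status[("x", "y")] == "free"
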