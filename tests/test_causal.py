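import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidscore.causal import (CITester, OracleCITester, learn_pag,
                               markov_blanket, select_alpha)
from lipidscore.causal.pag import PAG, Endpoint
from lipidscore.simulate import SEMConfig, generate_sem


def partial_corr_ztest(df, x, y, Z):
    """Independent oracle: residual-based partial correlation + Fisher z."""
    n = len(df)
    xv = df[x].to_numpy(dtype=float)
    yv = df[y].to_numpy(dtype=float)
    if Z:
        Xz = np.column_stack([np.ones(n)] +
                             [df[z].to_numpy(dtype=float) for z in Z])
        xv = xv - Xz @ np.linalg.lstsq(Xz, xv, rcond=None)[0]
        yv = yv - Xz @ np.linalg.lstsq(Xz, yv, rcond=None)[0]
    r = np.corrcoef(xv, yv)[0, 1]
    zstat = np.sqrt(n - len(Z) - 3) * np.arctanh(r)
    return 2 * stats.norm.sf(abs(zstat))


class TestCITest:
    def test_matches_partial_correlation_oracle(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(200, 4)),
                          columns=["a", "b", "c", "d"])
        df["b"] += 0.5 * df["a"]
        df["c"] += 0.5 * df["b"]
        tester = CITester(df)
        for x, y, Z in [("a", "b", ()), ("a", "c", ("b",)),
                        ("a", "d", ("b", "c"))]:
            assert tester.pvalue(x, y, Z) == pytest.approx(
                partial_corr_ztest(df, x, y, list(Z)), abs=1e-8)

    def test_near_copy_dependent(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=500)
        df = pd.DataFrame({"x": x, "y": x + 1e-3 * rng.normal(size=500)})
        df["z"] = rng.normal(size=500)
        tester = CITester(df)
        assert tester.pvalue("x", "y", ()) < 1e-6

    def test_chain_conditional_independence(self):
        hits = 0
        n_seeds = 20
        cfg = SEMConfig(
            variables=[("x", "continuous"), ("y", "continuous"),
                       ("z", "continuous")],
            edges=[("x", "y", 0.8), ("y", "z", 0.8)], n=2000)
        for seed in range(n_seeds):
            df, _ = generate_sem(cfg, seed)
            tester = CITester(df)
            hits += tester.pvalue("x", "z", ("y",)) >= 0.05
        assert hits >= int(0.9 * n_seeds)

    def test_null_calibration(self):
        rng = np.random.default_rng(2)
        alpha = 0.05
        rejections = 0
        reps = 300
        for _ in range(reps):
            df = pd.DataFrame(rng.normal(size=(100, 2)), columns=["x", "y"])
            tester = CITester(df)
            rejections += tester.pvalue("x", "y", ()) < alpha
        rate = rejections / reps
        mc_sd = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(rate - alpha) <= 3 * mc_sd + 0.01

    def test_mixed_binary_involvement(self):
        cfg = SEMConfig(
            variables=[("x", "continuous"), ("t", "binary"),
                       ("z", "continuous")],
            edges=[("x", "t", 2.0)], n=1000)
        df, _ = generate_sem(cfg, 5)
        tester = CITester(df, {"x": "continuous", "z": "continuous",
                               "t": "categorical"})
        assert tester.pvalue("x", "t", ()) < 1e-4
        assert tester.pvalue("z", "t", ()) > 0.01

    def test_insufficient_rows_conservative(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(size=(6, 4)),
                          columns=["a", "b", "c", "d"])
        tester = CITester(df)
        assert tester.pvalue("a", "b", ("c", "d")) == 0.0
        assert tester.skipped


def _random_dag(n_nodes, p_edge, seed):
    rng = np.random.default_rng(seed)
    names = [f"v{i}" for i in range(n_nodes)]
    dag = nx.DiGraph()
    dag.add_nodes_from(names)
    for i, j in itertools.combinations(range(n_nodes), 2):
        if rng.random() < p_edge:
            dag.add_edge(names[i], names[j])
    return dag


class TestLearnPAGOracle:
    def test_independent_variables_empty_graph(self):
        dag = nx.DiGraph()
        dag.add_nodes_from(["a", "b", "c"])
        pag = learn_pag(tester=OracleCITester(dag), alpha=0.5)
        assert pag.n_edges == 0

    def test_collider_orientation(self):
        dag = nx.DiGraph([("X", "Z"), ("Y", "Z")])
        pag = learn_pag(tester=OracleCITester(dag), alpha=0.5)
        assert pag.skeleton() == {frozenset(("X", "Z")),
                                  frozenset(("Y", "Z"))}
        assert pag.mark("X", "Z") is Endpoint.ARROW
        assert pag.mark("Y", "Z") is Endpoint.ARROW

    @pytest.mark.parametrize("n_nodes,p_edge,seed", [
        (4, 0.4, 0), (4, 0.6, 1), (5, 0.4, 2), (5, 0.5, 3),
        (6, 0.35, 4), (6, 0.5, 5), (7, 0.3, 6), (7, 0.4, 7),
    ])
    def test_oracle_exact_skeleton(self, n_nodes, p_edge, seed):
        dag = _random_dag(n_nodes, p_edge, seed)
        pag = learn_pag(tester=OracleCITester(dag), alpha=0.5,
                        max_cond_size=n_nodes)
        true_skel = {frozenset(e) for e in dag.edges}
        assert pag.skeleton() == true_skel

    def test_order_invariance(self):
        dag = _random_dag(6, 0.4, 11)
        pag1 = learn_pag(tester=OracleCITester(dag), alpha=0.5, max_cond_size=6)
        relabel = {v: f"w{9 - i}" for i, v in enumerate(sorted(dag.nodes))}
        dag2 = nx.relabel_nodes(dag, relabel)
        pag2 = learn_pag(tester=OracleCITester(dag2), alpha=0.5,
                         max_cond_size=6)
        skel1 = {frozenset(relabel[a] for a in e) for e in pag1.skeleton()}
        assert skel1 == pag2.skeleton()


class TestMarkovBlanket:
    def test_textbook_collider(self):
        dag = nx.DiGraph([("X", "T"), ("S", "T")])
        pag = learn_pag(tester=OracleCITester(dag), alpha=0.5)
        assert markov_blanket(pag, "T") == {"X", "S"}

    def test_isolated_target(self):
        dag = nx.DiGraph()
        dag.add_nodes_from(["T", "A", "B"])
        dag.add_edge("A", "B")
        pag = learn_pag(tester=OracleCITester(dag), alpha=0.5)
        assert markov_blanket(pag, "T") == set()

    def test_chain_blanket(self):
        # A -> B -> T: d-separation oracle says MB(T) = {B}
        dag = nx.DiGraph([("A", "B"), ("B", "T")])
        assert nx.is_d_separator(dag, {"A"}, {"T"}, {"B"})
        pag = learn_pag(tester=OracleCITester(dag), alpha=0.5)
        assert markov_blanket(pag, "T") == {"B"}

    def test_spouse_included(self):
        dag = nx.DiGraph([("T", "C"), ("S", "C"), ("A", "T")])
        pag = learn_pag(tester=OracleCITester(dag), alpha=0.5,
                        max_cond_size=4)
        mb = markov_blanket(pag, "T")
        assert "S" in mb and "C" in mb and "A" in mb

    def test_missing_target_errors(self):
        pag = PAG(["a", "b", "c"])
        with pytest.raises(KeyError):
            markov_blanket(pag, "zzz")


class TestLearnPAGData:
    def test_collider_from_data(self):
        cfg = SEMConfig(
            variables=[("X", "continuous"), ("Y", "continuous"),
                       ("Z", "continuous")],
            edges=[("X", "Z", 0.8), ("Y", "Z", 0.8)], n=2000)
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            df, _ = generate_sem(cfg, seed)
            pag = learn_pag(data=df, alpha=0.05)
            ok = (pag.skeleton() == {frozenset(("X", "Z")),
                                     frozenset(("Y", "Z"))}
                  and pag.mark("X", "Z") is Endpoint.ARROW
                  and pag.mark("Y", "Z") is Endpoint.ARROW)
            hits += ok
        assert hits >= int(0.9 * n_seeds)

    def test_independent_data_empty(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(2000, 4)),
                          columns=list("abcd"))
        pag = learn_pag(data=df, alpha=0.01)
        assert pag.n_edges == 0


class TestSelectAlpha:
    def test_grid_of_one(self):
        cfg = SEMConfig(
            variables=[("x", "continuous"), ("y", "continuous"),
                       ("t", "binary")],
            edges=[("x", "t", 2.0)], n=80)
        df, _ = generate_sem(cfg, 1)
        res = select_alpha(df, "t", grid=[0.1])
        assert res.chosen_alpha == 0.1
        assert set(res.auc) == {0.1}

    def test_no_signal_auc_near_half(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(60, 4)), columns=list("abcd"))
        df["t"] = rng.integers(0, 2, 60).astype(float)
        res = select_alpha(df, "t", grid=[0.05, 0.2])
        for auc in res.auc.values():
            assert abs(auc - 0.5) < 0.25

    def test_nonbinary_target_rejected(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abt"))
        with pytest.raises(ValueError):
            select_alpha(df, "t", grid=[0.1])

    def test_parents_recovered(self):
        cfg = SEMConfig(
            variables=[("x1", "continuous"), ("x2", "continuous"),
                       ("x3", "continuous"), ("x4", "continuous"),
                       ("t", "binary")],
            edges=[("x1", "t", 2.0), ("x2", "t", 2.0), ("x3", "x4", 0.7)],
            n=120)
        df, _ = generate_sem(cfg, 2)
        res = select_alpha(df, "t", grid=[0.05, 0.1, 0.2])
        assert {"x1", "x2"} <= res.final_mb
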