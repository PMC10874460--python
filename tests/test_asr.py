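"""Ancestral state reconstruction: GLS oracle, pruning vs enumeration,
marginal probabilities, and model averaging."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

from conftest import tree_from_newick
from jawmorph.asr import (
    MkModel,
    asr_bm_continuous,
    build_rate_matrix,
    mk_fit,
    mk_marginal_asr,
    model_average_states,
)


# -- independent enumeration oracle -------------------------------------------


def enum_likelihood_and_marginals(tree, tip_states, Q, states):
    """Brute-force joint sum over all internal-node state assignments."""
    k = len(states)
    sidx = {s: i for i, s in enumerate(states)}
    internals = [nd for nd in tree.nodes() if not nd.is_leaf()]
    prior = np.full(k, 1.0 / k)
    P = {
        nd.node_id: expm(Q * (nd.parent_node.age - nd.age))
        for nd in tree.nodes()
        if nd.parent_node is not None
    }
    total = 0.0
    marg = {nd.node_id: np.zeros(k) for nd in internals}
    root_id = tree.root.node_id
    for assign in itertools.product(range(k), repeat=len(internals)):
        amap = {nd.node_id: s for nd, s in zip(internals, assign)}
        prob = prior[amap[root_id]]
        for nd in tree.nodes():
            if nd.parent_node is None:
                continue
            ps = amap[nd.parent_node.node_id]
            cs = (
                sidx[tip_states[nd.taxon.label]]
                if nd.is_leaf()
                else amap[nd.node_id]
            )
            prob *= P[nd.node_id][ps, cs]
        total += prob
        for nid, s in amap.items():
            marg[nid][s] += prob
    marg = {nid: v / total for nid, v in marg.items()}
    return np.log(total), marg


def simulate_mk(tree, Q, states, seed):
    rng = np.random.default_rng(seed)
    k = len(states)
    vals = {}
    for nd in tree.nodes(order="preorder"):
        if nd.parent_node is None:
            vals[nd.node_id] = rng.integers(k)
        else:
            P = expm(Q * (nd.parent_node.age - nd.age))
            vals[nd.node_id] = rng.choice(k, p=P[vals[nd.parent_node.node_id]])
    return {t: states[vals[t]] for t in tree.tip_labels}


class TestContinuousAsr:
    def test_two_tip_symmetric_root_is_midpoint(self):
        t = tree_from_newick("(A:1,B:1);")
        res = asr_bm_continuous(t, {"A": 0.0, "B": 4.0})
        root = next(iter(res.estimates.index))
        assert res.estimates.loc[root, "trait"] == pytest.approx(2.0)

    def test_three_tip_gls_oracle(self, hand_tree):
        res = asr_bm_continuous(hand_tree, {"A": 0.0, "B": 0.0, "C": 3.0})
        V = np.array([[2.0, 1.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 2.0]])
        y = np.array([0.0, 0.0, 3.0])
        one = np.ones(3)
        Vi = np.linalg.inv(V)
        a = (one @ Vi @ y) / (one @ Vi @ one)
        assert res.root_estimate["trait"] == pytest.approx(a, abs=1e-9)
        # the cherry node (A,B): GLS prediction with shared depth vector (1,1,0)
        c = np.array([1.0, 1.0, 0.0])
        pred = a + c @ Vi @ (y - a)
        cherry = [n for n in res.estimates.index if n != hand_tree.root.node_id][0]
        assert res.estimates.loc[cherry, "trait"] == pytest.approx(pred, abs=1e-9)

    def test_constant_tips_zero_rate(self, four_tip_tree):
        res = asr_bm_continuous(
            four_tip_tree, {t: 7.0 for t in four_tip_tree.tip_labels}
        )
        assert np.allclose(res.estimates.to_numpy(), 7.0)
        assert res.sigma2_hat["trait"] == pytest.approx(0.0, abs=1e-12)

    def test_variance_calibration_under_bm(self):
        """Nominal 95% intervals cover true node states at close to the
        nominal rate on BM-simulated data."""
        from jawmorph.synthdata import simulate_bm_traits, simulate_tree

        hits = total = 0
        for rep in range(30):
            t = simulate_tree(40, 0.15, 0.03, root_age=100, seed=rep)
            truth = simulate_bm_traits(t, 0.3, seed=rep + 500)
            tips = {k: truth[k] for k in t.tip_labels}
            res = asr_bm_continuous(t, tips)
            for nid in res.estimates.index:
                est = res.estimates.loc[nid, "trait"]
                sd = np.sqrt(res.variances.loc[nid, "trait"])
                if sd == 0:
                    continue
                hits += abs(truth[nid] - est) <= 1.96 * sd
                total += 1
        assert 0.90 <= hits / total <= 0.99

    def test_nonpositive_branch_rejected(self):
        import dendropy

        from jawmorph.phylo import TimeTree

        tr = dendropy.Tree.get(data="(A:1,B:0.0):0;", schema="newick")
        with pytest.raises(ValueError):
            tt = TimeTree(tr)
            asr_bm_continuous(tt, {"A": 0.0, "B": 1.0})


class TestMkLikelihood:
    def test_pruning_equals_enumeration_four_tips(self, four_tip_tree):
        tip_states = {"A": "x", "B": "y", "C": "x", "D": "y"}
        for rate in (0.01, 0.1, 1.0):
            Q = build_rate_matrix("ER", [rate], 2)
            model = MkModel(four_tip_tree, tip_states, model="ER")
            ll = model.log_likelihood(Q)
            oracle, _ = enum_likelihood_and_marginals(
                four_tip_tree, tip_states, Q, ["x", "y"]
            )
            assert ll == pytest.approx(oracle, abs=1e-8)

    def test_invariant_character_drives_rate_to_zero(self, four_tip_tree):
        states = {t: "x" for t in four_tip_tree.tip_labels}
        states["A"] = "x"
        fit = mk_fit(four_tip_tree, states, model="ER",
                     states=["x", "y"], n_starts=2)
        # all tips identical: likelihood maximised as the rate vanishes
        assert fit.rate_matrix[0, 1] < 1e-3
        res = mk_marginal_asr(four_tip_tree, states, fit, states=["x", "y"])
        root = four_tip_tree.root.node_id
        assert res.node_probabilities.loc[root, "x"] > 0.99

    def test_model_nesting_likelihood_ordering(self, four_tip_tree):
        tip_states = {"A": "x", "B": "y", "C": "z", "D": "x"}
        fits = {
            m: mk_fit(four_tip_tree, tip_states, model=m, n_starts=3, seed=1)
            for m in ("ER", "SYM", "ARD")
        }
        assert fits["ER"].log_likelihood <= fits["SYM"].log_likelihood + 1e-6
        assert fits["SYM"].log_likelihood <= fits["ARD"].log_likelihood + 1e-6
        # AIC identity
        for f in fits.values():
            assert f.aic == pytest.approx(
                2 * f.n_params - 2 * f.log_likelihood, abs=1e-9
            )

    def test_er_rate_recovery(self):
        from jawmorph.synthdata import simulate_tree

        errs = []
        q = 0.05
        Q = build_rate_matrix("ER", [q], 3)
        for rep in range(25):
            t = simulate_tree(200, 0.15, 0.03, root_age=80, seed=rep)
            tips = simulate_mk(t, Q, ["a", "b", "c"], seed=rep)
            if len(set(tips.values())) < 2:
                continue
            fit = mk_fit(t, tips, model="ER", states=["a", "b", "c"], n_starts=2)
            errs.append(abs(fit.rate_matrix[0, 1] - q) / q)
        assert np.median(errs) < 0.25


class TestMarginalAsr:
    def test_symmetric_two_tip_root_half_half(self):
        t = tree_from_newick("(A:1,B:1);")
        Q = build_rate_matrix("ER", [0.3], 2)
        from jawmorph.asr import MkFit

        fit = MkFit(model="ER", states=["x", "y"], rate_matrix=Q,
                    log_likelihood=0.0, n_params=1)
        res = mk_marginal_asr(t, {"A": "x", "B": "y"}, fit)
        root = t.root.node_id
        assert res.node_probabilities.loc[root].to_numpy() == pytest.approx(
            [0.5, 0.5], abs=1e-9
        )

    def test_marginals_match_enumeration(self, four_tip_tree):
        tip_states = {"A": "x", "B": "y", "C": "x", "D": "y"}
        Q = build_rate_matrix("ASYM", [0.2, 0.05], 2)
        from jawmorph.asr import MkFit

        fit = MkFit(model="ASYM", states=["x", "y"], rate_matrix=Q,
                    log_likelihood=0.0, n_params=2)
        res = mk_marginal_asr(four_tip_tree, tip_states, fit)
        _, oracle = enum_likelihood_and_marginals(
            four_tip_tree, tip_states, Q, ["x", "y"]
        )
        for nid, vec in oracle.items():
            assert res.node_probabilities.loc[nid].to_numpy() == pytest.approx(
                vec, abs=1e-8
            )

    def test_probabilities_sum_to_one(self, four_tip_tree):
        tip_states = {"A": "x", "B": "y", "C": "x", "D": "x"}
        fit = mk_fit(four_tip_tree, tip_states, model="SYM", n_starts=2)
        res = mk_marginal_asr(four_tip_tree, tip_states, fit)
        s = res.node_probabilities.to_numpy().sum(axis=1)
        assert np.abs(s - 1).max() < 1e-9


class TestModelAveraging:
    def _fit_all(self, tree, tip_states):
        out = []
        for m in ("ER", "SYM", "ARD", "ASYM"):
            fit = mk_fit(tree, tip_states, model=m, n_starts=2, seed=0)
            out.append(mk_marginal_asr(tree, tip_states, fit))
        return out

    def test_idempotent_on_identical_inputs(self, four_tip_tree):
        tip_states = {"A": "x", "B": "y", "C": "x", "D": "y"}
        fit = mk_fit(four_tip_tree, tip_states, model="ER", n_starts=2)
        r = mk_marginal_asr(four_tip_tree, tip_states, fit)
        avg = model_average_states([r, r, r])
        assert np.allclose(
            avg.node_probabilities.to_numpy(),
            r.node_probabilities.to_numpy(),
            atol=1e-12,
        )

    def test_mean_of_opposite_certainty_is_half(self, four_tip_tree):
        import pandas as pd

        from jawmorph.asr import DiscreteAsrResult

        idx = ["n1", "n2"]
        a = DiscreteAsrResult(
            states=["x", "y"],
            node_probabilities=pd.DataFrame(
                [[1.0, 0.0], [1.0, 0.0]], index=idx, columns=["x", "y"]
            ),
        )
        b = DiscreteAsrResult(
            states=["x", "y"],
            node_probabilities=pd.DataFrame(
                [[0.0, 1.0], [0.0, 1.0]], index=idx, columns=["x", "y"]
            ),
        )
        avg = model_average_states([a, b])
        assert np.allclose(avg.node_probabilities.to_numpy(), 0.5)

    def test_average_of_four_verified_models(self, four_tip_tree):
        tip_states = {"A": "x", "B": "y", "C": "x", "D": "y"}
        results = self._fit_all(four_tip_tree, tip_states)
        avg = model_average_states(results)
        manual = np.mean(
            [r.node_probabilities.to_numpy() for r in results], axis=0
        )
        manual = manual / manual.sum(axis=1, keepdims=True)
        assert np.allclose(avg.node_probabilities.to_numpy(), manual, atol=1e-12)

    def test_disjoint_state_spaces_rejected(self, four_tip_tree):
        tip_states = {"A": "x", "B": "y", "C": "x", "D": "y"}
        fit = mk_fit(four_tip_tree, tip_states, model="ER", n_starts=1)
        r = mk_marginal_asr(four_tip_tree, tip_states, fit)
        fit2 = mk_fit(four_tip_tree, {k: v.upper() for k, v in tip_states.items()},
                      model="ER", n_starts=1)
        r2 = mk_marginal_asr(
            four_tip_tree, {k: v.upper() for k, v in tip_states.items()}, fit2
        )
        with pytest.raises(ValueError):
            model_average_states([r, r2])
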