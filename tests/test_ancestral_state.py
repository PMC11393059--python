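"""Parsimony and Mk1 reconstruction against brute-force enumeration."""

import itertools
import math

import numpy as np
import pytest

from thermofungi import ancestral_state as anc
from thermofungi import synthetic_data as sd
from thermofungi.formats_io import Phylogeny
import dendropy


def tree_from_newick(s: str) -> Phylogeny:
    t = dendropy.Tree.get(data=s, schema="newick", preserve_underscores=True)
    for e in t.preorder_edge_iter():
        if e.head_node is not t.seed_node and e.length is None:
            e.length = 0.0
    return Phylogeny(tree=t)


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_parsimony_score(phy: Phylogeny, states: dict[str, int], k: int) -> int:
    nodes = list(phy.tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    best = math.inf
    for assign in itertools.product(range(k), repeat=len(internal)):
        st = dict(zip(internal, assign))
        for n in nodes:
            if n.is_leaf():
                st[n] = states[n.taxon.label]
        changes = sum(
            st[n] != st[n.parent_node] for n in nodes if n.parent_node is not None
        )
        best = min(best, changes)
    return best


def brute_likelihood(phy, states, k, alpha):
    nodes = list(phy.tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        st = dict(zip(internal, assign))
        for n in nodes:
            if n.is_leaf():
                st[n] = states[n.taxon.label]
        p = 1.0 / k
        for n in nodes:
            if n.parent_node is not None:
                P = anc.mk1_transition(alpha, k, n.edge.length or 0.0)
                p *= P[st[n.parent_node], st[n]]
        total += p
    return total


def brute_marginals(phy, states, k, alpha):
    nodes = list(phy.tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    post = {n: np.zeros(k) for n in internal}
    for assign in itertools.product(range(k), repeat=len(internal)):
        st = dict(zip(internal, assign))
        for n in nodes:
            if n.is_leaf():
                st[n] = states[n.taxon.label]
        p = 1.0 / k
        for n in nodes:
            if n.parent_node is not None:
                P = anc.mk1_transition(alpha, k, n.edge.length or 0.0)
                p *= P[st[n.parent_node], st[n]]
        for n in internal:
            post[n][st[n]] += p
    return {n: v / v.sum() for n, v in post.items()}


# ---------------------------------------------------------------------------
# parsimony
# ---------------------------------------------------------------------------

class TestFitchParsimony:
    def test_identical_cherry_no_change(self):
        phy = tree_from_newick("(A:1,B:1);")
        rec = anc.fitch_parsimony(
            phy, anc.CharacterData(states={"A": 0, "B": 0}, k=2)
        )
        assert rec.score == 0

    def test_opposite_cherry_one_change(self):
        phy = tree_from_newick("(A:1,B:1);")
        rec = anc.fitch_parsimony(
            phy, anc.CharacterData(states={"A": 0, "B": 1}, k=2)
        )
        assert rec.score == 1

    def test_four_tip_root_set(self):
        phy = tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rec = anc.fitch_parsimony(
            phy, anc.CharacterData(states={"A": 0, "B": 1, "C": 1, "D": 1}, k=2)
        )
        assert rec.score == 1
        root_id = [i for i, s in rec.node_sets.items() if i.startswith("N")][0]
        # root optimal set is {1}: placing 0 at the root costs 2
        assert rec.node_sets["N0"] == frozenset({1})

    def test_missing_tip_state_names_tip(self):
        phy = tree_from_newick("(A:1,B:1);")
        with pytest.raises(ValueError, match="B"):
            anc.fitch_parsimony(phy, anc.CharacterData(states={"A": 0}, k=2))

    def test_matches_brute_force_on_random_trees(self):
        for seed in range(30):
            r = np.random.default_rng(seed)
            n = int(r.integers(3, 7))
            k = int(r.integers(2, 4))
            phy, tips, _ = sd.gen_tree_with_states(n, k, 1.0, seed=seed)
            rec = anc.fitch_parsimony(phy, anc.CharacterData(states=tips, k=k))
            assert rec.score == brute_parsimony_score(phy, tips, k)
            # the returned labeling realises the optimal score
            ids = anc._node_ids(phy)
            changes = sum(
                rec.labeling[ids[nd]] != rec.labeling[ids[nd.parent_node]]
                for nd in phy.tree.preorder_node_iter()
                if nd.parent_node is not None
            )
            assert changes == rec.score

    def test_score_bounds(self, rng):
        phy, tips, _ = sd.gen_tree_with_states(12, 3, 2.0, seed=99)
        rec = anc.fitch_parsimony(phy, anc.CharacterData(states=tips, k=3))
        assert rec.score <= 11
        if len(set(tips.values())) == 1:
            assert rec.score == 0


class TestMk1Transition:
    def test_zero_time_identity(self):
        np.testing.assert_allclose(anc.mk1_transition(1.0, 3, 0.0), np.eye(3))

    def test_long_time_stationary(self):
        P = anc.mk1_transition(1.0, 2, 1e6)
        np.testing.assert_allclose(P, np.full((2, 2), 0.5), atol=1e-12)

    def test_closed_form_value(self):
        P = anc.mk1_transition(1.0, 2, 0.5)
        assert P[0, 0] == pytest.approx(0.5 + 0.5 * math.exp(-1.0))

    def test_rows_sum_to_one(self):
        for k in (2, 3):
            P = anc.mk1_transition(0.7, k, 1.3)
            np.testing.assert_allclose(P.sum(axis=1), np.ones(k))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            anc.mk1_transition(1.0, 2, -0.1)


class TestMk1Likelihood:
    def test_stationary_cherry(self):
        phy = tree_from_newick("(A:1e7,B:1e7);")
        ll = anc.mk1_loglik(
            phy, anc.CharacterData(states={"A": 0, "B": 1}, k=2), 1.0
        )
        assert ll == pytest.approx(math.log(0.25), abs=1e-6)

    def test_tiny_rate_monomorphic_tips(self):
        phy = tree_from_newick("((A:1,B:1):1,C:2);")
        ll = anc.mk1_loglik(
            phy, anc.CharacterData(states={"A": 0, "B": 0, "C": 0}, k=2), 1e-9
        )
        assert ll == pytest.approx(math.log(0.5), abs=1e-6)

    def test_pruning_equals_brute_force(self):
        """Felsenstein pruning vs sum over all ancestral assignments."""
        for seed in range(100):
            r = np.random.default_rng(seed)
            n = int(r.integers(3, 7))
            k = int(r.integers(2, 4))
            alpha = float(r.uniform(0.05, 3.0))
            phy, tips, _ = sd.gen_tree_with_states(n, k, alpha, seed=seed + 1)
            data = anc.CharacterData(states=tips, k=k)
            ll = anc.mk1_loglik(phy, data, alpha)
            assert ll == pytest.approx(
                math.log(brute_likelihood(phy, tips, k, alpha)), abs=1e-10
            )

    def test_invalid_alpha_rejected(self):
        phy = tree_from_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            anc.mk1_loglik(phy, anc.CharacterData(states={"A": 0, "B": 1}, k=2), 0.0)


class TestMarginalStates:
    def test_symmetric_cherry_uniform_root(self):
        phy = tree_from_newick("(A:1,B:1);")
        rec = anc.marginal_states(
            phy, anc.CharacterData(states={"A": 0, "B": 1}, k=2), 1.0
        )
        np.testing.assert_allclose(rec.node_probs["N0"], [0.5, 0.5], atol=1e-12)

    def test_low_rate_ancestors_follow_tips(self):
        phy = tree_from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rec = anc.marginal_states(
            phy,
            anc.CharacterData(states={"A": 0, "B": 0, "C": 0, "D": 0}, k=2),
            1e-6,
        )
        for node, probs in rec.node_probs.items():
            assert probs[0] > 0.999

    def test_matches_brute_force_conditionals(self):
        for seed in range(40):
            r = np.random.default_rng(seed)
            n = int(r.integers(3, 6))
            k = int(r.integers(2, 4))
            alpha = float(r.uniform(0.1, 2.0))
            phy, tips, _ = sd.gen_tree_with_states(n, k, alpha, seed=seed + 2)
            data = anc.CharacterData(states=tips, k=k)
            rec = anc.marginal_states(phy, data, alpha)
            ids = anc._node_ids(phy)
            ref = brute_marginals(phy, tips, k, alpha)
            for node, probs in ref.items():
                np.testing.assert_allclose(
                    rec.node_probs[ids[node]], probs, atol=1e-10
                )

    def test_probabilities_sum_to_one(self):
        phy, tips, _ = sd.gen_tree_with_states(20, 3, 0.8, seed=5)
        rec = anc.marginal_states(phy, anc.CharacterData(states=tips, k=3), 0.8)
        for probs in rec.node_probs.values():
            assert probs.sum() == pytest.approx(1.0, abs=1e-9)


class TestMk1Fit:
    def test_monomorphic_boundary_flagged(self):
        phy = tree_from_newick("((A:1,B:1):1,C:2);")
        rec = anc.mk1_fit(
            phy, anc.CharacterData(states={"A": 1, "B": 1, "C": 1}, k=2)
        )
        assert rec.boundary_fit

    def test_fit_is_local_optimum(self):
        phy, tips, _ = sd.gen_tree_with_states(30, 2, 0.5, seed=8)
        data = anc.CharacterData(states=tips, k=2)
        rec = anc.mk1_fit(phy, data)
        ll_hat = anc.mk1_loglik(phy, data, rec.alpha)
        for trial in (rec.alpha * 0.8, rec.alpha * 1.25, 0.01, 1.5):
            assert ll_hat >= anc.mk1_loglik(phy, data, trial) - 1e-9
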