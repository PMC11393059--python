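"""Ancestral lifestyle-state reconstruction on a species tree.

Two reconstruction routes over k discrete, unordered states:

* unordered parsimony (unit-cost Sankoff, which generalises Fitch to
  multifurcating trees and yields per-node optimal state sets), and
* the Mk1 model — a continuous-time Markov chain with one symmetric rate
  ``alpha`` between every ordered state pair, whose transition probabilities
  on a branch of length ``t`` have the closed form

      P_same(t) = 1/k + (k-1)/k * exp(-k * alpha * t)
      P_diff(t) = 1/k - 1/k   * exp(-k * alpha * t)

  with a uniform (stationary) root prior. The tree likelihood is computed
  with Felsenstein's pruning recursion, the single rate is fitted by bounded
  1-D maximisation, and per-node marginal posteriors come from the combined
  downward/upward passes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .formats_io import Phylogeny

logger = logging.getLogger(__name__)


@dataclass
class CharacterData:
    """Tip label -> state index in {0..k-1}."""

    states: dict[str, int]
    k: int
    state_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        bad = {t: s for t, s in self.states.items() if not 0 <= s < self.k}
        if bad:
            raise ValueError(f"state indices out of range for k={self.k}: {bad}")
        if not self.state_names:
            self.state_names = tuple(f"state{i}" for i in range(self.k))


@dataclass
class Reconstruction:
    """Per-node reconstruction: marginal probabilities (likelihood) or
    optimal state sets (parsimony), plus the global score."""

    method: str
    node_probs: dict[str, np.ndarray] = field(default_factory=dict)
    node_sets: dict[str, frozenset[int]] = field(default_factory=dict)
    labeling: dict[str, int] = field(default_factory=dict)
    score: float = math.nan  # parsimony score or log-likelihood
    alpha: float = math.nan
    boundary_fit: bool = False


def _node_ids(phy: Phylogeny) -> dict:
    """Stable node identifiers: tip = taxon label, internal = label or N<i>."""
    ids = {}
    i = 0
    for node in phy.tree.preorder_node_iter():
        if node.is_leaf():
            ids[node] = node.taxon.label
        elif node.label:
            ids[node] = node.label
        else:
            ids[node] = f"N{i}"
            i += 1
    return ids


def _check_tips(phy: Phylogeny, data: CharacterData) -> None:
    missing = [t for t in phy.tip_labels if t not in data.states]
    if missing:
        raise ValueError(f"tip(s) missing a character state: {missing}")


# ---------------------------------------------------------------------------
# parsimony
# ---------------------------------------------------------------------------

def fitch_parsimony(phy: Phylogeny, data: CharacterData) -> Reconstruction:
    """Minimum-change reconstruction of an unordered character.

    Unit-cost Sankoff dynamic programming with a full up-pass, so the
    reported per-node sets contain exactly the states attainable in *some*
    globally optimal labeling, on binary and multifurcating trees alike.
    """
    _check_tips(phy, data)
    k = data.k
    ids = _node_ids(phy)
    inf = math.inf

    down: dict = {}
    for node in phy.tree.postorder_node_iter():
        if node.is_leaf():
            v = np.full(k, inf)
            v[data.states[ids[node]]] = 0.0
        else:
            # cost of each child subtree given parent state s:
            # min over the child's state of down[child] + 1{change}
            v = np.zeros(k)
            for child in node.child_nodes():
                c = down[child]
                v += np.minimum(c, c.min() + 1.0)
        down[node] = v

    root = phy.tree.seed_node
    score = float(down[root].min())

    # up-pass: cost of the rest of the tree given each state at a node
    up: dict = {root: np.zeros(k)}
    for node in phy.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        for child in node.child_nodes():
            sib_sum = np.zeros(k)
            for sib in node.child_nodes():
                if sib is child:
                    continue
                c = down[sib]
                sib_sum += np.minimum(c, c.min() + 1.0)
            base = up[node] + sib_sum  # cost above, indexed by parent state
            up[child] = np.minimum(base, base.min() + 1.0)

    recon = Reconstruction(method="parsimony", score=score)
    for node in phy.tree.postorder_node_iter():
        total = down[node] + up[node]
        recon.node_sets[ids[node]] = frozenset(np.flatnonzero(total == total.min()))

    # one optimal labeling: choose the smallest optimal state root-down
    choice: dict = {}
    for node in phy.tree.preorder_node_iter():
        if node.parent_node is None:
            choice[node] = int(down[node].argmin())
        else:
            c = down[node]
            parent_state = choice[node.parent_node]
            cand = c + (np.arange(k) != parent_state)
            choice[node] = int(cand.argmin())
        recon.labeling[ids[node]] = choice[node]
    return recon


# ---------------------------------------------------------------------------
# Mk1 likelihood
# ---------------------------------------------------------------------------

def mk1_transition(alpha: float, k: int, t: float) -> np.ndarray:
    """Closed-form Mk1 transition matrix for a branch of length ``t``."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    if alpha < 0:
        raise ValueError("rate must be non-negative")
    e = math.exp(-k * alpha * t)
    same = 1.0 / k + (k - 1.0) / k * e
    diff = 1.0 / k - 1.0 / k * e
    P = np.full((k, k), diff)
    np.fill_diagonal(P, same)
    return P


def _pruning(phy: Phylogeny, data: CharacterData, alpha: float):
    """Scaled partial likelihoods; returns (down, log_scale, ids)."""
    k = data.k
    ids = _node_ids(phy)
    down: dict = {}
    log_scale = 0.0
    for node in phy.tree.postorder_node_iter():
        if node.is_leaf():
            v = np.zeros(k)
            v[data.states[ids[node]]] = 1.0
        else:
            v = np.ones(k)
            for child in node.child_nodes():
                P = mk1_transition(alpha, k, child.edge.length or 0.0)
                v *= P @ down[child]
            m = v.max()
            if m <= 0:
                raise FloatingPointError("zero partial likelihood")
            v = v / m
            log_scale += math.log(m)
        down[node] = v
    return down, log_scale, ids


def mk1_loglik(phy: Phylogeny, data: CharacterData, alpha: float) -> float:
    """Log-likelihood of tip states under Mk1 with a uniform root prior."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    _check_tips(phy, data)
    down, log_scale, _ = _pruning(phy, data, alpha)
    root = phy.tree.seed_node
    lik = float(np.mean(down[root]))  # uniform prior 1/k
    return math.log(lik) + log_scale


def mk1_fit(
    phy: Phylogeny, data: CharacterData, alpha_max: "float | None" = None
) -> Reconstruction:
    """Maximum-likelihood estimate of the single Mk1 rate.

    Bounded scalar search on [1e-8, alpha_max] (default 100 / tree height);
    a monomorphic character drives the estimate to the lower bound, which is
    reported with ``boundary_fit=True``.
    """
    _check_tips(phy, data)
    observed = {data.states[t] for t in phy.tip_labels}
    height = phy.height()
    if alpha_max is None:
        alpha_max = 100.0 / height if height > 0 else 100.0
    lo = 1e-8
    if len(observed) < 2:
        ll = mk1_loglik(phy, data, lo)
        logger.info("mk1_fit: monomorphic tips, boundary fit at alpha=%g", lo)
        return Reconstruction(
            method="mk1", score=ll, alpha=lo, boundary_fit=True
        )
    res = minimize_scalar(
        lambda a: -mk1_loglik(phy, data, a),
        bounds=(lo, alpha_max),
        method="bounded",
        options={"xatol": 1e-8},
    )
    alpha = float(res.x)
    boundary = alpha <= lo * 10 or alpha >= alpha_max * 0.999
    logger.info("mk1_fit: alpha=%g loglik=%g boundary=%s", alpha, -res.fun, boundary)
    return Reconstruction(
        method="mk1", score=float(-res.fun), alpha=alpha, boundary_fit=boundary
    )


def marginal_states(phy: Phylogeny, data: CharacterData, alpha: float) -> Reconstruction:
    """Marginal posterior state probabilities at every node under Mk1.

    Downward (pruning) and upward passes are combined so each node's
    probabilities condition on *all* tip states; probabilities sum to 1 and
    the most probable state labels the node.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    _check_tips(phy, data)
    k = data.k
    down, log_scale, ids = _pruning(phy, data, alpha)
    ll = mk1_loglik(phy, data, alpha)

    root = phy.tree.seed_node
    prior = np.full(k, 1.0 / k)
    up: dict = {root: prior.copy()}
    for node in phy.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        # messages from each child into the parent, indexed by parent state
        child_msgs = {}
        for child in node.child_nodes():
            P = mk1_transition(alpha, k, child.edge.length or 0.0)
            child_msgs[child] = (P, P @ down[child])
        for child in node.child_nodes():
            out = up[node].copy()
            for sib in node.child_nodes():
                if sib is not child:
                    out = out * child_msgs[sib][1]
            P = child_msgs[child][0]
            v = out @ P  # sum over parent states
            m = v.max()
            up[child] = v / m if m > 0 else v

    recon = Reconstruction(method="mk1", score=ll, alpha=alpha)
    for node in phy.tree.postorder_node_iter():
        post = up[node] * down[node]
        post = post / post.sum()
        recon.node_probs[ids[node]] = post
        recon.labeling[ids[node]] = int(post.argmax())
    return recon


def lifestyle_character(
    meta, binary: bool = False
) -> CharacterData:
    """Build a CharacterData from a metadata table's lifestyle column.

    Ternary by default; ``binary=True`` merges thermotolerant into the
    mesophilic state (the treatment the classifier uses).
    """
    if binary:
        names = ("mesophilic", "thermophilic")
        mapping = {"mesophilic": 0, "thermotolerant": 0, "thermophilic": 1}
        k = 2
    else:
        names = ("mesophilic", "thermophilic", "thermotolerant")
        mapping = {n: i for i, n in enumerate(names)}
        k = 3
    states = {g: mapping[ls] for g, ls in meta["lifestyle"].items()}
    return CharacterData(states=states, k=k, state_names=names)
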