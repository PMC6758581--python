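"""Equal-rates Mk model: pruning likelihood, ML rate, marginal ancestral
states, and painting of selective regimes onto branches.

The discrete pollination syndrome is modelled as a k-state continuous-time
Markov chain with a single transition rate q between every ordered pair of
states (the "ER" model).  Transition probabilities have the closed form

    P_ii(t) = 1/k + (k-1)/k * exp(-k q t)
    P_ij(t) = 1/k - 1/k   * exp(-k q t)   (i != j)

The root state carries a uniform prior.  Ancestral states are marginal
reconstructions; every node is then assigned its most probable state and
each branch inherits the state of its tipward endpoint, producing one
regime per branch for the multi-optimum OU machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .phylo import Phylogeny
from .traits import SyndromeMap, SYNDROME_ORDER

logger = logging.getLogger(__name__)

__all__ = ["MkFit", "RegimePainting", "mk_loglik", "fit_mk_er",
           "marginal_asr", "paint_branches", "paint_from_syndromes"]


@dataclass(frozen=True)
class MkFit:
    rate: float
    loglik: float
    n_states: int
    monomorphic: bool = False


@dataclass(frozen=True)
class RegimePainting:
    """One regime per branch (keyed by the branch's child node id)."""

    branch_regime: dict[int, str]
    root_regime: str
    node_probabilities: pd.DataFrame | None = None
    states: tuple[str, ...] = field(default_factory=tuple)

    def regimes_present(self) -> list[str]:
        present = set(self.branch_regime.values()) | {self.root_regime}
        ordered = [s for s in self.states if s in present]
        return ordered + sorted(present - set(self.states))


def _er_transition(k: int, q: float, t: float) -> tuple[float, float]:
    """(P_same, P_diff) under the ER chain."""
    e = np.exp(-k * q * t)
    return 1.0 / k + (k - 1.0) / k * e, 1.0 / k - e / k


def _tip_state_indices(tree: Phylogeny, tip_states, states: list[str]) -> np.ndarray:
    if isinstance(tip_states, SyndromeMap):
        tip_states = tip_states.values
    sidx = {s: i for i, s in enumerate(states)}
    out = np.empty(tree.n_tips, dtype=np.int64)
    for i, lbl in enumerate(tree.tip_labels):
        if lbl not in tip_states:
            raise ValueError(f"tip {lbl!r} has no state")
        st = tip_states[lbl]
        if st not in sidx:
            raise ValueError(f"state {st!r} not in state list {states}")
        out[i] = sidx[st]
    return out


def _resolve_states(tip_states, states) -> list[str]:
    if states is not None:
        return list(states)
    if isinstance(tip_states, SyndromeMap):
        return list(SYNDROME_ORDER)
    observed = set(tip_states.values())
    return [s for s in SYNDROME_ORDER if s in observed] or sorted(observed)


def _pruning(tree: Phylogeny, tips_idx: np.ndarray, k: int, q: float):
    """Postorder conditional likelihoods; returns (L, log_scale) per node."""
    L = np.zeros((tree.n_nodes, k))
    logscale = np.zeros(tree.n_nodes)
    for v in tree.postorder:
        if v < tree.n_tips:
            L[v, tips_idx[v]] = 1.0
        else:
            L[v, :] = 1.0
            for c in tree.children[v]:
                ps, pd_ = _er_transition(k, q, tree.edge_length[c])
                # message from child c: sum_j P(i->j) L[c, j]
                tot = L[c].sum()
                msg = pd_ * tot + (ps - pd_) * L[c]
                L[v, :] *= msg
                logscale[v] += logscale[c]
            m = L[v].max()
            if m <= 0:
                raise FloatingPointError("zero likelihood in pruning")
            L[v] /= m
            logscale[v] += np.log(m)
    return L, logscale


def mk_loglik(tree: Phylogeny, tip_states, rate: float, states=None) -> float:
    """Log-likelihood of discrete tip states under the ER Mk model.

    Uses Felsenstein pruning with a uniform root prior over ``states``
    (defaults to the five syndromes for a :class:`SyndromeMap`, otherwise
    the observed states).
    """
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    states = _resolve_states(tip_states, states)
    k = len(states)
    tips_idx = _tip_state_indices(tree, tip_states, states)
    L, logscale = _pruning(tree, tips_idx, k, rate)
    r = tree.root
    return float(np.log(L[r].sum() / k) + logscale[r])


def fit_mk_er(tree: Phylogeny, tip_states, states=None) -> MkFit:
    """ML estimate of the single ER transition rate by bounded 1-D search."""
    states = _resolve_states(tip_states, states)
    k = len(states)
    tips_idx = _tip_state_indices(tree, tip_states, states)
    if len(np.unique(tips_idx)) < 2:
        logger.warning("monomorphic tip states: ER rate not identifiable, returning 0")
        return MkFit(0.0, float(np.log(1.0 / k)), k, monomorphic=True)
    T = tree.crown_age

    def nll(logq: float) -> float:
        return -mk_loglik(tree, tip_states, np.exp(logq), states)

    lo, hi = np.log(1e-8 / T), np.log(1e3 / T)
    grid = np.linspace(lo, hi, 25)
    vals = [nll(g) for g in grid]
    g0 = grid[int(np.argmin(vals))]
    res = minimize_scalar(nll, bounds=(max(lo, g0 - 1.5), min(hi, g0 + 1.5)),
                          method="bounded", options={"xatol": 1e-10})
    best = res.x if res.fun <= min(vals) else g0
    q = float(np.exp(best))
    return MkFit(q, mk_loglik(tree, tip_states, q, states), k)


def marginal_asr(tree: Phylogeny, tip_states, rate: float, states=None) -> pd.DataFrame:
    """Marginal posterior state probabilities for every node.

    Down messages come from pruning; up messages are propagated preorder,
    combining the parent's up message with the sibling subtrees.  Rows sum
    to one; tip rows are point masses on the observed states.
    """
    states = _resolve_states(tip_states, states)
    k = len(states)
    tips_idx = _tip_state_indices(tree, tip_states, states)
    L, _ = _pruning(tree, tips_idx, k, rate)

    up = np.zeros((tree.n_nodes, k))
    up[tree.root] = 1.0 / k
    for v in tree.preorder:
        for c in tree.children[v]:
            # combine parent's up message with messages from c's siblings
            part = up[v].copy()
            for b in tree.children[v]:
                if b == c:
                    continue
                ps, pd_ = _er_transition(k, rate, tree.edge_length[b])
                part *= pd_ * L[b].sum() + (ps - pd_) * L[b]
            ps, pd_ = _er_transition(k, rate, tree.edge_length[c])
            up[c] = pd_ * part.sum() + (ps - pd_) * part
            m = up[c].max()
            if m > 0:
                up[c] /= m
    post = up * L
    post /= post.sum(axis=1, keepdims=True)
    return pd.DataFrame(post, columns=states)


def paint_branches(tree: Phylogeny, node_probabilities: pd.DataFrame,
                   tip_states, states=None) -> RegimePainting:
    """Assign each node its most probable state and each branch the state of
    its tipward endpoint (terminal branches use the observed tip state).

    Argmax ties break deterministically toward the lowest state index.
    """
    states = list(node_probabilities.columns)
    if isinstance(tip_states, SyndromeMap):
        tip_states = tip_states.values
    probs = node_probabilities.to_numpy()
    node_state = {}
    for v in range(tree.n_nodes):
        if v < tree.n_tips:
            node_state[v] = tip_states[tree.tip_labels[v]]
        else:
            row = probs[v]
            best = int(np.argmax(row))  # np.argmax returns the first (lowest) index on ties
            if np.sum(np.isclose(row, row[best])) > 1:
                logger.info("argmax tie at node %d; using state %s", v, states[best])
            node_state[v] = states[best]
    branch_regime = {v: node_state[v] for v in range(tree.n_nodes) if v != tree.root}
    branch_regime[tree.root] = node_state[tree.root]  # root stem
    return RegimePainting(
        branch_regime=branch_regime,
        root_regime=node_state[tree.root],
        node_probabilities=node_probabilities,
        states=tuple(states),
    )


def paint_from_syndromes(tree: Phylogeny, syndromes: SyndromeMap) -> tuple[RegimePainting, MkFit]:
    """Full regime reconstruction: fit the ER rate, run marginal ASR, paint."""
    sub = syndromes.subset(tree.tip_labels)
    fit = fit_mk_er(tree, sub)
    probs = marginal_asr(tree, sub, fit.rate)
    return paint_branches(tree, probs, sub), fit
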