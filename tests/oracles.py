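"""Independent brute-force oracles used by the test suite.

Every routine here deliberately avoids the package's fast paths: discrete
likelihoods come from matrix exponentials and exhaustive enumeration over
internal-node states; OU means and covariances come from numerical
integration along root-to-tip paths; shared path lengths come from explicit
edge-set intersections.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.stats import multivariate_normal


# ----------------------------------------------------------------------
# Mk by matrix exponential + enumeration
# ----------------------------------------------------------------------
def er_rate_matrix(k: int, q: float) -> np.ndarray:
    Q = np.full((k, k), q)
    np.fill_diagonal(Q, -(k - 1) * q)
    return Q


def mk_loglik_enum(tree, tip_states, rate: float, states) -> float:
    """Exhaustive sum over internal-node state assignments (uniform root)."""
    k = len(states)
    sidx = {s: i for i, s in enumerate(states)}
    tips = {i: sidx[tip_states[lbl]] for i, lbl in enumerate(tree.tip_labels)}
    internal = [v for v in range(tree.n_nodes) if v >= tree.n_tips]
    P = {v: expm(er_rate_matrix(k, rate) * tree.edge_length[v])
         for v in range(tree.n_nodes)}
    total = 0.0
    for combo in itertools.product(range(k), repeat=len(internal)):
        st = dict(zip(internal, combo))
        st.update(tips)
        prob = 1.0 / k
        for v in range(tree.n_nodes):
            p = int(tree.parent[v])
            if p >= 0:
                prob *= P[v][st[p], st[v]]
        total += prob
    return float(np.log(total))


def marginal_enum(tree, tip_states, rate: float, states) -> np.ndarray:
    """Enumeration-based marginal state posteriors for every node."""
    k = len(states)
    sidx = {s: i for i, s in enumerate(states)}
    tips = {i: sidx[tip_states[lbl]] for i, lbl in enumerate(tree.tip_labels)}
    internal = [v for v in range(tree.n_nodes) if v >= tree.n_tips]
    P = {v: expm(er_rate_matrix(k, rate) * tree.edge_length[v])
         for v in range(tree.n_nodes)}
    post = np.zeros((tree.n_nodes, k))
    for combo in itertools.product(range(k), repeat=len(internal)):
        st = dict(zip(internal, combo))
        st.update(tips)
        prob = 1.0 / k
        for v in range(tree.n_nodes):
            p = int(tree.parent[v])
            if p >= 0:
                prob *= P[v][st[p], st[v]]
        for v in range(tree.n_nodes):
            post[v, st[v]] += prob
    return post / post.sum(axis=1, keepdims=True)


# ----------------------------------------------------------------------
# dense multivariate-normal likelihoods by path walking / integration
# ----------------------------------------------------------------------
def _path_edges(tree, tip: int) -> list[int]:
    path = []
    v = tip
    while int(tree.parent[v]) >= 0:
        path.append(v)
        v = int(tree.parent[v])
    return path


def shared_lengths(tree) -> np.ndarray:
    """C_ij by explicit intersection of root-to-tip edge sets."""
    n = tree.n_tips
    paths = [set(_path_edges(tree, i)) for i in range(n)]
    C = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            common = paths[i] & paths[j]
            C[i, j] = sum(tree.edge_length[v] for v in common)
    return C


def dense_loglik(tree, y, name, params, painting=None) -> float:
    """Reference log-density for any of the six models."""
    n = tree.n_tips
    C = shared_lengths(tree)
    if name == "WN":
        mean = np.full(n, params["mu"])
        V = params["s2"] * np.eye(n)
    elif name == "BM.s":
        mean = np.full(n, params["z0"])
        V = params["sigma2"] * C
    elif name == "Lambda":
        V = params["sigma2"] * params["lam"] * C
        np.fill_diagonal(V, params["sigma2"] * np.diag(C))
        mean = np.full(n, params["z0"])
    elif name == "BM.rate":
        s2r = params["sigma2_by_regime"]
        paths = [set(_path_edges(tree, i)) for i in range(n)]
        V = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                for v in (paths[i] & paths[j]):
                    V[i, j] += s2r[painting.branch_regime[v]] * tree.edge_length[v]
        mean = np.full(n, params["z0"])
    elif name in ("OU.s", "OU.poll"):
        alpha = params["alpha"]
        depths = {v: None for v in range(tree.n_nodes)}
        d = np.zeros(tree.n_nodes)
        for v in tree.preorder:
            p = int(tree.parent[v])
            d[v] = (d[p] if p >= 0 else 0.0) + (tree.edge_length[v] if p >= 0 else 0.0)
        V = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                s_ij = shared_lengths(tree)[i, j]
                # integrate sigma^2 e^{-a(Ti-t)} e^{-a(Tj-t)} over shared time
                f = lambda t: np.exp(-alpha * (d[i] - t)) * np.exp(-alpha * (d[j] - t))
                V[i, j] = params["sigma2"] * quad(f, 0.0, s_ij)[0]
        if name == "OU.s":
            mean = np.full(n, float(params["theta"]))
        else:
            theta = params["theta"]
            regimes = list(theta.index)
            th = {r: float(theta[r]) for r in regimes}
            mean = np.zeros(n)
            for i in range(n):
                Ti = d[i]
                w = {r: 0.0 for r in regimes}
                w[painting.root_regime] += np.exp(-alpha * Ti)
                for v in reversed(_path_edges(tree, i)):
                    p = int(tree.parent[v])
                    t0, t1 = d[p], d[v]
                    g = lambda t: alpha * np.exp(-alpha * (Ti - t))
                    w[painting.branch_regime[v]] += quad(g, t0, t1)[0]
                mean[i] = sum(w[r] * th[r] for r in regimes)
    else:
        raise ValueError(name)
    return float(multivariate_normal(mean=mean, cov=V, allow_singular=True).logpdf(y))
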