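"""Synthetic trees, regime histories and trait data.

Everything downstream of the field data — regime reconstruction, the
six-model comparison, PGLS, the multivariate nectar-syndrome stage — is
exercised on data from this module: an age-conditioned Yule tree, a
pollination syndrome evolving as an equal-rates Markov chain, and
continuous traits simulated under any of the six candidate models.
``generate_study_like_dataset`` bundles these into a 57-species dataset
whose sample sizes, trait ranges and OU parameter magnitudes emulate the
Balsaminaceae study design.

All generators are pure functions of their inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .phylo import Phylogeny
from .regimes import RegimePainting
from .traits import (SYNDROME_ORDER, SyndromeMap, TraitVector, transform,
                     write_trait_table)

__all__ = [
    "SimulationConfig", "MkHistory", "simulate_yule_tree",
    "simulate_mk_regimes", "simulate_trait", "generate_study_like_dataset",
    "StudyBundle",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Bundle of generator settings (used by the CLI ``simulate`` command)."""

    n_tips: int = 57
    crown_age: float = 22.0
    regime_states: tuple[str, ...] = SYNDROME_ORDER
    mk_rate: float = 0.02
    model: str = "OU.poll"
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.crown_age <= 0:
            raise ValueError("crown_age must be positive")
        if self.mk_rate < 0:
            raise ValueError("mk_rate must be nonnegative")


# ----------------------------------------------------------------------
# Yule trees conditioned on tip count and crown age
# ----------------------------------------------------------------------
def simulate_yule_tree(n_tips: int, crown_age: float, seed: int,
                       birth_rate: float | None = None) -> Phylogeny:
    """Pure-birth tree with exactly ``n_tips`` tips and the requested crown age.

    Uses the age-conditioned construction: besides the crown split at the
    root, the remaining n−2 node depths are iid with CDF
    F(t) = (e^{λt} − 1)/(e^{λT} − 1) on [0, T] measured from the root, and
    the topology follows from joining uniformly chosen lineage pairs
    backward in time.  ``birth_rate`` defaults to ln(n/2)/T, the rate whose
    expected tip count at T equals n.  Trees are exactly ultrametric by
    construction.
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    if crown_age <= 0:
        raise ValueError("crown_age must be positive")
    rng = np.random.default_rng(seed)
    T = float(crown_age)
    if birth_rate is None:
        birth_rate = np.log(n_tips / 2.0) / T if n_tips > 2 else 0.0
    u = rng.random(max(n_tips - 2, 0))
    if birth_rate > 1e-12:
        depths = np.log1p(u * np.expm1(birth_rate * T)) / birth_rate
    else:  # λ → 0 limit: uniform depths
        depths = u * T
    node_depth = np.sort(depths)[::-1]  # shallowest split merges last... deepest first

    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    depth = np.empty(n_nodes)
    depth[:n_tips] = T
    # merge backward from the present: deepest-from-root node merges last,
    # so process node depths in decreasing order (closest to the tips first)
    lineages = list(range(n_tips))
    merge_depths = list(node_depth) + [0.0]  # crown split at depth 0
    for j, d in enumerate(merge_depths):
        v = n_tips + j
        depth[v] = d
        a = lineages.pop(int(rng.integers(len(lineages))))
        b = lineages.pop(int(rng.integers(len(lineages))))
        parent[a] = v
        parent[b] = v
        lineages.append(v)
    edge_length = np.zeros(n_nodes)
    for v in range(n_nodes):
        if parent[v] >= 0:
            edge_length[v] = depth[v] - depth[parent[v]]
    labels = [f"sp{i + 1:02d}" for i in range(n_tips)]
    return Phylogeny(parent, edge_length, labels)


# ----------------------------------------------------------------------
# Mk regime histories
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class MkHistory:
    """Full jump history of a simulated discrete character.

    ``branch_segments[v]`` lists ``(duration, state)`` pieces along the
    branch ending at node ``v``, ordered parent → child; ``node_states``
    records the state at every node.
    """

    tip_states: dict[str, str]
    node_states: dict[int, str]
    branch_segments: dict[int, list[tuple[float, str]]]
    states: tuple[str, ...]
    root_state: str

    def syndrome_map(self) -> SyndromeMap:
        return SyndromeMap(dict(self.tip_states))

    def painting(self, tree: Phylogeny) -> RegimePainting:
        """Collapse to one regime per branch (the tipward endpoint's state)."""
        br = {v: self.node_states[v] for v in range(tree.n_nodes)}
        return RegimePainting(branch_regime=br,
                              root_regime=self.node_states[tree.root],
                              states=self.states)


def simulate_mk_regimes(tree: Phylogeny, states, mk_rate: float,
                        root_state: str, seed: int) -> MkHistory:
    """Evolve a discrete state along the tree under the ER Mk process.

    Jumps leave the current state at total rate (k−1)·q and land uniformly
    on the other states.  The full within-branch jump history is retained.
    """
    states = tuple(states)
    if root_state not in states:
        raise ValueError(f"root_state {root_state!r} not in states")
    if mk_rate < 0:
        raise ValueError("mk_rate must be nonnegative")
    rng = np.random.default_rng(seed)
    k = len(states)
    leave = (k - 1) * mk_rate
    node_states = {tree.root: root_state}
    segments: dict[int, list[tuple[float, str]]] = {}
    for v in tree.preorder:
        if v == tree.root:
            continue
        s = node_states[int(tree.parent[v])]
        t_left = float(tree.edge_length[v])
        segs: list[tuple[float, str]] = []
        while leave > 0:
            w = rng.exponential(1.0 / leave)
            if w >= t_left:
                break
            segs.append((w, s))
            others = [x for x in states if x != s]
            s = others[int(rng.integers(k - 1))]
            t_left -= w
        segs.append((t_left, s))
        segments[v] = segs
        node_states[v] = s
    tips = {tree.tip_labels[i]: node_states[i] for i in range(tree.n_tips)}
    return MkHistory(tip_states=tips, node_states=node_states,
                     branch_segments=segments, states=states,
                     root_state=root_state)


# ----------------------------------------------------------------------
# continuous trait simulation
# ----------------------------------------------------------------------
def _branch_segments(tree: Phylogeny, painting, v: int) -> list[tuple[float, str]]:
    if isinstance(painting, MkHistory):
        return painting.branch_segments[v]
    if painting is None:
        return [(float(tree.edge_length[v]), "")]
    return [(float(tree.edge_length[v]), painting.branch_regime[v])]


def simulate_trait(tree: Phylogeny, painting, name: str, params: dict,
                   seed: int) -> TraitVector:
    """Simulate tip values under one of the six models.

    ``painting`` may be a :class:`RegimePainting` (one regime per branch),
    an :class:`MkHistory` (within-branch regime changes are honoured), or
    None for regime-free models.  OU branches are simulated segment-wise:
    over a segment of duration t in regime r,

        x' | x ~ Normal(θ_r + (x − θ_r)·e^{−αt}, σ²(1 − e^{−2αt})/(2α)).
    """
    rng = np.random.default_rng(seed)
    n = tree.n_tips

    if name == "WN":
        vals = rng.normal(params["mu"], np.sqrt(params["s2"]), size=n)
        return TraitVector(pd.Series(vals, index=tree.tip_labels))

    if name == "Lambda":
        lam = params["lam"]
        tlam = tree.with_lambda(lam)
        return simulate_trait(tlam, None, "BM.s",
                              {"z0": params["z0"], "sigma2": params["sigma2"]},
                              seed)

    x = np.empty(tree.n_nodes)
    if name in ("BM.s", "BM.rate"):
        x[tree.root] = params["z0"]
        for v in tree.preorder:
            if v == tree.root:
                continue
            var = 0.0
            for dur, st in _branch_segments(tree, painting, v):
                s2 = (params["sigma2"] if name == "BM.s"
                      else params["sigma2_by_regime"][st])
                var += s2 * dur
            x[v] = rng.normal(x[int(tree.parent[v])], np.sqrt(var))
        return TraitVector(pd.Series(x[:n], index=tree.tip_labels))

    if name in ("OU.s", "OU.poll"):
        alpha = params["alpha"]
        if alpha <= 0:
            raise ValueError("OU requires alpha > 0")
        sigma2 = params["sigma2"]
        theta = params["theta"]

        def theta_of(st: str) -> float:
            if name == "OU.s":
                return float(theta)
            return float(theta[st])

        if "z0" in params and params["z0"] is not None:
            x[tree.root] = params["z0"]
        elif name == "OU.s":
            x[tree.root] = float(theta)
        else:
            root_regime = (painting.root_state if isinstance(painting, MkHistory)
                           else painting.root_regime)
            x[tree.root] = theta_of(root_regime)
        for v in tree.preorder:
            if v == tree.root:
                continue
            val = x[int(tree.parent[v])]
            for dur, st in _branch_segments(tree, painting, v):
                th = theta_of(st)
                e = np.exp(-alpha * dur)
                m = th + (val - th) * e
                sd = np.sqrt(sigma2 * (1.0 - e * e) / (2.0 * alpha))
                val = rng.normal(m, sd)
            x[v] = val
        return TraitVector(pd.Series(x[:n], index=tree.tip_labels))

    raise ValueError(f"unknown model {name!r}")


# ----------------------------------------------------------------------
# the study-like bundle
# ----------------------------------------------------------------------
# Natural-scale observed ranges the bundle is clipped into, and the OU
# parameter magnitudes the generator defaults to (transformed scale).
TRAIT_RANGES = {
    "volume_ul": (0.06, 72.16),
    "sugar_pct": (0.73, 76.9),
    "nsp_pct": (25.2, 99.8),
    "aa_mm": (0.20, 69.70),
}

STUDY_TRAITS = {
    # name: (model, transform, percent, alpha, sigma2, optima on natural scale)
    "volume_ul": ("OU.poll", "log", False, 14.9, 5.42,
                  {"bird": 37.1, "butterfly": 5.0, "bee": 4.0,
                   "fly": 0.5, "bee_and_butterfly": 2.5}),
    "sugar_pct": ("OU.poll", "logit", True, 15.0, 29.4,
                  {"bird": 15.0, "butterfly": 30.0, "bee": 25.0,
                   "fly": 4.0, "bee_and_butterfly": 33.0}),
    "nsp_pct": ("OU.poll", "logit", True, 14.9, 58.1,
                {"bird": 99.1, "butterfly": 60.0, "bee": 55.0,
                 "fly": 27.0, "bee_and_butterfly": 65.0}),
    "aa_mm": ("OU.s", "log", False, 0.45, 0.26, 3.40),
    "total_spur_mm": ("OU.poll", "log", False, 1.0, 0.3,
                      {"bird": 35.0, "butterfly": 25.0, "bee": 15.0,
                       "fly": 5.0, "bee_and_butterfly": 20.0}),
}

AMINO_ACIDS = (
    "alanine", "arginine", "asparagine", "aspartate", "cysteine", "gaba",
    "glutamate", "glutamine", "glycine", "histidine", "isoleucine",
    "leucine", "lysine", "methionine", "ornithine", "phenylalanine",
    "proline", "serine", "threonine", "tryptophan", "tyrosine", "valine",
)
# baseline relative abundances: ubiquitous amino acids high, methionine rare
_AA_CONC = {
    "alanine": 4.0, "arginine": 3.0, "glycine": 3.0, "threonine": 2.5,
    "valine": 2.5, "lysine": 2.0, "proline": 2.0, "serine": 2.0,
    "glutamine": 1.5, "glutamate": 1.5, "asparagine": 1.0, "aspartate": 1.0,
    "histidine": 0.8, "isoleucine": 0.8, "leucine": 0.8,
    "phenylalanine": 0.6, "tyrosine": 0.5, "gaba": 0.5, "ornithine": 0.4,
    "tryptophan": 0.3, "cysteine": 0.3, "methionine": 0.1,
}


@dataclass(frozen=True)
class StudyBundle:
    tree: Phylogeny
    syndromes: SyndromeMap
    table: pd.DataFrame          # species × traits, natural scale
    history: MkHistory           # true regime history
    true_params: dict            # generating parameters per trait
    seed: int

    def trait_vectors(self) -> list[TraitVector]:
        from .traits import TRAIT_UNITS
        out = []
        for c in self.table.columns:
            if c == "syndrome":
                continue
            s = self.table[c].dropna()
            out.append(TraitVector(s, name=c, units=TRAIT_UNITS.get(c, "")))
        return out


def _natural_to_transformed(value, kind: str, percent: bool) -> float:
    if kind == "log":
        return float(np.log(value))
    p = value / 100.0 if percent else value
    return float(np.log(p / (1.0 - p)))


def generate_study_like_dataset(seed: int, n_tips: int = 57,
                                crown_age: float = 22.0,
                                mk_rate: float = 0.02,
                                n_spur_missing: int = 9,
                                out_dir=None) -> StudyBundle:
    """57-species bundle emulating the study design.

    A Yule chronogram of ``n_tips`` tips and 22 Ma crown age carries a
    five-state pollination syndrome (ER rate ``mk_rate``/Ma; re-drawn with a
    shifted stream until all five classes occur at the tips).  The four main
    nectar traits follow multi/single-optimum OU processes with the
    study's reported α, σ² and optimum magnitudes, simulated on the
    transformed scale and
    clipped into the study's observed natural-scale ranges; the 22 amino-acid
    fractions are Dirichlet compositions without phylogenetic structure; spur
    lengths exist for a 48-species subset.  Writes Newick + CSV when
    ``out_dir`` is given.  Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    sub = rng.integers(2**31, size=16)
    tree = simulate_yule_tree(n_tips, crown_age, seed=int(sub[0]))
    history = None
    for attempt in range(50):
        h = simulate_mk_regimes(tree, SYNDROME_ORDER, mk_rate,
                                root_state="bee", seed=int(sub[1]) + attempt)
        if set(h.tip_states.values()) == set(SYNDROME_ORDER):
            history = h
            break
    if history is None:  # pragma: no cover — essentially impossible at n=57
        raise RuntimeError("could not realize all five syndromes at the tips")
    syn = history.syndrome_map()
    painting = history.painting(tree)

    table = pd.DataFrame(index=pd.Index(tree.tip_labels, name="species"))
    table["syndrome"] = [syn[s] for s in tree.tip_labels]
    true_params: dict = {"mk_rate": mk_rate, "crown_age": crown_age}
    for j, (name, (model, kind, percent, alpha, sigma2, optima)) in enumerate(
            STUDY_TRAITS.items()):
        if model == "OU.poll":
            theta = pd.Series({r: _natural_to_transformed(v, kind, percent)
                               for r, v in optima.items()})
        else:
            theta = _natural_to_transformed(optima, kind, percent)
        params = {"alpha": alpha, "sigma2": sigma2, "theta": theta}
        tv = simulate_trait(tree, painting, model, params, seed=int(sub[2 + j]))
        y = tv.values
        if kind == "log":
            nat = np.exp(y)
        else:
            nat = 1.0 / (1.0 + np.exp(-y))
            if percent:
                nat = nat * 100.0
        if name in TRAIT_RANGES:
            nat = nat.clip(*TRAIT_RANGES[name])
        table[name] = nat
        true_params[name] = {"model": model, "transform": kind, **params}

    # amino-acid composition: logistic-normal with three latent factors and
    # no phylogenetic structure, so a few ordination axes carry most of the
    # compositional variance (as in real nectar amino-acid profiles)
    aa_rng = np.random.default_rng(int(sub[10]))
    loading_scales = np.array([1.1, 0.9, 0.5])
    L = (np.random.default_rng(12345).normal(size=(len(AMINO_ACIDS), 3))
         * loading_scales)
    mu = np.log([_AA_CONC[a] for a in AMINO_ACIDS])
    f = aa_rng.normal(size=(n_tips, 3))
    logs = mu + f @ L.T + aa_rng.normal(0.0, 0.75, size=(n_tips, len(AMINO_ACIDS)))
    frac = np.exp(logs)
    frac /= frac.sum(axis=1, keepdims=True)
    for i, a in enumerate(AMINO_ACIDS):
        table[f"aa_frac_{a}"] = frac[:, i]

    # spur lengths: 48-species subset, spur a fixed fraction of total spur
    spur_rng = np.random.default_rng(int(sub[11]))
    table["spur_mm"] = table["total_spur_mm"] * 0.65 * np.exp(
        spur_rng.normal(0.0, 0.05, size=n_tips))
    missing = spur_rng.choice(tree.tip_labels, size=n_spur_missing, replace=False)
    table.loc[list(missing), ["spur_mm", "total_spur_mm"]] = np.nan
    # put spur columns last, main nectar traits first
    cols = (["syndrome", "volume_ul", "sugar_pct", "nsp_pct", "aa_mm"]
            + [f"aa_frac_{a}" for a in AMINO_ACIDS]
            + ["spur_mm", "total_spur_mm"])
    table = table[cols]

    bundle = StudyBundle(tree=tree, syndromes=syn, table=table,
                         history=history, true_params=true_params, seed=seed)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "tree.nwk", "w") as fh:
            fh.write(tree.to_newick())
        write_trait_table(out / "traits.csv", bundle.trait_vectors(), syn,
                          header_comment=f"synthetic study-like bundle, seed={seed}")
    return bundle


def transformed_trait(bundle: StudyBundle, name: str) -> TraitVector:
    """A bundle trait on its analysis scale (log / logit per study convention)."""
    info = STUDY_TRAITS.get(name)
    s = bundle.table[name].dropna()
    from .traits import TRAIT_UNITS
    tv = TraitVector(s, name=name, units=TRAIT_UNITS.get(name, ""))
    if name.startswith("aa_frac_"):
        return transform(tv, "logit", offset=0.01, percent=False)
    if info is None:
        return tv
    _, kind, percent, *_ = info
    if kind == "logit":
        zero = (s / 100.0 if percent else s) <= 0.0
        offset = 0.001 if bool(zero.any()) else 0.0
        one = (s / 100.0 if percent else s) >= 1.0
        if bool(one.any()):
            offset = -0.001
        return transform(tv, "logit", offset=offset, percent=percent)
    return transform(tv, kind)
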