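"""Six candidate models of continuous trait evolution, ML fitting, and
AICc-based model comparison.

The model menu:

========  ==========================================================
WN        white noise / star phylogeny: iid Normal(μ, s²) tips
BM.s      Brownian motion, one rate σ²; covariance σ²·C with
          C_ij the shared root-to-MRCA path length
BM.rate   Brownian motion with a separate rate σ²_r per selective
          regime; covariance Σ_r σ²_r·C_r, C_r accumulating only
          shared path length spent in regime r
Lambda    Pagel's λ: BM covariance with off-diagonals scaled by
          λ ∈ [0, 1]
OU.s      Ornstein–Uhlenbeck pull (α) toward a single optimum θ
OU.poll   OU with one optimum per pollination-syndrome regime
          (Hansen model): mean W(α)·θ with the regime weight
          matrix W, shared α and σ² across regimes
========  ==========================================================

On an ultrametric tree of height T the OU tip covariance is

    V_ij = σ²/(2α) · exp(−α·d_ij) · (1 − exp(−2α·s_ij)),

with d_ij the patristic tip–tip distance and s_ij the shared depth.  The
Hansen weight W_{ir} integrates α·e^{−α(T−t)} over the segments lineage i
spends in regime r, plus a root weight e^{−αT} credited to the root's
regime, so rows sum to one.  Optima, means and σ² are profiled out by
generalized least squares; α (log scale) and λ are optimized by bounded
deterministic multi-start search.

Model support is summarised by small-sample AICc and Akaike weights; the
speed of adaptation is reported as the phylogenetic half-life
t½ = ln(2)/α.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize, minimize_scalar

from .phylo import Phylogeny
from .regimes import RegimePainting
from .traits import TraitVector, back_transform_values

logger = logging.getLogger(__name__)

MODEL_NAMES = ("WN", "OU.s", "OU.poll", "BM.s", "BM.rate", "Lambda")
#: display aliases used in report tables
DISPLAY_NAMES = {"WN": "White"}

__all__ = [
    "MODEL_NAMES", "ModelFit", "ModelComparison", "ThetaUncertainty",
    "model_loglik", "fit_model", "compare_models", "aicc", "akaike_weights",
    "phylogenetic_half_life", "estimate_theta_uncertainty",
]


class DegenerateDataError(ValueError):
    pass


@dataclass(frozen=True)
class ModelFit:
    name: str
    params: dict
    loglik: float
    k: int
    n: int
    aicc: float
    half_life: float | None = None
    theta_se: pd.Series | None = None

    @property
    def sigma2(self):
        return self.params.get("sigma2")

    @property
    def alpha(self):
        return self.params.get("alpha")

    @property
    def lam(self):
        return self.params.get("lam")

    @property
    def theta(self):
        return self.params.get("theta")


@dataclass(frozen=True)
class ModelComparison:
    fits: dict[str, ModelFit]
    weights: pd.Series
    best: str
    failures: dict[str, str] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = []
        for name in MODEL_NAMES:
            if name in self.fits:
                f = self.fits[name]
                rows.append({
                    "model": DISPLAY_NAMES.get(name, name),
                    "loglik": f.loglik, "k": f.k, "aicc": f.aicc,
                    "weight": self.weights[name],
                    "best": name == self.best,
                })
            elif name in self.failures:
                rows.append({"model": DISPLAY_NAMES.get(name, name),
                             "error": self.failures[name]})
        return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# covariance / design builders
# ----------------------------------------------------------------------
def _ou_cov_structure(C: np.ndarray, alpha: float) -> np.ndarray:
    """OU tip covariance divided by σ², from the shared-depth matrix C."""
    depths = np.diag(C)
    d = depths[:, None] + depths[None, :] - 2.0 * C
    return np.exp(-alpha * d) * (1.0 - np.exp(-2.0 * alpha * C)) / (2.0 * alpha)


def _hansen_weights(tree: Phylogeny, painting: RegimePainting,
                    alpha: float, regimes: list[str]) -> np.ndarray:
    """Regime weight matrix W (tips × regimes); rows sum to 1."""
    ridx = {r: j for j, r in enumerate(regimes)}
    d = tree.depths
    W = np.zeros((tree.n_tips, len(regimes)))
    for i in range(tree.n_tips):
        Ti = d[i]
        W[i, ridx[painting.root_regime]] += np.exp(-alpha * Ti)
        for v in tree.lineage_edges(i):
            t0 = d[int(tree.parent[v])]
            t1 = d[v]
            w = np.exp(-alpha * (Ti - t1)) - np.exp(-alpha * (Ti - t0))
            W[i, ridx[painting.branch_regime[v]]] += w
    return W


def _bm_regime_cov(tree: Phylogeny, painting: RegimePainting,
                   regimes: list[str]) -> dict[str, np.ndarray]:
    """Per-regime shared path-length matrices C_r (Σ_r C_r = C)."""
    ridx = {r: j for j, r in enumerate(regimes)}
    R = len(regimes)
    acc = np.zeros((tree.n_nodes, R))  # time spent per regime, root → node
    for v in tree.preorder:
        p = int(tree.parent[v])
        if p >= 0:
            acc[v] = acc[p]
            acc[v, ridx[painting.branch_regime[v]]] += tree.edge_length[v]
    M = tree.mrca_matrix()
    return {r: acc[:, ridx[r]][M] for r in regimes}


def _gls_profile(y: np.ndarray, X: np.ndarray, V0: np.ndarray):
    """ML fit of mean = Xβ, cov = σ²·V0, with β and σ² profiled.

    Returns (beta, sigma2_hat, loglik, XtViX).
    """
    n = len(y)
    cf = cho_factor(V0, lower=True)
    Vi_y = cho_solve(cf, y)
    Vi_X = cho_solve(cf, X)
    XtViX = X.T @ Vi_X
    # lstsq: the Hansen design degenerates toward collinearity as α → 0
    beta = np.linalg.lstsq(XtViX, X.T @ Vi_y, rcond=None)[0]
    r = y - X @ beta
    rss = float(r @ cho_solve(cf, r))
    if rss <= 0:
        rss = 1e-300  # exact fit: keep the profiled likelihood finite
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    s2 = rss / n
    ll = -0.5 * (n * np.log(2.0 * np.pi * s2) + logdet + n)
    return beta, s2, ll, XtViX


def _mvn_loglik(y, mean, V) -> float:
    cf = cho_factor(V, lower=True)
    r = y - mean
    rss = float(r @ cho_solve(cf, r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    return -0.5 * (len(y) * np.log(2.0 * np.pi) + logdet + rss)


def _prepare(tree: Phylogeny, trait: TraitVector):
    common = [l for l in tree.tip_labels if l in trait.values.index]
    if len(common) < tree.n_tips:
        tree = tree.prune_to(common)
    y = trait.to_array(tree.tip_labels)
    if np.ptp(y) == 0:
        raise DegenerateDataError(f"trait {trait.name!r} is constant")
    return tree, y


def _lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


# ----------------------------------------------------------------------
# direct likelihood evaluation (explicit parameters)
# ----------------------------------------------------------------------
def model_loglik(tree: Phylogeny, trait: TraitVector,
                 painting: RegimePainting | None, name: str,
                 params: dict) -> float:
    """Multivariate-normal log-likelihood of a trait under one model with
    fully specified parameters (no fitting)."""
    tree, y = _prepare(tree, trait)
    n = len(y)
    C = tree.shared_depth_matrix()
    if name == "WN":
        return _mvn_loglik(y, np.full(n, params["mu"]),
                           params["s2"] * np.eye(n))
    if name == "BM.s":
        return _mvn_loglik(y, np.full(n, params["z0"]), params["sigma2"] * C)
    if name == "Lambda":
        lam = params["lam"]
        if not 0.0 <= lam <= 1.0:
            raise ValueError("lambda outside [0, 1]")
        return _mvn_loglik(y, np.full(n, params["z0"]),
                           params["sigma2"] * _lambda_cov(C, lam))
    if name == "BM.rate":
        if painting is None:
            raise ValueError("BM.rate requires a regime painting")
        s2r = params["sigma2_by_regime"]
        regimes = list(s2r)
        Cr = _bm_regime_cov(tree, painting, regimes)
        V = sum(s2r[r] * Cr[r] for r in regimes)
        return _mvn_loglik(y, np.full(n, params["z0"]), V)
    if name in ("OU.s", "OU.poll"):
        alpha = params["alpha"]
        if alpha <= 0:
            raise ValueError("OU requires alpha > 0")
        if not tree.is_ultrametric(rel_tol=1e-2):
            raise ValueError("OU models require an ultrametric tree")
        V = params["sigma2"] * _ou_cov_structure(C, alpha)
        if name == "OU.s":
            mean = np.full(n, params["theta"])
        else:
            if painting is None:
                raise ValueError("OU.poll requires a regime painting")
            theta = params["theta"]
            regimes = list(theta.index if isinstance(theta, pd.Series) else theta)
            th = (theta.to_numpy() if isinstance(theta, pd.Series)
                  else np.array([theta[r] for r in regimes]))
            W = _hansen_weights(tree, painting, alpha, regimes)
            mean = W @ th
        return _mvn_loglik(y, mean, V)
    raise ValueError(f"unknown model {name!r}")


# ----------------------------------------------------------------------
# information criteria
# ----------------------------------------------------------------------
def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (n - k - 1 <= 0)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """w_i = exp(−Δ_i/2) / Σ_j exp(−Δ_j/2), Δ_i = AICc_i − min AICc."""
    a = np.asarray(aicc_values, dtype=float)
    finite = np.isfinite(a)
    if not finite.any():
        raise ValueError("no finite AICc values")
    delta = a - a[finite].min()
    w = np.where(finite, np.exp(-0.5 * np.clip(delta, 0, 700)), 0.0)
    return w / w.sum()


def phylogenetic_half_life(alpha: float) -> float:
    """t½ = ln(2)/α: time to move halfway from the ancestral state to a
    new optimum."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return float(np.log(2.0) / alpha)


# ----------------------------------------------------------------------
# fitting
# ----------------------------------------------------------------------
def _optimize_scalar(nll, lo: float, hi: float, n_grid: int = 13,
                     n_starts: int = 3, window: float = 1.5):
    """Deterministic multi-start bounded 1-D minimisation."""
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([nll(g) for g in grid])
    order = np.argsort(vals)
    best_x, best_f = grid[order[0]], vals[order[0]]
    for j in order[:n_starts]:
        a = max(lo, grid[j] - window)
        b = min(hi, grid[j] + window)
        res = minimize_scalar(nll, bounds=(a, b), method="bounded",
                              options={"xatol": 1e-10})
        if res.fun < best_f:
            best_x, best_f = float(res.x), float(res.fun)
    return best_x, best_f


def fit_model(tree: Phylogeny, trait: TraitVector,
              painting: RegimePainting | None, name: str) -> ModelFit:
    """Maximum-likelihood fit of one model; deterministic given inputs.

    Means/optima and σ² are profiled analytically by GLS; α is optimized
    on the log scale over [1e-9/T, 1e3/T] and λ over [0, 1], both by
    multi-start bounded search.
    """
    tree, y = _prepare(tree, trait)
    n = len(y)
    C = tree.shared_depth_matrix()
    ones = np.ones((n, 1))
    T = tree.crown_age

    if name == "WN":
        mu = float(y.mean())
        s2 = float(np.mean((y - mu) ** 2))
        ll = _mvn_loglik(y, np.full(n, mu), s2 * np.eye(n))
        return _finish(name, {"mu": mu, "s2": s2}, ll, 2, n)

    if name == "BM.s":
        beta, s2, ll, _ = _gls_profile(y, ones, C)
        return _finish(name, {"z0": float(beta[0]), "sigma2": s2}, ll, 2, n)

    if name == "Lambda":
        def nll(lam):
            return -_gls_profile(y, ones, _lambda_cov(C, lam))[2]
        lam, f = _optimize_scalar(nll, 0.0, 1.0, n_grid=11, window=0.25)
        beta, s2, ll, _ = _gls_profile(y, ones, _lambda_cov(C, lam))
        return _finish(name, {"z0": float(beta[0]), "sigma2": s2, "lam": lam},
                       ll, 3, n)

    if name in ("OU.s", "OU.poll"):
        if not tree.is_ultrametric(rel_tol=1e-2):
            raise ValueError("OU models require an ultrametric tree")
        if name == "OU.poll":
            if painting is None:
                raise ValueError("OU.poll requires a regime painting")
            regimes = painting.regimes_present()
        else:
            regimes = None

        def design(alpha):
            if regimes is None:
                return ones
            return _hansen_weights(tree, painting, alpha, regimes)

        def nll(loga):
            a = np.exp(loga)
            try:
                return -_gls_profile(y, design(a), _ou_cov_structure(C, a))[2]
            except (np.linalg.LinAlgError, DegenerateDataError, ValueError):
                return np.inf
        lo, hi = np.log(1e-9 / T), np.log(1e3 / T)
        loga, _f = _optimize_scalar(nll, lo, hi)
        alpha = float(np.exp(loga))
        X = design(alpha)
        beta, s2, ll, XtViX = _gls_profile(y, X, _ou_cov_structure(C, alpha))
        if regimes is None:
            params = {"theta": float(beta[0]), "alpha": alpha, "sigma2": s2}
            k = 3
        else:
            params = {"theta": pd.Series(beta, index=regimes),
                      "alpha": alpha, "sigma2": s2}
            k = 2 + len(regimes)
        return _finish(name, params, ll, k, n)

    if name == "BM.rate":
        if painting is None:
            raise ValueError("BM.rate requires a regime painting")
        regimes = painting.regimes_present()
        Cr = _bm_regime_cov(tree, painting, regimes)
        Cstack = np.stack([Cr[r] for r in regimes])
        _, s2_bm, _, _ = _gls_profile(y, ones, C)

        def nll(logs2):
            V = np.tensordot(np.exp(logs2), Cstack, axes=1)
            try:
                cf = cho_factor(V, lower=True)
            except np.linalg.LinAlgError:
                return np.inf
            Vi_y = cho_solve(cf, y)
            Vi_1 = cho_solve(cf, ones[:, 0])
            b = float(ones[:, 0] @ Vi_y) / float(ones[:, 0] @ Vi_1)
            r = y - b
            rss = float(r @ cho_solve(cf, r))
            logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
            return 0.5 * (n * np.log(2.0 * np.pi) + logdet + rss)

        best = None
        for scale in (1.0, 0.1, 10.0):
            x0 = np.full(len(regimes), np.log(s2_bm * scale))
            res = minimize(nll, x0, method="L-BFGS-B",
                           bounds=[(np.log(s2_bm) - 16, np.log(s2_bm) + 16)] * len(regimes),
                           options={"ftol": 1e-12, "gtol": 1e-10})
            if best is None or res.fun < best.fun:
                best = res
        s2r = dict(zip(regimes, np.exp(best.x)))
        V = np.tensordot(np.exp(best.x), Cstack, axes=1)
        cf = cho_factor(V, lower=True)
        b = float(ones[:, 0] @ cho_solve(cf, y)) / float(ones[:, 0] @ cho_solve(cf, ones[:, 0]))
        ll = _mvn_loglik(y, np.full(n, b), V)
        return _finish(name, {"z0": b, "sigma2_by_regime": s2r,
                              "sigma2": pd.Series(s2r)}, ll, 1 + len(regimes), n)

    raise ValueError(f"unknown model {name!r}")


def _finish(name, params, ll, k, n) -> ModelFit:
    hl = None
    if "alpha" in params and params["alpha"] > 0:
        hl = phylogenetic_half_life(params["alpha"])
    return ModelFit(name=name, params=params, loglik=float(ll), k=k, n=n,
                    aicc=aicc(ll, k, n), half_life=hl)


def compare_models(tree: Phylogeny, trait: TraitVector,
                   painting: RegimePainting,
                   models=MODEL_NAMES) -> ModelComparison:
    """Fit the six-model menu and weigh the fits by AICc.

    Per-model failures are recorded (not raised) so one ill-posed model
    cannot abort the comparison.
    """
    fits: dict[str, ModelFit] = {}
    failures: dict[str, str] = {}
    for name in models:
        try:
            fits[name] = fit_model(tree, trait, painting, name)
        except Exception as exc:  # noqa: BLE001 — isolate per-model failures
            logger.warning("model %s failed for trait %s: %s", name, trait.name, exc)
            failures[name] = str(exc)
    if not fits:
        raise DegenerateDataError("all model fits failed")
    names = list(fits)
    w = akaike_weights([fits[m].aicc for m in names])
    weights = pd.Series(w, index=names)
    best = min(names, key=lambda m: fits[m].aicc)
    return ModelComparison(fits=fits, weights=weights, best=best,
                           failures=failures)


# ----------------------------------------------------------------------
# uncertainty of the optima
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class ThetaUncertainty:
    table: pd.DataFrame  # regime × [theta, se, ci_lo, ci_hi, + natural-scale]
    method: str          # "hessian" or "bootstrap"


def _num_hessian(f, x0: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    p = len(x0)
    h = rel_step * (1.0 + np.abs(x0))
    H = np.zeros((p, p))
    f0 = f(x0)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            if i == j:
                H[i, i] = (f(x0 + ei) - 2 * f0 + f(x0 - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    f(x0 + ei + ej) - f(x0 + ei - ej)
                    - f(x0 - ei + ej) + f(x0 - ei - ej)
                ) / (4 * h[i] * h[j])
    return H


def estimate_theta_uncertainty(fit: ModelFit, tree: Phylogeny,
                               trait: TraitVector,
                               painting: RegimePainting | None,
                               seed: int = 0,
                               n_boot: int = 199) -> ThetaUncertainty:
    """Standard errors and 95 % CIs for OU optima.

    The default route inverts the numerical Hessian of the negative
    log-likelihood at the ML point, parameterized as (θ_1..θ_R, log α,
    log σ²); CIs are θ̂ ± 1.96·s.e. on the transformed scale and are then
    back-transformed, so natural-scale intervals are asymmetric.  If the
    Hessian is singular or yields non-positive variances, a seeded
    parametric bootstrap (``n_boot`` replicates) is used instead.
    """
    if fit.name not in ("OU.s", "OU.poll"):
        raise ValueError("theta uncertainty applies to OU fits")
    theta = fit.theta
    if isinstance(theta, pd.Series):
        regimes = list(theta.index)
        th0 = theta.to_numpy(dtype=float)
    else:
        regimes = ["all"]
        th0 = np.array([float(theta)])
    R = len(th0)
    x0 = np.concatenate([th0, [np.log(fit.alpha)], [np.log(fit.sigma2)]])

    def nll(x):
        th = x[:R]
        params = {"alpha": float(np.exp(x[R])), "sigma2": float(np.exp(x[R + 1]))}
        if fit.name == "OU.s":
            params["theta"] = float(th[0])
        else:
            params["theta"] = pd.Series(th, index=regimes)
        try:
            return -model_loglik(tree, trait, painting, fit.name, params)
        except (np.linalg.LinAlgError, ValueError):
            return np.inf

    se = None
    method = "hessian"
    try:
        H = _num_hessian(nll, x0)
        cov = np.linalg.inv(H)
        var = np.diag(cov)[:R]
        if np.all(var > 0):
            se = np.sqrt(var)
    except np.linalg.LinAlgError:
        pass
    if se is None:
        method = "bootstrap"
        se = _bootstrap_theta_se(fit, tree, trait, painting, regimes, seed, n_boot)
        logger.warning("singular Hessian for trait %s: using %d-rep parametric "
                       "bootstrap", trait.name, n_boot)

    lo = th0 - 1.96 * se
    hi = th0 + 1.96 * se
    tab = pd.DataFrame({"theta": th0, "se": se, "ci_lo": lo, "ci_hi": hi},
                       index=pd.Index(regimes, name="regime"))
    tab["theta_natural"] = back_transform_values(th0, trait)
    tab["ci_lo_natural"] = back_transform_values(lo, trait)
    tab["ci_hi_natural"] = back_transform_values(hi, trait)
    return ThetaUncertainty(table=tab, method=method)


def _bootstrap_theta_se(fit, tree, trait, painting, regimes, seed, n_boot):
    from .simulate import simulate_trait  # local import: avoids a cycle at import time

    rng = np.random.default_rng(seed)
    est = []
    for _ in range(n_boot):
        sim = simulate_trait(tree, painting, fit.name, fit.params,
                             seed=int(rng.integers(2**31)))
        sim_tv = TraitVector(sim.values, name=trait.name,
                             transform=trait.transform, offset=trait.offset,
                             percent=trait.percent)
        try:
            bfit = fit_model(tree, sim_tv, painting, fit.name)
        except (DegenerateDataError, ValueError):
            continue
        th = bfit.theta
        est.append(th.reindex(regimes).to_numpy() if isinstance(th, pd.Series)
                   else [float(th)])
    return np.nanstd(np.asarray(est, dtype=float), axis=0, ddof=1)
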