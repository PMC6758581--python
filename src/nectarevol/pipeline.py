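"""Configuration-driven orchestration of the full nectar-evolution analysis.

``run_full_analysis`` takes a config (paths to a chronogram and trait
table, or a simulation block), reconstructs pollination-syndrome regimes,
runs the six-model comparison for each analysis trait, fits the PGLS
regressions, and performs the multivariate nectar-syndrome stage, writing
six report files:

* ``model_comparison.csv`` — trait × model AICc and Akaike weights
* ``model_parameters.csv`` — σ², α, t½ (and λ) per trait for the best model
* ``optima.csv``           — back-transformed OU optima with s.e. and 95 % CI
* ``pgls_reports.csv``     — regression coefficient tables with λ̂ and AICc
* ``multivariate_report.json`` — PCA variance, Mantel r/p, dendrogram
  (Newick) and its syndrome λ signal
* ``run_log.json``         — seed, config hash, versions, stage timings
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .models import compare_models, estimate_theta_uncertainty
from .multivariate import (dendrogram_lambda_signal, euclidean_distance_matrix,
                           mantel_test, pca, syndrome_distance_matrix, upgma)
from .pgls import pgls_fit
from .phylo import Phylogeny, read_newick
from .regimes import paint_from_syndromes
from .simulate import AMINO_ACIDS, generate_study_like_dataset
from .traits import (SyndromeMap, TraitVector, read_trait_table, transform)

logger = logging.getLogger(__name__)

REPORT_FILES = (
    "model_comparison.csv", "model_parameters.csv", "optima.csv",
    "pgls_reports.csv", "multivariate_report.json", "run_log.json",
)

#: trait column → (transform kind, percent scale) for the four main traits
ANALYSIS_TRANSFORMS = {
    "volume_ul": ("log", False),
    "sugar_pct": ("logit", True),
    "nsp_pct": ("logit", True),
    "aa_mm": ("log", False),
}


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    text = Path(path).read_text()
    cfg = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) \
        else json.loads(text)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    has_paths = "tree" in cfg and "traits" in cfg
    has_sim = "simulate" in cfg
    if has_paths == has_sim:
        raise ConfigError(
            "config must contain exactly one of (tree + traits paths) or a "
            "'simulate' block"
        )


def validate_inputs(tree: Phylogeny, vectors: list[TraitVector],
                    syndromes: SyndromeMap,
                    ultrametric_tol: float = 1e-3) -> dict:
    """Reconcile species sets and report data issues before analysis."""
    table_sp = set(syndromes.values)
    tree_sp = set(tree.tip_labels)
    common = tree_sp & table_sp
    if not common:
        raise ConfigError("tree and trait table share no species")
    offsets = {}
    for tv in vectors:
        kind = ANALYSIS_TRANSFORMS.get(tv.name, (None, None))[0]
        is_frac = tv.name.startswith("aa_frac_")
        if kind == "logit" or is_frac:
            vals = tv.values / (100.0 if not is_frac and "%" in tv.units else 1.0)
            if is_frac:
                offsets[tv.name] = 0.01
            elif (vals <= 0).any():
                offsets[tv.name] = 0.001
    return {
        "n_common_species": len(common),
        "pruned_from_tree": sorted(tree_sp - table_sp),
        "dropped_from_table": sorted(table_sp - tree_sp),
        "logit_offsets": offsets,
        "ultrametric": tree.is_ultrametric(ultrametric_tol),
        "crown_age": tree.crown_age,
    }


def _transformed_main_trait(table: pd.DataFrame, name: str) -> TraitVector:
    kind, percent = ANALYSIS_TRANSFORMS[name]
    from .traits import TRAIT_UNITS
    tv = TraitVector(table[name].dropna(), name=name,
                     units=TRAIT_UNITS.get(name, ""))
    if kind == "log":
        return transform(tv, "log")
    p = tv.values / 100.0 if percent else tv.values
    offset = 0.001 if (p <= 0).any() else 0.0
    return transform(tv, "logit", offset=offset, percent=percent)


def _aa_pca(table: pd.DataFrame):
    """PCA of the logit(x + 0.01)-transformed amino-acid fractions."""
    aa_cols = [c for c in table.columns if c.startswith("aa_frac_")]
    if not aa_cols:
        return None
    frac = table[aa_cols].dropna()
    logit = np.log((frac + 0.01) / (1.0 - (frac + 0.01)))
    keep = [c for c in aa_cols if logit[c].std() > 0]
    return pca(logit[keep], scale=True)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, seed: int, cfg_hash: str,
               index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# nectarevol {__version__} seed={seed} config={cfg_hash}\n")
        df.to_csv(fh, index=index)


def run_full_analysis(cfg: dict, out_dir) -> dict:
    """Run every stage and write the report bundle; returns a summary dict."""
    validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    n_perm = int(cfg.get("n_perm", 9999))
    cfg_hash = _config_hash(cfg)
    timings: dict[str, float] = {}
    t0 = time.perf_counter()

    def tick(stage):
        timings[stage] = round(time.perf_counter() - t0, 3)

    # ---------------- load or simulate ----------------
    if "simulate" in cfg:
        sim = dict(cfg["simulate"])
        sim.setdefault("seed", seed)
        bundle = generate_study_like_dataset(**sim)
        tree, syndromes, table = bundle.tree, bundle.syndromes, bundle.table
    else:
        tree = read_newick(str(cfg["tree"]))
        vectors, syndromes = read_trait_table(cfg["traits"])
        table = pd.DataFrame({tv.name: tv.values for tv in vectors})
        table.index.name = "species"
    vectors = [TraitVector(table[c].dropna(), name=c)
               for c in table.columns if c != "syndrome"]
    report = validate_inputs(tree, vectors, syndromes,
                             float(cfg.get("ultrametric_tol", 1e-3)))
    common = [s for s in tree.tip_labels if s in syndromes.values]
    if len(common) < tree.n_tips:
        tree = tree.prune_to(common)
    syndromes = syndromes.subset(tree.tip_labels)
    tick("load")

    # ---------------- regimes ----------------
    painting, mk_fit = paint_from_syndromes(tree, syndromes)
    tick("asr")

    # ---------------- analysis traits ----------------
    traits: dict[str, TraitVector] = {}
    for name in ANALYSIS_TRANSFORMS:
        if name in table.columns:
            traits[name] = _transformed_main_trait(table, name)
    aa_res = _aa_pca(table)
    if aa_res is not None:
        for j in range(min(3, aa_res.scores.shape[1])):
            ax = f"PC{j + 1}"
            traits[f"aa_{ax}"] = TraitVector(aa_res.scores[ax],
                                             name=f"aa_{ax}")
    # nectar PCA: the four transformed traits + three aa axes, unit variance
    nectar_vars = pd.DataFrame({
        k: v.values for k, v in traits.items()
    }).dropna()
    nectar_res = pca(nectar_vars, scale=True) if nectar_vars.shape[1] >= 2 else None
    if nectar_res is not None:
        for j in range(min(3, nectar_res.scores.shape[1])):
            ax = f"PC{j + 1}"
            traits[f"nectar_{ax}"] = TraitVector(nectar_res.scores[ax],
                                                 name=f"nectar_{ax}")
    tick("traits")

    # ---------------- model comparison ----------------
    comp_rows, param_rows, optima_rows = [], [], []
    for name, tv in traits.items():
        comp = compare_models(tree, tv, painting)
        for m, fit in comp.fits.items():
            comp_rows.append({
                "trait": name, "model": m, "aicc": round(fit.aicc, 2),
                "weight": round(float(comp.weights[m]), 4),
                "loglik": round(fit.loglik, 3), "k": fit.k,
                "best": m == comp.best,
            })
        best = comp.fits[comp.best]
        row = {"trait": name, "best_model": comp.best, "n": best.n}
        if best.sigma2 is not None and not isinstance(best.sigma2, pd.Series):
            row["sigma2"] = best.sigma2
        if best.alpha is not None:
            row["alpha"] = best.alpha
            row["half_life_ma"] = best.half_life
        if best.lam is not None:
            row["lambda"] = best.lam
        param_rows.append(row)
        if best.name in ("OU.s", "OU.poll"):
            unc = estimate_theta_uncertainty(best, tree, tv, painting,
                                             seed=seed)
            for regime, r in unc.table.iterrows():
                optima_rows.append({
                    "trait": name, "regime": regime,
                    "theta_transformed": r["theta"], "se": r["se"],
                    "theta": r["theta_natural"],
                    "ci_lo": r["ci_lo_natural"], "ci_hi": r["ci_hi_natural"],
                    "method": unc.method,
                })
    _write_csv(pd.DataFrame(comp_rows), out / "model_comparison.csv",
               seed, cfg_hash)
    _write_csv(pd.DataFrame(param_rows), out / "model_parameters.csv",
               seed, cfg_hash)
    _write_csv(pd.DataFrame(optima_rows), out / "optima.csv", seed, cfg_hash)
    tick("models")

    # ---------------- PGLS ----------------
    pgls_rows = []
    if "total_spur_mm" in table.columns and table["total_spur_mm"].notna().sum() >= 10:
        spur = TraitVector(table["total_spur_mm"].dropna(), name="total_spur_mm")
        log_spur = transform(spur, "log")
        cov = pd.DataFrame({"log_total_spur": log_spur.values})
        for resp_name, model_id in (("volume_ul", "log_volume~syndrome+log_total_spur"),
                                    ("nsp_pct", "logit_nsp~syndrome+log_total_spur")):
            if resp_name not in traits:
                continue
            fit = pgls_fit(traits[resp_name], tree, covariates=cov,
                           syndromes=syndromes)
            for term in fit.coefficients.index:
                pgls_rows.append({
                    "model": model_id, "term": term,
                    "coefficient": round(float(fit.coefficients[term]), 4),
                    "se": round(float(fit.standard_errors[term]), 4),
                    "t": round(float(fit.t_values[term]), 3),
                    "p": float(fit.p_values[term]),
                    "lambda": fit.lambda_hat, "aicc": round(fit.aicc, 2),
                    "n": fit.n,
                })
    _write_csv(pd.DataFrame(pgls_rows), out / "pgls_reports.csv", seed, cfg_hash)
    tick("pgls")

    # ---------------- multivariate ----------------
    cluster_vars = nectar_vars
    D = euclidean_distance_matrix(cluster_vars, standardized=True)
    dendro = upgma(D)
    syn_sub = syndromes.subset(list(cluster_vars.index))
    Dsyn = syndrome_distance_matrix(syn_sub)
    r, p = mantel_test(D, Dsyn.loc[D.index, D.index], n_perm=n_perm, seed=seed)
    lam_hat, lrt, lam_p = dendrogram_lambda_signal(dendro, syn_sub)
    mv = {
        "mantel": {"r": r, "p": p, "n_perm": n_perm},
        "dendrogram_lambda": {"lambda": lam_hat, "lrt": lrt, "p": lam_p},
        "dendrogram_newick": dendro.to_newick().strip(),
        "clustering_variables": list(cluster_vars.columns),
        "aa_pca_variance_explained": (
            aa_res.variance_explained.round(6).to_dict() if aa_res else None),
        "nectar_pca_variance_explained": (
            nectar_res.variance_explained.round(6).to_dict() if nectar_res else None),
        "seed": seed, "config": cfg_hash,
    }
    (out / "multivariate_report.json").write_text(json.dumps(mv, indent=2))
    tick("multivariate")

    log = {
        "package": "nectarevol", "version": __version__,
        "seed": seed, "config_hash": cfg_hash, "config": cfg,
        "n_species": tree.n_tips, "crown_age": tree.crown_age,
        "mk_rate": mk_fit.rate, "validation": report,
        "timings_s": timings,
        "versions": {m.__name__: m.__version__
                     for m in (np, pd)},
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return {"out_dir": str(out), "reports": list(REPORT_FILES),
            "validation": report, "mantel": mv["mantel"],
            "dendrogram_lambda": mv["dendrogram_lambda"]}
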