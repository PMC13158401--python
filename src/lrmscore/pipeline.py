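"""End-to-end orchestration: simulate/load -> prioritize -> score -> evaluate
-> robustness -> survival, with train-only fitting of standardization stats,
imputation references, penalty strength and cut-offs, and a deterministic
machine-readable report bundle.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    LEAKAGE_SAFE,
    PAPER_FAITHFUL,
    CohortTable,
    impute_stratified_median,
    read_cohort,
    split_train_test,
    standardize,
    write_cohort,
)
from .markers import default_panel
from .prioritize import (
    default_lambda_grid,
    fit_l1_logistic,
    lasso_path,
    logistic_predict,
    merge_rankings,
    pca_contribution,
    refit_ridge_logistic,
    select_lambda_cv,
)
from .robustness import bootstrap_auroc, mc_perturbation, repeated_splits
from .scoring import YOUDEN_ON_TOTAL, build_additive_model, score_cohort
from .simulate import generate_cohort, paper_like_config
from .stats import auroc, confusion_metrics, delong_compare, univariate_marker_stats
from .survival import (
    cox_hr_binary,
    km_estimate,
    logrank_hr_approx,
    median_ratio_bootstrap,
    stratify_by_median,
    weighted_logrank,
)

DEFAULT_VARIANTS = (
    "hybrid_with_afp",
    "hybrid_without_afp",
    "hybrid_fixed_afp",
    "prism",
)


@dataclass
class RunConfig:
    input_path: str | None = None
    profile: str | None = "paper_like"
    variants: tuple[str, ...] = DEFAULT_VARIANTS
    threshold_source: str = YOUDEN_ON_TOTAL
    seed: int = 42
    train_fraction: float = 0.8
    stratified: bool = True
    bootstrap_b: int = 1000
    mc_iters: int = 500
    mc_noise_levels: tuple[float, ...] = (0.05, 0.10, 0.20)
    mc_noise_law: str = "uniform"
    n_splits: int = 200
    lambda_strategy: str = "cv"  # "cv" for the reported model; splits use fixed fraction
    split_lambda_fraction: float | None = None
    q_contributions: int = 5
    survival_strata: tuple[tuple[int, str], ...] = (
        (1, "cd9_cd133_2_per_ml"),
        (0, "cd81_cd133_2_per_ml"),
    )

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class ReportBundle:
    config: RunConfig
    cohort: CohortTable
    marker_summary: pd.DataFrame
    prioritization: pd.DataFrame
    lasso_path_frame: pd.DataFrame
    evaluation: dict
    score_models: dict
    scorecards: dict
    robustness: dict
    per_split_aurocs: pd.DataFrame
    survival: dict


def _load_cohort(config: RunConfig) -> CohortTable:
    if config.input_path is not None:
        return read_cohort(config.input_path, default_panel())
    if config.profile == "paper_like":
        return generate_cohort(paper_like_config(seed=config.seed))
    raise ValueError(f"unknown profile {config.profile!r}")


def run_full_analysis(config: RunConfig) -> ReportBundle:
    """Execute every stage in fixed order; all randomness derives from
    ``config.seed`` with fixed offsets, so identical configs give identical
    numerical results."""
    cohort = _load_cohort(config)

    # --- split, impute, standardize (train-fitted, applied to test) -------
    train, test = split_train_test(
        cohort, config.train_fraction, seed=config.seed, stratified=config.stratified
    )
    train_i = impute_stratified_median(train, PAPER_FAITHFUL)
    test_i = impute_stratified_median(test, LEAKAGE_SAFE, reference=train_i)
    ztrain, zstats = standardize(train_i)
    ztest, _ = standardize(test_i, zstats)
    full_i = impute_stratified_median(cohort, PAPER_FAITHFUL)

    # --- univariate panel (native units, full cohort) ----------------------
    marker_summary = univariate_marker_stats(cohort)

    # --- prioritization ----------------------------------------------------
    X = ztrain.markers.to_numpy(float)
    y = train_i.label.astype(float)
    names = train_i.marker_names
    if config.lambda_strategy == "cv":
        lam = select_lambda_cv(X, y, seed=config.seed)
    else:
        lam = config.split_lambda_fraction * default_lambda_grid(X, y, 1, 1.0)[0]
    l1 = fit_l1_logistic(X, y, lam, names, tol=1e-7)
    grid = default_lambda_grid(X, y, n_points=30, ratio=1e-3)
    path = lasso_path(X, y, grid, names)
    contrib = pca_contribution(X, K=4, marker_names=names)
    prior = merge_rankings(l1, contrib, q=config.q_contributions)
    path_frame = pd.DataFrame(path.coefs, columns=names)
    path_frame.insert(0, "lambda", path.lambdas)

    # --- hybrid logistic evaluation per variant panel ----------------------
    evaluation: dict = {"lambda": lam, "hybrid": {}, "additive": {}, "delong": {}}
    hybrid_probs: dict[str, np.ndarray] = {}
    from .scoring import _panel_for_variant  # shared panel definitions

    for variant in config.variants:
        panel = _panel_for_variant(variant)
        cols = [names.index(m) for m in panel]
        refit = refit_ridge_logistic(X[:, cols], y, panel)
        p_test = logistic_predict(refit, ztest.markers.to_numpy(float)[:, cols])
        hybrid_probs[variant] = p_test
        evaluation["hybrid"][variant] = {
            "test_auroc": auroc(p_test, test_i.label),
            "coefficients": dict(zip(panel, refit.coef.tolist())),
            "intercept": refit.intercept,
        }

    if "hybrid_with_afp" in hybrid_probs and "hybrid_without_afp" in hybrid_probs:
        d = delong_compare(
            hybrid_probs["hybrid_with_afp"], hybrid_probs["hybrid_without_afp"], test_i.label
        )
        evaluation["delong"]["hybrid_with_vs_without_afp"] = {
            "auroc_a": d.auroc_a, "auroc_b": d.auroc_b, "z": d.z, "p": d.p,
        }

    # --- additive score models ---------------------------------------------
    score_models: dict = {}
    scorecards: dict = {}
    units = {s.name: s.units for s in cohort.specs}
    for variant in config.variants:
        model = build_additive_model(train_i, variant, config.threshold_source)
        score_models[variant] = model
        scorecards[variant] = model.scorecard(units)
        sc_test = score_cohort(model, test_i)
        sc_full = score_cohort(model, full_i)
        conf = confusion_metrics(sc_full["predicted"], full_i.label)
        evaluation["additive"][variant] = {
            "threshold": model.threshold,
            "cutoffs": {c.marker: c.cutoff for c in model.cutoffs},
            "test_auroc": auroc(sc_test["points"], test_i.label),
            "full_auroc": auroc(sc_full["points"], full_i.label),
            "sensitivity": conf.sensitivity,
            "specificity": conf.specificity,
            "ppv": conf.ppv,
            "npv": conf.npv,
            "chi2": conf.chi2,
            "chi2_p": conf.p,
        }

    # --- robustness ---------------------------------------------------------
    rob_variant = "prism" if "prism" in score_models else config.variants[0]
    rob_model = score_models[rob_variant]
    sc_full = score_cohort(rob_model, full_i)
    boot = bootstrap_auroc(
        sc_full["points"].to_numpy(), full_i.label, config.bootstrap_b, seed=config.seed + 1
    )
    mc = mc_perturbation(
        full_i, rob_model, config.mc_noise_levels, config.mc_iters,
        seed=config.seed + 2, noise_law=config.mc_noise_law,
    )
    splits = repeated_splits(
        cohort, config.n_splits, config.train_fraction, base_seed=config.seed + 3,
        lambda_fraction=config.split_lambda_fraction,
    )
    robustness = {
        "variant": rob_variant,
        "bootstrap": {
            "B": boot.n_boot, "mean_auroc": boot.mean,
            "ci_low": boot.ci_low, "ci_high": boot.ci_high,
        },
        "mc": [asdict(level) for level in mc],
        "splits": {
            "n_splits": splits.n_splits,
            "hybrid": splits.summary().loc["hybrid"].to_dict(),
            "additive": splits.summary().loc["additive"].to_dict(),
            "selection_frequency": splits.selection_frequency.to_dict(),
            "wilcoxon_p": splits.wilcoxon_p,
            "paired_t_p": splits.paired_t_p,
            "redraws": splits.redraws,
        },
    }
    per_split = pd.DataFrame(
        {"hybrid_auroc": splits.hybrid_aurocs, "additive_auroc": splits.additive_aurocs}
    )

    # --- survival ------------------------------------------------------------
    survival: dict = {}
    if cohort.has_survival:
        for cls, marker in config.survival_strata:
            sub_idx = np.flatnonzero(cohort.label == cls)
            sub = full_i.subset(sub_idx)
            group = stratify_by_median(sub, marker)
            t, e = sub.os_days, sub.event
            fits = {
                g: km_estimate(t[group == g], e[group == g]) for g in (0, 1)
            }
            lr = weighted_logrank(t, e, group, "logrank")
            gb = weighted_logrank(t, e, group, "gehan")
            cox = cox_hr_binary(t, e, group)
            mr = median_ratio_bootstrap(t, e, group, n_boot=1000, seed=config.seed + 4)
            key = f"{'icca' if cls == 1 else 'hcc'}_{marker}"
            survival[key] = {
                "n_above": int(group.sum()),
                "n_at_or_below": int((1 - group).sum()),
                "median_os_above": fits[1].median_os,
                "median_os_at_or_below": fits[0].median_os,
                "median_ratio": mr.ratio,
                "median_ratio_ci": [mr.ci_low, mr.ci_high],
                "logrank_chi2": lr.chi2, "logrank_p": lr.p,
                "gehan_chi2": gb.chi2, "gehan_p": gb.p,
                "cox_hr": cox.hr, "cox_ci": [cox.ci_low, cox.ci_high],
                "cox_log_hr_se": cox.se,
                "oe_ratio_hr": logrank_hr_approx(t, e, group),
            }

    return ReportBundle(
        config=config,
        cohort=cohort,
        marker_summary=marker_summary,
        prioritization=prior.table,
        lasso_path_frame=path_frame,
        evaluation=evaluation,
        score_models=score_models,
        scorecards=scorecards,
        robustness=robustness,
        per_split_aurocs=per_split,
        survival=survival,
    )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_report(bundle: ReportBundle, outdir: str, overwrite: bool = False) -> dict:
    """Write the bundle as CSV/JSON artifacts with a content-hash manifest.

    Filenames are deterministic; existing files raise unless ``overwrite``.
    The manifest carries the run config, seeds and package version but no
    timestamps, so repeated identical runs are hash-stable.
    """
    os.makedirs(outdir, exist_ok=True)

    def path_for(name: str) -> str:
        p = os.path.join(outdir, name)
        if os.path.exists(p) and not overwrite:
            raise FileExistsError(f"{p} exists (pass overwrite=True)")
        return p

    written: list[str] = []

    def put_csv(name: str, df: pd.DataFrame, index: bool = True) -> None:
        p = path_for(name)
        df.to_csv(p, index=index)
        written.append(name)

    def put_json(name: str, obj) -> None:
        p = path_for(name)
        with open(p, "w") as fh:
            json.dump(obj, fh, indent=2, default=_jsonable)
        written.append(name)

    def put_text(name: str, text: str) -> None:
        p = path_for(name)
        with open(p, "w") as fh:
            fh.write(text)
        written.append(name)

    write_cohort(bundle.cohort, path_for("cohort.csv"))
    written.append("cohort.csv")
    put_csv("marker_summary.csv", bundle.marker_summary)
    put_csv("prioritization.csv", bundle.prioritization)
    put_csv("lasso_path.csv", bundle.lasso_path_frame, index=False)
    put_json("evaluation.json", bundle.evaluation)
    for variant, model in bundle.score_models.items():
        put_text(f"scoremodel_{variant}.json", model.to_json())
        put_text(f"scorecard_{variant}.txt", bundle.scorecards[variant])
    put_json("robustness.json", bundle.robustness)
    put_csv("per_split_aurocs.csv", bundle.per_split_aurocs, index=False)
    if bundle.survival:
        put_json("survival.json", bundle.survival)

    manifest = {
        "package_version": __version__,
        "config": bundle.config.to_dict(),
        "artifacts": {name: _sha256(os.path.join(outdir, name)) for name in sorted(written)},
    }
    p = os.path.join(outdir, "manifest.json")
    if os.path.exists(p) and not overwrite:
        raise FileExistsError(f"{p} exists (pass overwrite=True)")
    with open(p, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")
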