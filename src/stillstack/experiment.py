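"""End-to-end experiment driver.

Reproduces the study workflow on synthetic registry data: generate ->
preprocess -> consensus ranking (both classification tasks) -> feature-set
construction -> stacked ensemble vs. standalone baselines per feature set
-> two-step cross-validated evaluation, calibration and permutation
significance.  Every run writes a manifest (config hash, seeds, versions)
sufficient to reproduce all outputs bit-identically.

Scale notes live in docs/methods.md: the model-development table is a
case-control style sample (enriched stillbirth rate) so that the
during-delivery minority is populated at desk-scale n, while the
prevalence-true table is used for the registry-statistics block.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ensemble import (
    CLASSIFIER_IDS,
    SEConfig,
    fit_layer,
    fit_se,
    make_classifier,
    predict_se,
)
from .evaluation import (
    METRIC_NAMES,
    _binary_report,
    isotonic_calibrate,
    kfold_cv,
    permutation_significance,
    roc_pr_auc,
)
from .hierarchy import TwoStepConfig
from .preprocess import DesignMatrix, DesignTransform, Imputer, balance_sample, remove_high_missing
from .ranking import (
    build_feature_set,
    build_mft,
    cluster_features,
    coef_importance,
    full_feature_set,
    gini_importance,
    mda_importance,
    normalize_mft,
    rank_clusters,
    select_k_candidates,
)
from .schema import (
    BEFORE,
    DURING,
    GeneratorConfig,
    OUTCOME1,
    OUTCOME2,
    STILLBIRTH,
    compact_schema,
    default_schema,
)
from .synth import generate_registry, inject_missing, missingness_report, write_registry

log = logging.getLogger("stillstack")


class StageError(RuntimeError):
    """An experiment stage failed; the message carries the stage tag."""


@dataclass
class ExperimentConfig:
    """Desk-scale experiment configuration (all seeds explicit).

    ``n_stats`` rows are generated at the registry-true prevalence for the
    statistics block; ``n_model`` rows at ``model_rate`` form the
    case-control model-development table.
    """

    n_stats: int = 50_000
    n_model: int = 20_000
    stillbirth_rate: float = 0.00396
    model_rate: float = 0.2751
    seed: int = 0
    k_min: int = 2
    k_max: int = 10
    n_candidates: int = 3
    mda_repeats: int = 5
    cv_folds: int = 5
    permutation_repeats: int = 200
    balance_ratio: float | None = 1.0
    stacking: str = "oof"
    n_rounds: int = 10
    holdout_fraction: float = 0.25
    schema_name: str = "default"  # "default" (50 features) or "compact" (14)
    make_plots: bool = False

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _holdout_split(n: int, fraction: float, strat: np.ndarray, seed: int):
    from sklearn.model_selection import train_test_split

    idx = np.arange(n)
    tr, te = train_test_split(idx, test_size=fraction, stratify=strat, random_state=seed)
    return np.sort(tr), np.sort(te)


def consensus_mft(dm_fit: DesignMatrix, dm_eval: DesignMatrix, seed: int, mda_repeats: int = 5):
    """Fit the five base classifiers and assemble the meta feature table:
    {DT, GBC, RF} x {GI, MDA} and {LR, SVM} x {MC, MDA}, MDA computed on
    held-out rows, columns min-max normalized."""
    bank = fit_layer(dm_fit.X, dm_fit.y, seed=seed)
    vectors = []
    for cid in ("DT", "GBC", "RF"):
        vectors.append(gini_importance(bank.models[cid], dm_fit, classifier=cid))
    for cid in ("LR", "SVM"):
        vectors.append(coef_importance(bank.models[cid], dm_fit, classifier=cid))
    for i, cid in enumerate(CLASSIFIER_IDS):
        vectors.append(
            mda_importance(
                bank.models[cid], dm_eval, n_repeats=mda_repeats, seed=seed + i, classifier=cid
            )
        )
    return normalize_mft(build_mft(vectors))


def _rank_task(mft: pd.DataFrame, cfg: ExperimentConfig, seed: int) -> dict:
    candidates = select_k_candidates(mft, cfg.k_min, cfg.k_max, cfg.n_candidates, seed=seed)
    clusterings = {}
    for k, sil in candidates:
        c = rank_clusters(cluster_features(mft, k, seed=seed))
        clusterings[k] = dataclasses.replace(c, mean_silhouette=sil)
    two = rank_clusters(cluster_features(mft, 2, seed=seed))
    return {"candidates": candidates, "clusterings": clusterings, "k2": two}


def _evaluate_classifiers(
    dm_train: DesignMatrix, dm_test: DesignMatrix, cfg: ExperimentConfig, seed: int
) -> dict[str, dict]:
    """Standalone base classifiers and the stacked ensemble on one split."""
    rows = {}
    se_cfg = SEConfig(stacking=cfg.stacking, n_rounds=cfg.n_rounds)
    bank = fit_layer(dm_train.X, dm_train.y, seed=seed)
    for cid in CLASSIFIER_IDS:
        pred = bank.models[cid].predict(dm_test.X)
        if hasattr(bank.models[cid], "predict_proba"):
            score = bank.models[cid].predict_proba(dm_test.X)[:, 1]
        else:
            score = bank.models[cid].decision_function(dm_test.X)
        rows[cid] = _binary_report(dm_test.y, pred, score)
    se = fit_se(dm_train.X, dm_train.y, se_cfg, seed=seed)
    labels, scores = predict_se(se, dm_test.X)
    rows["SE"] = _binary_report(dm_test.y, labels, scores)
    return rows


def run_experiment(config: ExperimentConfig, outdir) -> dict:
    """Execute the full workflow; artifacts are written under ``outdir``
    and the collected results returned as a dict (also ``metrics.json``).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "init"
    try:
        # ------------------------------------------------------ statistics
        stage = "generate"
        schema = default_schema() if config.schema_name == "default" else compact_schema()
        stats_cfg = GeneratorConfig(
            n_total=config.n_stats,
            schema=schema,
            stillbirth_rate=config.stillbirth_rate,
            seed=config.seed,
        )
        stats_table = inject_missing(generate_registry(stats_cfg), schema, seed=config.seed)
        rep = missingness_report(stats_table)
        results["registry_stats"] = {
            "n": config.n_stats,
            "stillbirth_fraction": float(
                (stats_table[OUTCOME1] == STILLBIRTH).mean()
            ),
            "row_any_missing": rep["row_any_missing"],
            "max_feature_missing": max(rep["per_feature"].values()),
        }
        del stats_table

        model_cfg = GeneratorConfig(
            n_total=config.n_model,
            schema=schema,
            stillbirth_rate=config.model_rate,
            seed=config.seed + 1,
        )
        table = inject_missing(generate_registry(model_cfg), schema, seed=config.seed + 1)
        write_registry(table.head(200), out / "registry_sample.csv")

        # ------------------------------------------------------ preprocess
        stage = "preprocess"
        table, surviving, removed = remove_high_missing(table, schema)
        results["removed_features"] = removed
        imputer = Imputer(surviving).fit(table)
        filled, _ = imputer.transform(table)
        transform = DesignTransform(surviving).fit(filled)

        strat = np.where(
            (table[OUTCOME1] == STILLBIRTH).to_numpy(),
            table[OUTCOME2].astype(str).to_numpy(),
            "livebirth",
        )
        tr, te = _holdout_split(len(table), config.holdout_fraction, strat, config.seed)

        y1 = (table[OUTCOME1] == STILLBIRTH).to_numpy().astype(int)
        dm_all = transform.transform(filled, y=y1)
        dm_tr, dm_te = dm_all.subset_rows(tr), dm_all.subset_rows(te)
        dm_tr_bal = (
            balance_sample(dm_tr, config.balance_ratio, seed=config.seed)
            if config.balance_ratio is not None
            else dm_tr
        )

        # --------------------------------------------------------- ranking
        stage = "ranking"
        log.info("ranking: task 1 (livebirth vs stillbirth)")
        mft1 = consensus_mft(dm_tr_bal, dm_te, seed=config.seed, mda_repeats=config.mda_repeats)
        mft1.to_csv(out / "mft_step1.csv")
        rank1 = _rank_task(mft1, config, config.seed)

        log.info("ranking: task 2 (before vs during delivery)")
        known = table[OUTCOME2].isin([BEFORE, DURING]).to_numpy()
        y2 = (table[OUTCOME2] == DURING).to_numpy().astype(int)
        dm2 = transform.transform(filled, y=y2)
        k_tr = np.intersect1d(tr, np.flatnonzero(known))
        k_te = np.intersect1d(te, np.flatnonzero(known))
        dm2_tr = balance_sample(dm2.subset_rows(k_tr), 3.0, seed=config.seed)
        dm2_te = dm2.subset_rows(k_te)
        mft2 = consensus_mft(dm2_tr, dm2_te, seed=config.seed + 7, mda_repeats=config.mda_repeats)
        mft2.to_csv(out / "mft_step2.csv")
        rank2 = _rank_task(mft2, config, config.seed + 7)

        results["silhouette_sweep"] = {
            "step1": rank1["candidates"],
            "step2": rank2["candidates"],
        }

        stage = "feature_sets"
        codes = [f.code for f in surviving]
        ffs = full_feature_set(codes)
        fsc22 = build_feature_set(
            [(rank1["k2"], [1]), (rank2["k2"], [1])], name="FSC22"
        )
        k1 = rank1["candidates"][0][0]
        k2 = rank2["candidates"][0][0]
        best1, best2 = rank1["clusterings"][k1], rank2["clusterings"][k2]
        fsc_best = build_feature_set(
            [
                (best1, list(range(1, max(best1.k, 2)))),  # drop only the worst cluster
                (best2, list(range(1, max(best2.k, 2)))),
            ],
            name=f"FSC{k1}{k2}",
        )
        feature_sets = [ffs, fsc22]
        if fsc_best.name != fsc22.name:  # best-K pair may coincide with (2,2)
            feature_sets.append(fsc_best)
        with open(out / "feature_sets.json", "w") as fh:
            json.dump(
                {
                    fs.name: {"members": list(fs.members), "provenance": list(fs.provenance)}
                    for fs in feature_sets
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        results["feature_sets"] = {fs.name: len(fs.members) for fs in feature_sets}

        # ------------------------------------------------------ comparison
        stage = "comparison"
        comparison = {}
        for fs in feature_sets:
            sub_schema = tuple(f for f in surviving if f.code in fs.members)
            sub_transform = DesignTransform(sub_schema).fit(filled)
            dm_fs = sub_transform.transform(filled, y=y1)
            d_tr, d_te = dm_fs.subset_rows(tr), dm_fs.subset_rows(te)
            if config.balance_ratio is not None:
                d_tr = balance_sample(d_tr, config.balance_ratio, seed=config.seed)
            comparison[fs.name] = _evaluate_classifiers(d_tr, d_te, config, config.seed)
        comp_rows = []
        for fs_name, rows in comparison.items():
            for cid, metrics in rows.items():
                comp_rows.append({"feature_set": fs_name, "classifier": cid, **metrics})
        comp_df = pd.DataFrame(comp_rows)
        comp_df.to_csv(out / "comparison.csv", index=False, float_format="%.6f")
        results["comparison"] = comparison

        # --------------------------------------------------------- twostep
        stage = "two_step_cv"
        ts_cfg = TwoStepConfig(
            se=SEConfig(stacking=config.stacking, n_rounds=config.n_rounds),
            step1_features=list(fsc_best.members),
            step2_features=list(fsc_best.members),
            balance_ratio=config.balance_ratio,
        )
        cv = kfold_cv(table, surviving, ts_cfg, k=config.cv_folds, seed=config.seed)
        results["two_step_cv_mean"] = cv["mean"]

        stage = "curves_calibration"
        se = fit_se(dm_tr_bal.X, dm_tr_bal.y, SEConfig(stacking=config.stacking), seed=config.seed)
        _, se_scores = predict_se(se, dm_te.X)
        curves = roc_pr_auc(se_scores, dm_te.y)
        pd.DataFrame(curves["roc_points"], columns=["fpr", "tpr"]).to_csv(
            out / "roc_curve.csv", index=False, float_format="%.6f"
        )
        pd.DataFrame(curves["pr_points"], columns=["recall", "precision"]).to_csv(
            out / "pr_curve.csv", index=False, float_format="%.6f"
        )
        calib = isotonic_calibrate(se_scores, dm_te.y)
        results["se_holdout"] = {
            "auc": curves["auc"],
            "calibration_brier": calib.brier,
        }

        stage = "significance"
        def _fit_score(X_tr, y_tr, X_te):
            m = fit_se(X_tr, y_tr, SEConfig(stacking="direct", n_rounds=config.n_rounds),
                       seed=config.seed)
            return predict_se(m, X_te)[1]

        # subsample for the permutation null so repeats stay tractable
        rng = np.random.default_rng(config.seed)
        sub = rng.choice(len(dm_tr_bal.X), size=min(400, len(dm_tr_bal.X)), replace=False)
        sig = permutation_significance(
            _fit_score,
            dm_tr_bal.X[sub],
            dm_tr_bal.y[sub],
            dm_te.X[: min(800, len(dm_te.X))],
            dm_te.y[: min(800, len(dm_te.X))],
            n_repeats=config.permutation_repeats,
            seed=config.seed,
        )
        results["significance"] = {
            "observed_auc": sig.observed_auc,
            "p_value": sig.p_value,
            "n_repeats": config.permutation_repeats,
        }

        if config.make_plots:
            stage = "plots"
            from . import plots

            plots.ranking_bars(mft1, out / "ranking_step1.png")
            plots.ranking_bars(mft2, out / "ranking_step2.png")
            plots.roc_plot(curves["roc_points"], curves["auc"], out / "roc.png")
            plots.pr_plot(curves["pr_points"], out / "pr.png")

        stage = "manifest"
        _write_results(results, config, out)
        return results
    except Exception as err:  # re-raise with the stage tag; keep partial output
        if isinstance(err, StageError):
            raise
        try:
            _write_results(results, config, out, partial=stage)
        except Exception:
            pass
        raise StageError(f"[stage:{stage}] {err}") from err


def _write_results(results: dict, config: ExperimentConfig, out: Path, partial: str | None = None):
    payload = json.dumps(results, indent=1, sort_keys=True, default=_jsonable)
    (out / "metrics.json").write_text(payload)
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "package_version": __version__,
        "partial_stage": partial,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
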