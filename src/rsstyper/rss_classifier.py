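"""Subtype classification on gene-module median scores.

Expression is reduced to one feature per gene module — the median (optionally
gene-standardised) log2 expression over the module's genes present in the
input — and a gradient-boosted multiclass model is trained on those features
with stratified cross-validation. Medians tolerate partial gene coverage,
which is what makes the classifier portable across platforms measuring
different gene panels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .datatypes import ExpressionMatrix, GeneModuleSet

__all__ = [
    "ModuleScoreMatrix",
    "SubtypeModel",
    "module_medians",
    "train_subtype_model",
    "predict_subtypes",
    "DEFAULT_HYPERPARAMS",
]

# Shallow trees and a moderate number of rounds: the feature space is a
# handful of module medians, so capacity needs are small.
DEFAULT_HYPERPARAMS = {
    "max_depth": 3,
    "eta": 0.1,
    "num_boost_round": 200,
    "subsample": 1.0,
    "tree_method": "hist",
}


@dataclass
class ModuleScoreMatrix:
    """Samples x modules median scores with per-module gene coverage.

    ``coverage`` is the fraction of each module's genes present in the scored
    matrix; modules under the coverage floor hold NaN scores and are listed in
    ``missing``. ``gene_mean``/``gene_sd`` record the standardisation applied
    (None when scores are raw medians).
    """

    scores: pd.DataFrame
    coverage: pd.Series
    module_set: GeneModuleSet
    gene_mean: pd.Series | None = None
    gene_sd: pd.Series | None = None
    missing: list[str] = field(default_factory=list)


def module_medians(
    m: ExpressionMatrix,
    modules: GeneModuleSet,
    min_coverage: float = 0.5,
    standardise: bool = True,
    gene_stats: tuple[pd.Series, pd.Series] | None = None,
) -> ModuleScoreMatrix:
    """Median module expression per sample.

    With ``standardise`` (default) genes are z-scored before taking medians,
    either with the cohort's own per-gene mean/sd or with externally supplied
    ``gene_stats`` (e.g. frozen training statistics). Modules whose gene
    coverage in ``m`` falls below ``min_coverage`` get NaN scores and are
    flagged; an error is raised when no module meets the floor.
    """
    present = set(m.gene_ids)
    any_overlap = any(set(g) & present for g in modules.modules.values())
    if not any_overlap:
        raise ValueError("no gene overlap between the matrix and the modules")

    values = m.values
    gene_mean = gene_sd = None
    if standardise:
        if gene_stats is not None:
            gene_mean, gene_sd = gene_stats
            common = values.index.intersection(gene_mean.index)
            values = values.loc[common]
            gene_mean = gene_mean.loc[common]
            gene_sd = gene_sd.loc[common]
        else:
            gene_mean = values.mean(axis=1)
            gene_sd = values.std(axis=1, ddof=1)
        safe_sd = gene_sd.replace(0.0, 1.0)
        values = values.sub(gene_mean, axis=0).div(safe_sd, axis=0)

    available = set(values.index)
    scores: dict[str, np.ndarray] = {}
    coverage: dict[str, float] = {}
    missing: list[str] = []
    for mid in modules.module_ids:
        genes = [g for g in modules.modules[mid] if g in available]
        coverage[mid] = len(genes) / len(modules.modules[mid])
        if coverage[mid] >= min_coverage and genes:
            scores[mid] = values.loc[genes].median(axis=0).to_numpy()
        else:
            scores[mid] = np.full(m.n_samples, np.nan)
            missing.append(mid)
    if len(missing) == len(modules.modules):
        raise ValueError("no module meets the coverage floor")
    score_df = pd.DataFrame(scores, index=m.sample_ids)[modules.module_ids]
    return ModuleScoreMatrix(
        scores=score_df,
        coverage=pd.Series(coverage, name="coverage")[modules.module_ids],
        module_set=modules,
        gene_mean=gene_mean,
        gene_sd=gene_sd,
        missing=missing,
    )


@dataclass
class SubtypeModel:
    """Frozen module definitions plus the trained boosted multiclass model.

    Holds everything prediction needs: the module set, the booster, the class
    labels, the per-gene standardisation statistics and the training median of
    each module score (used to impute modules missing from a new cohort), and
    the cross-validation metrics recorded at training time.
    """

    module_set: GeneModuleSet
    booster: xgb.Booster
    classes: list
    cv_metrics: pd.DataFrame
    config: dict
    gene_mean: pd.Series | None
    gene_sd: pd.Series | None
    score_medians: pd.Series

    # -- persistence ---------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Serialise to a single JSON archive (metadata + booster dump)."""
        raw = json.loads(bytes(self.booster.save_raw(raw_format="json")))
        payload = {
            "classes": list(self.classes),
            "config": self.config,
            "cv_metrics": self.cv_metrics.to_dict(orient="list"),
            "cv_columns": list(self.cv_metrics.columns),
            "gene_mean": None if self.gene_mean is None else self.gene_mean.to_dict(),
            "gene_sd": None if self.gene_sd is None else self.gene_sd.to_dict(),
            "score_medians": self.score_medians.to_dict(),
            "module_set": {
                "modules": self.module_set.modules,
                "unassigned": self.module_set.unassigned,
                "provenance": self.module_set.provenance,
            },
            "booster": raw,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, default=str)

    @classmethod
    def load(cls, path: str | Path) -> "SubtypeModel":
        payload = json.loads(Path(path).read_text())
        booster = xgb.Booster()
        booster.load_model(bytearray(json.dumps(payload["booster"]).encode()))
        ms = payload["module_set"]
        module_ids = list(payload["score_medians"].keys())
        return cls(
            module_set=GeneModuleSet(ms["modules"], ms["unassigned"], ms["provenance"]),
            booster=booster,
            classes=payload["classes"],
            cv_metrics=pd.DataFrame(payload["cv_metrics"])[payload["cv_columns"]],
            config=payload["config"],
            gene_mean=None
            if payload["gene_mean"] is None
            else pd.Series(payload["gene_mean"]),
            gene_sd=None if payload["gene_sd"] is None else pd.Series(payload["gene_sd"]),
            score_medians=pd.Series(payload["score_medians"])[module_ids],
        )


def _fit_booster(
    X: np.ndarray, y: np.ndarray, n_classes: int, seed: int, hyperparams: dict
) -> xgb.Booster:
    params = {
        "objective": "multi:softprob",
        "num_class": n_classes,
        "max_depth": hyperparams["max_depth"],
        "eta": hyperparams["eta"],
        "subsample": hyperparams["subsample"],
        "tree_method": hyperparams["tree_method"],
        "nthread": 1,
        "seed": int(seed) % (2**31),
        "verbosity": 0,
    }
    dtrain = xgb.DMatrix(X, label=y)
    return xgb.train(params, dtrain, num_boost_round=hyperparams["num_boost_round"])


def train_subtype_model(
    scores: ModuleScoreMatrix,
    labels,
    folds: int = 5,
    seed: int = 0,
    hyperparams: dict | None = None,
) -> SubtypeModel:
    """Stratified k-fold CV then a final refit on all samples.

    Records per-fold accuracy and per-class one-vs-rest ROC AUC, then refits
    on the full cohort. Deterministic under a fixed seed (single-threaded
    boosting). Classes with fewer samples than folds raise an error naming
    the class.
    """
    hyperparams = {**DEFAULT_HYPERPARAMS, **(hyperparams or {})}
    y_raw = pd.Series(np.asarray(labels), index=scores.scores.index)
    # native python class labels so the JSON archive round-trips losslessly
    classes = sorted(
        c.item() if isinstance(c, np.generic) else c for c in pd.unique(y_raw)
    )
    counts = y_raw.value_counts()
    thin = [c for c in classes if counts[c] < folds]
    if thin:
        raise ValueError(f"classes with fewer than {folds} samples: {thin}")
    class_index = {c: i for i, c in enumerate(classes)}
    y = y_raw.map(class_index).to_numpy()
    X = scores.scores.to_numpy(dtype=float)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31))
    rows = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        booster = _fit_booster(X[tr], y[tr], len(classes), seed + fold, hyperparams)
        proba = booster.predict(xgb.DMatrix(X[te]))
        pred = proba.argmax(axis=1)
        row = {"fold": fold, "accuracy": float((pred == y[te]).mean())}
        for c, i in class_index.items():
            row[f"auc_{c}"] = float(roc_auc_score((y[te] == i).astype(int), proba[:, i]))
        rows.append(row)
    cv_metrics = pd.DataFrame(rows)

    booster = _fit_booster(X, y, len(classes), seed, hyperparams)
    return SubtypeModel(
        module_set=scores.module_set,
        booster=booster,
        classes=classes,
        cv_metrics=cv_metrics,
        config={
            "folds": folds,
            "seed": int(seed),
            "hyperparams": hyperparams,
            "min_coverage": 0.5,
            "standardised": scores.gene_mean is not None,
        },
        gene_mean=scores.gene_mean,
        gene_sd=scores.gene_sd,
        score_medians=scores.scores.median(axis=0, skipna=True),
    )


def predict_subtypes(
    model: SubtypeModel,
    m: ExpressionMatrix,
    min_coverage: float = 0.5,
    min_module_frac: float = 0.8,
    standardise: str = "training",
) -> pd.DataFrame:
    """Classify a cohort with a trained model.

    Module scores are computed exactly as at training time; by default genes
    are standardised with the frozen training statistics (``"cohort"``
    switches to the new cohort's own statistics, for cross-platform inputs
    whose absolute scale is not comparable). At least ``min_module_frac`` of
    the modules must reach ``min_coverage`` gene coverage; scores of the
    remaining modules are imputed with their training medians.

    Returns a DataFrame indexed by sample with ``label`` and one probability
    column per class; probabilities sum to 1, ties resolve to the first class
    in sorted order.
    """
    if standardise not in {"training", "cohort"}:
        raise ValueError("standardise must be 'training' or 'cohort'")
    use_training_stats = (
        standardise == "training" and model.gene_mean is not None
    )
    scores = module_medians(
        m,
        model.module_set,
        min_coverage=min_coverage,
        standardise=model.config.get("standardised", True),
        gene_stats=(model.gene_mean, model.gene_sd) if use_training_stats else None,
    )
    ok = scores.coverage >= min_coverage
    if ok.mean() < min_module_frac:
        failing = sorted(scores.coverage.index[~ok])
        raise ValueError(
            f"module coverage below {min_coverage} for too many modules: {failing}"
        )
    X = scores.scores.copy()
    for mid in scores.missing:
        X[mid] = model.score_medians[mid]
    X = X.fillna(pd.Series(model.score_medians))

    proba = model.booster.predict(xgb.DMatrix(X.to_numpy(dtype=float)))
    proba = proba / proba.sum(axis=1, keepdims=True)
    labels = [model.classes[i] for i in proba.argmax(axis=1)]
    out = pd.DataFrame(
        proba, index=m.sample_ids, columns=[f"prob_{c}" for c in model.classes]
    )
    out.insert(0, "label", labels)
    return out
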