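"""Leave-one-dataset-out evaluation and model comparison.

The evaluation contract is strict about leakage: the held-out cohort never
contributes to gene selection, feature weights, organ weights or penalty
selection — it is normalized with its own within-cohort pipeline (which uses
no labels) and then only scored.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .io import DatasetCollection
from .top import (
    TOPConfig,
    prepare_collection,
    prepare_dataset,
    predict_risk,
    train_top,
)

logger = logging.getLogger(__name__)


@dataclass
class EvalResult:
    """Per-left-out-dataset AUC rows plus per-organ summary."""

    rows: pd.DataFrame       # dataset_id, organ, auc, n_samples, n_positive, evaluable
    split_hash: str          # fingerprint of the LODO splits, for paired designs

    def organ_summary(self) -> pd.DataFrame:
        ok = self.rows[self.rows["evaluable"]]
        return ok.groupby("organ", as_index=False)["auc"].mean()

    @property
    def mean_auc(self) -> float:
        ok = self.rows[self.rows["evaluable"]]
        return float(ok["auc"].mean())


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve, Mann-Whitney form with half credit for ties."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) != 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    fpr, tpr, thr = roc_curve(np.asarray(labels).astype(int), scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def _split_hash(dataset_ids: list[str]) -> str:
    return hashlib.sha256("|".join(dataset_ids).encode()).hexdigest()[:16]


def lodo_evaluate(
    collection: DatasetCollection,
    config: TOPConfig | None = None,
    prepared: dict | None = None,
    de_cache: dict | None = None,
) -> EvalResult:
    """Leave-one-dataset-out evaluation of a training configuration.

    For each cohort d: train on the collection minus d, score d, compute its
    AUC.  Cohorts with a single outcome class are reported as non-evaluable
    rather than silently dropped.  Within-cohort normalization and per-cohort
    DE statistics may be passed in pre-computed (they are independent of the
    training pool), which makes repeated LODO sweeps cheap.
    """
    config = config or TOPConfig()
    trainable = collection.trainable()
    if trainable.k < 2:
        raise ValueError("LODO needs at least two trainable datasets")
    if prepared is None:
        prepared = prepare_collection(trainable, config.already_log, config.voom_span)
    if de_cache is None:
        de_cache = {}
    rows = []
    for held_out in trainable.dataset_ids:
        test_ds = collection.get(held_out)
        train_pool = trainable.drop(held_out)
        row = {
            "dataset_id": held_out,
            "organ": test_ds.organ,
            "n_samples": test_ds.n_samples,
            "n_positive": int(test_ds.y.sum()),
        }
        try:
            model = train_top(train_pool, config, prepared=prepared, de_cache=de_cache)
            test_prep = prepare_dataset(
                test_ds, config.already_log, config.voom_span, for_training=False
            )
            pred = predict_risk(model, test_prep.frame())
            row["auc"] = auc(pred["logit_score"].to_numpy(), test_ds.y)
            row["evaluable"] = True
        except ValueError as err:
            logger.info("dataset %s not evaluable: %s", held_out, err)
            row["auc"] = np.nan
            row["evaluable"] = False
        rows.append(row)
    frame = pd.DataFrame(rows)
    return EvalResult(rows=frame, split_hash=_split_hash(trainable.dataset_ids))


def compare_models(
    collection: DatasetCollection,
    specs: dict[str, TOPConfig],
    prepared: dict | None = None,
) -> pd.DataFrame:
    """Run several training configurations over identical LODO splits.

    Returns a paired table with one AUC column per configuration; the split
    fingerprint is asserted equal across configurations.
    """
    if len(specs) < 2:
        raise ValueError("need at least two configurations to compare")
    if prepared is None:
        first = next(iter(specs.values()))
        prepared = prepare_collection(
            collection.trainable(), first.already_log, first.voom_span
        )
    de_cache: dict = {}
    results = {}
    hashes = set()
    for name, config in specs.items():
        res = lodo_evaluate(collection, config, prepared=prepared, de_cache=de_cache)
        results[name] = res
        hashes.add(res.split_hash)
    if len(hashes) != 1:
        raise AssertionError("LODO splits differ between configurations")
    base = next(iter(results.values())).rows[["dataset_id", "organ"]].copy()
    for name, res in results.items():
        base[f"auc_{name}"] = res.rows["auc"].to_numpy()
    return base


def clinical_baseline(
    features: pd.DataFrame,
    labels: np.ndarray,
    eval_features: pd.DataFrame | None = None,
    eval_labels: np.ndarray | None = None,
):
    """Plain logistic regression on clinical covariates, with its AUC.

    A singular or separable design falls back to a ridge-stabilized fit with
    a warning.  Returns ``(params, scores, auc)`` where params includes the
    intercept first and scores are on the eval split (training split if no
    eval data given).
    """
    import statsmodels.api as sm

    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    Xc = sm.add_constant(X, has_constant="add")
    params = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            if np.isfinite(fit.params).all() and np.abs(fit.params).max() < 1e3:
                params = np.asarray(fit.params)
        except Exception:
            params = None
    if params is None:
        warnings.warn("singular or separable clinical design; ridge-stabilized fit")
        from sklearn.linear_model import LogisticRegression

        est = LogisticRegression(C=1e3, solver="lbfgs", max_iter=5000)
        est.fit(X, y)
        params = np.concatenate([est.intercept_, est.coef_[0]])
    if eval_features is None:
        Xe, ye = Xc, y
    else:
        Xe = sm.add_constant(np.asarray(eval_features, dtype=float), has_constant="add")
        ye = np.asarray(eval_labels).astype(int)
    scores = Xe @ params
    if len(np.unique(scores)) == 1:
        model_auc = 0.5
    else:
        model_auc = auc(scores, ye)
    return params, scores, model_auc


def group_risk_ttest(scores_a: np.ndarray, scores_b: np.ndarray) -> tuple[float, float]:
    """Welch two-sided t-test contrasting two groups of logit-scale scores."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two samples")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
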