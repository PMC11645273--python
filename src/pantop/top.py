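"""The transferable omics prediction (TOP) classifier.

A model is trained on a family of cohorts that cannot be batch-corrected
against each other (cohort and organ are confounded).  The pipeline is:

1. select a gene panel whose members shift consistently across all training
   cohorts (per-cohort moderated t -> z -> Stouffer combination, ranked by
   combined p-value; default panel size 50);
2. form all pairwise log-ratio features within the panel — differences of
   two genes' log expression inside one sample, which cancel any per-sample
   scaling and make the model self-normalizing across platforms;
3. weight each ratio by the cross-cohort consistency of its fold change
   (inverse-sample-size weighted mean over a variance-plus-fudge-factor
   denominator, square-rooted);
4. weight each sample by its organ's representation (inverse fourth root of
   the organ's cohort count) so abundant organs do not dominate;
5. fit an L1-penalized model on the stacked, feature- and sample-weighted
   ratio matrix.

Predictions are a linear score on the logit scale; for the logistic loss a
probability is attached through the sigmoid.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .io import DatasetCollection, ExpressionDataset
from .meta import MetaResult, combine_de_results
from .preprocess import (
    DEResult,
    filter_zero_genes,
    log2_quantile_normalize,
    moderated_t_test,
    tmm_factors,
    voom_transform,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class RatioSet:
    """A gene panel and the ordered gene pairs defining its log-ratios."""

    panel: list[str]
    pairs: list[tuple[int, int]]

    @property
    def q(self) -> int:
        return len(self.pairs)

    def pair_names(self) -> list[str]:
        return [f"{self.panel[l]}/{self.panel[m]}" for l, m in self.pairs]


@dataclass
class RatioStats:
    """Cross-cohort consistency statistics for every log-ratio feature."""

    fold_changes: np.ndarray     # q ratios x k datasets
    dataset_weights: np.ndarray  # inverse sample sizes, length k
    weighted_mean: np.ndarray    # mu_w per ratio
    weighted_var: np.ndarray     # sigma_w^2 per ratio
    fudge: float                 # 90th percentile of the weighted variances
    t_stat: np.ndarray           # mu_w / (sigma_w^2 + fudge)
    feature_weights: np.ndarray  # sqrt(|t_stat|)


@dataclass
class OrganWeights:
    """Per-organ cohort counts and the sample weights they induce."""

    organ_counts: dict[str, int]
    organ_weight: dict[str, float]           # n_i ** (-1/4)
    sample_weights: dict[str, np.ndarray]    # dataset_id -> per-sample weights


@dataclass
class TOPConfig:
    """Training configuration; every stochastic step derives from ``seed``."""

    n_features: int = 50
    panel: list[str] | None = None           # fixed panel instead of selection
    loss: str = "logistic"                   # or "squared" (the lasso on raw y)
    lam: float | str = "cv"
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    cv_folds: int = 5
    organ_weighting: str = "balanced"        # or "naive" (all samples weight 1)
    organ_count_mode: str = "datasets"       # or "samples"
    already_log: bool = False                # array data already on log scale
    voom_span: float = 0.5
    quantile_method: str = "linear"          # estimator for the fudge quantile
    train_organs: list[str] | None = None    # restrict the training pool
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TOPModel:
    """A trained self-normalizing log-ratio classifier."""

    ratio_set: RatioSet
    w_f: np.ndarray
    beta0: float
    beta: np.ndarray
    lam: float
    loss: str
    dataset_ids: list[str]
    organs: list[str]
    seed: int
    config: dict = field(default_factory=dict)

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.beta))

    def to_dict(self) -> dict:
        return {
            "panel": list(self.ratio_set.panel),
            "pairs": [[int(l), int(m)] for l, m in self.ratio_set.pairs],
            "w_f": [float(v) for v in self.w_f],
            "beta0": float(self.beta0),
            "beta": [float(v) for v in self.beta],
            "lambda": float(self.lam),
            "loss": self.loss,
            "dataset_ids": list(self.dataset_ids),
            "organs": list(self.organs),
            "seed": int(self.seed),
            "config": self.config,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TOPModel":
        return cls(
            ratio_set=RatioSet(
                panel=list(d["panel"]),
                pairs=[(int(l), int(m)) for l, m in d["pairs"]],
            ),
            w_f=np.asarray(d["w_f"], dtype=float),
            beta0=float(d["beta0"]),
            beta=np.asarray(d["beta"], dtype=float),
            lam=float(d["lambda"]),
            loss=d["loss"],
            dataset_ids=list(d["dataset_ids"]),
            organs=list(d["organs"]),
            seed=int(d["seed"]),
            config=dict(d.get("config", {})),
        )

    def __eq__(self, other) -> bool:
        return isinstance(other, TOPModel) and self.to_dict() == other.to_dict()


@dataclass
class PreparedDataset:
    """A cohort brought to the log scale its platform pipeline defines."""

    dataset_id: str
    organ: str
    genes: list[str]
    samples: list[str]
    M: np.ndarray                      # log-scale genes x samples
    y: np.ndarray
    weights: np.ndarray | None = None  # voom precision weights (counts only)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.M, index=self.genes, columns=self.samples)


# ---------------------------------------------------------------------------
# preparation


def prepare_dataset(
    ds: ExpressionDataset,
    already_log: bool = False,
    voom_span: float = 0.5,
    for_training: bool = True,
) -> PreparedDataset:
    """Run the platform-appropriate normalization for one cohort.

    Arrays get log2(x+1) + quantile normalization; count data get zero-gene
    filtering, TMM factors and the voom-style log2-CPM transform.  During
    training the voom variance trend uses the two-group means; at prediction
    time (``for_training=False``) it uses gene means only, so labels are
    never touched.
    """
    if ds.platform == "array":
        M = log2_quantile_normalize(ds.X, already_log=already_log)
        return PreparedDataset(
            ds.dataset_id, ds.organ, list(ds.genes), list(ds.samples), M, ds.y
        )
    counts, kept = filter_zero_genes(ds.X)
    genes = [g for g, k in zip(ds.genes, kept) if k]
    factors = tmm_factors(counts)
    vw = voom_transform(
        counts,
        factors,
        y=ds.y if (for_training and ds.usable_for_training) else None,
        span=voom_span,
    )
    return PreparedDataset(
        ds.dataset_id, ds.organ, genes, list(ds.samples), vw.logcpm, ds.y,
        weights=vw.weights,
    )


def prepare_collection(
    collection: DatasetCollection,
    already_log: bool = False,
    voom_span: float = 0.5,
) -> dict[str, PreparedDataset]:
    return {
        ds.dataset_id: prepare_dataset(ds, already_log, voom_span)
        for ds in collection.datasets
    }


def de_statistics(prep: PreparedDataset) -> DEResult:
    """Moderated two-group test on a prepared cohort (voom-weighted if counts)."""
    return moderated_t_test(prep.M, prep.y, genes=prep.genes, weights=prep.weights)


# ---------------------------------------------------------------------------
# feature selection


def selection_meta(
    prepared: dict[str, PreparedDataset],
    de_cache: dict[str, DEResult] | None = None,
) -> MetaResult:
    """Stouffer combination of per-cohort moderated statistics."""
    results = {}
    for dataset_id, prep in prepared.items():
        if de_cache is not None and dataset_id in de_cache:
            results[dataset_id] = de_cache[dataset_id]
        else:
            results[dataset_id] = de_statistics(prep)
            if de_cache is not None:
                de_cache[dataset_id] = results[dataset_id]
    return combine_de_results(results)


def select_top_genes(
    collection: DatasetCollection,
    n: int = 50,
    prepared: dict[str, PreparedDataset] | None = None,
    de_cache: dict[str, DEResult] | None = None,
    already_log: bool = False,
    voom_span: float = 0.5,
) -> list[str]:
    """Select the n genes most consistently differentially expressed.

    Genes are drawn from the intersection across all training cohorts and
    ranked by Stouffer-combined p ascending, ties broken by |combined z|
    descending then symbol.
    """
    trainable = collection.trainable()
    if prepared is None:
        prepared = prepare_collection(trainable, already_log, voom_span)
    prepared = {d: prepared[d] for d in trainable.dataset_ids}
    meta = selection_meta(prepared, de_cache)
    order = sorted(
        range(len(meta.genes)),
        key=lambda i: (meta.p_combined[i], -abs(meta.z_combined[i]), meta.genes[i]),
    )
    if len(order) < n:
        warnings.warn(
            f"gene intersection ({len(order)}) smaller than requested panel ({n}); "
            "returning all intersection genes"
        )
        n = len(order)
    return [meta.genes[i] for i in order[:n]]


def select_fixed_panel(
    collection: DatasetCollection, panel: list[str]
) -> list[str]:
    """Intersect a user-supplied panel with the collection's gene space.

    Order is preserved, duplicates keep their first occurrence, and dropped
    genes are logged.
    """
    if not panel:
        raise ValueError("panel is empty")
    panel = list(dict.fromkeys(panel))
    available = set(collection.gene_intersection())
    kept = [g for g in panel if g in available]
    dropped = [g for g in panel if g not in available]
    if dropped:
        warnings.warn(f"{len(dropped)} panel gene(s) missing from the collection: "
                      f"{dropped[:10]}")
    if not kept:
        raise ValueError("no panel gene is present in every dataset")
    return kept


def make_ratio_set(panel: list[str]) -> RatioSet:
    """All p(p-1)/2 ordered gene pairs (l < m), lexicographic in indices."""
    p = len(panel)
    pairs = [(l, m) for l in range(p) for m in range(l + 1, p)]
    return RatioSet(panel=list(panel), pairs=pairs)


# ---------------------------------------------------------------------------
# ratio features and weights


def build_log_ratio_matrix(M: pd.DataFrame, ratio_set: RatioSet) -> np.ndarray:
    """Samples x q matrix of within-sample log-expression differences.

    ``Z[s, (l, m)] = M[panel[l], s] - M[panel[m], s]``.  Because both terms
    come from the same sample, any per-sample additive shift in log space
    (multiplicative scaling of raw intensities) cancels exactly.
    """
    missing = [g for g in ratio_set.panel if g not in M.index]
    if missing:
        raise KeyError(f"panel genes missing from expression matrix: {missing}")
    P = M.loc[ratio_set.panel].to_numpy(dtype=float)  # p x samples
    left = np.fromiter((l for l, _ in ratio_set.pairs), dtype=int)
    right = np.fromiter((m for _, m in ratio_set.pairs), dtype=int)
    return (P[left] - P[right]).T


def ratio_fold_changes(Z: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-ratio fold change: difference of class means of the log-ratio."""
    y = np.asarray(y).astype(int)
    if sorted(np.unique(y).tolist()) != [0, 1]:
        raise ValueError("both outcome classes are required")
    return Z[y == 1].mean(axis=0) - Z[y == 0].mean(axis=0)


def feature_weights(
    x: np.ndarray,
    sample_sizes: np.ndarray,
    quantile_method: str = "linear",
) -> RatioStats:
    """Cross-cohort consistency weights for every ratio.

    Cohort weights are inverse sample sizes.  The test statistic divides the
    weighted mean fold change by the weighted variance plus a fudge factor —
    the 90th percentile of the weighted variances across ratios — which stops
    near-zero-variance ratios from dominating; the feature weight is its
    square root in magnitude (direction is carried by the lasso coefficient).
    With a single cohort all variances vanish and the statistic degenerates
    to the fold change itself.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))  # q x k
    sizes = np.asarray(sample_sizes, dtype=float)
    if (sizes <= 0).any():
        raise ValueError("sample sizes must be positive")
    if x.shape[1] != sizes.size:
        raise ValueError("fold-change matrix and sample sizes are misaligned")
    w = 1.0 / sizes
    wn = w / w.sum()  # normalized: identical statistics, exact when k == 1
    mu = x @ wn
    sigma2 = ((x - mu[:, None]) ** 2) @ wn
    fudge = float(np.quantile(sigma2, 0.9, method=quantile_method))
    if fudge == 0.0:
        t = mu.copy()  # single-cohort degeneracy: unit denominator
    else:
        t = mu / (sigma2 + fudge)
    return RatioStats(
        fold_changes=x,
        dataset_weights=w,
        weighted_mean=mu,
        weighted_var=sigma2,
        fudge=fudge,
        t_stat=t,
        feature_weights=np.sqrt(np.abs(t)),
    )


def organ_sample_weights(
    collection: DatasetCollection, count_mode: str = "datasets"
) -> OrganWeights:
    """Organ-balancing sample weights: every sample of organ i gets n_i^(-1/4).

    ``n_i`` counts the organ's training datasets by default; ``count_mode=
    'samples'`` counts its samples instead.
    """
    counts: dict[str, int] = {}
    for ds in collection.datasets:
        inc = 1 if count_mode == "datasets" else ds.n_samples
        counts[ds.organ] = counts.get(ds.organ, 0) + inc
    organ_weight = {o: float(n) ** (-0.25) for o, n in counts.items()}
    sample_weights = {
        ds.dataset_id: np.full(ds.n_samples, organ_weight[ds.organ])
        for ds in collection.datasets
    }
    return OrganWeights(counts, organ_weight, sample_weights)


# ---------------------------------------------------------------------------
# weighted lasso


def _soft(x: float, lam: float) -> float:
    if x > lam:
        return x - lam
    if x < -lam:
        return x + lam
    return 0.0


def _wls_lasso_cd(X, u, v, lam, beta0, beta, tol, max_sweeps=1000):
    """Coordinate descent on 0.5 * sum_i v_i (u_i - b0 - x_i.b)^2 + lam*||b||_1.

    Active-set strategy with KKT screening: coordinate updates loop only over
    the working set; vectorized gradient passes over the full feature space
    admit violators until the stationarity conditions hold everywhere.
    """
    n, q = X.shape
    xv_sq = (v[:, None] * X * X).sum(axis=0)
    r = u - beta0 - X @ beta
    vsum = v.sum()

    def sweep(indices) -> float:
        nonlocal beta0, r
        delta = (v @ r) / vsum
        beta0 += delta
        r -= delta
        biggest = abs(delta)
        for j in indices:
            if xv_sq[j] <= 0:
                continue
            old = beta[j]
            rho = X[:, j] @ (v * r) + xv_sq[j] * old
            new = _soft(rho, lam) / xv_sq[j]
            if new != old:
                r += X[:, j] * (old - new)
                beta[j] = new
                biggest = max(biggest, abs(new - old))
        return biggest

    active = set(np.flatnonzero(beta).tolist())
    for _ in range(max_sweeps):
        for _ in range(max_sweeps):
            if not active or sweep(sorted(active)) < tol:
                break
        # intercept re-centering even when the active set is empty
        delta = (v @ r) / vsum
        beta0 += delta
        r -= delta
        grad = X.T @ (v * r)  # == lam * sign(beta_j) on the active set at optimum
        violators = np.flatnonzero((np.abs(grad) > lam + tol) & (beta == 0))
        new = [j for j in violators if j not in active and xv_sq[j] > 0]
        if not new:
            break
        active.update(new)
    return beta0, beta


def _logistic_lasso_cd(
    X, y, sw, lam, beta0=0.0, beta=None, tol=1e-10, max_outer=100
):
    """Penalized IRLS: quadratic approximations solved by weighted lasso CD."""
    n, q = X.shape
    beta = np.zeros(q) if beta is None else beta.copy()
    ys = y.astype(float)
    for _ in range(max_outer):
        z = np.clip(beta0 + X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-z))
        pq = np.clip(p * (1.0 - p), 1e-6, None)
        v = sw * pq
        u = z + (ys - p) / pq
        b0_old, b_old = beta0, beta.copy()
        beta0, beta = _wls_lasso_cd(X, u, v, lam, beta0, beta, tol=tol * 0.1)
        step = max(abs(beta0 - b0_old), float(np.max(np.abs(beta - b_old), initial=0.0)))
        if step < tol:
            break
    return beta0, beta


def _fit_l1(Xs, y, sw, lam, loss, seed, tol=1e-10, max_iter=100_000):
    """One L1 fit of the weighted objective at penalty ``lam``.

    Objective: sum_i w_si * loss(y_i, b0 + x_i . b) + lam * ||b||_1 with the
    intercept unpenalized; logistic loss is the binomial deviance in nats,
    squared loss the plain residual sum of squares on the 0/1 outcome.
    """
    if loss == "logistic":
        return _logistic_lasso_cd(Xs, y, sw, lam, tol=tol)
    est = Lasso(alpha=lam / (2.0 * sw.sum()), tol=tol, max_iter=max_iter)
    with warnings.catch_warnings():
        # tol is far below sklearn's default; late-stop chatter is expected
        warnings.simplefilter("ignore")
        est.fit(Xs, y.astype(float), sample_weight=sw)
    return float(est.intercept_), est.coef_.copy()


def _path_fits(Xs, y, sw, grid, loss, seed, tol=1e-5, max_iter=3_000):
    """Warm-started L1 fits along a decreasing penalty grid.

    Path solutions only rank penalties inside cross-validation, so they run
    at a looser tolerance than the final fit.
    """
    out = []
    if loss == "logistic":
        b0, b = 0.0, None
        for l in grid:
            b0, b = _logistic_lasso_cd(Xs, y, sw, l, beta0=b0, beta=b, tol=tol)
            out.append((b0, b.copy()))
    else:
        est = Lasso(
            alpha=grid[0] / (2.0 * sw.sum()), tol=tol, max_iter=max_iter,
            warm_start=True,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for l in grid:
                est.set_params(alpha=l / (2.0 * sw.sum()))
                est.fit(Xs, y.astype(float), sample_weight=sw)
                out.append((float(est.intercept_), est.coef_.copy()))
    return out


def lambda_max(Xs: np.ndarray, y: np.ndarray, sw: np.ndarray, loss: str) -> float:
    """Smallest penalty at which every coefficient is zero."""
    ybar = float(np.sum(sw * y) / sw.sum())
    grad = Xs.T @ (sw * (y - ybar))
    lmax = float(np.max(np.abs(grad)))
    if loss == "squared":
        lmax *= 2.0
    return lmax


def fit_weighted_lasso(
    Z_all: np.ndarray,
    y_all: np.ndarray,
    w_f: np.ndarray,
    w_s: np.ndarray,
    lam: float | str = "cv",
    loss: str = "logistic",
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-3,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[float, np.ndarray, float]:
    """Fit the feature- and sample-weighted L1 model on stacked ratios.

    Feature weights enter by rescaling columns (``Z_j * w_fj``); columns with
    zero weight are excluded and their coefficients forced to zero.  With
    ``lam='cv'`` the penalty is chosen by stratified k-fold cross-validation
    maximizing AUC over a logarithmic grid anchored at the smallest
    all-zero penalty; ties prefer the sparser (larger) penalty.

    Returns ``(beta0, beta, lam)`` with ``beta`` on the full ratio space.
    """
    Z_all = np.asarray(Z_all, dtype=float)
    y_all = np.asarray(y_all).astype(int)
    w_f = np.asarray(w_f, dtype=float)
    w_s = np.asarray(w_s, dtype=float)
    if loss not in ("logistic", "squared"):
        raise ValueError(f"unknown loss {loss!r}")
    if sorted(np.unique(y_all).tolist()) != [0, 1]:
        raise ValueError("stacked outcome has a single class")
    active = w_f > 0
    if not active.any():
        raise ValueError("all feature weights are zero")
    Xs = Z_all[:, active] * w_f[active]

    if lam == "cv":
        lmax = lambda_max(Xs, y_all, w_s, loss)
        if lmax <= 0:
            raise ValueError("degenerate design: lambda_max is zero")
        grid = np.geomspace(lmax, lmax * lambda_min_ratio, n_lambda)
        n_pos, n_neg = int(y_all.sum()), int((1 - y_all).sum())
        folds = min(cv_folds, n_pos, n_neg)
        if folds < 2:
            raise ValueError("too few samples per class for cross-validation; "
                             "pass a numeric lambda")
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        auc_grid = np.zeros((folds, len(grid)))
        for f, (tr, va) in enumerate(skf.split(Xs, y_all)):
            path = _path_fits(Xs[tr], y_all[tr], w_s[tr], grid, loss, seed)
            for g, (b0, b) in enumerate(path):
                scores = b0 + Xs[va] @ b
                if len(np.unique(scores)) == 1 or len(np.unique(y_all[va])) == 1:
                    auc_grid[f, g] = 0.5
                else:
                    auc_grid[f, g] = roc_auc_score(y_all[va], scores)
        mean_auc = auc_grid.mean(axis=0)
        best = int(np.argmax(mean_auc))  # argmax takes the first (largest) lam
        lam = float(grid[best])
    lam = float(lam)
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    b0, b_active = _fit_l1(Xs, y_all, w_s, max(lam, 1e-12), loss, seed)
    beta = np.zeros(Z_all.shape[1])
    beta[active] = b_active
    return b0, beta, lam


# ---------------------------------------------------------------------------
# orchestration


def train_top(
    collection: DatasetCollection,
    config: TOPConfig | None = None,
    prepared: dict[str, PreparedDataset] | None = None,
    de_cache: dict[str, DEResult] | None = None,
) -> TOPModel:
    """Train a TOP model end to end on a dataset collection.

    Sample weights are normalized to mean one before fitting so that the
    penalty scale is comparable between balanced and naive weighting (with
    equal organ representation the two coincide exactly).
    """
    config = config or TOPConfig()
    pool = collection
    if config.train_organs is not None:
        keep = [d.dataset_id for d in pool.datasets if d.organ in config.train_organs]
        if not keep:
            raise ValueError(f"no dataset from organs {config.train_organs}")
        pool = pool.subset(keep)
    trainable = pool.trainable()
    if prepared is None:
        prepared = prepare_collection(trainable, config.already_log, config.voom_span)
    prepared = {d: prepared[d] for d in trainable.dataset_ids}

    if config.panel is not None:
        panel = select_fixed_panel(trainable, config.panel)
    else:
        panel = select_top_genes(
            trainable, config.n_features, prepared=prepared, de_cache=de_cache
        )
    ratio_set = make_ratio_set(panel)

    Z_blocks, fold_changes, sizes = [], [], []
    for dataset_id in trainable.dataset_ids:
        prep = prepared[dataset_id]
        Z = build_log_ratio_matrix(prep.frame(), ratio_set)
        Z_blocks.append(Z)
        fold_changes.append(ratio_fold_changes(Z, prep.y))
        sizes.append(len(prep.samples))
    stats = feature_weights(
        np.column_stack(fold_changes), np.array(sizes), config.quantile_method
    )

    if config.organ_weighting == "balanced":
        ow = organ_sample_weights(trainable, config.organ_count_mode)
        w_s = np.concatenate([ow.sample_weights[d] for d in trainable.dataset_ids])
    elif config.organ_weighting == "naive":
        w_s = np.ones(sum(sizes))
    else:
        raise ValueError(f"unknown organ_weighting {config.organ_weighting!r}")
    w_s = w_s / w_s.mean()

    Z_all = np.vstack(Z_blocks)
    y_all = np.concatenate([prepared[d].y for d in trainable.dataset_ids])
    beta0, beta, lam = fit_weighted_lasso(
        Z_all, y_all, stats.feature_weights, w_s,
        lam=config.lam, loss=config.loss,
        n_lambda=config.n_lambda, lambda_min_ratio=config.lambda_min_ratio,
        cv_folds=config.cv_folds, seed=config.seed,
    )
    return TOPModel(
        ratio_set=ratio_set,
        w_f=stats.feature_weights,
        beta0=beta0,
        beta=beta,
        lam=lam,
        loss=config.loss,
        dataset_ids=trainable.dataset_ids,
        organs=[d.organ for d in trainable.datasets],
        seed=config.seed,
        config=config.to_dict(),
    )


def predict_risk(model: TOPModel, M_new: pd.DataFrame) -> pd.DataFrame:
    """Score a new cohort's log-expression matrix (genes x samples).

    Returns per-sample ``logit_score`` (beta0 + sum_j Z_j w_fj beta_j) and
    ``probability`` (sigmoid of the score for the logistic loss, the raw
    score for the squared loss).
    """
    missing = [g for g in model.ratio_set.panel if g not in M_new.index]
    if missing:
        raise KeyError(f"panel genes missing from new data: {missing}")
    Z = build_log_ratio_matrix(M_new, model.ratio_set)
    score = model.beta0 + Z @ (model.w_f * model.beta)
    if model.loss == "logistic":
        prob = 1.0 / (1.0 + np.exp(-score))
    else:
        prob = score
    return pd.DataFrame(
        {"sample_id": list(M_new.columns), "logit_score": score, "probability": prob}
    )


def predict_dataset(
    model: TOPModel,
    ds: ExpressionDataset,
    already_log: bool = False,
    voom_span: float = 0.5,
) -> pd.DataFrame:
    """Normalize a raw cohort with its platform pipeline, then score it."""
    prep = prepare_dataset(ds, already_log, voom_span, for_training=False)
    return predict_risk(model, prep.frame())
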