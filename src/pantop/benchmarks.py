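"""Seeded benchmark suites on synthetic collections.

These routines are the repository's regression baselines: they generate the
benchmark conditions defined by :class:`~pantop.simulate.SyntheticSpec`
defaults, run the full pipeline, and report recovery / transfer summaries.
Problem sizes are chosen so each suite runs in minutes on one core: the
transfer suites use 20-gene panels (190 ratios), the squared-loss lasso and a
20-point penalty grid, which preserves the pipeline's structure at a fraction
of the default model's cost.
"""

from __future__ import annotations

import numpy as np

from .evaluate import auc
from .meta import combine_de_results
from .simulate import (
    SyntheticSpec,
    dominant_organ_spec,
    generate_collection,
    null_spec,
    truth_recovery_report,
)
from .top import (
    TOPConfig,
    prepare_collection,
    prepare_dataset,
    predict_risk,
    select_top_genes,
    train_top,
)


def transfer_config(seed: int, **overrides) -> TOPConfig:
    """The scaled-down training configuration used by the benchmark suites."""
    base = dict(n_features=20, loss="squared", n_lambda=20, cv_folds=5, seed=seed)
    base.update(overrides)
    return TOPConfig(**base)


def selection_recovery(base_seed: int, n_seeds: int = 10) -> dict:
    """Panel-selection recovery of planted shared signal over seeds.

    For each seed, generates the benchmark collection, selects the top-50
    panel, and reports the recall of the planted shared genes plus the
    fraction of (dataset, shared gene) pairs whose moderated fold-change sign
    matches the planted sign.
    """
    recalls, agree, total = [], 0, 0
    for s in range(n_seeds):
        coll, truth = generate_collection(SyntheticSpec(), seed=base_seed + s)
        de_cache: dict = {}
        panel = select_top_genes(coll, n=50, de_cache=de_cache)
        recalls.append(truth_recovery_report(truth, panel).recall_shared)
        for res in de_cache.values():
            lookup = dict(zip(res.genes, res.log_fc))
            for g, sign in zip(truth.shared_genes, truth.shared_signs):
                if g in lookup:
                    total += 1
                    agree += np.sign(lookup[g]) == sign
    return {
        "recall_per_seed": recalls,
        "recall_median": float(np.median(recalls)),
        "sign_agreement": agree / total,
        "n_seeds": n_seeds,
    }


def _lodo_auc(collection, held_out_ids, config, prepared, de_cache):
    """Mean held-out AUC over the named datasets under one configuration."""
    trainable = collection.trainable()
    aucs = []
    for held_out in held_out_ids:
        test_ds = collection.get(held_out)
        model = train_top(
            trainable.drop(held_out), config, prepared=prepared, de_cache=de_cache
        )
        prep = prepare_dataset(test_ds, for_training=False)
        scores = predict_risk(model, prep.frame())["logit_score"].to_numpy()
        aucs.append(auc(scores, test_ds.y))
    return float(np.mean(aucs))


def minority_organ_transfer(base_seed: int, n_seeds: int = 10) -> dict:
    """Pan-organ vs organ-specific models on minority-organ test cohorts.

    On the benchmark collection (kidney-majority, heart and liver with two
    cohorts each), every minority-organ cohort is held out in turn and scored
    by (a) a model trained on all remaining cohorts and (b) a model trained
    only on the held-out cohort's organ.  Reports per-seed mean AUCs and how
    often the pan-organ model wins.
    """
    pan, organ_specific, wins = [], [], 0
    for s in range(n_seeds):
        seed = base_seed + s
        coll, _ = generate_collection(SyntheticSpec(), seed=seed)
        minority = [d.dataset_id for d in coll.datasets if d.organ != "kidney"]
        prepared = prepare_collection(coll.trainable())
        de_cache: dict = {}
        pan_auc = _lodo_auc(
            coll, minority, transfer_config(seed), prepared, de_cache
        )
        org_aucs = []
        for held_out in minority:
            organ = coll.get(held_out).organ
            cfg = transfer_config(seed, train_organs=[organ])
            org_aucs.append(_lodo_auc(coll, [held_out], cfg, prepared, {}))
        org_auc = float(np.mean(org_aucs))
        pan.append(pan_auc)
        organ_specific.append(org_auc)
        wins += pan_auc > org_auc
    return {
        "pan_auc_per_seed": pan,
        "organ_specific_auc_per_seed": organ_specific,
        "pan_auc_mean": float(np.mean(pan)),
        "organ_specific_auc_mean": float(np.mean(organ_specific)),
        "pan_wins": int(wins),
        "n_seeds": n_seeds,
    }


def weighting_comparison(base_seed: int, n_seeds: int = 10) -> dict:
    """Balanced vs naive organ weighting on a dominant-organ collection.

    Uses the kidney-dominant condition (six kidney cohorts with strong
    private signal) and compares mean held-out AUC on the non-dominant
    cohorts between organ-balanced and naive sample weighting over seeds;
    ties count for the balanced model.
    """
    balanced, naive, wins = [], [], 0
    for s in range(n_seeds):
        seed = base_seed + s
        coll, _ = generate_collection(dominant_organ_spec(), seed=seed)
        non_dominant = [d.dataset_id for d in coll.datasets if d.organ != "kidney"]
        prepared = prepare_collection(coll.trainable())
        de_cache: dict = {}
        bal = _lodo_auc(coll, non_dominant, transfer_config(seed), prepared, de_cache)
        nai = _lodo_auc(
            coll,
            non_dominant,
            transfer_config(seed, organ_weighting="naive"),
            prepared,
            de_cache,
        )
        balanced.append(bal)
        naive.append(nai)
        wins += bal >= nai
    return {
        "balanced_auc_per_seed": balanced,
        "naive_auc_per_seed": naive,
        "balanced_auc_mean": float(np.mean(balanced)),
        "naive_auc_mean": float(np.mean(naive)),
        "balanced_wins": int(wins),
        "n_seeds": n_seeds,
    }


def null_calibration(seed: int, n_genes: int = 5000, alpha: float = 0.05) -> dict:
    """Type-I calibration under the no-signal synthetic condition.

    Generates a four-cohort null collection (two organs, alternating
    platforms), runs per-cohort moderated tests and the cross-cohort
    Stouffer combination, and reports Kolmogorov-Smirnov distances of the
    p-value distributions from uniform plus the DE call rate at ``alpha``.
    """
    from scipy import stats

    spec = null_spec(
        organs={"kidney": 2, "heart": 2},
        n_genes=n_genes,
        n_samples_range=(40, 40),
    )
    coll, _ = generate_collection(spec, seed=seed)
    prepared = prepare_collection(coll.trainable())
    de_cache: dict = {}
    select_top_genes(coll, n=1, prepared=prepared, de_cache=de_cache)
    first_array = next(
        d.dataset_id for d in coll.datasets if d.platform == "array"
    )
    moderated_p = de_cache[first_array].p_value
    meta = combine_de_results(de_cache)
    call_rate = float(np.mean(meta.p_combined < alpha))
    band = 1.96 * np.sqrt(alpha * (1 - alpha) / len(meta.genes))
    return {
        "moderated_p_ks": float(stats.kstest(moderated_p, "uniform").statistic),
        "combined_p_ks": float(stats.kstest(meta.p_combined, "uniform").statistic),
        "call_rate": call_rate,
        "alpha": alpha,
        "binomial_band": float(band),
        "n_genes": len(meta.genes),
    }
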