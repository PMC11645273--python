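"""Cross-dataset meta-analysis of differential expression.

Per-dataset moderated t-statistics are mapped to normal z-scores through
their t distribution and combined across datasets with Stouffer's method,
``z_c = sum(z_i) / sqrt(k)``.  On top of the combined statistics sit the
downstream procedures: calling differentially expressed genes at a p-value
threshold, testing whether a multi-organ intersection is larger than chance,
rank-based gene-set enrichment, and derivation of a ranked cross-phenotype
gene panel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from .io import GeneSetLibrary
from .preprocess import DEResult, bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class MetaResult:
    """Per-gene per-dataset z-scores and their Stouffer combination."""

    genes: list[str]
    dataset_ids: list[str]
    zmat: np.ndarray          # genes x datasets
    z_combined: np.ndarray
    p_combined: np.ndarray    # two-sided normal p
    adj_p: np.ndarray         # Benjamini-Hochberg across genes

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.zmat, index=self.genes, columns=[f"z_{d}" for d in self.dataset_ids])
        df.insert(0, "gene", self.genes)
        df["z_combined"] = self.z_combined
        df["p_combined"] = self.p_combined
        df["adj_p"] = self.adj_p
        return df.reset_index(drop=True)


@dataclass
class OverlapTest:
    """Chi-square test of an observed multi-organ DE intersection size."""

    marginal_p: list[float]
    universe_size: int
    expected: float
    observed: int
    chi_square: float
    p_value: float


def t_to_z(t: np.ndarray, df: float | np.ndarray) -> np.ndarray:
    """Map t statistics to standard normal z-scores of equal tail probability.

    Computed through the tail nearest zero (sign-symmetrically) so that
    extreme statistics keep full floating-point precision; sign(z) = sign(t).
    """
    t = np.asarray(t, dtype=float)
    if not np.isfinite(t).all():
        raise ValueError("non-finite t statistics")
    df = np.broadcast_to(np.asarray(df, dtype=float), t.shape)
    if (df <= 0).any():
        raise ValueError("degrees of freedom must be positive")
    tail = stats.t.sf(np.abs(t), df)       # upper tail of |t|, well conditioned
    z = -ndtri(tail)                       # positive z with the same tail mass
    return np.where(t < 0, -z, np.where(t == 0, 0.0, z))


def stouffer_combine(zmat: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Combine per-dataset z-scores per gene: z_c = sum(z) / sqrt(k).

    Returns ``(z_combined, p_combined, adj_p)`` with two-sided normal
    p-values and BH adjustment across genes.
    """
    zmat = np.atleast_2d(np.asarray(zmat, dtype=float))
    if not np.isfinite(zmat).all():
        raise ValueError("zmat has missing or non-finite entries; "
                         "genes must be pre-intersected across datasets")
    k = zmat.shape[1]
    if k < 1:
        raise ValueError("need at least one dataset")
    z_c = zmat.sum(axis=1) / np.sqrt(k)
    p = 2.0 * stats.norm.sf(np.abs(z_c))
    return z_c, p, bh_adjust(p)


def combine_de_results(
    results: dict[str, DEResult],
    min_datasets: int | None = None,
) -> MetaResult:
    """Build a :class:`MetaResult` from per-dataset moderated statistics.

    By default only genes present in every contributing dataset are combined
    (intersection rule).  ``min_datasets=m`` enables the partial-presence
    mode: genes present in at least m datasets are kept and each gene's
    combined z uses its own dataset count.
    """
    if not results:
        raise ValueError("no DE results supplied")
    dataset_ids = sorted(results)
    gene_sets = [set(results[d].genes) for d in dataset_ids]
    if min_datasets is None:
        common = set.intersection(*gene_sets)
        genes = sorted(common)
        if not genes:
            raise ValueError("empty gene intersection across datasets")
    else:
        counts: dict[str, int] = {}
        for gs in gene_sets:
            for g in gs:
                counts[g] = counts.get(g, 0) + 1
        genes = sorted(g for g, c in counts.items() if c >= min_datasets)
        if not genes:
            raise ValueError(f"no gene present in >= {min_datasets} datasets")

    zmat = np.full((len(genes), len(dataset_ids)), np.nan)
    for j, d in enumerate(dataset_ids):
        res = results[d]
        z = t_to_z(res.moderated_t, res.total_df)
        lookup = {g: i for i, g in enumerate(res.genes)}
        for i, g in enumerate(genes):
            if g in lookup:
                zmat[i, j] = z[lookup[g]]
    if min_datasets is None:
        z_c, p, adj = stouffer_combine(zmat)
    else:
        present = ~np.isnan(zmat)
        k_per_gene = present.sum(axis=1)
        z_c = np.nansum(zmat, axis=1) / np.sqrt(k_per_gene)
        p = 2.0 * stats.norm.sf(np.abs(z_c))
        adj = bh_adjust(p)
    return MetaResult(
        genes=genes, dataset_ids=dataset_ids, zmat=zmat,
        z_combined=z_c, p_combined=p, adj_p=adj,
    )


def call_de_genes(
    meta: MetaResult, threshold: float, scope: str = "combined_p"
) -> tuple[np.ndarray, int]:
    """Call genes with combined (or BH-adjusted) p strictly below threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    if scope == "combined_p":
        p = meta.p_combined
    elif scope == "adj_p":
        p = meta.adj_p
    else:
        raise ValueError(f"unknown scope {scope!r}")
    called = p < threshold
    return called, int(called.sum())


def expected_overlap_test(per_organ_calls: list[np.ndarray]) -> OverlapTest:
    """Compare an observed full intersection of DE calls with chance.

    Marginal probabilities are the per-organ DE fractions over the common
    universe of size G; the expected intersection size is ``E = G * prod(p_o)``
    and the observed size is tested with a 1-df Pearson chi-square on the
    two-cell partition {in full intersection, not in it}.
    """
    if len(per_organ_calls) < 2:
        raise ValueError("need calls from at least two organs")
    calls = [np.asarray(c, dtype=bool) for c in per_organ_calls]
    G = calls[0].size
    if any(c.size != G for c in calls):
        raise ValueError("call vectors must share one gene universe")
    marginal = [float(c.mean()) for c in calls]
    if any(p == 0.0 for p in marginal):
        raise ValueError(
            "an organ has zero DE calls: expected intersection is 0 and the "
            "chi-square test is undefined"
        )
    expected = G * float(np.prod(marginal))
    observed = int(np.logical_and.reduce(calls).sum())
    chi_sq = (observed - expected) ** 2 / expected + (
        (G - observed) - (G - expected)
    ) ** 2 / (G - expected)
    p_value = float(stats.chi2.sf(chi_sq, df=1))
    return OverlapTest(
        marginal_p=marginal,
        universe_size=G,
        expected=float(expected),
        observed=observed,
        chi_square=float(chi_sq),
        p_value=p_value,
    )


def wilcoxon_set_enrichment(
    z_combined: np.ndarray,
    genes: list[str],
    library: GeneSetLibrary,
    method: str = "auto",
) -> pd.DataFrame:
    """Rank-sum enrichment of gene sets on the combined statistics.

    Each set's member statistics are compared with all other genes by a
    two-sided Wilcoxon rank-sum test.  ``method='auto'`` uses the exact null
    distribution on small tie-free universes (<= 25 genes) and the normal
    approximation with tie correction otherwise.  Sets without members in
    the universe, or covering the whole universe, are skipped with a warning.
    """
    z = np.asarray(z_combined, dtype=float)
    if z.size != len(genes):
        raise ValueError("z_combined and genes are misaligned")
    index = {g: i for i, g in enumerate(genes)}
    ranks = stats.rankdata(z)
    rows = []
    for name, members in library.sets.items():
        in_idx = sorted({index[g] for g in members if g in index})
        if not in_idx:
            warnings.warn(f"gene set {name!r} has no members in the universe; skipped")
            continue
        if len(in_idx) == z.size:
            warnings.warn(f"gene set {name!r} covers the whole universe; skipped")
            continue
        mask = np.zeros(z.size, dtype=bool)
        mask[in_idx] = True
        if method == "auto":
            tie_free = np.unique(z).size == z.size
            use = "exact" if (z.size <= 25 and tie_free) else "asymptotic"
        else:
            use = method
        res = stats.mannwhitneyu(
            z[mask], z[~mask], alternative="two-sided", method=use
        )
        direction = float(np.sign(ranks[mask].mean() - ranks[~mask].mean()))
        rows.append(
            {
                "set": name,
                "n_members": int(mask.sum()),
                "statistic": float(res.statistic),
                "p_value": float(res.pvalue),
                "direction": direction,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["set", "n_members", "statistic", "p_value", "direction", "adj_p"]
        )
    out = pd.DataFrame(rows)
    out["adj_p"] = bh_adjust(out["p_value"].to_numpy())
    return out


def derive_panel(
    metas: list[MetaResult],
    n_panel: int = 500,
    method: str = "stouffer",
) -> list[str]:
    """Rank genes by combined change across phenotype-level meta-results.

    The per-gene cross-phenotype score is a second-level Stouffer combination
    of the phenotype z_combined values (``method='stouffer'``) or the mean of
    within-phenotype |z| ranks (``method='mean_rank'``); genes are returned
    in descending order of score magnitude, ties broken by symbol.
    """
    if not metas:
        raise ValueError("no meta-results supplied")
    common = set(metas[0].genes)
    for m in metas[1:]:
        common &= set(m.genes)
    if not common:
        raise ValueError("meta-results have non-overlapping gene universes")
    genes = sorted(common)
    if n_panel > len(genes):
        raise ValueError(f"n_panel={n_panel} exceeds common universe size {len(genes)}")
    zcols = []
    for m in metas:
        lookup = dict(zip(m.genes, m.z_combined))
        zcols.append(np.array([lookup[g] for g in genes]))
    Z = np.column_stack(zcols)
    if method == "stouffer":
        score = np.abs(Z.sum(axis=1) / np.sqrt(Z.shape[1]))
    elif method == "mean_rank":
        score = np.column_stack(
            [stats.rankdata(np.abs(col)) for col in Z.T]
        ).mean(axis=1)
    else:
        raise ValueError(f"unknown method {method!r}")
    order = sorted(range(len(genes)), key=lambda i: (-score[i], genes[i]))
    return [genes[i] for i in order[:n_panel]]
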