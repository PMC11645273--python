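"""Within-dataset normalization and moderated differential expression.

Two platform pipelines feed the same two-group empirical-Bayes test:

* microarray log-intensities: ``log2(x + 1)`` then quantile normalization;
* RNA-seq counts: zero-gene filtering, TMM library-size factors, then a
  mean-variance ("voom"-style) transform to log2-CPM with per-observation
  precision weights.

The moderated t-statistic shrinks each gene's residual variance toward a
common prior estimated by moment matching on the log residual variances, the
standard empirical-Bayes construction for expression data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class DEResult:
    """Per-gene two-group moderated test statistics for one dataset."""

    genes: list[str]
    log_fc: np.ndarray            # difference of class means, log2 units
    residual_var: np.ndarray      # s_g^2
    residual_df: float            # d_g (n - 2, shared across genes)
    prior_df: float               # d0
    prior_var: float              # s0^2
    moderated_var: np.ndarray     # shrunken s~_g^2
    moderated_t: np.ndarray
    p_value: np.ndarray
    adj_p: np.ndarray

    @property
    def total_df(self) -> float:
        return self.prior_df + self.residual_df


@dataclass
class VoomWeights:
    """log2-CPM matrix with mean-variance precision weights."""

    logcpm: np.ndarray            # genes x samples
    weights: np.ndarray           # genes x samples, strictly positive
    trend_x: np.ndarray           # fitted log2-count grid
    trend_y: np.ndarray           # sqrt residual sd at trend_x


def log2_quantile_normalize(X: np.ndarray, already_log: bool = False) -> np.ndarray:
    """log2(x+1) transform followed by quantile normalization across samples.

    Each sample's sorted values are replaced by the mean sorted profile over
    samples; tied values within a sample receive the mean of the profile
    values their ranks span, making the map deterministic.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a genes x samples matrix")
    if not already_log:
        if (X < 0).any():
            raise ValueError("intensities must be nonnegative before log transform")
        M = np.log2(X + 1.0)
    else:
        M = X.copy()
    n_genes, n_samples = M.shape
    if n_samples == 1:
        warnings.warn("single-sample matrix: log transform applied, no normalization")
        return M
    mean_profile = np.sort(M, axis=0).mean(axis=1)
    out = np.empty_like(M)
    for j in range(n_samples):
        col = M[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n_genes)
        assigned[order] = mean_profile
        # ties share the mean of the profile values assigned to their ranks
        vals, inverse = np.unique(col, return_inverse=True)
        if len(vals) < n_genes:
            sums = np.bincount(inverse, weights=assigned)
            counts = np.bincount(inverse)
            assigned = (sums / counts)[inverse]
        out[:, j] = assigned
    return out


def filter_zero_genes(X: np.ndarray, genes: list[str] | None = None):
    """Drop genes with zero counts in every sample.

    Returns ``(filtered_X, kept_mask)``; the removal count is logged.
    """
    X = np.asarray(X)
    if (X < 0).any():
        raise ValueError("counts must be nonnegative")
    kept = (X > 0).any(axis=1)
    if not kept.any():
        raise ValueError("all genes have zero counts in every sample")
    n_removed = int((~kept).sum())
    if n_removed:
        logger.info("filtered %d gene(s) with no expression in any sample", n_removed)
    return X[kept], kept


def tmm_factors(
    X: np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values library-size normalization factors.

    The reference sample is the one whose 75th-percentile count fraction is
    closest to the mean of those fractions.  For each sample, gene-wise
    log2 relative proportions against the reference (M) and average log2
    proportions (A) are double-trimmed (``trim_m`` of M, ``trim_a`` of A,
    both two-sided) and the factor is 2 to the precision-weighted mean of
    the surviving M values, with asymptotic binomial variance weights.
    Factors are rescaled to geometric mean one.
    """
    X = np.asarray(X, dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 2:
        raise ValueError("TMM needs at least two samples")
    lib = X.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("sample with all-zero counts")
    f75 = np.array([np.quantile(X[:, j] / lib[j], 0.75) for j in range(n_samples)])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    r = X[:, ref]
    factors = np.ones(n_samples)
    for j in range(n_samples):
        if j == ref:
            continue
        x = X[:, j]
        pos = (x > 0) & (r > 0)
        if not pos.any():
            raise ValueError(
                f"sample {j} shares no positively expressed gene with reference"
            )
        px, pr = x[pos] / lib[j], r[pos] / lib[ref]
        M = np.log2(px / pr)
        A = 0.5 * np.log2(px * pr)
        w = (lib[j] - x[pos]) / (lib[j] * x[pos]) + (lib[ref] - r[pos]) / (
            lib[ref] * r[pos]
        )
        n = len(M)
        lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - np.floor(n * trim_m)
        lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - np.floor(n * trim_a)
        rank_m = stats.rankdata(M)
        rank_a = stats.rankdata(A)
        keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not keep.any():
            keep = np.ones(n, dtype=bool)
        factors[j] = 2 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def _group_fitted(M: np.ndarray, y: np.ndarray | None) -> np.ndarray:
    """Fitted values under the two-group (or intercept-only) mean model."""
    if y is None:
        return np.repeat(M.mean(axis=1, keepdims=True), M.shape[1], axis=1)
    fitted = np.empty_like(M)
    for cls in (0, 1):
        idx = y == cls
        fitted[:, idx] = M[:, idx].mean(axis=1, keepdims=True)
    return fitted


def voom_transform(
    X: np.ndarray,
    factors: np.ndarray,
    y: np.ndarray | None = None,
    span: float = 0.5,
) -> VoomWeights:
    """Log2-CPM with precision weights from the fitted mean-variance trend.

    ``logcpm = log2((count + 0.5) / (libsize * factor + 1) * 1e6)``.  The
    square-root residual standard deviation of each gene (about its group
    means when ``y`` is given) is smoothed against its average log2 count by
    lowess; each observation's weight is the predicted standard deviation at
    its fitted log2 count raised to the power -4, with predictions clipped
    to the range of the fitted trend.
    """
    X = np.asarray(X, dtype=float)
    factors = np.asarray(factors, dtype=float)
    n_genes, n_samples = X.shape
    if n_genes < 10:
        raise ValueError("too few genes (<10) to fit a mean-variance trend")
    lib = X.sum(axis=0)
    eff = lib * factors + 1.0
    logcpm = np.log2((X + 0.5) / eff * 1e6)
    df = n_samples - (1 if y is None else 2)
    if df < 1:
        raise ValueError("no residual degrees of freedom for the variance trend")
    fitted = _group_fitted(logcpm, y)
    resid_sd = np.sqrt(((logcpm - fitted) ** 2).sum(axis=1) / df)
    sqrt_sd = np.sqrt(resid_sd)
    # average log2 count: mean logcpm shifted back to the count scale
    mean_logcount = logcpm.mean(axis=1) + np.mean(np.log2(eff)) - np.log2(1e6)
    smooth = lowess(sqrt_sd, mean_logcount, frac=span, return_sorted=True)
    trend_x, trend_y = smooth[:, 0], np.maximum(smooth[:, 1], 1e-6)
    fitted_logcount = fitted + (np.log2(eff) - np.log2(1e6))[None, :]
    pred = np.interp(
        np.clip(fitted_logcount, trend_x[0], trend_x[-1]), trend_x, trend_y
    )
    weights = pred ** (-4.0)
    return VoomWeights(logcpm=logcpm, weights=weights, trend_x=trend_x, trend_y=trend_y)


def trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration on 1/trigamma."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < tol:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching estimate of the variance prior (d0, s0^2).

    Matches the mean and variance of log residual variances to a scaled
    F distribution via digamma/trigamma inversion.  Returns
    ``(inf, exp(mean adjusted log s2))`` when the observed spread is no
    larger than expected from chi-square sampling noise alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least two positive residual variances")
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_sq = np.exp(emean)
    return float(d0), float(s0_sq)


def moderated_t_test(
    M: np.ndarray,
    y: np.ndarray,
    genes: list[str] | None = None,
    weights: np.ndarray | None = None,
    prior_df: float | None = None,
) -> DEResult:
    """Empirical-Bayes moderated two-group t-test on a log-scale matrix.

    With observation ``weights`` (e.g. voom precision weights) the group
    means, residual variances and contrast variance are all weighted.
    ``prior_df`` overrides the estimated d0 (0 recovers the ordinary pooled
    t-test; ``inf`` forces every gene to the prior variance).
    """
    M = np.asarray(M, dtype=float)
    y = np.asarray(y).astype(int)
    n_genes, n_samples = M.shape
    if genes is None:
        genes = [f"g{i}" for i in range(n_genes)]
    if sorted(np.unique(y).tolist()) != [0, 1]:
        raise ValueError("y must contain both classes 0 and 1")
    df = n_samples - 2
    if df < 1:
        raise ValueError("no residual degrees of freedom (need n > 2)")
    W = np.ones_like(M) if weights is None else np.asarray(weights, dtype=float)
    if (W <= 0).any():
        raise ValueError("weights must be strictly positive")

    idx1, idx0 = y == 1, y == 0
    sw1, sw0 = W[:, idx1].sum(axis=1), W[:, idx0].sum(axis=1)
    m1 = (W[:, idx1] * M[:, idx1]).sum(axis=1) / sw1
    m0 = (W[:, idx0] * M[:, idx0]).sum(axis=1) / sw0
    log_fc = m1 - m0
    fitted = np.empty_like(M)
    fitted[:, idx1] = m1[:, None]
    fitted[:, idx0] = m0[:, None]
    s2 = (W * (M - fitted) ** 2).sum(axis=1) / df
    v = 1.0 / sw1 + 1.0 / sw0  # unscaled variance of the mean difference

    if prior_df is None:
        d0, s0_sq = estimate_prior(s2, df)
    elif prior_df == 0:
        d0, s0_sq = 0.0, float(np.exp(np.mean(np.log(s2[s2 > 0]))))
    else:
        d0 = float(prior_df)
        _, s0_sq = estimate_prior(s2, df)
    if np.isinf(d0):
        s2_mod = np.full(n_genes, s0_sq)
        total_df = np.inf
    else:
        s2_mod = (d0 * s0_sq + df * s2) / (d0 + df)
        total_df = d0 + df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log_fc / np.sqrt(s2_mod * v)
    t = np.where(log_fc == 0, 0.0, t)
    if np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    return DEResult(
        genes=list(genes),
        log_fc=log_fc,
        residual_var=s2,
        residual_df=float(df),
        prior_df=float(d0),
        prior_var=float(s0_sq),
        moderated_var=s2_mod,
        moderated_t=t,
        p_value=p,
        adj_p=bh_adjust(p),
    )


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
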