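"""Count normalization, negative-binomial differential expression and the
expression-level comparative analyses (clustering, PCA, GO accumulation).

Normalization offers three standard schemes: quantile normalization (all
columns share the mean order-statistic vector), TMM (trimmed mean of
M-values, a composition correction), and median-of-ratios size factors.

The DE engine is a two-group negative-binomial model in the NB2
parameterization (Var = mu + alpha*mu^2): counts are depth-corrected with
median-of-ratios size factors supplied as a GLM offset, per-feature
dispersions are estimated by method of moments and floored at a fitted
mean-dispersion trend, and the group effect is tested by a Wald test on the
group coefficient of a log-link NB GLM.  It is exposed statsmodels-style:

    model = NBDifferentialExpression(matrix, group_a, group_b)
    res = model.fit()
    res.summary()

A feature is called differentially expressed when |log2FC| exceeds the
threshold strictly and the Benjamini-Hochberg adjusted p-value falls below
alpha strictly; calls are intersected across species pairs to find effects
common to every comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .records import CountMatrix

logger = logging.getLogger(__name__)

_MIN_DISPERSION = 1e-8
_MAX_DISPERSION = 20.0


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def _as_frame(m: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    return m.counts if isinstance(m, CountMatrix) else m


def _wrap_like(m: CountMatrix | pd.DataFrame, counts: pd.DataFrame):
    return m.with_counts(counts) if isinstance(m, CountMatrix) else counts


def quantile_normalize(m: CountMatrix | pd.DataFrame):
    """Force all columns onto the mean order-statistic distribution.

    Each column's values are replaced by the cross-column mean of the sorted
    values at their rank; ties receive the mean of their quantile values
    (average ranks interpolate between adjacent order statistics).
    """
    x = _as_frame(m)
    if x.shape[1] < 2:
        raise ValueError("quantile normalization needs at least two libraries")
    values = x.to_numpy(dtype=float)
    ref = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        order = np.argsort(values[:, j], kind="stable")
        sorted_vals = values[order, j]
        # tied runs share the mean of the reference values at their ranks,
        # which keeps every column sum equal to sum(ref)
        run_starts = np.r_[0, np.nonzero(np.diff(sorted_vals))[0] + 1]
        run_sums = np.add.reduceat(ref, run_starts)
        run_lens = np.diff(np.r_[run_starts, ref.size])
        assigned = np.repeat(run_sums / run_lens, run_lens)
        out[order, j] = assigned
    return _wrap_like(m, pd.DataFrame(out, index=x.index, columns=x.columns))


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> float:
    """log2 TMM factor of one library against the reference library."""
    n_obs, n_ref = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 0.0
    m = np.log2((obs / n_obs) / (ref / n_ref))
    a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    # asymptotic (delta-method) inverse variance of M
    w = 1.0 / (
        (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    )
    n = m.size
    rank_m = stats.rankdata(m, method="ordinal")
    rank_a = stats.rankdata(a, method="ordinal")
    lo_m, hi_m = np.floor(n * trim_m) + 1, n + 1 - np.floor(n * trim_m)
    lo_a, hi_a = np.floor(n * trim_a) + 1, n + 1 - np.floor(n * trim_a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 0.0
    return float(np.sum(w[keep] * m[keep]) / np.sum(w[keep]))


def tmm_factors(
    m: CountMatrix | pd.DataFrame,
    reference_library: str | None = None,
) -> pd.Series:
    """Per-library TMM normalization factors, geometric-mean centred at 1.

    M-values are doubly trimmed (30 % of M, 5 % of A, both tails) over
    features with nonzero counts in both the library and the reference, and
    combined with inverse-asymptotic-variance weights.  When no reference is
    given the library whose upper quartile of scaled counts is closest to the
    mean upper quartile is used.
    """
    x = _as_frame(m)
    values = x.to_numpy(dtype=float)
    if (values.sum(axis=0) == 0).any():
        raise ValueError("a library with all-zero counts cannot be normalized")
    if reference_library is None:
        scaled_q75 = np.array(
            [np.quantile(values[:, j] / values[:, j].sum(), 0.75)
             for j in range(values.shape[1])]
        )
        ref_idx = int(np.argmin(np.abs(scaled_q75 - scaled_q75.mean())))
        reference_library = x.columns[ref_idx]
    ref = x[reference_library].to_numpy(dtype=float)
    log_factors = np.array(
        [_tmm_pair(values[:, j], ref) for j in range(values.shape[1])]
    )
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=x.columns, name="tmm_factor")


def size_factors_median_ratio(m: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios depth factors (the DESeq size-factor estimator).

    For features with nonzero counts in every library, each library's factor
    is the median ratio of its count to the feature's geometric mean across
    libraries.
    """
    x = _as_frame(m)
    values = x.to_numpy(dtype=float)
    usable = (values > 0).all(axis=1)
    if not usable.any():
        raise ValueError("no feature has nonzero counts in all libraries")
    sub = values[usable]
    log_geo = np.mean(np.log(sub), axis=1)
    factors = np.exp(np.median(np.log(sub) - log_geo[:, None], axis=0))
    return pd.Series(factors, index=x.columns, name="size_factor")


def filter_expressed(m: CountMatrix | pd.DataFrame):
    """Drop features with zero counts in every library."""
    x = _as_frame(m)
    keep = x.sum(axis=1) > 0
    return _wrap_like(m, x.loc[keep])


# ---------------------------------------------------------------------------
# negative-binomial differential expression
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEResults:
    """Results of a two-group NB differential-expression fit.

    ``table`` has one row per feature with columns base_mean_a, base_mean_b,
    log2fc, pvalue, padj and call; untestable features (all-zero in both
    groups) carry NaN statistics and call "ns".
    """

    table: pd.DataFrame
    group_a: list[str]
    group_b: list[str]
    size_factors: pd.Series
    lfc_threshold: float
    alpha: float

    @property
    def called(self) -> pd.DataFrame:
        return self.table[self.table["call"] != "ns"]

    def calls(self) -> dict[str, str]:
        """feature -> direction for the called set."""
        return dict(self.called["call"])

    def summary(self) -> str:
        n_tested = int(self.table["pvalue"].notna().sum())
        n_up = int((self.table["call"] == "up").sum())
        n_down = int((self.table["call"] == "down").sum())
        lines = [
            "Negative-binomial differential expression (NB2, Wald)",
            "=" * 56,
            f"group A libraries : {len(self.group_a)}",
            f"group B libraries : {len(self.group_b)}",
            f"features tested   : {n_tested} / {len(self.table)}",
            f"call thresholds   : |log2FC| > {self.lfc_threshold:g}, "
            f"BH-adjusted p < {self.alpha:g}",
            f"up in group B     : {n_up}",
            f"down in group B   : {n_down}",
        ]
        return "\n".join(lines)


class NBDifferentialExpression:
    """Two-group negative-binomial DE model on a count matrix.

    Parameters
    ----------
    matrix : CountMatrix or DataFrame
        Raw (un-normalized) feature x library counts.
    group_a, group_b : sequences of library ids
        The two groups to compare; the reported fold change is B over A
        (focal species conventionally in B).
    lfc_threshold, alpha : call thresholds (strict inequalities).
    """

    def __init__(
        self,
        matrix: CountMatrix | pd.DataFrame,
        group_a: Sequence[str],
        group_b: Sequence[str],
        lfc_threshold: float = 2.0,
        alpha: float = 0.01,
    ) -> None:
        x = _as_frame(matrix)
        group_a, group_b = list(group_a), list(group_b)
        if not group_a or not group_b:
            raise ValueError("both groups need at least one library")
        missing = (set(group_a) | set(group_b)) - set(x.columns)
        if missing:
            raise ValueError(f"libraries not in matrix: {sorted(missing)}")
        self.counts = x[group_a + group_b]
        self.group_a = group_a
        self.group_b = group_b
        self.lfc_threshold = lfc_threshold
        self.alpha = alpha

    # -- dispersion ---------------------------------------------------------

    @staticmethod
    def _dispersion_mom(
        norm: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray
    ) -> np.ndarray:
        """Per-feature NB2 dispersion by method of moments, pooling the
        within-group variances of normalized counts."""
        n_a, n_b = idx_a.size, idx_b.size
        mu_a = norm[:, idx_a].mean(axis=1, keepdims=True)
        mu_b = norm[:, idx_b].mean(axis=1, keepdims=True)
        ss = ((norm[:, idx_a] - mu_a) ** 2).sum(axis=1) + (
            (norm[:, idx_b] - mu_b) ** 2
        ).sum(axis=1)
        dof = max(n_a + n_b - 2, 1)
        var = ss / dof
        mu = norm.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha = (var - mu) / mu**2
        alpha[~np.isfinite(alpha)] = 0.0
        return np.clip(alpha, _MIN_DISPERSION, _MAX_DISPERSION)

    @staticmethod
    def _dispersion_trend(mu: np.ndarray, alpha_mom: np.ndarray) -> np.ndarray:
        """Fit alpha(mu) = a0 + a1/mu over informative features and return
        the trend value per feature (the floor for the final dispersion)."""
        ok = (mu > 0) & (alpha_mom > _MIN_DISPERSION)
        if ok.sum() < 10:
            floor = float(np.median(alpha_mom[ok])) if ok.any() else _MIN_DISPERSION
            return np.full_like(mu, max(floor, _MIN_DISPERSION))
        design = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
        coef, *_ = np.linalg.lstsq(design, alpha_mom[ok], rcond=None)
        a0 = max(coef[0], _MIN_DISPERSION)
        a1 = max(coef[1], 0.0)
        with np.errstate(divide="ignore"):
            trend = a0 + a1 / np.maximum(mu, 1e-9)
        return np.clip(trend, _MIN_DISPERSION, _MAX_DISPERSION)

    # -- fitting ------------------------------------------------------------

    def fit(self) -> DEResults:
        x = self.counts
        values = x.to_numpy(dtype=float)
        size_factors = size_factors_median_ratio(x)
        sf = size_factors.to_numpy()
        norm = values / sf
        n_a = len(self.group_a)
        idx_a = np.arange(n_a)
        idx_b = np.arange(n_a, n_a + len(self.group_b))

        testable = values.sum(axis=1) > 0
        alpha_mom = self._dispersion_mom(norm, idx_a, idx_b)
        mu = norm.mean(axis=1)
        trend = self._dispersion_trend(mu[testable], alpha_mom[testable])
        # the trend is the working dispersion (the per-feature moment
        # estimate is far too noisy at small n); features sitting well above
        # the trend keep their own estimate so outliers are not anti-
        # conservatively squeezed onto the curve
        mom_t = alpha_mom[testable]
        dispersion = np.full(values.shape[0], np.nan)
        dispersion[testable] = np.where(mom_t > 4.0 * trend, mom_t, trend)

        design = np.column_stack(
            [np.ones(values.shape[1]), np.r_[np.zeros(n_a), np.ones(len(self.group_b))]]
        )
        offset = np.log(sf)

        mean_a = norm[:, idx_a].mean(axis=1)
        mean_b = norm[:, idx_b].mean(axis=1)
        log2fc = np.where(
            testable, np.log2((mean_b + 0.5) / (mean_a + 0.5)), np.nan
        )

        pvalues = np.full(values.shape[0], np.nan)
        for i in np.nonzero(testable)[0]:
            pvalues[i] = self._wald_pvalue(
                values[i], design, offset, dispersion[i]
            )

        padj = np.full(values.shape[0], np.nan)
        tested = ~np.isnan(pvalues)
        if tested.any():
            padj[tested] = bh_adjust(pvalues[tested])

        table = pd.DataFrame(
            {
                "base_mean_a": mean_a,
                "base_mean_b": mean_b,
                "dispersion": dispersion,
                "log2fc": log2fc,
                "pvalue": pvalues,
                "padj": padj,
            },
            index=x.index,
        )
        table["call"] = call_de(table, self.lfc_threshold, self.alpha)
        return DEResults(
            table=table,
            group_a=self.group_a,
            group_b=self.group_b,
            size_factors=size_factors,
            lfc_threshold=self.lfc_threshold,
            alpha=self.alpha,
        )

    @staticmethod
    def _wald_pvalue(
        counts: np.ndarray,
        design: np.ndarray,
        offset: np.ndarray,
        dispersion: float,
    ) -> float:
        """Wald p-value for the group coefficient of a log-link NB GLM."""
        endog = counts
        for bump in (0.0, 0.5):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    model = sm.GLM(
                        endog + bump,
                        design,
                        family=sm.families.NegativeBinomial(alpha=float(dispersion)),
                        offset=offset,
                    )
                    fit = model.fit(maxiter=200, tol=1e-9)
                coef, bse = fit.params[1], fit.bse[1]
                if np.isfinite(coef) and np.isfinite(bse) and bse > 0 and bse < 50:
                    z = coef / bse
                    return float(2.0 * stats.norm.sf(abs(z)))
            except Exception:  # noqa: BLE001 - any numerical failure -> retry
                continue
        return 1.0


def nb_de_test(
    m: CountMatrix | pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    lfc_threshold: float = 2.0,
    alpha: float = 0.01,
) -> DEResults:
    """Convenience wrapper: fit the two-group NB model and return results."""
    return NBDifferentialExpression(
        m, group_a, group_b, lfc_threshold=lfc_threshold, alpha=alpha
    ).fit()


def call_de(
    table: pd.DataFrame, lfc_threshold: float = 2.0, alpha: float = 0.01
) -> pd.Series:
    """Direction calls from a results table (strict thresholds).

    up/down when |log2fc| > lfc_threshold and padj < alpha; "ns" otherwise.
    """
    lfc = table["log2fc"]
    padj = table["padj"]
    significant = (lfc.abs() > lfc_threshold) & (padj < alpha)
    call = pd.Series("ns", index=table.index, name="call")
    call[significant & (lfc > 0)] = "up"
    call[significant & (lfc < 0)] = "down"
    return call


def intersect_de(
    per_comparison_calls: Mapping[str, Mapping[str, str]],
) -> tuple[set[str], set[str]]:
    """Features consistently up (down) in EVERY comparison.

    A feature missing from any comparison, or called in conflicting
    directions, is excluded from both sets.
    """
    if len(per_comparison_calls) < 2:
        raise ValueError("need at least two comparisons to intersect")
    call_maps = list(per_comparison_calls.values())
    common_up = set.intersection(
        *({f for f, c in cm.items() if c == "up"} for cm in call_maps)
    )
    common_down = set.intersection(
        *({f for f, c in cm.items() if c == "down"} for cm in call_maps)
    )
    return common_up, common_down


# ---------------------------------------------------------------------------
# expression-pattern analyses
# ---------------------------------------------------------------------------

@dataclass
class CorrelationClustering:
    """Hierarchical clustering of expression vectors by correlation distance."""

    labels: list[str]
    method: str  # "pearson" or "spearman"
    distance: np.ndarray  # condensed
    linkage: np.ndarray  # scipy linkage matrix (complete)


def correlation_cluster(
    m: CountMatrix | pd.DataFrame, axis: str = "rows"
) -> CorrelationClustering:
    """Complete-linkage clustering with a normality-gated correlation metric.

    Each vector is tested for normality (Shapiro-Wilk); when the median
    p-value exceeds 0.05 the data are treated as normal and Pearson
    correlation is used, otherwise Spearman.  Distance is 1 - correlation;
    vectors with undefined correlations (constant) get the maximal distance 2.
    """
    x = _as_frame(m)
    data = x.to_numpy(dtype=float) if axis == "rows" else x.to_numpy(dtype=float).T
    labels = list(x.index) if axis == "rows" else list(x.columns)
    if data.shape[0] < 3:
        raise ValueError("need at least three vectors to cluster")
    shapiro_p = []
    for row in data:
        if np.ptp(row) == 0 or row.size < 3:
            shapiro_p.append(0.0)
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            shapiro_p.append(float(stats.shapiro(row).pvalue))
    method = "pearson" if float(np.median(shapiro_p)) > 0.05 else "spearman"
    if method == "pearson":
        corr = np.corrcoef(data)
    else:
        corr = stats.spearmanr(data, axis=1).statistic
        corr = np.atleast_2d(corr)
    bad = ~np.isfinite(corr)
    if bad.any():
        logger.warning("constant vectors: %d undefined correlations set to -1",
                       int(bad.sum()))
        corr = np.where(bad, -1.0, corr)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    z = linkage(condensed, method="complete")
    return CorrelationClustering(
        labels=labels, method=method, distance=condensed, linkage=z
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame  # libraries x components
    variance_ratio: np.ndarray


def pca(m: CountMatrix | pd.DataFrame) -> PCAResult:
    """PCA of libraries on feature-centred expression (SVD).

    Libraries are the observations; variance proportions over all components
    sum to 1 and the per-library scores of the leading components describe
    the species separation.
    """
    x = _as_frame(m)
    if x.shape[1] < 2:
        raise ValueError("PCA needs at least two libraries")
    data = x.to_numpy(dtype=float).T  # libraries x features
    centred = data - data.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    var = s**2
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    scores = pd.DataFrame(
        u * s,
        index=x.columns,
        columns=[f"PC{i + 1}" for i in range(s.size)],
    )
    return PCAResult(scores=scores, variance_ratio=ratio)


def accumulate_go_expression(
    m: CountMatrix,
    go_map: Mapping[str, Iterable[str]],
    terms: Sequence[str],
) -> pd.DataFrame:
    """Per-species accumulated expression of selected GO terms.

    For each species, every gene is averaged over that species' libraries;
    a term's total is the sum of those averages over its annotated genes
    present in the matrix.  Terms with no annotated gene in the matrix are
    reported as 0 with a warning.
    """
    x = m.counts
    species_names = sorted(set(m.species.values()))
    gene_means = pd.DataFrame(
        {
            sp: x[m.libraries_of(sp)].mean(axis=1)
            for sp in species_names
        }
    )
    term_to_genes: dict[str, list[str]] = {t: [] for t in terms}
    for gene, gene_terms in go_map.items():
        for t in gene_terms:
            if t in term_to_genes and gene in x.index:
                term_to_genes[t].append(gene)
    rows = {}
    for term in terms:
        genes = term_to_genes[term]
        if not genes:
            warnings.warn(f"GO term {term} has no annotated gene in the matrix")
            rows[term] = pd.Series(0.0, index=species_names)
        else:
            rows[term] = gene_means.loc[genes].sum(axis=0)
    return pd.DataFrame(rows).T[species_names]


__all__ = [
    "CorrelationClustering",
    "DEResults",
    "NBDifferentialExpression",
    "PCAResult",
    "accumulate_go_expression",
    "bh_adjust",
    "call_de",
    "correlation_cluster",
    "filter_expressed",
    "intersect_de",
    "nb_de_test",
    "pca",
    "quantile_normalize",
    "size_factors_median_ratio",
    "tmm_factors",
]
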