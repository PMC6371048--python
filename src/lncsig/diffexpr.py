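"""Normalization, abundance transforms, lncRNA classification and
negative-binomial differential-expression tests.

The count model is NB(mean μ, dispersion α) with Var = μ + α·μ².  Sample
library depth enters through median-of-ratios size factors used as
multiplicative offsets: the expected count of gene g in sample s is
sf_s · m_{g,level(s)}.  Two tests are provided:

* a Wald test on the log2 fold-change between two groups, with a
  delta-method standard error (two-group cohort contrasts);
* a likelihood-ratio test of a full versus a nested reduced mean model
  (time-course designs), with a chi-square reference distribution.

Dispersions are per-gene method-of-moments estimates on normalized counts,
moderated towards the across-gene median (see ``estimate_dispersion``); no
trend fitting and no outlier refitting.  Calibration of the resulting tests
is enforced by simulation-based tests.  Raw p-values are adjusted by
Benjamini–Hochberg.

A gene is classified as a lncRNA when its biotype is neither protein_coding
nor pseudogene and its transcript is at least 200 bp long.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln, xlogy
from scipy.stats import chi2, norm
from sklearn.base import BaseEstimator

from .data import CountMatrix

LNCRNA_EXCLUDED_BIOTYPES = frozenset({"protein_coding", "pseudogene"})
MIN_LNCRNA_LENGTH = 200
DISPERSION_FLOOR = 1e-8
FOLD_CHANGE_PSEUDOCOUNT = 0.5  # added inside the ratio so zero groups stay finite

DE_COLUMNS = ["base_mean", "log2fc", "stat", "p", "padj", "test", "contrast"]


def _as_counts(counts) -> pd.DataFrame:
    if isinstance(counts, CountMatrix):
        return counts.counts
    return counts


def classify_lncrna(annotation: pd.DataFrame) -> set[str]:
    """Return the gene ids considered long non-coding RNAs.

    A gene qualifies when its biotype is not protein_coding or pseudogene and
    its transcript length is at least 200 bp.  Genes with a missing biotype
    are rejected with a warning.
    """
    biotype = annotation["biotype"]
    missing = biotype.isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} genes lack a biotype and were excluded")
    keep = (~missing) & (~biotype.isin(LNCRNA_EXCLUDED_BIOTYPES)) & (
        annotation["transcript_length"] >= MIN_LNCRNA_LENGTH
    )
    return set(annotation.index[keep])


def size_factors(counts) -> pd.Series:
    """Median-of-ratios library-size factors.

    For genes with nonzero counts in every sample, each sample's factor is
    the median ratio of its counts to the per-gene geometric mean.  If no
    gene is nonzero everywhere, falls back to total-count ratios (column sum
    over geometric mean of column sums) with a warning.
    """
    c = _as_counts(counts)
    x = c.to_numpy(dtype=float)
    all_nonzero = (x > 0).all(axis=1)
    if all_nonzero.any():
        logx = np.log(x[all_nonzero])
        geomean = np.exp(logx.mean(axis=1))
        ratios = x[all_nonzero] / geomean[:, None]
        factors = np.median(ratios, axis=0)
    else:
        warnings.warn("no gene with nonzero counts in all samples; using total-count ratios")
        totals = x.sum(axis=0)
        if (totals == 0).any():
            raise ValueError("sample with zero total counts")
        factors = totals / np.exp(np.mean(np.log(totals)))
    if (factors <= 0).any():
        raise ValueError("non-positive size factor")
    return pd.Series(factors, index=c.columns, name="size_factor")


def fpkm(counts, annotation: pd.DataFrame) -> pd.DataFrame:
    """Fragments per kilobase of transcript per million mapped fragments.

    FPKM_gs = count_gs / (transcript_length_kb_g × column_total_millions_s).
    """
    c = _as_counts(counts)
    lengths = annotation.loc[c.index, "transcript_length"].to_numpy(dtype=float)
    totals = c.sum(axis=0).to_numpy(dtype=float)
    if (totals == 0).any():
        raise ValueError("sample with zero total counts")
    values = c.to_numpy(dtype=float) / (lengths[:, None] / 1e3) / (totals[None, :] / 1e6)
    out = pd.DataFrame(values, index=c.index, columns=c.columns)
    out.attrs["kind"] = "fpkm"
    return out


def vst(counts, factors: pd.Series | None = None) -> pd.DataFrame:
    """Variance-flattening transform: log2(normalized count + 1).

    A monotone stand-in for a parametric variance-stabilizing transform;
    downstream stages (z-scoring, correlation, networks) only require
    monotone flattening of the count-variance relationship.
    """
    c = _as_counts(counts)
    if factors is None:
        factors = size_factors(c)
    values = np.log2(c.to_numpy(dtype=float) / factors.to_numpy()[None, :] + 1.0)
    out = pd.DataFrame(values, index=c.index, columns=c.columns)
    out.attrs["kind"] = "vst"
    return out


def estimate_dispersion(counts, groups: pd.Series, factors: pd.Series | None = None,
                        prior_df: float = 10.0) -> pd.Series:
    """Moderated method-of-moments NB dispersion per gene on normalized counts.

    The raw estimate is α_g = max(0, (pooled within-group variance − mean) /
    mean²), floored at 1e-8; groups with a single sample contribute nothing.
    With few residual degrees of freedom the raw estimate is noisy enough to
    make downstream tests anticonservative, so it is shrunk on the log scale
    towards the across-gene median with prior weight ``prior_df`` (relative
    to the pooled residual df), in the spirit of the moderated dispersions
    used by standard count-model frameworks.  ``prior_df=0`` disables
    shrinkage.
    """
    c = _as_counts(counts)
    if factors is None:
        factors = size_factors(c)
    norm_counts = c.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    groups = pd.Series(groups).loc[c.columns]

    ss = np.zeros(c.shape[0])
    dof = 0
    used = np.zeros(c.shape[1], dtype=bool)
    for level in groups.unique():
        idx = (groups == level).to_numpy()
        n = int(idx.sum())
        if n < 2:
            continue
        sub = norm_counts[:, idx]
        ss += sub.var(axis=1, ddof=1) * (n - 1)
        dof += n - 1
        used |= idx
    if dof == 0:
        raise ValueError("need at least one group with >= 2 samples")
    pooled_var = ss / dof
    mean = norm_counts[:, used].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_var - mean) / mean**2
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    alpha = np.maximum(alpha, DISPERSION_FLOOR)
    if prior_df > 0 and alpha.size > 1:
        log_a = np.log(alpha)
        prior = np.median(log_a)
        alpha = np.exp((dof * log_a + prior_df * prior) / (dof + prior_df))
        alpha = np.maximum(alpha, DISPERSION_FLOOR)
    return pd.Series(alpha, index=c.index, name="dispersion")


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (order-preserving).

    NaN inputs propagate to NaN and are excluded from the adjustment.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    q = p[ok]
    if ((q < 0) | (q > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    n = q.size
    if n == 0:
        return out
    order = np.argsort(q, kind="stable")
    ranked = q[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(n)
    res[order] = adj
    out[ok] = res
    return out


# ---------------------------------------------------------------------------
# NB likelihood machinery (vectorized over genes)


def _nb_loglik(c: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Row sums of NB log-likelihood; c, mu are genes × samples, alpha per gene."""
    r = 1.0 / alpha[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (
            gammaln(c + r)
            - gammaln(r)
            - gammaln(c + 1.0)
            - r * np.log1p(mu / r)
            + xlogy(c, mu)
            - xlogy(c, mu + r)
        )
    return np.nansum(ll, axis=1)


def _fit_group_means(c: np.ndarray, sf: np.ndarray, alpha: np.ndarray, n_iter: int = 100,
                     tol: float = 1e-10) -> np.ndarray:
    """MLE of the per-gene NB mean m with offsets sf (expected count sf_s·m).

    Fixed-point iteration on the score equation
    Σ_s (c_s − sf_s m) / (1 + α sf_s m) = 0.
    """
    m = c.sum(axis=1) / sf.sum()
    for _ in range(n_iter):
        denom = 1.0 + alpha[:, None] * sf[None, :] * m[:, None]
        num = (c / denom).sum(axis=1)
        den = (sf[None, :] / denom).sum(axis=1)
        m_new = num / den
        if np.max(np.abs(m_new - m) / (m + 1.0)) < tol:
            m = m_new
            break
        m = m_new
    return m


def _resolve_groups(counts, groups, column: str | None):
    c = _as_counts(counts)
    if groups is None:
        if not isinstance(counts, CountMatrix) or column not in counts.sample_meta.columns:
            raise ValueError(f"need a grouping Series or sample_meta column {column!r}")
        groups = counts.sample_meta[column]
    return c, pd.Series(groups).loc[c.columns].astype(str)


def nb_wald_test(counts, contrast: tuple[str, str], groups: pd.Series | None = None,
                 group_col: str = "group", factors: pd.Series | None = None,
                 dispersions: pd.Series | None = None) -> pd.DataFrame:
    """Per-gene NB Wald test of group B versus group A.

    ``contrast`` is (reference A, comparison B); log2fc is
    log2((μ_B + ε)/(μ_A + ε)) on normalized group means with ε = 0.5, the
    Wald statistic is log2fc over its delta-method standard error and the
    two-sided p comes from the standard normal.  All-zero genes get
    log2fc = 0, p = 1.
    """
    c, grp = _resolve_groups(counts, groups, group_col)
    ref, alt = contrast
    for g in (ref, alt):
        if not (grp == g).any():
            raise ValueError(f"contrast group {g!r} has no samples")
    if factors is None:
        factors = size_factors(c)
    if dispersions is None:
        sub = grp[grp.isin([ref, alt])]
        dispersions = estimate_dispersion(c[sub.index], sub, factors.loc[sub.index])
    alpha = dispersions.loc[c.index].to_numpy()

    x = c.to_numpy(dtype=float)
    sf = factors.to_numpy()
    norm_counts = x / sf[None, :]

    stats = {}
    for g in (ref, alt):
        idx = (grp == g).to_numpy()
        n = idx.sum()
        mu = norm_counts[:, idx].mean(axis=1)
        # Var(c_s/sf_s) = μ/sf_s + α μ² under NB(sf_s μ, α)
        var_hat = (mu[:, None] / sf[None, idx] + alpha[:, None] * mu[:, None] ** 2).sum(axis=1) / n**2
        stats[g] = (mu, var_hat)

    mu_a, var_a = stats[ref]
    mu_b, var_b = stats[alt]
    eps = FOLD_CHANGE_PSEUDOCOUNT
    log2fc = np.log2((mu_b + eps) / (mu_a + eps))
    ln2 = np.log(2.0)
    se = np.sqrt(var_a / (mu_a + eps) ** 2 + var_b / (mu_b + eps) ** 2) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * norm.sf(np.abs(z))
    p = np.where(se > 0, p, 1.0)

    res = pd.DataFrame(
        {
            "base_mean": norm_counts.mean(axis=1),
            "log2fc": log2fc,
            "stat": z,
            "p": p,
            "padj": bh_adjust(p),
            "test": "wald",
            "contrast": f"{alt}_vs_{ref}",
        },
        index=c.index.rename("gene_id"),
    )
    return res


def nb_lrt_test(counts, full: pd.Series | None = None, reduced: pd.Series | None = None,
                full_col: str = "timepoint", factors: pd.Series | None = None,
                dispersions: pd.Series | None = None) -> pd.DataFrame:
    """Per-gene NB likelihood-ratio test of a full versus nested reduced factor.

    Each factor level gets its own NB mean (with size-factor offsets); the
    statistic 2·ΔlogL is referred to chi-square with df = the difference in
    level counts.  ``reduced`` defaults to the intercept-only model.
    log2fc reports the largest pairwise normalized-mean contrast between the
    first full level (reference) and any other level.
    """
    c, full = _resolve_groups(counts, full, full_col)
    if reduced is None:
        reduced = pd.Series("all", index=c.columns)
    reduced = pd.Series(reduced).loc[c.columns].astype(str)
    # nestedness: every full level must sit inside a single reduced level
    nesting = pd.crosstab(full, reduced)
    if ((nesting > 0).sum(axis=1) > 1).any():
        raise ValueError("reduced factor is not nested in full factor")
    df = full.nunique() - reduced.nunique()

    if factors is None:
        factors = size_factors(c)
    if dispersions is None:
        dispersions = estimate_dispersion(c, full, factors)
    alpha = dispersions.loc[c.index].to_numpy()

    x = c.to_numpy(dtype=float)
    sf = factors.to_numpy()

    def model_loglik(labels: pd.Series) -> tuple[np.ndarray, dict]:
        ll = np.zeros(x.shape[0])
        means = {}
        for level in labels.unique():
            idx = (labels == level).to_numpy()
            m = _fit_group_means(x[:, idx], sf[idx], alpha)
            means[level] = m
            ll += _nb_loglik(x[:, idx], sf[None, idx] * m[:, None], alpha)
        return ll, means

    ll_full, means_full = model_loglik(full)
    if df == 0:  # nested identity: nothing to test
        stat = np.zeros(x.shape[0])
        p = np.ones(x.shape[0])
    else:
        ll_red, _ = model_loglik(reduced)
        stat = np.maximum(2.0 * (ll_full - ll_red), 0.0)
        p = chi2.sf(stat, df)

    levels = list(dict.fromkeys(full))
    ref = means_full[levels[0]]
    eps = FOLD_CHANGE_PSEUDOCOUNT
    lfc = np.zeros(x.shape[0])
    for level in levels[1:]:
        cand = np.log2((means_full[level] + eps) / (ref + eps))
        take = np.abs(cand) > np.abs(lfc)
        lfc = np.where(take, cand, lfc)

    all_zero = x.sum(axis=1) == 0
    p = np.where(all_zero, 1.0, p)
    lfc = np.where(all_zero, 0.0, lfc)
    stat = np.where(all_zero, 0.0, stat)

    res = pd.DataFrame(
        {
            "base_mean": (x / sf[None, :]).mean(axis=1),
            "log2fc": lfc,
            "stat": stat,
            "p": p,
            "padj": bh_adjust(p),
            "test": "lrt",
            "contrast": f"{full_col}_full_vs_reduced",
        },
        index=c.index.rename("gene_id"),
    )
    return res


class NegativeBinomialDE(BaseEstimator):
    """Negative-binomial differential expression, sklearn-estimator style.

    Parameters
    ----------
    method : {"wald", "lrt"}
        Wald test of ``contrast`` (two groups) or likelihood-ratio test of
        the full ``design`` factor against the intercept.
    design : str
        Column of ``CountMatrix.sample_meta`` holding the factor.
    contrast : tuple of (reference, comparison) group labels, Wald only.

    Attributes
    ----------
    size_factors_ : pd.Series
    dispersions_ : pd.Series
    results_ : pd.DataFrame with base_mean, log2fc, stat, p, padj per gene.
    """

    def __init__(self, method: str = "wald", design: str = "group",
                 contrast: tuple[str, str] | None = None):
        self.method = method
        self.design = design
        self.contrast = contrast

    def fit(self, counts: CountMatrix, y=None):
        if self.method not in {"wald", "lrt"}:
            raise ValueError(f"unknown method {self.method!r}")
        grp = counts.sample_meta[self.design]
        self.size_factors_ = size_factors(counts)
        self.dispersions_ = estimate_dispersion(counts, grp, self.size_factors_)
        if self.method == "wald":
            if self.contrast is None:
                raise ValueError("Wald test needs a (reference, comparison) contrast")
            self.results_ = nb_wald_test(
                counts, self.contrast, groups=grp,
                factors=self.size_factors_, dispersions=self.dispersions_,
            )
        else:
            self.results_ = nb_lrt_test(
                counts, full=grp, full_col=self.design,
                factors=self.size_factors_, dispersions=self.dispersions_,
            )
        return self
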