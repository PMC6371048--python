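"""Candidate lncRNA selection and cohort replication.

The discovery half pairs stimulus-modulated lncRNAs with interferon /
antiviral protein-coding genes by Spearman correlation (p ≤ 0.05, both
signs) and keeps only lncRNAs with at least one correlated partner located
in cis — gene bodies on the same chromosome within a ±150 kb window.

The replication half checks candidates in case/control cohorts: a candidate
replicates when it is up-regulated (log2FC ≥ 0.58, p ≤ 0.05) versus matched
controls in at least two case groups, and its association with the type I
interferon signature is quantified by Spearman correlation with a six-gene
IFN score (per-sample mean of control-referenced z-scores of IFI27, IFI44L,
IFIT1, IFIT2, IFIT3 and SERPING1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from scipy.stats import t as t_dist
from sklearn.base import BaseEstimator, TransformerMixin

IFN_SIGNATURE_GENES = ("IFI27", "IFI44L", "IFIT1", "IFIT2", "IFIT3", "SERPING1")


@dataclass
class PipelineConfig:
    """Printed analysis constants, overridable per run."""

    cis_window: int = 150_000            # ±150 kb cis window, gene-body gap, inclusive
    log2fc_min: float = 0.58             # |log2FC| threshold for cohort contrasts
    p_max: float = 0.05                  # raw p threshold for cohort contrasts
    padj_max: float = 0.05               # BH threshold for the time course
    fpkm_min: float = 2.0                # expression filter on PCGs
    min_groups: int = 2                  # case groups required for replication
    ifn_genes: tuple[str, ...] = IFN_SIGNATURE_GENES
    corr_p_max: float = 0.05             # Spearman significance for lnc–PCG pairs
    enrich_fdr_max: float = 0.05
    betas: dict = field(default_factory=lambda: {"timecourse": 18, "cohort": 13})
    min_module_size: dict = field(default_factory=lambda: {"timecourse": 20, "cohort": 10})
    cut_height: float = 0.995

    def __post_init__(self) -> None:
        for name in ("cis_window", "log2fc_min", "p_max", "padj_max", "fpkm_min",
                     "min_groups", "corr_p_max", "enrich_fdr_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# correlation


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Ties get average ranks; p uses t = rho·sqrt((n−2)/(1−rho²)) on n−2 df.
    A constant input yields (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input: Spearman correlation undefined")
        return float("nan"), float("nan")
    rx = rankdata(x)
    ry = rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = float(2.0 * t_dist.sf(abs(t), n - 2))
    return rho, p


def _rank_rows(values: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(rankdata, 1, values)


def correlate_lnc_pcg(lnc_expr: pd.DataFrame, pcg_expr: pd.DataFrame,
                      cfg: PipelineConfig | None = None) -> pd.DataFrame:
    """All significant lncRNA × PCG Spearman pairs (both signs retained).

    Expression matrices must share sample columns.  Returns a DataFrame with
    lnc_id, pcg_id, rho, p for pairs with p ≤ ``cfg.corr_p_max``.
    """
    cfg = cfg or PipelineConfig()
    if list(lnc_expr.columns) != list(pcg_expr.columns):
        raise ValueError("sample columns differ between lncRNA and PCG matrices")
    if len(pcg_expr) == 0 or len(lnc_expr) == 0:
        return pd.DataFrame(columns=["lnc_id", "pcg_id", "rho", "p"])
    n = lnc_expr.shape[1]
    if n < 4:
        raise ValueError("need at least 4 samples")

    rl = _rank_rows(lnc_expr.to_numpy(dtype=float))
    rp = _rank_rows(pcg_expr.to_numpy(dtype=float))

    def standardize(r):
        r = r - r.mean(axis=1, keepdims=True)
        sd = r.std(axis=1, ddof=0, keepdims=True)
        ok = sd[:, 0] > 0
        sd[~ok] = 1.0
        return r / sd, ok

    zl, ok_l = standardize(rl)
    zp, ok_p = standardize(rp)
    rho = np.clip(zl @ zp.T / n, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * t_dist.sf(np.abs(t), n - 2)
    p = np.where(np.abs(rho) == 1.0, 0.0, p)
    valid = np.outer(ok_l, ok_p)

    keep = valid & (p <= cfg.corr_p_max)
    li, pi = np.nonzero(keep)
    return pd.DataFrame(
        {
            "lnc_id": lnc_expr.index[li],
            "pcg_id": pcg_expr.index[pi],
            "rho": rho[li, pi],
            "p": p[li, pi],
        }
    )


# ---------------------------------------------------------------------------
# cis pairing


def gene_body_gap(start_a: int, end_a: int, start_b: int, end_b: int) -> int:
    """Gap in bp between two 1-based inclusive gene bodies; 0 when they overlap."""
    return max(0, max(start_a, start_b) - min(end_a, end_b) - 1)


def cis_pairs(lnc: pd.DataFrame, pcg: pd.DataFrame, window: int = 150_000) -> pd.DataFrame:
    """Same-chromosome gene pairs whose body gap is ≤ ``window`` (inclusive).

    ``lnc`` and ``pcg`` are annotation subsets (indexed by gene id, with
    chrom/start/end).  Strand is ignored; overlapping bodies have gap 0.
    Returns lnc_id, pcg_id, gap.
    """
    rows = []
    pcg_by_chrom = dict(tuple(pcg.groupby("chrom", sort=False)))
    for lnc_id, l in lnc.iterrows():
        block = pcg_by_chrom.get(l["chrom"])
        if block is None:
            continue
        gaps = np.maximum(
            0,
            np.maximum(block["start"].to_numpy(), l["start"])
            - np.minimum(block["end"].to_numpy(), l["end"])
            - 1,
        )
        for pcg_id, gap in zip(block.index[gaps <= window], gaps[gaps <= window]):
            if pcg_id != lnc_id:
                rows.append((lnc_id, pcg_id, int(gap)))
    return pd.DataFrame(rows, columns=["lnc_id", "pcg_id", "gap"])


def select_ifn_viral_lncrnas(corr: pd.DataFrame, cis: pd.DataFrame) -> pd.DataFrame:
    """lncRNAs with ≥ 1 PCG both significantly correlated and in cis.

    Returns one row per candidate lncRNA with its supporting PCGs and the
    best (largest |rho|) supporting pair's rho, p and gap.
    """
    if len(corr) == 0 or len(cis) == 0:
        return pd.DataFrame(columns=["lnc_id", "supporting_pcgs", "best_pcg", "rho", "p", "gap"])
    merged = corr.merge(cis, on=["lnc_id", "pcg_id"])
    rows = []
    for lnc_id, block in merged.groupby("lnc_id", sort=False):
        best = block.loc[block["rho"].abs().idxmax()]
        rows.append(
            (lnc_id, ",".join(sorted(block["pcg_id"])), best["pcg_id"],
             float(best["rho"]), float(best["p"]), int(best["gap"]))
        )
    return pd.DataFrame(rows, columns=["lnc_id", "supporting_pcgs", "best_pcg", "rho", "p", "gap"])


# ---------------------------------------------------------------------------
# cohort replication and IFN score


def cohort_replication_filter(de_results: Sequence[pd.DataFrame],
                              cfg: PipelineConfig | None = None) -> set[str]:
    """Genes up-regulated in at least ``min_groups`` case-vs-control contrasts.

    Up-regulation means log2fc ≥ log2fc_min and p ≤ p_max (inclusive bounds);
    down-regulated genes never qualify.
    """
    cfg = cfg or PipelineConfig()
    if len(de_results) < cfg.min_groups:
        raise ValueError(
            f"need >= {cfg.min_groups} case contrasts, got {len(de_results)}"
        )
    hits: dict[str, int] = {}
    for res in de_results:
        sig = res[(res["log2fc"] >= cfg.log2fc_min) & (res["p"] <= cfg.p_max)]
        for g in sig.index:
            hits[g] = hits.get(g, 0) + 1
    return {g for g, n in hits.items() if n >= cfg.min_groups}


class IFNScorer(BaseEstimator, TransformerMixin):
    """Six-gene type I interferon signature score.

    ``fit`` learns per-gene mean and sd on healthy-control samples (columns
    of a vst matrix); ``transform`` returns, per sample, the mean across
    signature genes of (vst − HC mean) / HC sd.  Genes absent from the
    matrix or with zero HC sd are dropped with a warning.
    """

    def __init__(self, genes: Iterable[str] = IFN_SIGNATURE_GENES):
        self.genes = tuple(genes)

    def fit(self, hc_expr: pd.DataFrame, y=None):
        if hc_expr.shape[1] < 2:
            raise ValueError("need at least 2 healthy-control samples")
        present = [g for g in self.genes if g in hc_expr.index]
        absent = set(self.genes) - set(present)
        if absent:
            warnings.warn(f"signature genes missing from matrix: {sorted(absent)}")
        if not present:
            raise ValueError("no signature genes present")
        sub = hc_expr.loc[present]
        mean = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        degenerate = sd == 0
        if degenerate.any():
            warnings.warn(f"zero control sd, dropping: {sorted(sub.index[degenerate])}")
        self.genes_ = [g for g in present if sd[g] > 0]
        if not self.genes_:
            raise ValueError("all signature genes degenerate in controls")
        self.hc_mean_ = mean[self.genes_]
        self.hc_sd_ = sd[self.genes_]
        return self

    def transform(self, expr: pd.DataFrame) -> pd.Series:
        z = expr.loc[self.genes_].sub(self.hc_mean_, axis=0).div(self.hc_sd_, axis=0)
        return pd.Series(z.mean(axis=0), name="ifn_score")


def ifn_score(expr: pd.DataFrame, cfg: PipelineConfig | None = None,
              hc_samples: Iterable[str] = ()) -> pd.Series:
    """Per-sample IFN score of ``expr`` referenced to the ``hc_samples`` columns."""
    cfg = cfg or PipelineConfig()
    hc = list(hc_samples)
    scorer = IFNScorer(genes=cfg.ifn_genes).fit(expr[hc])
    return scorer.transform(expr)


def score_correlation(lnc_expr, scores) -> tuple[float, float]:
    """Spearman rho and p between a candidate lncRNA's expression and the IFN score."""
    lnc_expr = pd.Series(lnc_expr)
    scores = pd.Series(scores)
    common = lnc_expr.index.intersection(scores.index)
    if len(common) != len(scores) or len(common) != len(lnc_expr):
        raise ValueError("sample mismatch between expression and scores")
    return spearman(lnc_expr[common].to_numpy(), scores[common].to_numpy())


# ---------------------------------------------------------------------------
# cross-dataset intersection


def intersect_de_sets(sets: Sequence[set[str]], names: Sequence[str] | None = None) -> dict:
    """Intersection lattice (all 2-way … full combinations) with sizes."""
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    if names is None:
        names = [f"set{i + 1}" for i in range(len(sets))]
    out: dict = {"sets": {n: sorted(s) for n, s in zip(names, sets)}, "intersections": {}}
    for r in range(2, len(sets) + 1):
        for combo in combinations(range(len(sets)), r):
            inter = set(sets[combo[0]])
            for i in combo[1:]:
                inter &= set(sets[i])
            key = "&".join(names[i] for i in combo)
            out["intersections"][key] = {"genes": sorted(inter), "size": len(inter)}
    full_key = "&".join(names)
    out["full"] = out["intersections"][full_key]
    return out
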