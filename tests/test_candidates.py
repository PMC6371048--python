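"""Correlation, cis pairing, replication filter, IFN score, intersections."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from lncsig import (
    PipelineConfig,
    cis_pairs,
    cohort_replication_filter,
    correlate_lnc_pcg,
    ifn_score,
    intersect_de_sets,
    score_correlation,
    select_ifn_viral_lncrnas,
    spearman,
)
from lncsig.candidates import IFNScorer, gene_body_gap


# ---------------------------------------------------------------------------
# Spearman


def test_spearman_monotone_and_antitone():
    x = np.arange(10.0)
    assert spearman(x, 2 * x + 1)[0] == pytest.approx(1.0)
    assert spearman(x, -(x**3))[0] == pytest.approx(-1.0)


def test_spearman_printed_five_point_example():
    rho, p = spearman([1, 2, 3, 4, 5], [1, 2, 3, 5, 4])
    assert rho == pytest.approx(0.9)  # 1 - 6*2/(5*24)
    assert 0 < p < 1


def test_spearman_matches_scipy_with_ties():
    rng = np.random.default_rng(0)
    for _ in range(20):
        x = rng.integers(0, 5, 15).astype(float)  # heavy ties
        y = rng.normal(size=15)
        rho, p = spearman(x, y)
        ref = spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


def test_spearman_constant_input_flagged():
    with pytest.warns(UserWarning):
        rho, p = spearman([1, 1, 1, 1], [1, 2, 3, 4])
    assert np.isnan(rho) and np.isnan(p)


# ---------------------------------------------------------------------------
# lnc x PCG correlation


def _expr(values, prefix):
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        values,
        index=[f"{prefix}{i}" for i in range(values.shape[0])],
        columns=[f"s{i}" for i in range(values.shape[1])],
    )


def test_identical_rows_retained_with_rho_one():
    rng = np.random.default_rng(1)
    base = rng.normal(size=12)
    lnc = _expr([base], "l")
    pcg = _expr([base, rng.normal(size=12)], "p")
    out = correlate_lnc_pcg(lnc, pcg)
    hit = out[(out["lnc_id"] == "l0") & (out["pcg_id"] == "p0")]
    assert len(hit) == 1
    assert hit.iloc[0]["rho"] == pytest.approx(1.0)


def test_null_correlation_calibration():
    # independent lncRNA retained against ~corr_p_max of PCGs
    rng = np.random.default_rng(2)
    fracs = []
    for _ in range(5):
        lnc = _expr(rng.normal(size=(1, 20)), "l")
        pcg = _expr(rng.normal(size=(200, 20)), "p")
        fracs.append(len(correlate_lnc_pcg(lnc, pcg)) / 200)
    assert np.mean(fracs) < 0.12


def test_empty_pcg_set_gives_empty_output():
    lnc = _expr(np.random.default_rng(0).normal(size=(2, 10)), "l")
    out = correlate_lnc_pcg(lnc, lnc.iloc[:0], PipelineConfig())
    assert len(out) == 0


def test_sample_mismatch_rejected():
    lnc = _expr(np.zeros((1, 5)), "l")
    pcg = _expr(np.zeros((1, 5)), "p")
    pcg.columns = [f"x{i}" for i in range(5)]
    with pytest.raises(ValueError, match="sample"):
        correlate_lnc_pcg(lnc, pcg)


# ---------------------------------------------------------------------------
# cis pairing


def _ann(rows):
    return pd.DataFrame(
        [(chrom, s, e) for chrom, s, e in rows],
        columns=["chrom", "start", "end"],
        index=[f"g{i}" for i in range(len(rows))],
    )


def test_cis_gap_boundary_case():
    # bodies [100000, 101000] and [251000, 260000]: gap 149999 <= 150000
    lnc = _ann([("chr1", 100_000, 101_000)])
    pcg = _ann([("chr1", 251_000, 260_000)])
    pcg.index = ["p0"]
    out = cis_pairs(lnc, pcg, window=150_000)
    assert len(out) == 1
    assert out.iloc[0]["gap"] == 149_999
    assert gene_body_gap(100_000, 101_000, 251_000, 260_000) == 149_999


def test_cis_overlap_and_different_chromosome():
    lnc = _ann([("chr1", 100, 500)])
    overlapping = _ann([("chr1", 400, 900)])
    overlapping.index = ["p0"]
    out = cis_pairs(lnc, overlapping, window=0)
    assert len(out) == 1 and out.iloc[0]["gap"] == 0
    far_chrom = _ann([("chr2", 100, 500)])
    far_chrom.index = ["p0"]
    assert len(cis_pairs(lnc, far_chrom, window=10**9)) == 0


def test_cis_symmetry_and_window_monotonicity():
    rng = np.random.default_rng(3)
    rows = [("chr1", int(s), int(s + rng.integers(100, 5000)))
            for s in rng.integers(1, 2_000_000, 30)]
    a = _ann(rows[:15])
    b = _ann(rows[15:])
    b.index = [f"h{i}" for i in range(15)]
    small = cis_pairs(a, b, window=50_000)
    large = cis_pairs(a, b, window=200_000)
    assert set(map(tuple, small.values)) <= set(map(tuple, large.values))
    mirrored = cis_pairs(b, a, window=50_000)
    assert {(l, p, g) for l, p, g in small.values} == {(p, l, g) for l, p, g in mirrored.values}


def test_candidate_selection_requires_both_conditions():
    corr = pd.DataFrame({"lnc_id": ["l1", "l2"], "pcg_id": ["pA", "pB"],
                         "rho": [0.9, 0.8], "p": [0.01, 0.01]})
    cis = pd.DataFrame({"lnc_id": ["l1", "l3"], "pcg_id": ["pA", "pC"],
                        "gap": [1000, 0]})
    out = select_ifn_viral_lncrnas(corr, cis)
    assert list(out["lnc_id"]) == ["l1"]  # l2 not cis, l3 not correlated
    assert out.iloc[0]["best_pcg"] == "pA"


# ---------------------------------------------------------------------------
# cohort replication


def _de(genes, lfc, p):
    return pd.DataFrame({"log2fc": lfc, "p": p}, index=genes)


def test_replication_boundary_inclusive():
    g = ["x"]
    des = [_de(g, [0.58], [0.05]), _de(g, [0.58], [0.05]), _de(g, [0.1], [0.9])]
    assert cohort_replication_filter(des) == {"x"}


def test_replication_requires_two_groups_and_up_direction():
    g = ["x"]
    one_hit = [_de(g, [2.0], [0.001]), _de(g, [0.0], [0.9]), _de(g, [0.0], [0.9])]
    assert cohort_replication_filter(one_hit) == set()
    down = [_de(g, [-0.9], [0.001])] * 3
    assert cohort_replication_filter(down) == set()
    with pytest.raises(ValueError):
        cohort_replication_filter([_de(g, [1.0], [0.01])])


# ---------------------------------------------------------------------------
# IFN score


@pytest.fixture()
def hc_expr():
    rng = np.random.default_rng(4)
    genes = list(PipelineConfig().ifn_genes)
    return pd.DataFrame(rng.normal(10, 2, size=(6, 8)), index=genes,
                        columns=[f"HC{i}" for i in range(8)])


def test_score_zero_at_hc_mean(hc_expr):
    scorer = IFNScorer().fit(hc_expr)
    probe = pd.DataFrame({"new": hc_expr.mean(axis=1)})
    assert scorer.transform(probe)["new"] == pytest.approx(0.0)


def test_score_two_sd_construction(hc_expr):
    scorer = IFNScorer().fit(hc_expr)
    probe = pd.DataFrame({"new": hc_expr.mean(axis=1) + 2 * hc_expr.std(axis=1, ddof=1)})
    assert scorer.transform(probe)["new"] == pytest.approx(2.0)


def test_hc_scores_center_at_zero(hc_expr):
    scores = ifn_score(hc_expr, PipelineConfig(), hc_samples=list(hc_expr.columns))
    assert scores.mean() == pytest.approx(0.0, abs=1e-12)


def test_missing_signature_gene_dropped_with_warning(hc_expr):
    with pytest.warns(UserWarning, match="missing"):
        scorer = IFNScorer().fit(hc_expr.drop(index="IFI27"))
    assert "IFI27" not in scorer.genes_


def test_score_correlation_with_signature_mean(hc_expr):
    rng = np.random.default_rng(5)
    expr = pd.concat(
        [hc_expr, pd.DataFrame(rng.normal(12, 3, size=(6, 12)), index=hc_expr.index,
                               columns=[f"P{i}" for i in range(12)])], axis=1)
    scores = ifn_score(expr, PipelineConfig(), hc_samples=list(hc_expr.columns))
    # a lncRNA tracking the signature mean correlates perfectly
    lnc = expr.sub(expr[hc_expr.columns].mean(axis=1), axis=0).div(
        expr[hc_expr.columns].std(axis=1, ddof=1), axis=0).mean(axis=0)
    rho, p = score_correlation(lnc, scores)
    assert rho == pytest.approx(1.0)
    assert p == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# DE-set intersections


def test_intersection_lattice():
    out = intersect_de_sets([{"A", "B", "C"}, {"B", "C"}, {"C"}],
                            names=["lps", "ssc", "sle"])
    assert out["full"]["genes"] == ["C"]
    assert out["intersections"]["lps&ssc"]["size"] == 2
    disjoint = intersect_de_sets([{"A"}, {"B"}])
    assert disjoint["full"]["size"] == 0
    equal = intersect_de_sets([{"A", "B"}, {"A", "B"}])
    assert set(equal["full"]["genes"]) == {"A", "B"}
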