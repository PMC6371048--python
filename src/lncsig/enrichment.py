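"""Hypergeometric gene-set over-representation with BH FDR.

One-sided over-representation only: for a query of n genes drawn from a
universe of N, a term with K members in the universe and k in the query is
scored by the upper hypergeometric tail p = P(X ≥ k).  The universe is the
caller's responsibility; the discovery pipeline uses all genes passing the
expression filter (mean FPKM > 2 in at least one condition), the standard
choice for expression-matched backgrounds.

Interferon / antiviral terms are picked out of the significant set by
case-insensitive keyword match on the term name — a proxy for a curated
term list.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust

RESPONSE_KEYWORDS = ("interferon", "type I IFN", "virus", "viral", "defense response")

ENRICHMENT_COLUMNS = ["term_id", "term_name", "k", "K", "n", "N", "p", "fdr"]

TermMap = Mapping[str, tuple[str, set[str]]]


def hypergeom_enrich(query: set[str], universe: set[str], terms: TermMap) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in each term.

    Term gene sets are intersected with the universe first; terms left empty
    are skipped.  FDR is BH across the tested terms.
    """
    if not query:
        raise ValueError("empty query gene set")
    extra = set(query) - set(universe)
    if extra:
        raise ValueError(f"query genes outside universe: {sorted(extra)[:5]}")
    N = len(universe)
    n = len(query)
    rows = []
    for term_id, (name, genes) in terms.items():
        members = genes & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, name, k, K, n, N, p))
    res = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
    res["fdr"] = bh_adjust(res["p"]) if len(res) else []
    return res.sort_values("p", kind="stable").reset_index(drop=True)


def select_response_terms(results: pd.DataFrame, keywords: Iterable[str] = RESPONSE_KEYWORDS,
                          fdr_max: float = 0.05) -> list[str]:
    """Significant terms whose name matches any keyword (case-insensitive)."""
    kw = [k.lower() for k in keywords]
    keep = results[
        (results["fdr"] <= fdr_max)
        & results["term_name"].str.lower().map(lambda s: any(k in s for k in kw))
    ]
    return list(keep["term_id"])


def genes_of_terms(term_ids: Iterable[str], terms: TermMap, restrict: set[str]) -> set[str]:
    """Union of member genes of the given terms, intersected with ``restrict``."""
    out: set[str] = set()
    for term_id in term_ids:
        if term_id not in terms:
            raise KeyError(f"unknown term id {term_id!r}")
        out |= terms[term_id][1]
    return out & set(restrict)
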