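"""Gene-set enrichment of annotation terms by the hypergeometric
(one-sided Fisher) test.

Designed for transcription-factor-family labels but works for any
gene -> term mapping (e.g. GO-style slims).  The default 2x2 table compares
a gene set against the disjoint remainder of the universe:

    [[k, n_set - k], [K - k, N - n_set - (K - k)]]

where k = set members carrying the term, n_set = set size, K = universe
genes carrying the term, N = universe size.  An overlapping variant that
compares the set against the whole universe is available via
``background="universe"``.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .decore import bh_adjust
from .memclass import round_half_up


def _terms_of(annotation: Mapping, gene) -> Iterable[str]:
    v = annotation.get(gene)
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return ()
    if isinstance(v, str):
        return (v,)
    return tuple(v)


def fisher_enrichment(
    gene_set: Iterable,
    universe: Iterable,
    annotation: Mapping,
    alternative: str = "greater",
    background: str = "remainder",
) -> pd.DataFrame:
    """Per-term enrichment of ``gene_set`` within ``universe``.

    Returns a DataFrame with columns term, k, n_set, K, N, odds_ratio,
    pvalue, padj, ordered by padj then pvalue.  The odds ratio is taken from
    the 2x2 table, with 0.5 added to every cell only when a zero cell would
    make it undefined.
    """
    universe = set(universe)
    gene_set = set(gene_set)
    stray = gene_set - universe
    if stray:
        raise ValueError(f"gene_set not contained in universe: {sorted(stray)[:10]}")
    bad_keys = set(annotation) - universe
    if bad_keys:
        raise ValueError(f"annotation keys outside universe: {sorted(bad_keys)[:10]}")

    n_set, n_univ = len(gene_set), len(universe)
    term_k: dict[str, int] = {}
    term_total: dict[str, int] = {}
    for gene in universe:
        for term in _terms_of(annotation, gene):
            term_total[term] = term_total.get(term, 0) + 1
            if gene in gene_set:
                term_k[term] = term_k.get(term, 0) + 1

    rows = []
    for term in sorted(term_total):
        k = term_k.get(term, 0)
        big_k = term_total[term]
        if background == "remainder":
            table = np.array(
                [[k, n_set - k], [big_k - k, n_univ - n_set - (big_k - k)]], dtype=float
            )
            if alternative == "greater":
                pvalue = float(stats.hypergeom.sf(k - 1, n_univ, big_k, n_set))
            else:
                pvalue = float(
                    stats.fisher_exact(table.astype(int), alternative=alternative)[1]
                )
        elif background == "universe":
            table = np.array([[k, n_set - k], [big_k, n_univ - big_k]], dtype=float)
            pvalue = float(stats.fisher_exact(table.astype(int), alternative=alternative)[1])
        else:
            raise ValueError(f"unknown background: {background!r}")
        a, b, c, d = table.ravel()
        if b * c == 0:  # odds ratio undefined; Haldane-Anscombe correction
            a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        odds = (a * d) / (b * c)
        rows.append(
            {
                "term": term,
                "k": k,
                "n_set": n_set,
                "K": big_k,
                "N": n_univ,
                "odds_ratio": odds,
                "pvalue": pvalue,
            }
        )
    result = pd.DataFrame(
        rows, columns=["term", "k", "n_set", "K", "N", "odds_ratio", "pvalue"]
    )
    if len(result):
        result["padj"] = bh_adjust(result["pvalue"].to_numpy())
        result = result.sort_values(["padj", "pvalue", "term"], kind="mergesort")
        result = result.reset_index(drop=True)
    else:
        result["padj"] = pd.Series(dtype=float)
    return result


def fisher_2x2(k: int, n_set: int, big_k: int, n_univ: int) -> float:
    """Upper-tail hypergeometric p for one term without building a mapping:
    k of n_set set genes carry the term, K of N universe genes carry it."""
    return float(stats.hypergeom.sf(k - 1, n_univ, big_k, n_set))


def proportion(numerator: int, denominator: int) -> float:
    """Percentage ``100 * numerator / denominator`` rounded to one decimal."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round_half_up(100.0 * numerator / denominator, 1)
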