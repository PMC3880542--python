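"""Hypergeometric GO over-representation with Benjamini-Hochberg adjustment.

Given a query gene list (e.g. the upregulated genes of the screen) and a
gene-to-term annotation table, each term is tested for over-representation
with the exact upper-tail hypergeometric probability

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n)

where N is the universe size, K the term size, n the query size and k the
observed overlap ("at least k" convention).  Raw p-values are adjusted with
the Benjamini-Hochberg step-up over the family of tested terms (terms with
k >= 1), and a term is called significant at p_adj <= alpha (default 0.05).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k).

    X counts the overlap when drawing n genes from a universe of N of which
    K carry the term.  Computed exactly via the hypergeometric survival
    function, never a normal approximation.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N; got K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"need 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved.

    p_adj for the i-th smallest p is min over j >= i of (m/j) p_(j), capped
    at 1, with m the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size and (np.isnan(p).any() or (p < 0).any() or (p > 1).any()):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def enrich(
    query,
    annotation: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    universe=None,
) -> pd.DataFrame:
    """Over-representation test of every annotated term against a query list.

    Parameters
    ----------
    query
        Gene identifiers of interest (e.g. the up list of the fold-change
        screen).  Genes outside the universe are dropped with a warning.
    annotation
        Two columns, ``gene`` and ``term``; duplicated pairs are ignored.
    alpha
        Significance level applied to BH-adjusted p-values.
    universe
        Reference gene set; defaults to all genes in the annotation table.

    Returns
    -------
    DataFrame with one row per term with overlap k >= 1, columns
    term, k, K, n, N, p_raw, p_adj, significant; sorted by p_adj ascending
    with ties broken by term id.
    """
    pairs = annotation[["gene", "term"]].drop_duplicates()
    universe = set(universe) if universe is not None else set(pairs["gene"])
    if not universe:
        raise ValueError("empty universe")
    stray = set(pairs["gene"]) - universe
    if stray:
        raise ValueError(f"annotated genes missing from universe: {sorted(stray)[:5]}...")

    query = list(dict.fromkeys(query))
    outside = [g for g in query if g not in universe]
    if outside:
        logger.warning(
            "dropping %d query gene(s) outside the universe: %s",
            len(outside), outside[:10],
        )
    query_set = {g for g in query if g in universe}

    N = len(universe)
    n = len(query_set)
    rows = []
    for term, genes in pairs.groupby("term")["gene"]:
        term_set = set(genes)
        k = len(term_set & query_set)
        if k == 0:
            continue
        K = len(term_set)
        rows.append((term, k, K, n, N, hypergeom_tail(k, K, n, N)))
    result = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p_raw"])
    if len(result):
        result["p_adj"] = bh_adjust(result["p_raw"].to_numpy())
    else:
        result["p_adj"] = pd.Series(dtype=float)
    result["significant"] = result["p_adj"] <= alpha
    return result.sort_values(["p_adj", "term"], kind="stable").reset_index(drop=True)
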