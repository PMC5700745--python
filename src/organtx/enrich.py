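"""Hypergeometric over-representation analysis of gene sets.

For a DEG set of size n drawn from a background of N genes, a term with K
annotated background genes and k annotated DEGs is scored by the upper tail
of the hypergeometric distribution, P(X >= k) — the chance of seeing at
least that much overlap if the DEG set were a uniform draw. p-values are
corrected across all tested terms (Benjamini-Hochberg by default,
Bonferroni optionally) and terms pass at corrected p <= 0.05.

The background is the measured gene universe recorded in the TermMap, not
the whole annotation database; all terms are tested, including those with
zero overlap (which get p = 1), so the correction denominator is the full
term count.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError
from .io import PipelineConfig, TermMap

__all__ = ["hypergeom_test", "enrich"]

#: Columns of an enrichment result table, one row per term.
ENRICHMENT_COLUMNS = (
    "term_id", "term_name", "k", "K", "n", "N", "p_raw", "p_adj", "significant",
)


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    X counts term-annotated genes in a size-n uniform draw from N background
    genes of which K carry the term.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ParameterError(
            f"inconsistent counts k={k}, K={K}, n={n}, N={N}"
        )
    # sf(k-1) = P(X > k-1) = P(X >= k)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    deg_set: set[str], terms: TermMap, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Score every term for over-representation in ``deg_set``.

    Returns one row per term (k = 0 terms included with p_raw = 1), corrected
    across all tested terms, sorted by p_adj then term id. ``significant``
    is corrected p <= ``config.enrich_alpha``.
    """
    config = config or PipelineConfig()
    if not terms.background:
        raise ParameterError("empty annotation background")
    degs = deg_set & terms.background
    if not degs:
        raise ParameterError("DEG set does not intersect the background")
    N = len(terms.background)
    n = len(degs)
    inv = terms.term_genes()
    rows = []
    for tid in terms.term_ids:
        members = inv[tid] & terms.background
        K = len(members)
        k = len(members & degs)
        rows.append(
            {
                "term_id": tid,
                "term_name": terms.term_names.get(tid, tid),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_raw": hypergeom_test(k, K, n, N),
            }
        )
    df = pd.DataFrame(rows)
    _, p_adj, _, _ = multipletests(df["p_raw"], method=config.correction)
    df["p_adj"] = p_adj
    df["significant"] = df["p_adj"] <= config.enrich_alpha
    df = df.sort_values(["p_adj", "term_id"], kind="mergesort").reset_index(drop=True)
    return df
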