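"""TF-to-target co-expression network by Pearson correlation.

Every (transcription factor, target gene) pair is scored by the Pearson
product-moment correlation r of their expression profiles across all
replicate samples, with the standard two-sided significance test

    t = r * sqrt((n - 2) / (1 - r^2))   on n - 2 degrees of freedom.

An edge is retained when |r| >= 0.95 (inclusive) AND p < 0.01 (strict), the
published joint rule; the sign of r is kept on the edge but both signs are
retained. Profiles are correlated at replicate level (not organ means): with
eight samples the t-test has six degrees of freedom, enough for p < 0.01 to
be attainable, which three organ means would not allow.

Also provides the family tally of network TFs and deterministic hierarchical
clustering (average linkage on 1 - PCC distance) for heatmap row ordering.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .errors import ComputationError, ConsistencyError, ParameterError
from .io import ExpressionMatrix, PipelineConfig, TFTable

__all__ = [
    "pearson",
    "build_network",
    "family_distribution",
    "hcluster_order",
]

logger = logging.getLogger(__name__)

#: Columns of a network edge table, one row per retained TF-target edge.
EDGE_COLUMNS = ("regulator", "target", "r", "p", "family")


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r and its two-sided t-test p-value.

    Computed from the product-moment formula directly (the p-value via the
    t transform on n - 2 df); requires n >= 3 and non-constant vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 3:
        raise ParameterError("need at least 3 samples for a correlation p-value")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt((xd**2).sum() * (yd**2).sum())
    if denom == 0:
        raise ComputationError("constant vector: correlation undefined")
    r = float(np.clip((xd * yd).sum() / denom, -1.0, 1.0))
    p = _r_pvalue(np.asarray([r]), n)[0]
    return r, float(p)


def _r_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for Pearson r on n samples via the t-distribution."""
    with np.errstate(divide="ignore"):
        t = np.abs(r) * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 0.0))
    return 2.0 * stats.t.sf(t, df=n - 2)


def r_tail_probability(r0: float, n: int) -> float:
    """P(|r| >= r0) for independent Gaussian profiles of length n.

    Closed-form null tail used to bound the false-edge rate of
    :func:`build_network`: under independence, r * sqrt((n-2)/(1-r^2)) is
    Student-t with n - 2 df, so the tail is the two-sided t-tail at r0.
    """
    t0 = r0 * np.sqrt((n - 2) / (1.0 - r0**2))
    return float(2.0 * stats.t.sf(t0, df=n - 2))


def build_network(
    tf_expr: ExpressionMatrix,
    target_expr: ExpressionMatrix,
    config: PipelineConfig | None = None,
    tf_table: TFTable | None = None,
) -> pd.DataFrame:
    """Score every TF x target pair; retain |r| >= pcc_threshold and p < pcc_alpha.

    Correlations are computed in one standardized matrix product over the
    shared sample axis. Constant profiles (zero variance) cannot be
    correlated; their pairs are skipped with a logged warning. Returns an
    edge table with columns regulator, target, r, p, family (family empty
    when no ``tf_table`` is given), sorted by regulator then target.
    """
    config = config or PipelineConfig()
    shared = [s for s in tf_expr.sample_ids if s in set(target_expr.sample_ids)]
    if not shared:
        raise ConsistencyError("no shared samples between TF and target matrices")
    n = len(shared)
    if n < 3:
        raise ParameterError("need at least 3 shared samples")
    X = tf_expr.values[shared].to_numpy(dtype=float)
    Y = target_expr.values[shared].to_numpy(dtype=float)

    def _standardize(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        centered = a - a.mean(axis=1, keepdims=True)
        norm = np.sqrt((centered**2).sum(axis=1, keepdims=True))
        ok = norm[:, 0] > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(norm > 0, centered / norm, 0.0)
        return z, ok

    Zx, ok_x = _standardize(X)
    Zy, ok_y = _standardize(Y)
    for ids, ok, label in (
        (tf_expr.gene_ids, ok_x, "TF"),
        (target_expr.gene_ids, ok_y, "target"),
    ):
        dropped = [g for g, o in zip(ids, ok) if not o]
        if dropped:
            logger.warning(
                "%s profile(s) constant across samples, skipped: %s", label, dropped
            )
    R = np.clip(Zx @ Zy.T, -1.0, 1.0)
    P = _r_pvalue(R, n)
    fam = tf_table.family_of() if tf_table is not None else {}
    rows = []
    tf_ids = tf_expr.gene_ids
    tgt_ids = target_expr.gene_ids
    keep = (np.abs(R) >= config.pcc_threshold) & (P < config.pcc_alpha)
    keep &= ok_x[:, None] & ok_y[None, :]
    for i, j in zip(*np.nonzero(keep)):
        rows.append(
            {
                "regulator": tf_ids[i],
                "target": tgt_ids[j],
                "r": float(R[i, j]),
                "p": float(P[i, j]),
                "family": fam.get(tf_ids[i], ""),
            }
        )
    df = pd.DataFrame(rows, columns=list(EDGE_COLUMNS))
    return df.sort_values(["regulator", "target"], kind="mergesort").reset_index(
        drop=True
    )


def family_distribution(
    genes_or_edges: pd.DataFrame | set[str], tfs: TFTable
) -> pd.DataFrame:
    """Count TF families among network regulators (or any TF gene set).

    Sorted by descending count, ties broken alphabetically by family. Every
    gene must appear in the TF table.
    """
    if isinstance(genes_or_edges, pd.DataFrame):
        genes = set(genes_or_edges["regulator"])
    else:
        genes = set(genes_or_edges)
    fam = tfs.family_of()
    missing = sorted(g for g in genes if g not in fam)
    if missing:
        raise ConsistencyError(f"gene(s) missing from TF table: {missing[:10]}")
    counts: dict[str, int] = {}
    for g in genes:
        counts[fam[g]] = counts.get(fam[g], 0) + 1
    df = pd.DataFrame(
        {"family": list(counts), "count": list(counts.values())}
    )
    return df.sort_values(
        ["count", "family"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def hcluster_order(
    expr: ExpressionMatrix, metric: str = "correlation"
) -> tuple[list[str], np.ndarray]:
    """Deterministic leaf order for an expression heatmap.

    Agglomerative clustering with average linkage; distance is 1 - PCC by
    default. Returns (ordered gene ids, SciPy linkage matrix). A constant
    row has no defined correlation distance; callers should fall back to
    ``metric="euclidean"`` for such data.
    """
    vals = expr.values.to_numpy(dtype=float)
    if vals.shape[0] < 2:
        raise ParameterError("need at least 2 rows to cluster")
    if metric == "correlation":
        if (vals.std(axis=1) == 0).any():
            bad = [g for g, s in zip(expr.gene_ids, vals.std(axis=1)) if s == 0]
            raise ComputationError(
                f"constant row(s) {bad[:5]} have no correlation distance; "
                "use metric='euclidean'"
            )
    dist = pdist(vals, metric=metric)
    # correlation distance can dip epsilon-negative by roundoff
    dist = np.clip(dist, 0.0, None)
    Z = hierarchy.linkage(dist, method="average")
    order = hierarchy.leaves_list(Z)
    return [expr.gene_ids[i] for i in order], Z
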