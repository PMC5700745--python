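"""Noise-distribution differential-expression screen (NOIseq-style M/D/P).

For a pair of organs the screen compares, per gene, the log2 fold change
M = log2(x1/x2) and the absolute expression difference D = |x1 - x2| of the
replicate-mean RPKM values against an empirical *noise distribution* of the
same two statistics computed between replicates of the same organ. The
probability that gene i is differentially expressed is the fraction of noise
points strictly dominated by its signal:

    P = P(|M*| < |m_i|  and  D* < d_i)

with strict inequalities on both coordinates. Genes with P > 0.8 and
|M| > 2 are called differential (up or down by the sign of M relative to the
first-listed organ).

Zeros are handled by substituting 0.001 for an unexpressed value inside the
log ratio only; D keeps the actual RPKM difference by default, so a gene at
(10, 0) gets M = log2(10/0.001) and D = 10. The substitution can optionally
also apply inside D (``config.substitute_in_d``) for strict parity with
implementations that substitute before both statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ComputationError, ParameterError
from .io import ExpressionMatrix, PipelineConfig

__all__ = [
    "NoiseDistribution",
    "compute_md",
    "build_noise",
    "signal_md",
    "deg_probability",
    "deg_probabilities",
    "call_degs",
    "pairwise_screen",
]

#: Columns of a DEG record table: one row per gene for one organ pair.
DEG_COLUMNS = ("gene", "m", "d", "p", "call")


@dataclass(frozen=True)
class NoiseDistribution:
    """Pooled empirical (M*, D*) pairs from within-organ replicate contrasts."""

    m: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        if self.m.shape != self.d.shape or self.m.ndim != 1:
            raise ParameterError("noise m and d must be matching 1-d arrays")
        if not (np.isfinite(self.m).all() and np.isfinite(self.d).all()):
            raise ParameterError("noise distribution contains non-finite values")

    @property
    def n_points(self) -> int:
        return self.m.size


def _md_arrays(
    x1: np.ndarray, x2: np.ndarray, zero_substitute: float, substitute_in_d: bool
) -> tuple[np.ndarray, np.ndarray]:
    if (x1 < 0).any() or (x2 < 0).any():
        raise ParameterError("expression values must be non-negative")
    s1 = np.where(x1 == 0, zero_substitute, x1)
    s2 = np.where(x2 == 0, zero_substitute, x2)
    # log difference rather than log of the ratio: bitwise antisymmetric
    # under swapping the organs, which the screen's mirror property relies on
    m = np.log2(s1) - np.log2(s2)
    d = np.abs(s1 - s2) if substitute_in_d else np.abs(x1 - x2)
    return m, d


def compute_md(
    x1: float,
    x2: float,
    zero_substitute: float = 0.001,
    substitute_in_d: bool = False,
) -> tuple[float, float]:
    """M and D for one gene in one contrast.

    M = log2(x1/x2) after replacing any zero with ``zero_substitute``;
    D = |x1 - x2| of the original values (pre-substitution) unless
    ``substitute_in_d`` is set.
    """
    m, d = _md_arrays(
        np.asarray([x1], dtype=float),
        np.asarray([x2], dtype=float),
        zero_substitute,
        substitute_in_d,
    )
    return float(m[0]), float(d[0])


def build_noise(
    expr: ExpressionMatrix,
    organ_pair: tuple[str, str],
    config: PipelineConfig | None = None,
) -> NoiseDistribution:
    """Pool (M*, D*) over all within-organ replicate pairs of both organs.

    For every unordered pair of replicate samples inside the same organ,
    M and D are computed per gene (earlier replicate index first) and all
    points pooled, giving ``n_genes * (C(r1,2) + C(r2,2))`` noise points.
    Each organ needs at least two replicates.
    """
    config = config or PipelineConfig()
    ms: list[np.ndarray] = []
    ds: list[np.ndarray] = []
    for organ in organ_pair:
        samples = expr.samples_of(organ)
        if len(samples) < 2:
            raise ComputationError(
                f"organ {organ!r} has {len(samples)} replicate(s); need >= 2 "
                "to estimate the noise distribution"
            )
        for a, b in combinations(samples, 2):
            m, d = _md_arrays(
                expr.values[a].to_numpy(dtype=float),
                expr.values[b].to_numpy(dtype=float),
                config.zero_substitute,
                config.substitute_in_d,
            )
            ms.append(m)
            ds.append(d)
    return NoiseDistribution(np.concatenate(ms), np.concatenate(ds))


def signal_md(
    expr: ExpressionMatrix,
    organ_pair: tuple[str, str],
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-gene (m, d) between the replicate-mean profiles of the two organs.

    m is signed relative to the first organ of the pair (positive: higher
    expression there).
    """
    config = config or PipelineConfig()
    o1, o2 = organ_pair
    for o in organ_pair:
        if not expr.samples_of(o):
            raise ParameterError(f"organ {o!r} absent from expression matrix")
    x1 = expr.values[expr.samples_of(o1)].mean(axis=1).to_numpy()
    x2 = expr.values[expr.samples_of(o2)].mean(axis=1).to_numpy()
    m, d = _md_arrays(x1, x2, config.zero_substitute, config.substitute_in_d)
    return pd.DataFrame({"gene": expr.gene_ids, "m": m, "d": d})


def deg_probability(m: float, d: float, noise: NoiseDistribution) -> float:
    """Probability of differential expression for one gene.

    The fraction of noise points with |M*| < |m| AND D* < d — both
    inequalities strict, so a gene with m = 0 or d = 0 always gets p = 0.
    """
    if noise.n_points == 0:
        raise ComputationError("empty noise distribution")
    hits = np.count_nonzero((np.abs(noise.m) < abs(m)) & (noise.d < d))
    return hits / noise.n_points


def deg_probabilities(
    m: np.ndarray, d: np.ndarray, noise: NoiseDistribution, chunk: int = 512
) -> np.ndarray:
    """Vectorized :func:`deg_probability` over many genes.

    Processes genes in chunks to bound the boolean workspace at
    ``chunk * n_points`` entries.
    """
    if noise.n_points == 0:
        raise ComputationError("empty noise distribution")
    am = np.abs(np.asarray(m, dtype=float))
    dd = np.asarray(d, dtype=float)
    abs_noise_m = np.abs(noise.m)
    out = np.empty(am.size)
    for lo in range(0, am.size, chunk):
        hi = min(lo + chunk, am.size)
        block = (abs_noise_m[None, :] < am[lo:hi, None]) & (
            noise.d[None, :] < dd[lo:hi, None]
        )
        out[lo:hi] = block.sum(axis=1) / noise.n_points
    return out


def call_degs(
    records: pd.DataFrame, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Apply the P/M threshold rule and attach the call column.

    Default rule: up if p > p_threshold and m > m_threshold; down if
    p > p_threshold and -m > m_threshold; otherwise not_de. Both
    comparisons are strict, so p exactly at the threshold is not called.
    With ``config.signed_m`` only positive m can be called (no "down").
    """
    config = config or PipelineConfig()
    p = records["p"].to_numpy(dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ParameterError("p values must lie in [0, 1]")
    m = records["m"].to_numpy(dtype=float)
    passed_p = p > config.p_threshold
    up = passed_p & (m > config.m_threshold)
    if config.signed_m:
        down = np.zeros_like(up)
    else:
        down = passed_p & (-m > config.m_threshold)
    call = np.where(up, "up", np.where(down, "down", "not_de"))
    out = records.copy()
    out["call"] = call
    return out


def pairwise_screen(
    expr: ExpressionMatrix,
    organ_pairs: list[tuple[str, str]] | None = None,
    config: PipelineConfig | None = None,
) -> dict[tuple[str, str], pd.DataFrame]:
    """Run the full screen for each organ pair.

    Defaults to all unordered pairs in matrix organ order. Returns one DEG
    table per pair with columns gene, m, d, p, call — one row per input gene
    (genes silent in both organs come out as not_de with p = 0, never
    dropped).
    """
    config = config or PipelineConfig()
    if organ_pairs is None:
        organ_pairs = list(combinations(expr.organs, 2))
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for pair in organ_pairs:
        noise = build_noise(expr, pair, config)
        sig = signal_md(expr, pair, config)
        sig["p"] = deg_probabilities(
            sig["m"].to_numpy(), sig["d"].to_numpy(), noise
        )
        out[tuple(pair)] = call_degs(sig, config)
    return out
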