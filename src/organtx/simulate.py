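"""Synthetic three-organ RNA-seq datasets with planted ground truth.

The generator emulates the structure of a flower/leaf/bulb-scale digital
gene-expression study: a few thousand genes, two to three biological
replicates per organ, sequencing depths around ten million mapped reads, a
planted fraction of differentially expressed genes at a known fold change,
organ-unique genes with structural zeros in the other two organs, a gene-set
annotation with one deliberately over-represented term, and a transcription-
factor panel in which a known subset of regulators shares latent signal with
designated scent-pathway target genes.

Counts follow a gamma-mixed Poisson (negative binomial): for mean ``mu`` and
dispersion ``d`` the count variance is ``mu + d * mu**2``, the standard
replicate-noise model for bulk RNA-seq. Baseline transcript abundances are
log-normal so RPKM spans several orders of magnitude as real transcriptomes
do. A single global seed fans out to independent substreams per generator so
each stage can be regenerated on its own.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import CountMatrix, ExpressionMatrix, TermMap, TFTable

__all__ = [
    "SimulationTruth",
    "simulate_counts",
    "simulate_annotation",
    "simulate_tf_panel",
    "assign_tf_families",
]

# Representative plant TF families (the study's panel spans 53; this subset
# is enough to exercise family tallies).
_TF_FAMILIES = (
    "bHLH", "bZIP", "MYB related", "MYB", "ERF/AP2", "C3H", "WRKY", "NAC",
    "C2H2", "GRAS", "HB", "MADS", "ARF", "Dof", "TCP", "GATA", "Trihelix",
    "LBD", "SBP", "HSF",
)


@dataclass
class SimulationTruth:
    """Everything that was planted, for downstream recovery checks.

    ``de_genes`` maps an unordered organ pair (tuple, generator organ order)
    to ``{gene: signed_log2fc}`` where the sign is relative to the first
    organ of the pair (positive: higher in the first organ).
    """

    gene_ids: list[str] = field(default_factory=list)
    de_genes: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)
    unique_genes: dict[str, set[str]] = field(default_factory=dict)
    enriched_terms: set[str] = field(default_factory=set)
    planted_edges: set[tuple[str, str]] = field(default_factory=set)
    parameters: dict = field(default_factory=dict)

    def de_union(self) -> set[str]:
        out: set[str] = set()
        for d in self.de_genes.values():
            out |= set(d)
        return out

    def to_dict(self) -> dict:
        return {
            "gene_ids": self.gene_ids,
            "de_genes": {
                "|".join(pair): genes for pair, genes in self.de_genes.items()
            },
            "unique_genes": {o: sorted(g) for o, g in self.unique_genes.items()},
            "enriched_terms": sorted(self.enriched_terms),
            "planted_edges": sorted(self.planted_edges),
            "parameters": self.parameters,
        }


def _substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic named substream of the global seed."""
    root = np.random.SeedSequence(seed)
    # stable per-label offset so generators are independent and regenerable
    offsets = {"means": 0, "counts": 1, "annotation": 2, "tf": 3, "families": 4}
    return np.random.default_rng(root.spawn(max(offsets.values()) + 1)[offsets[label]])


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson; structural zeros stay exact zeros."""
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if dispersion > 0:
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu[pos] * dispersion)
    else:
        lam = mu[pos]
    out[pos] = rng.poisson(lam)
    return out


def simulate_counts(
    n_genes: int,
    organs: tuple[str, ...] = ("F", "L", "S"),
    reps: int | tuple[int, ...] = 3,
    de_fraction: float = 0.05,
    fold_change: float = 8.0,
    dispersion: float = 0.1,
    unique_per_organ: int = 25,
    depth: int = 10_000_000,
    seed: int = 0,
) -> tuple[CountMatrix, SimulationTruth]:
    """Generate an overdispersed count matrix with planted DE and unique genes.

    Parameters
    ----------
    n_genes
        Total genes, including planted ones.
    organs
        Organ labels; the study design uses flower (F), leaf (L), scale (S).
    reps
        Replicates per organ — a single int, or one int per organ (the study
        kept 3/2/3 usable replicates after discarding one contaminated leaf
        library).
    de_fraction
        Fraction of genes planted as differential, split evenly across the
        unordered organ pairs, alternating direction.
    fold_change
        True mean ratio between the designated organ pair for each DE gene.
    dispersion
        Negative-binomial dispersion; variance = mu + dispersion * mu^2.
    unique_per_organ
        Genes expressed in exactly one organ (structural zeros elsewhere).
    depth
        Expected mapped reads per sample (library size).
    seed
        Global seed; identical seeds give bitwise-identical output.
    """
    organs = tuple(organs)
    if len(organs) < 2:
        raise ParameterError("need at least 2 organs")
    if isinstance(reps, int):
        reps = tuple([reps] * len(organs))
    if len(reps) != len(organs):
        raise ParameterError("reps must be an int or one int per organ")
    if any(r < 1 for r in reps):
        raise ParameterError("each organ needs at least one replicate")
    if not 0 <= de_fraction < 1:
        raise ParameterError("de_fraction must be in [0, 1)")
    if fold_change <= 1:
        raise ParameterError("fold_change must exceed 1")
    if dispersion <= 0:
        raise ParameterError("dispersion must be positive")
    if depth <= 0:
        raise ParameterError("depth must be positive")

    n_de = int(round(de_fraction * n_genes)) if de_fraction > 0 else 0
    if de_fraction > 0 and n_de < 1:
        raise ParameterError("de_fraction too small: fewer than one DE gene requested")
    n_unique_total = unique_per_organ * len(organs)
    if n_de + n_unique_total >= n_genes:
        raise ParameterError(
            f"planted sets ({n_de} DE + {n_unique_total} unique) exceed n_genes={n_genes}"
        )

    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    rng_means = _substream(seed, "means")
    rng_counts = _substream(seed, "counts")

    # log-normal baseline abundances: several orders of magnitude of RPKM
    base = rng_means.lognormal(mean=2.0, sigma=1.8, size=n_genes)
    mu = np.tile(base[:, None], (1, len(organs)))  # genes x organs, relative

    # plant organ-unique genes first (structural zeros elsewhere)
    truth = SimulationTruth(gene_ids=gene_ids)
    cursor = 0
    for oi, organ in enumerate(organs):
        idx = range(cursor, cursor + unique_per_organ)
        truth.unique_genes[organ] = {gene_ids[gi] for gi in idx}
        for gi in idx:
            mu[gi, :] = 0.0
            mu[gi, oi] = base[gi]
        cursor += unique_per_organ

    # plant DE genes across unordered organ pairs, alternating direction
    pairs = list(combinations(range(len(organs)), 2))
    de_slice = list(range(cursor, cursor + n_de))
    for j, gi in enumerate(de_slice):
        a, b = pairs[j % len(pairs)]
        key = (organs[a], organs[b])
        up_in_first = j % 2 == 0
        if up_in_first:
            mu[gi, a] *= fold_change
            signed = float(np.log2(fold_change))
        else:
            mu[gi, b] *= fold_change
            signed = -float(np.log2(fold_change))
        truth.de_genes.setdefault(key, {})[gene_ids[gi]] = signed
    for a, b in pairs:
        truth.de_genes.setdefault((organs[a], organs[b]), {})

    # per-sample expected counts: relative abundance scaled to library depth
    lengths = rng_means.integers(200, 3001, size=n_genes)
    frac = mu / mu.sum(axis=0, keepdims=True)
    sample_ids: list[str] = []
    organ_map: dict[str, str] = {}
    rep_map: dict[str, int] = {}
    cols: list[np.ndarray] = []
    for oi, organ in enumerate(organs):
        for r in range(1, reps[oi] + 1):
            sid = f"{organ}{r}"
            sample_ids.append(sid)
            organ_map[sid] = organ
            rep_map[sid] = r
            cols.append(_nb_draw(rng_counts, frac[:, oi] * depth, dispersion))
    counts = pd.DataFrame(
        np.column_stack(cols), index=gene_ids, columns=sample_ids
    )
    cm = CountMatrix(
        counts, pd.Series(lengths, index=gene_ids), organ_map, rep_map
    )
    truth.parameters = {
        "n_genes": n_genes,
        "organs": list(organs),
        "reps": list(reps),
        "de_fraction": de_fraction,
        "fold_change": fold_change,
        "dispersion": dispersion,
        "unique_per_organ": unique_per_organ,
        "depth": depth,
        "seed": seed,
    }
    return cm, truth


def simulate_annotation(
    truth: SimulationTruth,
    n_terms: int = 50,
    term_size: int = 20,
    enrichment_bias: float = 20.0,
    seed: int = 0,
) -> TermMap:
    """Build a gene-set annotation with one term enriched for planted DE genes.

    The designated term ("T0001") samples its members without replacement
    with weight ``enrichment_bias`` on planted DE genes and 1 elsewhere; the
    remaining terms sample uniformly. ``enrichment_bias=1`` is the null:
    every term is exchangeable.
    """
    genes = truth.gene_ids
    if not genes:
        raise ParameterError("truth carries no gene universe")
    if term_size > len(genes):
        raise ParameterError("term_size exceeds the gene universe")
    if enrichment_bias < 1:
        raise ParameterError("enrichment_bias must be >= 1")
    rng = _substream(seed, "annotation")
    de = truth.de_union()
    weights = np.array([enrichment_bias if g in de else 1.0 for g in genes])
    weights /= weights.sum()

    term_ids = [f"T{i + 1:04d}" for i in range(n_terms)]
    names = {t: f"term_{t}" for t in term_ids}
    names[term_ids[0]] = "planted_enriched_term"
    g2t: dict[str, set[str]] = {}
    arr = np.array(genes)
    for i, tid in enumerate(term_ids):
        p = weights if i == 0 else None
        members = rng.choice(arr, size=term_size, replace=False, p=p)
        for g in members:
            g2t.setdefault(str(g), set()).add(tid)
    if enrichment_bias > 1:
        truth.enriched_terms = {term_ids[0]}
    return TermMap(term_ids, names, g2t, set(genes))


def assign_tf_families(tf_ids: list[str], seed: int = 0) -> TFTable:
    """Assign each TF a family label from a representative plant-TF panel."""
    rng = _substream(seed, "families")
    fams = rng.choice(np.array(_TF_FAMILIES), size=len(tf_ids), replace=True)
    return TFTable(pd.DataFrame({"gene": tf_ids, "family": fams}))


def simulate_tf_panel(
    target_expr: ExpressionMatrix,
    n_tfs: int = 839,
    n_linked: int = 31,
    link_strength: float = 0.98,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[ExpressionMatrix, set[tuple[str, str]]]:
    """Generate TF expression profiles, a subset sharing signal with targets.

    Each linked TF's profile is ``link_strength * target_profile + noise``
    with the target assigned round-robin over the designated target genes;
    ``noise_sd`` scales Gaussian noise relative to the target profile's
    standard deviation. Unlinked TFs are independent log-normal noise.
    Profiles are floored at zero to stay valid expression values.

    Returns the TF expression rows and the set of planted (TF, target) edges.
    """
    if n_linked > n_tfs:
        raise ParameterError("n_linked cannot exceed n_tfs")
    targets = target_expr.gene_ids
    if not targets:
        raise ParameterError("need at least one target row")
    n_samples = len(target_expr.sample_ids)
    if n_samples == 0:
        raise ParameterError("target rows have zero samples")
    if not 0 <= link_strength <= 1:
        raise ParameterError("link_strength must be in [0, 1]")
    if noise_sd <= 0:
        raise ParameterError("noise_sd must be positive")

    rng = _substream(seed, "tf")
    tf_ids = [f"TF{i:04d}" for i in range(n_tfs)]
    rows = np.empty((n_tfs, n_samples))
    edges: set[tuple[str, str]] = set()
    tvals = target_expr.values.to_numpy()
    for i, tf in enumerate(tf_ids):
        if i < n_linked:
            tgt_i = i % len(targets)
            prof = tvals[tgt_i]
            scale = prof.std() if prof.std() > 0 else 1.0
            rows[i] = link_strength * prof + rng.normal(0, noise_sd * scale, n_samples)
            edges.add((tf, targets[tgt_i]))
        else:
            rows[i] = rng.lognormal(mean=1.5, sigma=1.0, size=n_samples)
    np.maximum(rows, 0.0, out=rows)
    em = ExpressionMatrix(
        pd.DataFrame(rows, index=tf_ids, columns=target_expr.sample_ids),
        target_expr.sample_organ,
        target_expr.sample_replicate,
    )
    return em, edges
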