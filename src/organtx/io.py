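"""Core domain containers and tabular I/O.

The pipeline moves four kinds of data around:

* :class:`CountMatrix` — integer read counts, genes x samples, with per-gene
  transcript lengths and a sample sheet mapping each sample to an organ and a
  replicate index.
* :class:`ExpressionMatrix` — RPKM values on the same axes.
* :class:`TermMap` — a flat gene-set annotation (GO/KEGG terms treated
  identically), read and written in GMT format.
* :class:`TFTable` — transcription-factor identifiers with family labels.

All on-disk formats are tab-separated UTF-8 text with the gene identifier in
the first column, matching the plain-spreadsheet supplementary-table
convention of organ-comparison RNA-seq studies.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConsistencyError, FormatError, ParameterError

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "TermMap",
    "TFTable",
    "PipelineConfig",
    "read_count_matrix",
    "write_count_matrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_sample_sheet",
    "read_gmt",
    "write_gmt",
    "read_tf_table",
    "write_tf_table",
    "write_edge_list",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dupes = seen[seen.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what} id(s): {dupes[:5]}")


@dataclass
class CountMatrix:
    """Read counts per gene per sample with organ/replicate labels.

    Parameters
    ----------
    counts
        Integer DataFrame, genes as the index, samples as columns.
    gene_lengths
        Transcript length in nucleotides, indexed by gene, all > 0.
    sample_organ
        Mapping sample id -> organ label; every column of ``counts`` must
        appear exactly once.
    sample_replicate
        Mapping sample id -> replicate index within its organ.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    sample_organ: dict[str, str]
    sample_replicate: dict[str, int]

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        _check_unique(list(self.counts.index), "gene")
        _check_unique(list(self.counts.columns), "sample")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(np.equal(np.mod(vals, 1), 0)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise FormatError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.sample_organ]
        if missing:
            raise ConsistencyError(
                f"sample(s) in matrix missing from sample sheet: {missing}"
            )
        missing_rep = [s for s in self.counts.columns if s not in self.sample_replicate]
        if missing_rep:
            raise ConsistencyError(f"sample(s) without replicate index: {missing_rep}")
        if not self.gene_lengths.index.equals(self.counts.index):
            lengths = self.gene_lengths.reindex(self.counts.index)
            if lengths.isna().any():
                missing_g = lengths[lengths.isna()].index.tolist()
                raise ConsistencyError(f"gene(s) without length: {missing_g[:5]}")
            self.gene_lengths = lengths
        if (self.gene_lengths <= 0).any():
            bad = self.gene_lengths[self.gene_lengths <= 0].index.tolist()
            raise FormatError(f"non-positive gene length(s): {bad[:5]}")

    # -- convenience ------------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def organs(self) -> list[str]:
        """Organ labels in first-appearance order over the sample axis."""
        seen: list[str] = []
        for s in self.counts.columns:
            o = self.sample_organ[s]
            if o not in seen:
                seen.append(o)
        return seen

    def samples_of(self, organ: str) -> list[str]:
        """Samples of one organ, ordered by replicate index."""
        ss = [s for s in self.counts.columns if self.sample_organ[s] == organ]
        return sorted(ss, key=lambda s: self.sample_replicate[s])


@dataclass
class ExpressionMatrix:
    """Normalized expression (RPKM) on the same gene x sample axes as counts."""

    values: pd.DataFrame
    sample_organ: dict[str, str]
    sample_replicate: dict[str, int]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check_unique(list(self.values.index), "gene")
        _check_unique(list(self.values.columns), "sample")
        if (self.values.to_numpy() < 0).any():
            raise FormatError("expression values must be non-negative")
        missing = [s for s in self.values.columns if s not in self.sample_organ]
        if missing:
            raise ConsistencyError(f"sample(s) without organ label: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def organs(self) -> list[str]:
        seen: list[str] = []
        for s in self.values.columns:
            o = self.sample_organ[s]
            if o not in seen:
                seen.append(o)
        return seen

    def samples_of(self, organ: str) -> list[str]:
        ss = [s for s in self.values.columns if self.sample_organ[s] == organ]
        return sorted(ss, key=lambda s: self.sample_replicate.get(s, 0))

    def organ_means(self) -> pd.DataFrame:
        """Replicate-mean expression per organ (genes x organs)."""
        cols = {o: self.values[self.samples_of(o)].mean(axis=1) for o in self.organs}
        return pd.DataFrame(cols)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise ConsistencyError(f"gene(s) absent from matrix: {missing[:5]}")
        return ExpressionMatrix(
            self.values.loc[list(genes)], self.sample_organ, self.sample_replicate
        )


@dataclass
class TermMap:
    """Flat gene-set annotation: terms, their member genes, and the background.

    ``background`` is the measured gene universe against which enrichment is
    assessed; every annotated gene must belong to it.
    """

    term_ids: list[str]
    term_names: dict[str, str]
    gene_to_terms: dict[str, set[str]]
    background: set[str]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        _check_unique(self.term_ids, "term")
        known = set(self.term_ids)
        for gene, terms in self.gene_to_terms.items():
            if gene not in self.background:
                raise ConsistencyError(f"annotated gene {gene!r} not in background")
            unknown = terms - known
            if unknown:
                raise ConsistencyError(
                    f"gene {gene!r} references unknown term(s): {sorted(unknown)[:5]}"
                )

    def term_genes(self) -> dict[str, set[str]]:
        """Inverse map: term -> set of annotated genes."""
        out: dict[str, set[str]] = {t: set() for t in self.term_ids}
        for gene, terms in self.gene_to_terms.items():
            for t in terms:
                out[t].add(gene)
        return out


@dataclass
class TFTable:
    """Transcription factors with family labels (bHLH, MYB related, bZIP, ...)."""

    table: pd.DataFrame  # columns: gene, family

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if list(self.table.columns[:2]) != ["gene", "family"]:
            raise FormatError("TF table needs columns 'gene' and 'family'")
        _check_unique(list(self.table["gene"]), "TF gene")
        fam = self.table["family"].astype(str)
        if (fam.str.len() == 0).any() or fam.isna().any():
            raise FormatError("empty TF family label")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene"])

    def family_of(self) -> dict[str, str]:
        return dict(zip(self.table["gene"], self.table["family"]))


@dataclass
class PipelineConfig:
    """Thresholds and seed shared by all stages.

    Defaults follow the published screening rules: genes are differential when
    the noise-distribution probability P exceeds 0.8 and |M| (log2 fold
    change) exceeds 2; zero expression is replaced by 0.001 inside the log
    ratio; co-expression edges require |PCC| >= 0.95 at p < 0.01; enriched
    terms require corrected p <= 0.05.
    """

    zero_substitute: float = 0.001
    p_threshold: float = 0.8
    m_threshold: float = 2.0
    pcc_threshold: float = 0.95
    pcc_alpha: float = 0.01
    enrich_alpha: float = 0.05
    rng_seed: int = 0
    signed_m: bool = False  # True: only M > m_threshold (signed rule) calls "up"
    substitute_in_d: bool = False  # True: D uses post-substitution values
    correction: str = "fdr_bh"  # or "bonferroni"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.zero_substitute > 0:
            raise ParameterError("zero_substitute must be positive")
        if not 0 < self.p_threshold <= 1:
            raise ParameterError("p_threshold must be in (0, 1]")
        if self.m_threshold < 0:
            raise ParameterError("m_threshold must be non-negative")
        if not 0 <= self.pcc_threshold <= 1:
            raise ParameterError("pcc_threshold must be in [0, 1]")
        if not 0 < self.pcc_alpha < 1:
            raise ParameterError("pcc_alpha must be in (0, 1)")
        if not 0 < self.enrich_alpha < 1:
            raise ParameterError("enrich_alpha must be in (0, 1)")
        if self.correction not in ("fdr_bh", "bonferroni"):
            raise ParameterError("correction must be 'fdr_bh' or 'bonferroni'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ParameterError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> tuple[dict[str, str], dict[str, int]]:
    """Read the sample sheet (columns: sample, organ, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "organ": str})
    required = {"sample", "organ", "replicate"}
    if not required.issubset(df.columns):
        raise FormatError(
            f"sample sheet needs columns {sorted(required)}, got {list(df.columns)}"
        )
    _check_unique(list(df["sample"]), "sample-sheet sample")
    return (
        dict(zip(df["sample"], df["organ"])),
        dict(zip(df["sample"], df["replicate"].astype(int))),
    )


def read_count_matrix(
    path: str | Path, sample_sheet: str | Path, lengths: str | Path
) -> CountMatrix:
    """Assemble a validated :class:`CountMatrix` from its three TSV files.

    ``path`` is a genes x samples table (first column gene id, header row of
    sample ids); ``lengths`` a two-column (gene, length) table. Row and column
    order are preserved from the files.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    try:
        df = df.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-integer count in {path}: {exc}") from exc
    organ, rep = read_sample_sheet(sample_sheet)
    ldf = pd.read_csv(lengths, sep="\t")
    if ldf.shape[1] < 2:
        raise FormatError("lengths file needs two columns: gene, length")
    ldf.columns = ["gene", "length", *ldf.columns[2:]]
    lengths_s = pd.Series(
        ldf["length"].astype(int).to_numpy(), index=ldf["gene"].astype(str)
    )
    return CountMatrix(df, lengths_s, organ, rep)


def write_count_matrix(cm: CountMatrix, path: str | Path, sample_sheet: str | Path,
                       lengths: str | Path) -> None:
    """Write the three files :func:`read_count_matrix` consumes."""
    cm.counts.to_csv(path, sep="\t", index_label="gene")
    sheet = pd.DataFrame(
        {
            "sample": cm.sample_ids,
            "organ": [cm.sample_organ[s] for s in cm.sample_ids],
            "replicate": [cm.sample_replicate[s] for s in cm.sample_ids],
        }
    )
    sheet.to_csv(sample_sheet, sep="\t", index=False)
    pd.DataFrame({"gene": cm.gene_ids, "length": cm.gene_lengths.to_numpy()}).to_csv(
        lengths, sep="\t", index=False
    )


def read_expression_matrix(
    path: str | Path, sample_sheet: str | Path
) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.index.name = None
    organ, rep = read_sample_sheet(sample_sheet)
    return ExpressionMatrix(df.astype(float), organ, rep)


def write_expression_matrix(em: ExpressionMatrix, path: str | Path) -> None:
    # %.17g round-trips every double, so downstream stages reading this file
    # reproduce in-memory results bit for bit
    em.values.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


def read_gmt(path: str | Path, background: Iterable[str] | None = None) -> TermMap:
    """Read a GMT file: per line, term id, term name, then member genes.

    When ``background`` is None the universe defaults to the union of all
    member genes.
    """
    term_ids: list[str] = []
    names: dict[str, str] = {}
    g2t: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise FormatError(f"GMT line with fewer than 2 fields: {line[:60]!r}")
        tid, name, *genes = parts
        term_ids.append(tid)
        names[tid] = name
        for g in genes:
            if g:
                g2t.setdefault(g, set()).add(tid)
    bg = set(background) if background is not None else set(g2t)
    return TermMap(term_ids, names, g2t, bg)


def write_gmt(terms: TermMap, path: str | Path) -> None:
    inv = terms.term_genes()
    with open(path, "w") as fh:
        for tid in terms.term_ids:
            genes = sorted(inv[tid])
            fh.write("\t".join([tid, terms.term_names.get(tid, tid), *genes]) + "\n")


def read_tf_table(path: str | Path) -> TFTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return TFTable(df)


def write_tf_table(tfs: TFTable, path: str | Path) -> None:
    tfs.table.to_csv(path, sep="\t", index=False)


def write_edge_list(
    edges: pd.DataFrame, path: str | Path, format: str = "tsv"
) -> None:
    """Export network edges.

    ``edges`` carries columns regulator, target, r, p (family optional).
    SIF writes ``regulator<TAB>coexpr<TAB>target`` one edge per line with no
    header; TSV keeps all columns at full precision with a header row.
    """
    if format == "sif":
        with open(path, "w") as fh:
            for reg, tgt in zip(edges["regulator"], edges["target"]):
                fh.write(f"{reg}\tcoexpr\t{tgt}\n")
    elif format == "tsv":
        edges.to_csv(path, sep="\t", index=False, float_format="%.17g")
    else:
        raise ParameterError(f"unknown edge-list format {format!r}")


def rpkm_from_counts(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """RPKM(g, s) = 1e9 * count(g, s) / (total(s) * length(g)).

    Raw helper shared by :mod:`organtx.quantify`; prefer
    :func:`organtx.quantify.rpkm` which returns a labelled matrix.
    """
    totals = counts.sum(axis=0).astype(float)
    zero = totals[totals == 0]
    if len(zero):
        from .errors import ComputationError

        raise ComputationError(
            f"sample(s) with zero total counts: {list(zero.index)}"
        )
    # divide counts by the column total first: the count/depth ratio is a
    # correctly-rounded division of an exact rational, so scaling a whole
    # sample by a constant leaves its RPKM column bitwise unchanged
    ratio = counts.to_numpy(dtype=float) / totals.to_numpy()[None, :]
    per_kb = 1e9 / lengths.to_numpy(dtype=float)
    return pd.DataFrame(
        ratio * per_kb[:, None], index=counts.index, columns=counts.columns
    )
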