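"""End-to-end orchestration: quantify -> DEG screen -> profiles -> enrichment -> network.

`run_all` executes every stage on real input files or on a freshly simulated
dataset, writes each stage's table as TSV into an output directory, and
records a run manifest (resolved config, input digests, seed, per-stage row
counts, timestamp). Stage outputs are deterministic given the same inputs
and config — the manifest alone carries the timestamp — so reruns produce
byte-identical TSVs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from itertools import combinations
from pathlib import Path

import pandas as pd

from . import __version__
from .deg import pairwise_screen
from .enrich import enrich
from .errors import OrgantxError
from .io import (
    CountMatrix,
    PipelineConfig,
    TFTable,
    TermMap,
    read_count_matrix,
    read_gmt,
    read_tf_table,
    write_count_matrix,
    write_edge_list,
    write_expression_matrix,
    write_gmt,
    write_tf_table,
)
from .network import build_network, family_distribution
from .profile import common_degs, find_unique_genes, organ_summary, updown_tally
from .quantify import rpkm
from .simulate import (
    assign_tf_families,
    simulate_annotation,
    simulate_counts,
    simulate_tf_panel,
)

__all__ = ["RunManifest", "run_all", "validate_inputs"]

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict
    inputs: dict[str, str]  # path -> sha256
    seed: int | None
    stage_rows: dict[str, int] = field(default_factory=dict)
    version: str = __version__
    timestamp: str = ""

    def write(self, path: Path) -> None:
        self.timestamp = datetime.now(timezone.utc).isoformat()
        path.write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _float_csv(df: pd.DataFrame, path: Path, **kw) -> None:
    # fixed float formatting keeps reruns byte-identical
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", **kw)


def run_all(
    outdir: str | Path,
    config: PipelineConfig | None = None,
    counts_path: str | Path | None = None,
    sample_sheet: str | Path | None = None,
    lengths_path: str | Path | None = None,
    gmt_path: str | Path | None = None,
    tf_table_path: str | Path | None = None,
    target_genes: list[str] | None = None,
    simulate: bool = False,
    seed: int | None = None,
    sim_kwargs: dict | None = None,
) -> Path:
    """Run the whole pipeline; returns the output directory.

    Either provide the input files (counts, sample sheet, lengths, and
    optionally GMT / TF table / target gene list) or set ``simulate=True``
    to generate a synthetic dataset first — then the targets are the planted
    linked targets and the truth document is written alongside the outputs.
    """
    config = config or PipelineConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), inputs={}, seed=seed)

    if simulate:
        seed = config.rng_seed if seed is None else seed
        kw = dict(sim_kwargs or {})
        cm, truth = simulate_counts(seed=seed, **kw)
        terms = simulate_annotation(truth, seed=seed)
        write_count_matrix(
            cm, outdir / "counts.tsv", outdir / "samples.tsv", outdir / "lengths.tsv"
        )
        write_gmt(terms, outdir / "annotation.gmt")
        tfs = None  # built after RPKM below
    else:
        if not (counts_path and sample_sheet and lengths_path):
            raise OrgantxError("need counts, sample sheet and lengths (or simulate)")
        for p in (counts_path, sample_sheet, lengths_path, gmt_path, tf_table_path):
            if p is not None:
                if not Path(p).exists():
                    raise OrgantxError(f"input file not found: {p}")
                manifest.inputs[str(p)] = _digest(p)
        cm = read_count_matrix(counts_path, sample_sheet, lengths_path)
        terms = read_gmt(gmt_path, background=cm.gene_ids) if gmt_path else None
        tfs = read_tf_table(tf_table_path) if tf_table_path else None
        truth = None

    logger.info("stage quantify: %d genes x %d samples", len(cm.gene_ids), len(cm.sample_ids))
    expr = rpkm(cm)
    write_expression_matrix(expr, outdir / "rpkm.tsv")
    manifest.stage_rows["rpkm"] = len(expr.gene_ids)

    logger.info("stage deg: screening organ pairs")
    screens = pairwise_screen(expr, config=config)
    for (o1, o2), df in screens.items():
        _float_csv(df, outdir / f"deg_{o1}_vs_{o2}.tsv")
        manifest.stage_rows[f"deg_{o1}_vs_{o2}"] = int((df["call"] != "not_de").sum())

    logger.info("stage profile: unique genes and common DEGs")
    unique = find_unique_genes(expr) if len(expr.organs) >= 3 else {}
    for organ, genes in unique.items():
        (outdir / f"unique_{organ}.tsv").write_text(
            "gene\n" + "".join(g + "\n" for g in sorted(genes))
        )
    if unique:
        _float_csv(organ_summary(unique), outdir / "organ_summary.tsv")
    tallies = {pair: updown_tally(df) for pair, df in screens.items()}
    tally_df = pd.DataFrame(
        [
            {"pair": f"{a}_vs_{b}", "n_up": u, "n_down": d}
            for (a, b), (u, d) in tallies.items()
        ]
    )
    _float_csv(tally_df, outdir / "updown_tally.tsv")
    common = common_degs(screens) if len(screens) == 3 else set()
    (outdir / "common_degs.tsv").write_text(
        "gene\n" + "".join(g + "\n" for g in sorted(common))
    )
    manifest.stage_rows["common_degs"] = len(common)

    if terms is not None:
        logger.info("stage enrich: %d terms", len(terms.term_ids))
        for (o1, o2), df in screens.items():
            degs = set(df.loc[df["call"] != "not_de", "gene"])
            if degs & terms.background:
                res = enrich(degs, terms, config)
                _float_csv(res, outdir / f"enrichment_{o1}_vs_{o2}.tsv")
                manifest.stage_rows[f"enrichment_{o1}_vs_{o2}"] = int(
                    res["significant"].sum()
                )

    if simulate:
        # TF panel rides on the simulated expression of designated targets
        seven = [
            g
            for g in expr.gene_ids
            if g not in {x for s in (truth.unique_genes or {}).values() for x in s}
        ][:7]
        tf_expr, edges = simulate_tf_panel(expr.subset_genes(seven), seed=seed)
        truth.planted_edges = edges
        tfs = assign_tf_families(tf_expr.gene_ids, seed=seed)
        write_tf_table(tfs, outdir / "tf_table.tsv")
        target_genes = seven
        (outdir / "truth.json").write_text(
            json.dumps(truth.to_dict(), indent=2, sort_keys=True) + "\n"
        )
    else:
        tf_expr = None

    if tfs is not None and target_genes:
        logger.info("stage network: %d TFs x %d targets", len(tfs.gene_ids), len(target_genes))
        if tf_expr is None:
            tf_expr = expr.subset_genes([g for g in tfs.gene_ids if g in expr.values.index])
        net = build_network(tf_expr, expr.subset_genes(target_genes), config, tfs)
        write_edge_list(net, outdir / "network.tsv", format="tsv")
        write_edge_list(net, outdir / "network.sif", format="sif")
        if len(net):
            _float_csv(family_distribution(net, tfs), outdir / "tf_families.tsv")
        manifest.stage_rows["network_edges"] = len(net)

    manifest.write(outdir / "manifest.json")
    return outdir


def validate_inputs(
    counts_path: str | Path,
    sample_sheet: str | Path,
    lengths_path: str | Path,
    gmt_path: str | Path | None = None,
) -> list[dict]:
    """Run all container invariant checks without executing stages.

    Returns a machine-readable list of {check, status, detail} entries;
    failures are entries, never exceptions.
    """
    report: list[dict] = []

    def record(check: str, fn) -> object | None:
        try:
            out = fn()
            report.append({"check": check, "status": "pass", "detail": ""})
            return out
        except Exception as exc:  # noqa: BLE001 - report, don't raise
            report.append({"check": check, "status": "fail", "detail": str(exc)})
            return None

    cm = record(
        "count_matrix",
        lambda: read_count_matrix(counts_path, sample_sheet, lengths_path),
    )
    if cm is not None:
        for organ in cm.organs:
            n = len(cm.samples_of(organ))
            if n < 2:
                report.append(
                    {
                        "check": f"replicates_{organ}",
                        "status": "warn",
                        "detail": f"organ {organ!r} has {n} replicate(s); "
                        "the DEG stage needs at least 2",
                    }
                )
            else:
                report.append(
                    {"check": f"replicates_{organ}", "status": "pass", "detail": ""}
                )
    if gmt_path is not None:
        record(
            "term_map",
            lambda: read_gmt(
                gmt_path, background=cm.gene_ids if cm is not None else None
            ),
        )
    return report
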