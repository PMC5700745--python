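"""Expression quantification: RPKM and qPCR relative quantification.

RPKM (reads per kilobase of transcript per million mapped reads) removes the
two nuisance scales of count data — transcript length and sequencing depth —
so expression can be compared directly across genes and samples:

    RPKM(g, s) = 1e9 * count(g, s) / (total_mapped(s) * length(g))

Total mapped reads per sample is the column sum of the count matrix, which is
what the matrix represents once alignment is done.

qPCR validation uses the 2^-ddCt method: target Ct is normalized to a
reference gene within each sample (dCt), then to a calibrator organ (ddCt),
and relative quantity RQ = 2^-ddCt. Replicate Ct values are averaged before
differencing, the standard convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ComputationError, DataError, ParameterError
from .io import CountMatrix, ExpressionMatrix, rpkm_from_counts

__all__ = ["QpcrTable", "rpkm", "ddct_rq", "expression_concordance"]


def rpkm(counts: CountMatrix) -> ExpressionMatrix:
    """Convert read counts to RPKM.

    Raises :class:`ComputationError` naming the sample if any library has
    zero total counts.
    """
    values = rpkm_from_counts(counts.counts, counts.gene_lengths)
    return ExpressionMatrix(values, counts.sample_organ, counts.sample_replicate)


@dataclass
class QpcrTable:
    """Long-format qPCR Ct measurements.

    ``table`` columns: sample, organ, gene, ct. The reference gene must be
    measured in every sample; the calibrator organ anchors RQ = 1.
    """

    table: pd.DataFrame
    reference_gene: str
    calibrator_organ: str

    def __post_init__(self) -> None:
        required = {"sample", "organ", "gene", "ct"}
        if not required.issubset(self.table.columns):
            raise DataError(f"Ct table needs columns {sorted(required)}")
        if not np.isfinite(self.table["ct"].to_numpy(dtype=float)).all():
            raise DataError("non-finite Ct value")
        samples = set(self.table["sample"])
        ref_samples = set(
            self.table.loc[self.table["gene"] == self.reference_gene, "sample"]
        )
        missing = samples - ref_samples
        if missing:
            raise DataError(
                f"reference gene {self.reference_gene!r} missing in sample(s): "
                f"{sorted(missing)}"
            )
        if self.calibrator_organ not in set(self.table["organ"]):
            raise DataError(f"calibrator organ {self.calibrator_organ!r} absent")


def ddct_rq(table: QpcrTable) -> dict[tuple[str, str], float]:
    """Relative quantification by 2^-ddCt.

    Per organ: mean Ct over replicates per gene; dCt = Ct(gene) - Ct(ref);
    ddCt = dCt(organ) - dCt(calibrator); RQ = 2^-ddCt. The calibrator organ
    gets RQ = 1 exactly for every gene.
    """
    df = table.table
    mean_ct = df.groupby(["organ", "gene"])["ct"].mean()
    out: dict[tuple[str, str], float] = {}
    genes = sorted(set(df["gene"]) - {table.reference_gene})
    organs = list(dict.fromkeys(df["organ"]))
    for gene in genes:
        dct = {}
        for organ in organs:
            try:
                dct[organ] = mean_ct[(organ, gene)] - mean_ct[(organ, table.reference_gene)]
            except KeyError:
                continue  # gene not measured in this organ
        if table.calibrator_organ not in dct:
            raise DataError(
                f"gene {gene!r} not measured in calibrator organ "
                f"{table.calibrator_organ!r}"
            )
        cal = dct[table.calibrator_organ]
        for organ, v in dct.items():
            ddct = v - cal
            out[(gene, organ)] = float(2.0 ** (-ddct))
        out[(gene, table.calibrator_organ)] = 1.0  # exact, not 2**(-0.0) roundoff
    return out


def expression_concordance(
    rq: dict[tuple[str, str], float],
    expr: ExpressionMatrix,
    genes: list[str],
) -> pd.Series:
    """Spearman rank correlation between qPCR RQ and RPKM organ means, per gene.

    Both assays are reduced to one value per organ (RQ is already per-organ;
    RPKM is averaged over replicates) and compared by rank, since the claim
    being checked is agreement of expression *pattern* across organs, not of
    magnitude. With fewer than 3 organs the correlation is undefined and
    reported as NaN.
    """
    means = expr.organ_means()
    organs = [o for o in means.columns]
    out = {}
    for gene in genes:
        if gene not in means.index:
            raise ParameterError(f"gene {gene!r} absent from expression matrix")
        rq_vec = [rq.get((gene, o)) for o in organs]
        if any(v is None for v in rq_vec):
            missing = [o for o, v in zip(organs, rq_vec) if v is None]
            raise ParameterError(f"gene {gene!r} lacks RQ for organ(s) {missing}")
        if len(organs) < 3:
            out[gene] = float("nan")
            continue
        rho = stats.spearmanr(rq_vec, means.loc[gene, organs].to_numpy()).statistic
        out[gene] = float(rho)
    return pd.Series(out, name="spearman_rho")
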