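"""Organ-level expression summaries.

Three views of the pairwise DEG screens and the expression matrix:

* organ-unique genes — expressed (replicate-mean RPKM > 0) in exactly one of
  the three organs and exactly zero in the other two;
* up/down tallies per comparison, signed relative to the first-listed organ;
* the DEGs common to all three pairwise comparisons, irrespective of
  direction.
"""

from __future__ import annotations

import pandas as pd

from .errors import ParameterError
from .io import ExpressionMatrix

__all__ = ["find_unique_genes", "updown_tally", "common_degs", "organ_summary"]


def find_unique_genes(
    expr: ExpressionMatrix, organs: tuple[str, str, str] | None = None
) -> dict[str, set[str]]:
    """Genes expressed in exactly one organ.

    Uniqueness is evaluated on replicate-mean RPKM with an exact-zero test:
    RPKM of an all-zero count row is exactly 0.0, so no epsilon is needed,
    and a single nonzero replicate disqualifies the zero condition. A gene
    silent everywhere belongs to no organ.
    """
    organs = tuple(organs) if organs is not None else tuple(expr.organs)
    if len(organs) < 3:
        raise ParameterError(f"need 3 organs, got {organs}")
    means = expr.organ_means()[list(organs)]
    out: dict[str, set[str]] = {}
    for organ in organs:
        others = [o for o in organs if o != organ]
        mask = (means[organ] > 0) & (means[others] == 0).all(axis=1)
        out[organ] = set(means.index[mask])
    return out


def updown_tally(records: pd.DataFrame) -> tuple[int, int]:
    """(n_up, n_down) for one pair's DEG table."""
    calls = records["call"]
    return int((calls == "up").sum()), int((calls == "down").sum())


def common_degs(records_by_pair: dict[tuple[str, str], pd.DataFrame]) -> set[str]:
    """Genes called differential (either direction) in every comparison."""
    sets = [
        set(df.loc[df["call"] != "not_de", "gene"]) for df in records_by_pair.values()
    ]
    if not sets:
        return set()
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def organ_summary(unique: dict[str, set[str]]) -> pd.DataFrame:
    """Tabular summary (organ, n_unique) mirroring a unique-gene count table."""
    return pd.DataFrame(
        {"organ": list(unique), "n_unique": [len(v) for v in unique.values()]}
    )
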