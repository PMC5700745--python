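"""Hypergeometric term enrichment of a DEG set.

Builds a 50-term annotation in which one term preferentially samples planted
DE genes, then tests every term for over-representation among the screen's
DEG calls with Benjamini-Hochberg correction at corrected p <= 0.05.
"""

from organtx import (
    enrich,
    pairwise_screen,
    rpkm,
    simulate_annotation,
    simulate_counts,
)

cm, truth = simulate_counts(n_genes=2000, de_fraction=0.05, fold_change=8.0,
                            seed=3)
degs = set()
for df in pairwise_screen(rpkm(cm)).values():
    degs |= set(df.loc[df["call"] != "not_de", "gene"])

terms = simulate_annotation(truth, n_terms=50, term_size=20,
                            enrichment_bias=50.0, seed=3)
result = enrich(degs, terms)

print(f"{len(degs)} DEGs tested against {len(terms.term_ids)} terms")
print(result.head(5)[["term_id", "term_name", "k", "K", "p_raw", "p_adj",
                      "significant"]].to_string(index=False))
planted = next(iter(truth.enriched_terms))
rank = result.index[result["term_id"] == planted][0] + 1
print(f"planted term {planted} ranks #{rank}")
# k of K term members fall in the DEG set of size n; a small corrected p
# means that overlap is far larger than a uniform draw would give.
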