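"""Intersect the three high-association sets; extract the extreme subset.

Computes the Venn-region counts, the common gene set, each collection's
nearest-rank 90th-percentile threshold and the joint extreme subset, plus
per-chromosome counts of the common set and a Manhattan-style plot of gene
scores.  Reports how many planted causal genes survive the intersection.
"""

import pandas as pd

from common import COLLECTIONS, DATA_DIR, OUT_DIR
from poolseq_assoc import (
    extreme_subset,
    intersect_collections,
    positional_summary,
    read_category_map,
    read_gene_models,
)
from poolseq_assoc.plotting import manhattan_plot


def main() -> None:
    categories = read_category_map(DATA_DIR / "categories.tsv")
    genes = read_gene_models(DATA_DIR / "genes.gff3", categories)
    truth = pd.read_csv(DATA_DIR / "truth_genes.tsv", sep="\t")
    causal = set(truth.loc[truth["is_causal"], "gene_id"])

    tables, sets, scores = {}, {}, {}
    for label in COLLECTIONS:
        t = pd.read_csv(OUT_DIR / f"genes_{label}.tsv", sep="\t",
                        dtype={"chrom": str})
        tables[label] = t
        sets[label] = t.loc[t["pass_high"], "gene_id"].tolist()
        scores[label] = dict(zip(t["gene_id"], t["score"]))

    common = intersect_collections(sets, scores)
    pd.DataFrame({"gene_id": common.common}).to_csv(
        OUT_DIR / "common_genes.tsv", sep="\t", index=False
    )
    regions = [("+".join(sorted(k)), v) for k, v in
               sorted(common.region_counts.items(), key=lambda kv: sorted(kv[0]))]
    pd.DataFrame(regions, columns=["region", "n_genes"]).to_csv(
        OUT_DIR / "venn_regions.tsv", sep="\t", index=False
    )
    print(f"common to all three collections: {len(common.common)} genes "
          f"({len(set(common.common) & causal)} causal); union "
          f"{common.union_size}")

    extreme = extreme_subset(common, 0.10)
    pd.DataFrame(
        {"gene_id": extreme.members}
    ).to_csv(OUT_DIR / "extreme_genes.tsv", sep="\t", index=False)
    thr = ", ".join(f"{k} > {v:.2f}" for k, v in extreme.thresholds.items())
    print(f"extreme (top 10% in every collection): {len(extreme.members)} "
          f"genes; thresholds {thr}")

    summary = positional_summary(common.common, genes)
    summary.per_chromosome.rename("n_genes").to_csv(
        OUT_DIR / "common_per_chromosome.tsv", sep="\t", index_label="chrom"
    )
    print("common genes per chromosome:",
          dict(summary.per_chromosome))

    manhattan_plot(tables, OUT_DIR / "gene_scores_manhattan.png", cutoff=4.0)
    print(f"wrote {OUT_DIR / 'gene_scores_manhattan.png'}")


if __name__ == "__main__":
    main()
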