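"""Hypergeometric category enrichment of the common high-association set.

Merges mitochondrial and redox categories, then tests each functional
category's representation in the common set against all background genes.
The planted transport-category signal should rank first.
"""

import pandas as pd

from common import DATA_DIR, OUT_DIR
from poolseq_assoc import enrich_all, percent_truncated, read_category_map


def main() -> None:
    background = read_category_map(DATA_DIR / "categories.tsv")
    common = pd.read_csv(OUT_DIR / "common_genes.tsv", sep="\t")["gene_id"]
    table = enrich_all(common.tolist(), background)
    table.to_csv(OUT_DIR / "enrichment.tsv", sep="\t", index=False,
                 float_format="%.6g")
    print(f"category enrichment over {len(common)} common genes "
          f"(background {len(background)}):")
    for _, row in table.iterrows():
        share = percent_truncated(int(row["k"]), int(row["n"]))
        print(
            f"  {row['category']:>9}: {row['k']:>3.0f}/{row['n']:.0f} "
            f"({share:4.1f}%)  K={row['K']:.0f}  p = {row['p_upper']:.3g}  "
            f"fold = {row['fold']:.2f}"
        )


if __name__ == "__main__":
    main()
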