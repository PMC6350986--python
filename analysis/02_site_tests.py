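"""Filter sites and run the per-SNP contingency chi-square per collection.

Applies the per-library minimum-coverage filter (15) and the monomorphic
exclusion, then tests every remaining site: replicates summed within
phenotype, Pearson chi-square on the 2 x k nucleotide table, df = k - 1.
Writes per-site result tables and a site-accounting summary in the style of
a polymorphism/coverage table.
"""

import pandas as pd

from common import COLLECTIONS, DATA_DIR, OUT_DIR
from poolseq_assoc import (
    CountsTable,
    coverage_summary,
    filter_sites,
    flag_monomorphic,
    read_manifest,
    sites_per_aligned_nt_ratio,
)
from poolseq_assoc.association import test_sites


def main() -> None:
    manifest = read_manifest(DATA_DIR / "manifest.tsv")
    rows = []
    for label in COLLECTIONS:
        table = CountsTable.read(DATA_DIR / f"counts_{label}.tsv",
                                 manifest=manifest)
        table, cov_report = filter_sites(table, 15)
        table, mono_report = flag_monomorphic(table)
        cov = coverage_summary(table)
        results = test_sites(table)
        results.to_csv(OUT_DIR / f"sites_{label}.tsv", sep="\t", index=False,
                       float_format="%.6g")
        n_tested = int((results["flag"] == "tested").sum())
        aligned = sum(
            lib.aligned_read_count for lib in table.libraries
            if lib.collection_id == label
        )
        ratio = sites_per_aligned_nt_ratio(n_tested, aligned, 100)
        rows.append(
            (label, cov_report.n_input, cov_report.n_low_coverage,
             mono_report.n_monomorphic, n_tested, cov.min, cov.max,
             cov.mean, cov.median, ratio)
        )
        print(
            f"{label}: {cov_report.n_input} sites in, "
            f"{cov_report.n_low_coverage} low-coverage, "
            f"{mono_report.n_monomorphic} monomorphic excluded, "
            f"{n_tested} tested; coverage mean {cov.mean:.0f} "
            f"median {cov.median:.0f}; sites/aligned-nt*1000 = {ratio:.3f}"
        )
    pd.DataFrame(
        rows,
        columns=["collection", "n_input", "n_low_coverage", "n_monomorphic",
                 "n_tested", "cov_min", "cov_max", "cov_mean", "cov_median",
                 "sites_per_aligned_nt_x1000"],
    ).to_csv(OUT_DIR / "site_summary.tsv", sep="\t", index=False,
             float_format="%.3f")


if __name__ == "__main__":
    main()
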