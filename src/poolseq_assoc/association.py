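"""Per-SNP contingency chi-square between resistant and susceptible pools.

Replicate libraries are summed within phenotype, giving a 2 x k table over
the k nucleotides with nonzero total count at the site; Pearson's statistic
is computed against independence expectations, with df = k - 1 by default.
The per-site score is -log10 of the upper-tail p-value, capped so that
underflowing p-values stay finite for downstream gene averaging.

An alternative df convention (number of alternate, i.e. non-reference,
nucleotides minus 1) is available for sites with three or more observed
alleles; at biallelic sites it would give df = 0, which admits no test, so
it falls back to df = 1 there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .counts_io import NUCLEOTIDES, CountsTable

DF_RULES = ("observed_minus_1", "alternates_minus_1")

#: cap on -log10(p); double precision underflows near p = 1e-323
DEFAULT_NEGLOG10P_CAP = 320.0


@dataclass(frozen=True)
class SiteTestResult:
    chromosome: str
    position: int
    alleles_observed: tuple[str, ...]
    chi2: float | None
    df: int | None
    p_value: float | None
    neglog10p: float | None
    hexp_resistant: float | None
    hexp_susceptible: float | None
    flag: str  # tested | monomorphic | low_coverage


def chi2_2xk(table: np.ndarray, df: int | None = None) -> tuple[float, int, float]:
    """Pearson chi-square for one 2 x k contingency table of read counts.

    Columns with zero total are dropped before forming expectations. Returns
    ``(chi2, df, p)`` with df = k - 1 unless overridden.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] != 2:
        raise ValueError("expected a 2 x k table")
    table = table[:, table.sum(axis=0) > 0]
    k = table.shape[1]
    if k < 2:
        raise ValueError("fewer than two alleles observed; nothing to test")
    row = table.sum(axis=1)
    if (row == 0).any():
        raise ValueError("a phenotype has zero total reads")
    col = table.sum(axis=0)
    n = table.sum()
    expected = np.outer(row, col) / n
    chi2 = float(((table - expected) ** 2 / expected).sum())
    if df is None:
        df = k - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def hexp(counts: np.ndarray) -> float:
    """Expected heterozygosity 1 - sum(p_i^2) from nucleotide read counts."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("expected heterozygosity undefined at zero depth")
    p = counts / total
    return float(1.0 - (p ** 2).sum())


def _phenotype_tables(table: CountsTable) -> tuple[np.ndarray, np.ndarray]:
    res = table.phenotype_mask("resistant")
    sus = table.phenotype_mask("susceptible")
    if not res.any() or not sus.any():
        raise ValueError("libraries must span both phenotypes")
    return (
        table.counts[:, res, :].sum(axis=1),
        table.counts[:, sus, :].sum(axis=1),
    )


def test_sites(
    table: CountsTable,
    df_rule: str = "observed_minus_1",
    neglog10p_cap: float = DEFAULT_NEGLOG10P_CAP,
) -> pd.DataFrame:
    """Vectorised per-site chi-square over a whole counts table.

    Returns one row per input site with columns ``chrom, pos, ref, alleles,
    k, chi2, df, p, neglog10p, hexp_res, hexp_sus, flag``; sites that cannot
    be tested (one allele, or a phenotype with zero reads) carry NaN
    statistics and an explanatory flag.
    """
    if df_rule not in DF_RULES:
        raise ValueError(f"df_rule must be one of {DF_RULES}")
    res, sus = _phenotype_tables(table)  # each (S, 4)
    obs = np.stack([res, sus], axis=1)  # (S, 2, 4)

    col = obs.sum(axis=1)  # (S, 4) per-nucleotide totals
    k = (col > 0).sum(axis=1)
    row = obs.sum(axis=2)  # (S, 2)
    n = row.sum(axis=1)

    monomorphic = k < 2
    low_cov = (row == 0).any(axis=1)
    tested = ~(monomorphic | low_cov)

    with np.errstate(divide="ignore", invalid="ignore"):
        expected = row[:, :, None] * col[:, None, :] / n[:, None, None]
        cell = np.where(expected > 0, (obs - expected) ** 2 / expected, 0.0)
    chi2 = cell.sum(axis=(1, 2))

    if df_rule == "observed_minus_1":
        df = k - 1
    else:
        df = np.maximum(k - 2, 1)
    df = np.where(tested, df, 1)

    p = stats.chi2.sf(chi2, df)
    with np.errstate(divide="ignore"):
        nlp = np.minimum(-np.log10(p), neglog10p_cap)

    # per-phenotype expected heterozygosity from pooled read frequencies
    hexp_vals = np.full((table.n_sites, 2), np.nan)
    for i, pheno in enumerate((res, sus)):
        depth = pheno.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            freq = pheno / depth
            h = 1.0 - (freq ** 2).sum(axis=1)
        hexp_vals[:, i] = np.where(depth[:, 0] > 0, h, np.nan)

    alleles = [
        "".join(nuc for j, nuc in enumerate(NUCLEOTIDES) if col[i, j] > 0)
        for i in range(table.n_sites)
    ]
    flag = np.where(monomorphic, "monomorphic",
                    np.where(low_cov, "low_coverage", "tested"))

    out = pd.DataFrame(
        {
            "chrom": table.sites["chrom"].to_numpy(),
            "pos": table.sites["pos"].to_numpy(),
            "ref": table.sites["ref"].to_numpy(),
            "alleles": alleles,
            "k": k,
            "chi2": np.where(tested, chi2, np.nan),
            "df": np.where(tested, df, np.nan),
            "p": np.where(tested, p, np.nan),
            "neglog10p": np.where(tested, nlp, np.nan),
            "hexp_res": hexp_vals[:, 0],
            "hexp_sus": hexp_vals[:, 1],
            "flag": flag,
        }
    )
    return out


def site_chi2(
    table: CountsTable,
    index: int,
    df_rule: str = "observed_minus_1",
    neglog10p_cap: float = DEFAULT_NEGLOG10P_CAP,
) -> SiteTestResult:
    """Single-site convenience wrapper around :func:`test_sites`."""
    row = test_sites(table.subset(np.arange(table.n_sites) == index),
                     df_rule=df_rule, neglog10p_cap=neglog10p_cap).iloc[0]
    tested = row["flag"] == "tested"
    return SiteTestResult(
        chromosome=row["chrom"],
        position=int(row["pos"]),
        alleles_observed=tuple(row["alleles"]),
        chi2=float(row["chi2"]) if tested else None,
        df=int(row["df"]) if tested else None,
        p_value=float(row["p"]) if tested else None,
        neglog10p=float(row["neglog10p"]) if tested else None,
        hexp_resistant=(None if np.isnan(row["hexp_res"]) else float(row["hexp_res"])),
        hexp_susceptible=(None if np.isnan(row["hexp_sus"]) else float(row["hexp_sus"])),
        flag=str(row["flag"]),
    )


def replicate_heterogeneity(table: CountsTable, phenotype: str) -> pd.DataFrame:
    """Diagnostic replicates x alleles chi-square within one phenotype.

    Measures disagreement between replicate pools of the same phenotype; it
    does not gate the association results.
    """
    mask = table.phenotype_mask(phenotype)
    reps = table.counts[:, mask, :]  # (S, R, 4)
    col = reps.sum(axis=1)
    k = (col > 0).sum(axis=1)
    row = reps.sum(axis=2)
    n = row.sum(axis=1)
    ok = (k >= 2) & (row > 0).all(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = row[:, :, None] * col[:, None, :] / n[:, None, None]
        cell = np.where(expected > 0, (reps - expected) ** 2 / expected, 0.0)
    chi2 = cell.sum(axis=(1, 2))
    df = (reps.shape[1] - 1) * np.maximum(k - 1, 1)
    p = stats.chi2.sf(chi2, df)
    return pd.DataFrame(
        {
            "chrom": table.sites["chrom"].to_numpy(),
            "pos": table.sites["pos"].to_numpy(),
            "chi2": np.where(ok, chi2, np.nan),
            "df": np.where(ok, df, np.nan),
            "p": np.where(ok, p, np.nan),
        }
    )
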