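"""Seeded pooled-sequencing read-count simulator with planted associations.

Emulates the study design downstream of alignment: three collections, each
with resistant and susceptible phenotype classes sequenced as two replicate
pools of 25 diploid females, yielding per-site nucleotide read counts per
pool library.  A chosen subset of genes is "causal": at their sites the
alternate-allele population frequency differs between phenotype classes by
``delta``.  Causal genes are over-represented in one functional category so
that downstream enrichment has a planted signal to find.

Two sampling modes are provided.  ``pooled`` (default) models the finite
pool explicitly: each replicate pool draws 2 x 25 chromosomes binomially
from the phenotype's population frequency, then reads are drawn from the
realized pool frequency — the read-frequency variance therefore approaches
p(1-p)/50 at high depth rather than vanishing.  ``ideal`` draws reads
directly from the population frequency, giving the independent-read setting
under which the contingency chi-square is nominally calibrated.

Sequencing error miscalls each read uniformly onto the other three
nucleotides.  Per-library site depth follows a negative binomial
(mean + dispersion) to emulate the heavy-tailed coverage of exome-capture
data at reduced scale.  Identical config + seed reproduce byte-identical
output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counts_io import (
    CATEGORY_CODES,
    NUCLEOTIDES,
    CountsTable,
    GeneModel,
    PoolLibrary,
    genes_to_frame,
    write_category_map,
    write_gff3,
    write_manifest,
)

#: category codes used by the simulator, in assignment order (kept to a
#: handful so a ~100-gene universe yields informative category sizes;
#: includes MIT and ReDox so the merge step is exercised downstream)
DEFAULT_SIM_CATEGORIES = (
    "TRP", "RRTT", "MET", "SigT", "PROT", "CYT/STR", "MIT", "ReDox",
)

DEFAULT_COLLECTIONS = ("VCP", "VCD", "VeP")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic generator.

    Defaults reproduce the emulated design: 3 collections x {resistant,
    susceptible} x 2 replicate pools of 25 diploid females, ~100 genes on 3
    chromosomes of which 20 are causal with an allele-frequency differential
    of 0.35, negative-binomial coverage with mean 150 per library.
    """

    seed: int = 0
    n_collections: int = 3
    n_chromosomes: int = 3
    n_genes: int = 100
    gene_length_bp: tuple[int, int] = (2_000, 8_000)  # uniform int bounds
    intergenic_gap_bp: tuple[int, int] = (500, 2_000)
    snps_per_gene: tuple[int, int] = (10, 30)  # uniform int bounds
    n_causal_genes: int = 20
    delta: float = 0.35
    baseline_freq_range: tuple[float, float] = (0.05, 0.5)
    pool_individuals: int = 25  # diploid, per pool
    replicates_per_phenotype: int = 2
    coverage_mean: float = 150.0
    coverage_dispersion: float = 8.0
    seq_error: float = 0.001
    mode: str = "pooled"  # pooled | ideal
    triallelic_fraction: float = 0.02
    n_categories: int = 8
    category_enrichment: Mapping[str, float] = field(
        default_factory=lambda: {"TRP": 5.0}
    )

    def __post_init__(self) -> None:
        if self.mode not in ("pooled", "ideal"):
            raise ValueError("mode must be 'pooled' or 'ideal'")
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if not 0 <= self.n_causal_genes <= self.n_genes:
            raise ValueError("n_causal_genes must be in [0, n_genes]")
        if self.pool_individuals <= 0:
            raise ValueError("pool_individuals must be positive")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        if not 0.0 <= self.seq_error < 1.0:
            raise ValueError("seq_error must lie in [0, 1)")
        lo, hi = self.baseline_freq_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("baseline_freq_range must lie inside [0, 1]")
        if not 2 <= self.n_categories <= len(DEFAULT_SIM_CATEGORIES):
            raise ValueError(
                f"n_categories must be in [2, {len(DEFAULT_SIM_CATEGORIES)}]"
            )

    @property
    def category_codes(self) -> tuple[str, ...]:
        return DEFAULT_SIM_CATEGORIES[: self.n_categories]


@dataclass
class TruthTable:
    """Planted ground truth: gene flags and per-site population frequencies."""

    genes: pd.DataFrame  # gene_id, chrom, start, end, category, is_causal
    sites: pd.DataFrame  # chrom, pos, gene_id, is_causal, freq per phenotype

    def write(self, gene_path: str | Path, site_path: str | Path) -> None:
        self.genes.to_csv(gene_path, sep="\t", index=False)
        self.sites.to_csv(site_path, sep="\t", index=False, float_format="%.6f")


@dataclass
class SimulatedCollection:
    collection_id: str
    counts: CountsTable
    genes: list[GeneModel]
    categories: dict[str, str]
    truth: TruthTable


def _gene_layout(config: SimulationConfig) -> tuple[list[GeneModel], dict[str, str], np.ndarray]:
    """Shared-across-collections layout: intervals, categories, causal flags."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    lengths = rng.integers(*config.gene_length_bp, size=config.n_genes, endpoint=True)
    gaps = rng.integers(*config.intergenic_gap_bp, size=config.n_genes, endpoint=True)
    chrom_of = np.arange(config.n_genes) % config.n_chromosomes

    causal = np.zeros(config.n_genes, dtype=bool)
    causal[rng.choice(config.n_genes, size=config.n_causal_genes, replace=False)] = True

    codes = config.category_codes
    # background rates are uniform over the categories as they are *tested*
    # downstream: codes that the default merge collapses into one category
    # (MIT + ReDox) split one group's share, so the merged null categories
    # stay exchangeable and the planted signal has fair competitors
    group_of = {c: ("MIT/ReDox" if c in ("MIT", "ReDox") else c) for c in codes}
    groups = list(dict.fromkeys(group_of.values()))
    group_size = {g: sum(1 for c in codes if group_of[c] == g) for g in groups}
    base = np.array(
        [1.0 / len(groups) / group_size[group_of[c]] for c in codes]
    )
    # the plant is an exact rate multiplier: a causal gene carries a planted
    # code at w times its background rate; the remaining mass is spread over
    # the unlisted codes proportionally to their background rates
    listed = np.array([c in config.category_enrichment for c in codes])
    causal_probs = base.copy()
    causal_probs[listed] = np.array(
        [config.category_enrichment[c] * base[i]
         for i, c in enumerate(codes) if listed[i]]
    )
    planted_mass = causal_probs[listed].sum()
    if planted_mass > 1.0 + 1e-12:
        raise ValueError(
            "category_enrichment multipliers are infeasible: planted "
            f"probability mass {planted_mass:.3f} exceeds 1"
        )
    if (~listed).any():
        causal_probs[~listed] = (
            (1.0 - planted_mass) * base[~listed] / base[~listed].sum()
        )

    genes: list[GeneModel] = []
    categories: dict[str, str] = {}
    cursor = {c: 1 for c in range(config.n_chromosomes)}
    for i in range(config.n_genes):
        c = int(chrom_of[i])
        start = cursor[c] + int(gaps[i])
        end = start + int(lengths[i]) - 1
        cursor[c] = end + 1
        gid = f"G{i + 1:04d}"
        probs = causal_probs if causal[i] else base
        code = codes[int(rng.choice(len(codes), p=probs))]
        genes.append(
            GeneModel(gid, str(c + 1), start, end, category_code=code,
                      description="causal" if causal[i] else "")
        )
        categories[gid] = code
    return genes, categories, causal


def _error_mix(freq: np.ndarray, e: float) -> np.ndarray:
    """Per-read miscall: keep with prob 1-e, scatter uniformly to the rest."""
    return freq * (1.0 - e) + (1.0 - freq) * e / 3.0


def simulate_collection(
    config: SimulationConfig,
    collection_id: str = "C1",
    collection_index: int = 0,
) -> SimulatedCollection:
    """Simulate one collection's pooled read counts plus its ground truth.

    The gene layout (intervals, categories, causal flags) depends only on
    the master seed, so collections simulated from the same config share
    their causal genes; SNP positions, baseline frequencies, pool draws and
    read noise are collection-specific (seeded by ``collection_index``).
    """
    genes, categories, causal = _gene_layout(config)
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 1 + collection_index])
    )

    # SNP positions per gene
    site_chrom: list[str] = []
    site_pos: list[int] = []
    site_gene: list[str] = []
    site_causal: list[bool] = []
    for g, is_causal in zip(genes, causal):
        span = g.end - g.start + 1
        n_snps = int(rng.integers(*config.snps_per_gene, endpoint=True))
        n_snps = min(n_snps, span)
        offsets = np.sort(rng.choice(span, size=n_snps, replace=False))
        site_chrom.extend([g.chromosome] * n_snps)
        site_pos.extend((g.start + offsets).tolist())
        site_gene.extend([g.gene_id] * n_snps)
        site_causal.extend([bool(is_causal)] * n_snps)
    n_sites = len(site_pos)
    site_causal_arr = np.array(site_causal)

    # alleles: ref + one alt (a configurable fraction gains a second alt)
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    tri = rng.random(n_sites) < config.triallelic_fraction
    alt2_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    tri &= alt2_idx != alt_idx

    lo, hi = config.baseline_freq_range
    q = rng.uniform(lo, hi, size=n_sites)  # total alternate-allele mass
    split = np.where(tri, rng.uniform(0.2, 0.8, size=n_sites), 1.0)

    # population frequencies per phenotype over the 4 nucleotides
    freq = np.zeros((n_sites, 2, 4))  # phenotype 0 = resistant, 1 = susceptible
    rows = np.arange(n_sites)
    q1 = q * split
    q2 = q * (1.0 - split)
    for ph in (0, 1):
        freq[rows, ph, alt_idx] += q1
        freq[rows, ph, alt2_idx] += np.where(tri, q2, 0.0)
        freq[rows, ph, ref_idx] += 1.0 - q1 - np.where(tri, q2, 0.0)
    # causal sites: the primary alternate allele is `delta` more frequent in
    # the resistant class, taken from the reference allele
    if config.delta > 0:
        causal_rows = np.flatnonzero(site_causal_arr)
        new_ref = freq[causal_rows, 0, ref_idx[causal_rows]] - config.delta
        bad = new_ref < -1e-12
        if bad.any():
            i = causal_rows[np.flatnonzero(bad)[0]]
            raise ValueError(
                f"applying delta={config.delta} at site "
                f"{site_chrom[i]}:{site_pos[i]} drives the reference "
                "frequency below 0; shrink delta or the baseline range"
            )
        freq[causal_rows, 0, ref_idx[causal_rows]] = np.maximum(new_ref, 0.0)
        freq[causal_rows, 0, alt_idx[causal_rows]] += config.delta

    # libraries: resistant then susceptible, replicates in order
    libraries: list[PoolLibrary] = []
    for ph, tag in ((0, "R"), (1, "S")):
        for r in range(1, config.replicates_per_phenotype + 1):
            libraries.append(
                PoolLibrary(
                    library_id=f"{collection_id}.{tag}{r}",
                    collection_id=collection_id,
                    phenotype="resistant" if ph == 0 else "susceptible",
                    replicate_index=r,
                )
            )

    n_libs = len(libraries)
    counts = np.zeros((n_sites, n_libs, 4), dtype=np.int64)
    nb_n = config.coverage_dispersion
    nb_p = nb_n / (nb_n + config.coverage_mean)
    two_n = 2 * config.pool_individuals
    for j, lib in enumerate(libraries):
        ph = 0 if lib.phenotype == "resistant" else 1
        depth = rng.negative_binomial(nb_n, nb_p, size=n_sites)
        if config.mode == "pooled":
            pool = rng.multinomial(two_n, freq[:, ph, :])  # (S, 4)
            read_freq = pool / two_n
        else:
            read_freq = freq[:, ph, :]
        counts[:, j, :] = rng.multinomial(
            depth, _error_mix(read_freq, config.seq_error)
        )

    sites = pd.DataFrame(
        {
            "chrom": pd.Series(site_chrom, dtype=str),
            "pos": pd.Series(site_pos, dtype=np.int64),
            "ref": pd.Series([NUCLEOTIDES[i] for i in ref_idx], dtype=str),
        }
    )
    table = CountsTable(sites, counts, libraries)

    truth_genes = genes_to_frame(genes).drop(columns=["description"])
    truth_genes["is_causal"] = causal
    truth_sites = pd.DataFrame(
        {
            "chrom": sites["chrom"],
            "pos": sites["pos"],
            "gene_id": site_gene,
            "is_causal": site_causal_arr,
            "freq_alt_resistant": freq[rows, 0, alt_idx],
            "freq_alt_susceptible": freq[rows, 1, alt_idx],
        }
    )
    # synthetic aligned-read totals for the sites/aligned-nt ratio op
    libraries = [
        PoolLibrary(
            lib.library_id, lib.collection_id, lib.phenotype,
            lib.replicate_index,
            aligned_read_count=int(counts[:, j, :].sum() // lib.read_length_nt + 1),
            read_length_nt=lib.read_length_nt,
        )
        for j, lib in enumerate(libraries)
    ]
    table.libraries = libraries
    return SimulatedCollection(
        collection_id, table, genes, categories,
        TruthTable(truth_genes, truth_sites),
    )


def simulate_study(
    config: SimulationConfig,
    outdir: str | Path | None = None,
    collection_ids: Sequence[str] | None = None,
) -> list[SimulatedCollection]:
    """Simulate all collections of the study design, optionally writing files.

    Writes, per collection, ``counts_<id>.tsv`` and
    ``truth_sites_<id>.tsv``; and once, the shared ``genes.gff3``,
    ``categories.tsv``, ``truth_genes.tsv`` and ``manifest.tsv``.
    """
    if collection_ids is None:
        collection_ids = DEFAULT_COLLECTIONS[: config.n_collections]
    if len(collection_ids) != config.n_collections:
        raise ValueError("collection_ids length must equal n_collections")
    sims = [
        simulate_collection(config, cid, i)
        for i, cid in enumerate(collection_ids)
    ]
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gff3(sims[0].genes, outdir / "genes.gff3")
        write_category_map(sims[0].categories, outdir / "categories.tsv")
        sims[0].truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        manifest = [lib for s in sims for lib in s.counts.libraries]
        write_manifest(manifest, outdir / "manifest.tsv")
        for s in sims:
            s.counts.write(outdir / f"counts_{s.collection_id}.tsv")
            s.truth.sites.to_csv(
                outdir / f"truth_sites_{s.collection_id}.tsv",
                sep="\t", index=False, float_format="%.6f",
            )
    return sims
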