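"""Per-site per-pool nucleotide count tables and the site filters applied to them.

The on-disk dialect mirrors a Varscan ``readcounts``-style table flattened to
one row per genomic site: ``chrom``, ``pos`` (1-based), ``ref``, then one
block of five columns per pool library, ``<lib>:A``, ``<lib>:C``, ``<lib>:G``,
``<lib>:T``, ``<lib>:depth``.  Library identity is carried in the column
names and cross-checked against an optional manifest.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

NUCLEOTIDES = ("A", "C", "G", "T")
NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}
PHENOTYPES = ("resistant", "susceptible")

#: controlled functional-category vocabulary
CATEGORY_CODES = (
    "APOP", "CSR", "CYT/STR", "DIV", "MIT", "LIPID", "ReDox",
    "PROT", "RRTT", "SigT", "MET", "UNK", "TRP",
)


class CountsFormatError(ValueError):
    """Raised on a malformed counts table, with the offending line number."""


@dataclass(frozen=True)
class PoolLibrary:
    """One pooled sequencing library (one DNA pool of many individuals)."""

    library_id: str
    collection_id: str
    phenotype: str
    replicate_index: int
    aligned_read_count: int | None = None
    read_length_nt: int = 100

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise ValueError(
                f"phenotype must be one of {PHENOTYPES}, got {self.phenotype!r}"
            )
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")


def _parse_library_id(library_id: str) -> PoolLibrary:
    """Infer collection/phenotype/replicate from ``<collection>.<R|S><rep>``."""
    try:
        collection, tag = library_id.rsplit(".", 1)
        phenotype = {"R": "resistant", "S": "susceptible"}[tag[0]]
        replicate = int(tag[1:])
    except (ValueError, KeyError, IndexError):
        raise CountsFormatError(
            f"cannot infer pool metadata from library id {library_id!r}; "
            "expected '<collection>.<R|S><replicate>' or provide a manifest"
        ) from None
    return PoolLibrary(library_id, collection, phenotype, replicate)


@dataclass
class CountsTable:
    """In-memory per-site counts for one collection's pool libraries.

    ``counts`` has shape ``(n_sites, n_libraries, 4)`` in A,C,G,T order;
    ``sites`` carries ``chrom``, ``pos`` (1-based) and ``ref`` aligned with
    the first axis.
    """

    sites: pd.DataFrame
    counts: np.ndarray
    libraries: list[PoolLibrary]

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.sites), len(self.libraries), 4):
            raise ValueError("counts array shape does not match sites/libraries")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def depth(self) -> np.ndarray:
        """Per-site per-library depth, shape (n_sites, n_libraries)."""
        return self.counts.sum(axis=2)

    def total_depth(self) -> np.ndarray:
        """Per-site depth summed over all libraries."""
        return self.counts.sum(axis=(1, 2))

    def phenotype_mask(self, phenotype: str) -> np.ndarray:
        return np.array([lib.phenotype == phenotype for lib in self.libraries])

    def subset(self, keep: np.ndarray) -> "CountsTable":
        return CountsTable(
            self.sites.loc[keep].reset_index(drop=True),
            self.counts[np.asarray(keep)],
            list(self.libraries),
        )

    # -- round-trippable TSV dialect -------------------------------------

    def write(self, path: str | Path) -> None:
        cols: dict[str, object] = {
            "chrom": self.sites["chrom"].to_numpy(),
            "pos": self.sites["pos"].to_numpy(),
            "ref": self.sites["ref"].to_numpy(),
        }
        for j, lib in enumerate(self.libraries):
            for i, nuc in enumerate(NUCLEOTIDES):
                cols[f"{lib.library_id}:{nuc}"] = self.counts[:, j, i]
            cols[f"{lib.library_id}:depth"] = self.counts[:, j].sum(axis=1)
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)

    @classmethod
    def read(
        cls,
        path: str | Path,
        manifest: Sequence[PoolLibrary] | None = None,
    ) -> "CountsTable":
        """Read a counts TSV; every defect is reported with its line number."""
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str})
        for col in ("chrom", "pos", "ref"):
            if col not in df.columns:
                raise CountsFormatError(f"{path}: missing required column {col!r}")

        lib_ids: list[str] = []
        for col in df.columns[3:]:
            if ":" not in col:
                raise CountsFormatError(f"{path}: malformed library column {col!r}")
            lib, part = col.rsplit(":", 1)
            if part not in NUCLEOTIDES and part != "depth":
                raise CountsFormatError(
                    f"{path}: unknown nucleotide {part!r} in column {col!r}"
                )
            if lib not in lib_ids:
                lib_ids.append(lib)
        for lib in lib_ids:
            missing = [
                f"{lib}:{p}" for p in (*NUCLEOTIDES, "depth")
                if f"{lib}:{p}" not in df.columns
            ]
            if missing:
                raise CountsFormatError(f"{path}: library {lib!r} missing {missing}")

        if manifest is not None:
            by_id = {m.library_id: m for m in manifest}
            unknown = [l for l in lib_ids if l not in by_id]
            if unknown:
                raise CountsFormatError(
                    f"{path}: libraries {unknown} absent from manifest"
                )
            libraries = [by_id[l] for l in lib_ids]
        else:
            libraries = [_parse_library_id(l) for l in lib_ids]

        n = len(df)
        counts = np.empty((n, len(lib_ids), 4), dtype=np.int64)
        if n:
            # first data row of the file is line 2 (header is line 1)
            bad_pos = df.index[df["pos"] < 1]
            if len(bad_pos):
                raise CountsFormatError(
                    f"{path}: line {bad_pos[0] + 2}: position must be >= 1"
                )
            bad_ref = df.index[~df["ref"].isin(NUCLEOTIDES)]
            if len(bad_ref):
                raise CountsFormatError(
                    f"{path}: line {bad_ref[0] + 2}: unknown reference "
                    f"nucleotide {df['ref'].iloc[bad_ref[0]]!r}"
                )
            dup = df.duplicated(subset=["chrom", "pos"])
            if dup.any():
                i = int(np.flatnonzero(dup.to_numpy())[0])
                raise CountsFormatError(
                    f"{path}: line {i + 2}: duplicate site "
                    f"{df['chrom'].iloc[i]}:{df['pos'].iloc[i]}"
                )
            for j, lib in enumerate(lib_ids):
                block = df[[f"{lib}:{nuc}" for nuc in NUCLEOTIDES]].to_numpy()
                if (block < 0).any():
                    i = int(np.flatnonzero((block < 0).any(axis=1))[0])
                    raise CountsFormatError(
                        f"{path}: line {i + 2}: negative count for library {lib!r}"
                    )
                depth = df[f"{lib}:depth"].to_numpy()
                bad = block.sum(axis=1) != depth
                if bad.any():
                    i = int(np.flatnonzero(bad)[0])
                    raise CountsFormatError(
                        f"{path}: line {i + 2}: depth column disagrees with "
                        f"A+C+G+T sum for library {lib!r} at site "
                        f"{df['chrom'].iloc[i]}:{df['pos'].iloc[i]}"
                    )
                counts[:, j, :] = block

        sites = df[["chrom", "pos", "ref"]].copy()
        sites["pos"] = sites["pos"].astype(np.int64)
        return cls(sites.reset_index(drop=True), counts, libraries)


# -- site filters --------------------------------------------------------


@dataclass
class FilterReport:
    """Accounting for the per-library minimum-coverage filter."""

    n_input: int
    n_low_coverage: int
    min_coverage_per_library: int

    @property
    def n_kept(self) -> int:
        return self.n_input - self.n_low_coverage


def filter_sites(
    table: CountsTable, min_coverage_per_library: int = 15
) -> tuple[CountsTable, FilterReport]:
    """Keep sites where *every* library reaches the minimum depth.

    The coverage rule is per library (each pool independently), so a
    collection of four pools at the default threshold admits only sites with
    total depth of at least 60.
    """
    depth = table.depth()
    keep = (depth >= min_coverage_per_library).all(axis=1)
    report = FilterReport(
        n_input=table.n_sites,
        n_low_coverage=int((~keep).sum()),
        min_coverage_per_library=min_coverage_per_library,
    )
    return table.subset(keep), report


@dataclass
class MonomorphicReport:
    n_input: int
    n_monomorphic: int
    n_no_data: int

    @property
    def n_polymorphic(self) -> int:
        return self.n_input - self.n_monomorphic - self.n_no_data


def flag_monomorphic(table: CountsTable) -> tuple[CountsTable, MonomorphicReport]:
    """Split off sites where a single nucleotide carries all reads.

    A site with exactly one nonzero nucleotide total (summed over libraries)
    is monomorphic and excluded from testing; a site with zero reads
    everywhere is classed "no-data", never "monomorphic", so the two
    exclusion reasons are accounted separately.
    """
    totals = table.counts.sum(axis=1)  # (n_sites, 4)
    n_alleles = (totals > 0).sum(axis=1)
    mono = n_alleles == 1
    no_data = n_alleles == 0
    keep = ~(mono | no_data)
    report = MonomorphicReport(
        n_input=table.n_sites,
        n_monomorphic=int(mono.sum()),
        n_no_data=int(no_data.sum()),
    )
    return table.subset(keep), report


@dataclass
class CoverageSummary:
    min: float
    max: float
    mean: float
    median: float


def coverage_summary(table: CountsTable) -> CoverageSummary:
    """Min/max/mean/median of per-site depth totalled across all libraries."""
    if table.n_sites == 0:
        raise ValueError("coverage_summary requires at least one site")
    totals = table.total_depth()
    return CoverageSummary(
        min=float(totals.min()),
        max=float(totals.max()),
        mean=float(totals.mean()),
        median=float(statistics.median(totals.tolist())),
    )


def sites_per_aligned_nt_ratio(
    n_variant_sites: int, aligned_reads: int, read_length: int = 100
) -> float:
    """Variant sites per aligned nucleotide, scaled by 1000."""
    total_nt = aligned_reads * read_length
    if total_nt <= 0:
        raise ValueError("aligned nucleotides must be positive")
    return n_variant_sites * 1000 / total_nt


# -- gene models and auxiliary tables ------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene's full genomic footprint (UTRs + exons + introns), 1-based inclusive."""

    gene_id: str
    chromosome: str
    start: int
    end: int
    category_code: str = "UNK"
    description: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.category_code not in CATEGORY_CODES:
            raise ValueError(
                f"{self.gene_id}: category {self.category_code!r} not in "
                "controlled vocabulary"
            )

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def genes_to_frame(genes: Iterable[GeneModel]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (g.gene_id, g.chromosome, g.start, g.end, g.category_code, g.description)
            for g in genes
        ],
        columns=["gene_id", "chrom", "start", "end", "category", "description"],
    )


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for g in genes:
        attrs = f"ID={g.gene_id}"
        if g.description:
            attrs += f";description={g.description}"
        lines.append(
            "\t".join(
                [g.chromosome, "poolseq_assoc", "gene", str(g.start), str(g.end),
                 ".", "+", ".", attrs]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _read_gff3(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chromosome=feat.seqid,
                start=feat.start,
                end=feat.end,
                description=feat.attributes.get("description", [""])[0],
            )
        )
    return genes


def _read_bed(path: Path) -> list[GeneModel]:
    # BED is 0-based half-open; convert to 1-based inclusive on read
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "name"],
        dtype={"chrom": str, "name": str},
    )
    return [
        GeneModel(
            gene_id=r.name, chromosome=r.chrom, start=int(r.start) + 1,
            end=int(r.end),
        )
        for r in df.itertuples()
    ]


def read_gene_models(
    path: str | Path, categories: Mapping[str, str] | None = None
) -> list[GeneModel]:
    """Read gene models from GFF3 (``.gff``/``.gff3``) or BED, optionally
    attaching a gene → category map."""
    path = Path(path)
    if path.suffix.lower() in (".bed",):
        genes = _read_bed(path)
    else:
        genes = _read_gff3(path)
    if categories is not None:
        genes = [
            replace(g, category_code=categories.get(g.gene_id, "UNK")) for g in genes
        ]
    return genes


def read_category_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene_id", "category_code"]:
        raise CountsFormatError(
            f"{path}: expected columns gene_id, category_code"
        )
    return dict(zip(df["gene_id"], df["category_code"]))


def write_category_map(categories: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(categories.items()), columns=["gene_id", "category_code"]
    ).to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> list[PoolLibrary]:
    df = pd.read_csv(path, sep="\t")
    return [
        PoolLibrary(
            library_id=str(r.library_id),
            collection_id=str(r.collection),
            phenotype=str(r.phenotype),
            replicate_index=int(r.replicate),
            aligned_read_count=(
                int(r.aligned_reads) if pd.notna(r.aligned_reads) else None
            ),
        )
        for r in df.itertuples()
    ]


def write_manifest(libraries: Sequence[PoolLibrary], path: str | Path) -> None:
    pd.DataFrame(
        [
            (l.library_id, l.collection_id, l.phenotype, l.replicate_index,
             l.aligned_read_count)
            for l in libraries
        ],
        columns=["library_id", "collection", "phenotype", "replicate",
                 "aligned_reads"],
    ).to_csv(path, sep="\t", index=False)
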