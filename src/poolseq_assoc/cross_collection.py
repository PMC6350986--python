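"""Combine per-collection high-association gene lists.

Covers the three-way intersection with Venn-region accounting, the joint
top-10% "extreme" subset (a gene must strictly exceed every collection's
90th-percentile threshold), and positional summaries relative to
chromosomes, chromosome arms and a focal locus such as the voltage-gated
sodium channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .counts_io import GeneModel

#: voltage-gated sodium channel locus (chromosome 3, AaegL5 coordinates) —
#: the pyrethroid target site used as the default focal interval
VGSC_INTERVAL = ("3", 315_926_360, 316_405_639)


@dataclass
class CommonSet:
    """Genes present in every collection's high-association set."""

    common: list[str]
    region_counts: dict[frozenset, int]
    scores: pd.DataFrame  # genes x collections, rows indexed by gene_id
    n_removed_non_coding: int = 0

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())


def intersect_collections(
    sets: Mapping[str, Iterable[str]],
    scores: Mapping[str, Mapping[str, float]] | None = None,
    non_coding: Iterable[str] = (),
) -> CommonSet:
    """Intersection of per-collection gene lists with Venn-region counts.

    ``region_counts`` maps each nonempty subset of collection labels
    (frozenset) to the number of genes appearing in exactly those
    collections; the counts therefore sum to the size of the union.
    Genes listed in ``non_coding`` are removed from the intersection (the
    removal is counted, mirroring the 1,054 -> 1,053 coding filter).
    """
    if len(sets) < 2:
        raise ValueError("need at least two collections to intersect")
    membership: dict[str, set[str]] = {}
    for label, genes in sets.items():
        for g in genes:
            membership.setdefault(g, set()).add(label)
    region_counts: dict[frozenset, int] = {}
    for g, labels in membership.items():
        key = frozenset(labels)
        region_counts[key] = region_counts.get(key, 0) + 1
    all_labels = frozenset(sets)
    common = sorted(g for g, l in membership.items() if frozenset(l) == all_labels)
    non_coding = set(non_coding)
    removed = [g for g in common if g in non_coding]
    common = [g for g in common if g not in non_coding]
    if scores is not None:
        missing = [
            g for g in common
            if any(g not in scores[label] for label in sets)
        ]
        if missing:
            raise ValueError(f"common genes missing a score: {missing[:5]}")
        score_df = pd.DataFrame(
            {label: [scores[label][g] for g in common] for label in sets},
            index=pd.Index(common, name="gene_id"),
        )
    else:
        score_df = pd.DataFrame(index=pd.Index(common, name="gene_id"))
    return CommonSet(common, region_counts, score_df, len(removed))


def nearest_rank_percentile(values: Sequence[float], q: float) -> float:
    """Empirical q-th percentile by the nearest-rank convention."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample")
    rank = max(1, math.ceil(q / 100.0 * v.size))
    return float(v[rank - 1])


@dataclass
class ExtremeSet:
    thresholds: dict[str, float]
    members: list[str]


def extreme_subset(common: CommonSet, top_fraction: float = 0.10) -> ExtremeSet:
    """Joint top-fraction subset of the common set.

    Per collection the threshold is the nearest-rank (100 - 100f)-th
    percentile of common-set scores; membership requires a score *strictly*
    above the threshold in every collection.
    """
    if common.scores.empty or common.scores.shape[1] == 0:
        raise ValueError("common set carries no per-collection scores")
    q = 100.0 * (1.0 - top_fraction)
    thresholds = {
        label: nearest_rank_percentile(common.scores[label].to_numpy(), q)
        for label in common.scores.columns
    }
    above = np.ones(len(common.scores), dtype=bool)
    for label, thr in thresholds.items():
        above &= common.scores[label].to_numpy() > thr
    members = sorted(common.scores.index[above])
    return ExtremeSet(thresholds, members)


@dataclass
class PositionalSummary:
    per_chromosome: pd.Series
    per_arm: pd.Series | None
    distances: pd.Series | None  # signed bp from gene midpoint to focal interval
    missing_coordinates: list[str] = field(default_factory=list)


def positional_summary(
    gene_ids: Sequence[str],
    genes: Sequence[GeneModel],
    arm_boundaries: Mapping[str, int] | None = None,
    focal_interval: tuple[str, int, int] | None = None,
) -> PositionalSummary:
    """Chromosome / arm counts and distances to a focal locus.

    ``arm_boundaries`` maps chromosome -> centromere position; genes with
    midpoint at or before the boundary are on the p arm.  The distance to
    the focal interval is signed (negative upstream of the interval start,
    0 if the gene overlaps it) and only defined for genes on the focal
    chromosome.
    """
    by_id = {g.gene_id: g for g in genes}
    missing = [gid for gid in gene_ids if gid not in by_id]
    present = [by_id[gid] for gid in gene_ids if gid in by_id]

    chrom_counts = (
        pd.Series([g.chromosome for g in present], dtype=str)
        .value_counts()
        .sort_index()
    )
    per_arm = None
    if arm_boundaries is not None:
        labels = []
        for g in present:
            boundary = arm_boundaries.get(g.chromosome)
            if boundary is None:
                labels.append(f"{g.chromosome}?")
            else:
                labels.append(
                    f"{g.chromosome}p" if g.midpoint <= boundary
                    else f"{g.chromosome}q"
                )
        per_arm = pd.Series(labels, dtype=str).value_counts().sort_index()
    distances = None
    if focal_interval is not None:
        fchrom, fstart, fend = focal_interval
        vals = {}
        for g in present:
            if g.chromosome != fchrom:
                continue
            if g.end < fstart:
                vals[g.gene_id] = g.end - fstart
            elif g.start > fend:
                vals[g.gene_id] = g.start - fend
            else:
                vals[g.gene_id] = 0
        distances = pd.Series(vals, dtype=float).sort_index()
    return PositionalSummary(chrom_counts, per_arm, distances, missing)


def percent_truncated(k: int, n: int, decimals: int = 1) -> float:
    """Share k/n as a percentage truncated (not rounded) to ``decimals``."""
    if n <= 0:
        raise ValueError("denominator must be positive")
    scale = 10 ** decimals
    return math.floor(k / n * 100 * scale) / scale
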