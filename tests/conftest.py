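"""Shared fixtures: hand-built count tables and small simulated studies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from poolseq_assoc import CountsTable, PoolLibrary


def make_libraries(collection: str = "X", replicates: int = 2) -> list[PoolLibrary]:
    libs = []
    for tag, pheno in (("R", "resistant"), ("S", "susceptible")):
        for r in range(1, replicates + 1):
            libs.append(PoolLibrary(f"{collection}.{tag}{r}", collection, pheno, r))
    return libs


def make_counts(rows: list[tuple], counts: np.ndarray,
                libraries: list[PoolLibrary] | None = None) -> CountsTable:
    """Build a CountsTable from (chrom, pos, ref) rows and a (S, L, 4) array."""
    if libraries is None:
        libraries = make_libraries()
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref"])
    sites["chrom"] = sites["chrom"].astype(str)
    sites["pos"] = sites["pos"].astype(np.int64)
    return CountsTable(sites, np.asarray(counts, dtype=np.int64), libraries)


@pytest.fixture
def four_libraries() -> list[PoolLibrary]:
    return make_libraries()


@pytest.fixture
def three_site_table(four_libraries) -> CountsTable:
    """Three biallelic sites, 4 libraries, depths around 20-40."""
    rng = np.random.default_rng(42)
    counts = np.zeros((3, 4, 4), dtype=np.int64)
    counts[:, :, 0] = rng.integers(10, 30, size=(3, 4))  # A
    counts[:, :, 2] = rng.integers(5, 20, size=(3, 4))   # G
    rows = [("1", 100, "A"), ("1", 250, "A"), ("2", 50, "G")]
    return make_counts(rows, counts, four_libraries)
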