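"""Hypergeometric over-representation of functional categories.

Each category in the high-association gene set is compared with the same
category among all background (coding) genes: with N background genes of
which K carry the category, and n genes drawn into the high-association
set of which k carry it, the reported p-value is the upper tail
P(X >= k) of Hypergeometric(N, K, n).  Mitochondrial and redox categories
are merged before testing by default, since key redox enzymes localise to
mitochondria.  Raw p-values are reported; an optional BH adjustment across
categories is off by default.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .counts_io import CATEGORY_CODES
from .gene_scores import bh_fdr

#: default merge: mitochondrial + redox -> one category
DEFAULT_MERGES: dict[str, tuple[str, ...]] = {"MIT/ReDox": ("MIT", "ReDox")}


def merge_categories(
    categories: Mapping[str, str],
    merges: Mapping[str, tuple[str, ...]] | None = None,
) -> dict[str, str]:
    """Replace each merged source code by its merged label.

    ``merges`` maps the merged label to the tuple of source codes; sources
    must belong to the controlled vocabulary.
    """
    if merges is None:
        merges = DEFAULT_MERGES
    remap: dict[str, str] = {}
    for merged, sources in merges.items():
        for code in sources:
            if code not in CATEGORY_CODES:
                raise ValueError(f"unknown category code in merge spec: {code!r}")
            remap[code] = merged
    return {gene: remap.get(code, code) for gene, code in categories.items()}


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    Population N with K successes, n draws without replacement; evaluated
    in log space by scipy for numerical stability at genome scale.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(
            f"inconsistent hypergeometric arguments N={N}, K={K}, n={n}, k={k}"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_all(
    high_set: Iterable[str],
    background: Mapping[str, str],
    merges: Mapping[str, tuple[str, ...]] | None = DEFAULT_MERGES,
    adjust: bool = False,
) -> pd.DataFrame:
    """One over-representation test per (merged) category.

    ``background`` maps every background gene to its category; it must
    contain every high-set gene (high-set genes without a category are
    assigned UNK and counted in the ``n_unknown_category`` attribute of the
    result frame).  Returns one row per category sorted by p-value, with
    the fold-enrichment (k/n)/(K/N) alongside.
    """
    high = set(high_set)
    stray = sorted(high - set(background))
    cats = dict(background)
    for g in stray:
        cats[g] = "UNK"
    if merges is not None:
        cats = merge_categories(cats, merges)

    N = len(cats)
    n = len(high)
    records = []
    all_codes = sorted(set(cats.values()))
    for code in all_codes:
        K = sum(1 for c in cats.values() if c == code)
        k = sum(1 for g in high if cats[g] == code)
        p = hypergeom_upper(N, K, n, k)
        fold = (k / n) / (K / N) if n and K else float("nan")
        records.append((code, k, n, K, N, p, fold))
    out = pd.DataFrame(
        records, columns=["category", "k", "n", "K", "N", "p_upper", "fold"]
    )
    if adjust and len(out):
        out["p_adjusted"] = _bh_adjust(out["p_upper"].to_numpy())
    out = out.sort_values("p_upper", kind="stable").reset_index(drop=True)
    out.attrs["n_unknown_category"] = len(stray)
    return out


def _bh_adjust(p):
    """Step-up adjusted p-values (monotone BH q-values)."""
    import numpy as np

    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
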