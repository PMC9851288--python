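"""Offline over-representation analysis against GMT gene-set collections.

A query gene list (typically DE genes) is tested against each set in a
collection with the upper-tail hypergeometric test, using a user-supplied
background -- by convention, all genes expressed in the data set (i.e. the
features surviving noise removal).  Set membership is intersected with the
background before testing so that un-assayed genes cannot inflate term sizes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexp import benjamini_hochberg
from .matrixio import GeneSetCollection, MatrixIOError

__all__ = ["EnrichmentResult", "enrich"]


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # term_id, term_name, overlap, query_size, term_size, background_size, pvalue, padj
    query_size: int
    background_size: int

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["padj"] < alpha]


def enrich(
    query: list[str] | set[str],
    sets: GeneSetCollection,
    background: list[str] | set[str],
) -> EnrichmentResult:
    """Hypergeometric over-representation of ``query`` within ``background``.

    Per term: with background size N, term size K (after intersection with
    the background), query size n and overlap k, the p-value is
    P[X >= k] for X ~ Hypergeom(N, K, n).  Terms empty after restriction are
    skipped; Benjamini-Hochberg adjustment runs across the tested terms and
    the output is sorted by p-value (ties by term id).
    """
    background = set(map(str, background))
    query = set(map(str, query))
    if not query:
        raise MatrixIOError("empty query gene list")
    if not background:
        raise MatrixIOError("empty background gene list")
    outside = query - background
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the background were dropped",
            stacklevel=2,
        )
        query = query & background
        if not query:
            raise MatrixIOError("no query gene is in the background")

    N, n = len(background), len(query)
    rows = []
    for t in sets:
        members = t.members & background
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((t.term_id, t.term_name, k, n, K, N, min(p, 1.0)))
    if not rows:
        raise MatrixIOError("no gene set overlaps the background")
    df = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "overlap", "query_size", "term_size", "background_size", "pvalue"],
    )
    df["padj"] = benjamini_hochberg(df["pvalue"].to_numpy())
    df = df.sort_values(["pvalue", "term_id"], kind="mergesort").reset_index(drop=True)
    return EnrichmentResult(table=df, query_size=n, background_size=N)
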