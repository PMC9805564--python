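"""Offline over-representation analysis (ORA) of a query gene list.

Each library set is tested for overlap with the query against a background
universe using the one-sided Fisher exact test (hypergeometric upper tail
``P[X >= k]``), with Benjamini-Hochberg adjustment across the library's
terms, a conditional-odds-ratio, and an Enrichr-style combined score
``-ln(p) * z``.  Here ``z`` is the standardised deviation of the observed
overlap from its hypergeometric expectation — a local, fully offline
surrogate for Enrichr's server-side rank-deviation z-score, so combined
scores are comparable within a run but not numerically identical to the
Enrichr web service's.

The default universe is the union of all library genes, keeping the
analysis self-contained; a custom background may be supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneSetLibrary

__all__ = ["OraRecord", "fisher_enrich", "adjust_pvalues", "combined_score", "ora_frame"]


@dataclass
class OraRecord:
    """Over-representation result for one gene set."""

    set_name: str
    overlap_k: int
    set_size_K: int
    query_size_n: int
    universe_N: int
    p_fisher: float
    p_adjusted: float
    odds_ratio: float
    combined_score: float
    pct_query_in_set: float
    overlap_genes: tuple[str, ...]


def hypergeom_pvalue(k, N, K, n):
    """One-sided upper-tail hypergeometric probability ``P[X >= k]`` for an
    overlap of *k* between a query of size *n* and a set of size *K* drawn
    from a universe of size *N*.  Accepts scalars or equal-shape arrays."""
    k_arr = np.asarray(k)
    out = np.where(k_arr <= 0, 1.0, stats.hypergeom.sf(k_arr - 1, N, K, n))
    return float(out) if out.ndim == 0 else out


def _odds_ratio(k: int, N: int, K: int, n: int) -> float:
    """Sample odds ratio of the 2x2 overlap table, with a Haldane 0.5
    correction applied only when a zero cell would leave it undefined."""
    a, b, c, d = k, n - k, K - k, N - K - n + k
    if b == 0 or c == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float((a * d) / (b * c))


def combined_score(p_fisher: float, z: float) -> float:
    """Enrichr-convention combined score ``c = -ln(p) * z``."""
    if not 0.0 < p_fisher <= 1.0:
        raise ValueError("p_fisher must lie in (0, 1]")
    return float(-np.log(p_fisher) * z)


def _overlap_zscore(k: int, N: int, K: int, n: int) -> float:
    """Standardised deviation of the overlap from its hypergeometric
    expectation ``nK/N``; 0 when the variance degenerates."""
    expect = n * K / N
    var = n * (K / N) * (1 - K / N) * (N - n) / (N - 1) if N > 1 else 0.0
    if var <= 0.0:
        return 0.0
    return float((k - expect) / np.sqrt(var))


def adjust_pvalues(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to <= 1."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr
    if np.any((arr < 0) | (arr > 1) | ~np.isfinite(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def fisher_enrich(
    query, library: GeneSetLibrary, universe=None
) -> list[OraRecord]:
    """Over-representation of *query* in every library set.

    Query symbols are case-folded; symbols outside the universe are dropped
    with a warning stating how many.  Library sets are intersected with the
    universe before building each 2x2 table.  Records are returned in
    library order; adjusted p-values are BH across the library's terms.
    """
    qry = list(dict.fromkeys(str(g).strip().upper() for g in query))
    if universe is None:
        uni = library.all_genes()
    else:
        uni = {str(g).strip().upper() for g in universe}
    if not uni:
        raise ValueError("universe is empty")
    dropped = [g for g in qry if g not in uni]
    if dropped:
        warnings.warn(
            f"{len(dropped)} query gene(s) absent from the universe were dropped",
            UserWarning,
            stacklevel=2,
        )
    qset = {g for g in qry if g in uni}
    if not qset:
        raise ValueError("query is empty after intersecting with the universe")
    N, n = len(uni), len(qset)
    if N < n:
        raise ValueError("universe smaller than query")
    records = []
    for gs in library:
        members = [g for g in gs.members if g in uni]
        K = len(members)
        overlap = tuple(g for g in members if g in qset)
        k = len(overlap)
        p = hypergeom_pvalue(k, N, K, n)
        z = _overlap_zscore(k, N, K, n)
        records.append(
            OraRecord(
                set_name=gs.name,
                overlap_k=k,
                set_size_K=K,
                query_size_n=n,
                universe_N=N,
                p_fisher=p,
                p_adjusted=np.nan,
                odds_ratio=_odds_ratio(k, N, K, n) if K > 0 else 0.0,
                combined_score=combined_score(p, z),
                pct_query_in_set=100.0 * k / n,
                overlap_genes=overlap,
            )
        )
    adjusted = adjust_pvalues([r.p_fisher for r in records])
    for rec, padj in zip(records, adjusted):
        rec.p_adjusted = float(padj)
    return records


def ora_frame(records: list[OraRecord]) -> pd.DataFrame:
    """Tabulate ORA records, sorted by Fisher p ascending (ties by term)."""
    frame = pd.DataFrame(
        [
            {
                "Term": r.set_name,
                "Overlap": f"{r.overlap_k}/{r.set_size_K}",
                "P-value": r.p_fisher,
                "Adjusted P-value": r.p_adjusted,
                "Odds Ratio": r.odds_ratio,
                "Combined Score": r.combined_score,
                "% Query In Set": r.pct_query_in_set,
                "Genes": ";".join(r.overlap_genes),
            }
            for r in records
        ]
    )
    if len(frame):
        frame = frame.sort_values(["P-value", "Term"]).reset_index(drop=True)
    return frame
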