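"""Weighted Kolmogorov-Smirnov running-sum enrichment statistic with
permutation null distributions.

The enrichment score (ES) of a gene set against a ranked gene list is the
signed maximum deviation from zero of a running sum that, walking down the
list, increments by the normalised weight ``|score|^w`` at set members and
decrements by ``1/(N - N_hits)`` at non-members.  With ``w = 0`` this is the
classic (signed) two-sample Kolmogorov-Smirnov supremum between the member
and non-member rank ECDFs; ``w = 1`` is the conventional weighted form.

Two permutation nulls are provided:

* ``gene_set`` — set membership is reassigned to uniform random same-size
  gene subsets while the ranking stays fixed (equivalent, under
  exchangeability, to permuting gene labels); the standard pre-ranked null.
* ``phenotype`` — sample class labels are shuffled preserving class sizes
  and the ranking metric is recomputed per permutation, so the null carries
  the inter-gene correlation of the expression matrix.

From the null, each set gets an empirical p-value (add-one smoothed,
conditioned on the sign of its ES), a normalised enrichment score
(NES = ES / mean same-sign null |ES|) and a GSEA-style FDR q-value
(ratio of null to observed tail fractions at its NES, clipped to [0, 1]
with monotonicity enforced).
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import ExpressionDataset, GeneSetLibrary, RankedList
from .ranking import MetricSpec, metric_scores, score_genes

__all__ = [
    "EnrichmentParams",
    "RunningSum",
    "NullDistribution",
    "EnrichmentRecord",
    "EnrichmentResult",
    "running_enrichment",
    "build_null",
    "empirical_pvalue",
    "normalize_es",
    "fdr_qvalues",
    "leading_edge",
    "run_prerank",
    "run_gsea",
]

_CHUNK_ELEMS = 20_000_000  # permutation matrices are processed in chunks of this many cells


@dataclass(frozen=True)
class EnrichmentParams:
    """Parameters of a GSEA run.

    ``n_permutations`` defaults to 1000 null permutations per gene set.
    ``weight_exponent`` is the exponent on |ranking score| used to weight
    member increments (0 gives the unweighted KS statistic).  Sets whose
    matched size falls outside ``[min_set_size, max_set_size]`` are skipped.
    """

    weight_exponent: float = 1.0
    n_permutations: int = 1000
    permutation_type: str = "gene_set"
    min_set_size: int = 15
    max_set_size: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weight_exponent < 0 or not np.isfinite(self.weight_exponent):
            raise ValueError("weight_exponent must be finite and >= 0")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.permutation_type not in ("gene_set", "phenotype"):
            raise ValueError("permutation_type must be 'gene_set' or 'phenotype'")
        if self.min_set_size > self.max_set_size:
            raise ValueError("min_set_size must be <= max_set_size")


@dataclass
class RunningSum:
    """The running enrichment curve of one gene set on one ranked list.

    ``curve[i]`` is the running sum after rank position ``i + 1``; positions
    are 1-based throughout.  ``es == curve[peak_position - 1]`` and ``|es|``
    is the maximum of ``|curve|``.
    """

    curve: np.ndarray
    hit_positions: np.ndarray
    es: float
    peak_position: int


@dataclass
class NullDistribution:
    """Per-set permutation null ES vectors; reproducible from ``seed``."""

    per_set_es: dict[str, np.ndarray]
    permutation_type: str
    seed: int


@dataclass
class EnrichmentRecord:
    set_name: str
    matched_size: int
    set_size: int
    es: float
    nes: float
    p_empirical: float
    fdr_q: float
    leading_edge: tuple[str, ...]
    running: RunningSum = field(repr=False)


@dataclass
class EnrichmentResult:
    """Full output of :func:`run_gsea` / :func:`run_prerank`."""

    records: list[EnrichmentRecord]
    skipped: list[tuple[str, int, str]]  # (set name, matched size, reason)
    params: EnrichmentParams
    null: NullDistribution = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Result table sorted by NES descending (NaN NES last)."""
        rows = [
            {
                "Term": r.set_name,
                "ES": r.es,
                "NES": r.nes,
                "p-val": r.p_empirical,
                "FDR q-val": r.fdr_q,
                "matched_size": r.matched_size,
                "set_size": r.set_size,
                "leading_edge": ",".join(r.leading_edge),
            }
            for r in self.records
        ]
        frame = pd.DataFrame(rows)
        if len(frame):
            frame = frame.sort_values(
                ["NES", "Term"], ascending=[False, True], na_position="last"
            ).reset_index(drop=True)
        return frame

    def __getitem__(self, set_name: str) -> EnrichmentRecord:
        for r in self.records:
            if r.set_name == set_name:
                return r
        raise KeyError(set_name)


# ---------------------------------------------------------------------------
# Core running sum
# ---------------------------------------------------------------------------

def _abs_pow(scores: np.ndarray, weight_exponent: float) -> np.ndarray:
    if weight_exponent == 0.0:
        return np.ones_like(scores)  # |s|^0 := 1 for every gene, including s == 0
    if weight_exponent == 1.0:
        return np.abs(scores)
    return np.abs(scores) ** weight_exponent


#: tolerance on comparing the positive and negative curve extremes; exact
#: mathematical ties (which the decrement lattice does produce) must resolve
#: identically in every code path despite differing float arithmetic
_TIE_TOL = 1e-12


def _pick_extreme(curve_max: float, curve_min: float) -> bool:
    """True if the positive extreme wins; ties (within 1e-12) go positive."""
    return curve_max >= -curve_min - _TIE_TOL


def running_enrichment(
    ranked: RankedList, members, weight_exponent: float = 1.0
) -> RunningSum:
    """Compute the full running-sum curve and ES of one gene set.

    *members* may be a :class:`~gseatk.io_formats.GeneSet` or any iterable
    of gene symbols; symbols absent from the ranked list are ignored.  The
    matched members must be a non-empty strict subset of the ranked genes.
    """
    symbols = getattr(members, "members", members)
    member_set = {str(s).strip().upper() for s in symbols}
    mask = np.isin(ranked.genes, np.asarray(sorted(member_set)))
    n_total = len(ranked)
    n_hits = int(mask.sum())
    if n_hits == 0:
        raise ValueError("set not represented in the ranked list")
    if n_hits == n_total:
        raise ValueError(
            "set covers every ranked gene; the non-member decrement is undefined"
        )
    weights = _abs_pow(ranked.scores, weight_exponent)
    hit_w = np.where(mask, weights, 0.0)
    sum_w = hit_w.sum()
    if sum_w == 0.0:
        warnings.warn(
            "all member scores are zero under this weight; falling back to "
            "uniform (unweighted) increments",
            RuntimeWarning,
            stacklevel=2,
        )
        hit_w = mask.astype(float)
        sum_w = float(n_hits)
    curve = np.cumsum(hit_w) / sum_w - np.cumsum(~mask) / (n_total - n_hits)
    cmax, cmin = float(curve.max()), float(curve.min())
    if _pick_extreme(cmax, cmin):
        es, peak = cmax, int(np.argmax(curve)) + 1
    else:
        es, peak = cmin, int(np.argmin(curve)) + 1
    return RunningSum(
        curve=curve,
        hit_positions=np.flatnonzero(mask) + 1,
        es=es,
        peak_position=peak,
    )


def _es_from_hits(abs_pow: np.ndarray, hits: np.ndarray, n_total: int) -> np.ndarray:
    """ES values for a batch of hit-position rows without building full curves.

    ``hits`` is ``(n_rows, m)`` of 0-based rank positions, each row sorted
    ascending.  Relies on the curve being piecewise monotone between hits:
    positive extremes occur just after a hit, negative extremes just before
    one, so only ``2 m`` candidate values per row need checking.
    """
    n_rows, m = hits.shape
    w = abs_pow[hits]
    sum_w = w.sum(axis=1, keepdims=True)
    degenerate = sum_w[:, 0] == 0.0
    if degenerate.any():
        w = np.where(degenerate[:, None], 1.0, w)
        sum_w = np.where(degenerate[:, None], float(m), sum_w)
    inc = w / sum_w
    cum_inc = np.cumsum(inc, axis=1)
    dec = 1.0 / (n_total - m)
    j = np.arange(1, m + 1)
    before = (cum_inc - inc) - dec * (hits + 1 - j)  # value at position p_j - 1
    after = before + inc                              # value at position p_j
    curve_max = after.max(axis=1)
    curve_min = np.minimum(before.min(axis=1), 0.0)
    return np.where(curve_max >= -curve_min - _TIE_TOL, curve_max, curve_min)


# ---------------------------------------------------------------------------
# Null distributions
# ---------------------------------------------------------------------------

def _set_seed_sequence(seed: int, set_name: str) -> np.random.SeedSequence:
    """Per-set RNG stream keyed by a stable hash of the set name, so library
    order never changes any set's null."""
    digest = hashlib.sha256(set_name.encode("utf-8")).digest()
    return np.random.SeedSequence([int(seed), int.from_bytes(digest[:8], "big")])


def _null_es_gene_set(
    abs_pow: np.ndarray, matched_size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Gene-permutation null: ES of ``n_perm`` uniform random subsets of size
    ``matched_size`` against the fixed score profile."""
    n_total = len(abs_pow)
    out = np.empty(n_perm)
    chunk = max(1, _CHUNK_ELEMS // n_total)
    done = 0
    while done < n_perm:
        size = min(chunk, n_perm - done)
        keys = rng.random((size, n_total))
        hits = np.argpartition(keys, matched_size - 1, axis=1)[:, :matched_size]
        hits.sort(axis=1)
        out[done : done + size] = _es_from_hits(abs_pow, hits, n_total)
        done += size
    return out


def _null_es_phenotype(
    matrix: np.ndarray,
    lex_rank: np.ndarray,
    mask_a: np.ndarray,
    spec: MetricSpec,
    member_indices: list[np.ndarray],
    params: EnrichmentParams,
) -> np.ndarray:
    """Phenotype-permutation null: shuffle sample labels preserving class
    sizes, recompute the ranking metric, re-rank, and rescore every set.

    ``member_indices`` holds, per set, the row indices (into *matrix*) of its
    matched members.  Returns an ``(n_sets, n_perm)`` matrix.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed)]))
    n_genes, n_samples = matrix.shape
    n_a = int(mask_a.sum())
    null = np.empty((len(member_indices), params.n_permutations))
    for t in range(params.n_permutations):
        perm = rng.permutation(n_samples)
        shuffled = np.zeros(n_samples, dtype=bool)
        shuffled[perm[:n_a]] = True
        scores = metric_scores(matrix, shuffled, spec)
        order = np.lexsort((lex_rank, -scores))
        inv = np.empty(n_genes, dtype=np.int64)
        inv[order] = np.arange(n_genes)
        abs_pow = _abs_pow(scores[order], params.weight_exponent)
        for s, midx in enumerate(member_indices):
            hits = np.sort(inv[midx])
            null[s, t] = _es_from_hits(abs_pow, hits[None, :], n_genes)[0]
    return null


def build_null(
    data,
    library: GeneSetLibrary,
    params: EnrichmentParams,
    metric: MetricSpec | None = None,
) -> NullDistribution:
    """Build the permutation null ES distribution for every applicable set.

    *data* is a :class:`RankedList` for ``permutation_type='gene_set'`` or a
    two-class :class:`ExpressionDataset` for ``'phenotype'``.  Sets with an
    empty or complete intersection with the ranked genes are omitted.  The
    same seed always regenerates identical values.
    """
    if params.permutation_type == "gene_set":
        if not isinstance(data, RankedList):
            raise TypeError("gene_set permutation requires a RankedList")
        ranked_genes = set(data.genes)
        abs_pow = _abs_pow(data.scores, params.weight_exponent)
        per_set: dict[str, np.ndarray] = {}
        for gs in library:
            matched = sum(1 for g in gs.members if g in ranked_genes)
            if matched == 0 or matched == len(data):
                continue
            rng = np.random.default_rng(_set_seed_sequence(params.seed, gs.name))
            per_set[gs.name] = _null_es_gene_set(
                abs_pow, matched, params.n_permutations, rng
            )
        return NullDistribution(per_set, "gene_set", params.seed)

    if not isinstance(data, ExpressionDataset) or data.phenotypes is None:
        raise ValueError("phenotype permutation requires a dataset with phenotypes")
    metric = metric or MetricSpec()
    gene_index = {g: i for i, g in enumerate(data.gene_ids)}
    names, member_indices = [], []
    for gs in library:
        idx = np.asarray([gene_index[g] for g in gs.members if g in gene_index], dtype=np.int64)
        if idx.size == 0 or idx.size == data.n_genes:
            continue
        names.append(gs.name)
        member_indices.append(idx)
    lex_rank = np.argsort(np.argsort(np.asarray(data.gene_ids, dtype=str)))
    null = _null_es_phenotype(
        data.values.to_numpy(dtype=float), lex_rank, data.class_mask(),
        metric, member_indices, params,
    )
    return NullDistribution(dict(zip(names, null)), "phenotype", params.seed)


# ---------------------------------------------------------------------------
# Null summaries: p, NES, FDR q
# ---------------------------------------------------------------------------

def empirical_pvalue(es: float, null_vector: np.ndarray) -> float:
    """Add-one smoothed empirical p-value against same-sign null values.

    ``p = (1 + #{x in S : |x| >= |es|}) / (1 + |S|)`` with
    ``S = {x in null : sign(x) == sign(es)}``; an ES of exactly 0 gets
    p = 1 by convention, as does an empty same-sign null.
    """
    null = np.asarray(null_vector, dtype=float)
    if null.size == 0:
        raise ValueError("null vector is empty")
    if es == 0.0:
        return 1.0
    same = null[null > 0.0] if es > 0 else null[null < 0.0]
    return (1 + int(np.count_nonzero(np.abs(same) >= abs(es)))) / (1 + same.size)


def normalize_es(es: float, null_vector: np.ndarray) -> float:
    """NES = ES / mean(|x|) over same-sign null values; NaN (with a warning)
    when no same-sign null value exists."""
    null = np.asarray(null_vector, dtype=float)
    if null.size == 0:
        raise ValueError("null vector is empty")
    if es == 0.0:
        return 0.0
    same = null[null > 0.0] if es > 0 else null[null < 0.0]
    if same.size == 0:
        warnings.warn(
            "no same-sign null ES values; NES undefined", RuntimeWarning, stacklevel=2
        )
        return float("nan")
    return float(es / np.mean(np.abs(same)))


def _normalize_null(null_vector: np.ndarray) -> np.ndarray:
    """Normalise a null ES vector by its own same-sign mean magnitudes, as
    needed for the pooled-null FDR estimate."""
    null = np.asarray(null_vector, dtype=float)
    out = np.zeros_like(null)
    pos, neg = null > 0.0, null < 0.0
    if pos.any():
        out[pos] = null[pos] / np.mean(null[pos])
    if neg.any():
        out[neg] = null[neg] / np.mean(np.abs(null[neg]))
    return out


def fdr_qvalues(observed_nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """GSEA-style FDR q-values from observed NES and pooled normalised null NES.

    For a set with NES* >= 0, ``q_raw = P(null NES >= NES*) / P(observed NES
    >= NES*)`` over the non-negative pools (mirrored with <= for negative
    NES*), clipped to [0, 1].  Monotonicity is then enforced: each set's q is
    the minimum raw q over all same-sign sets at or below its extremity, so
    q never decreases as |NES| shrinks.  NaN NES yields NaN q.
    """
    obs = np.asarray(observed_nes, dtype=float)
    null = np.asarray(null_nes, dtype=float).ravel()
    null = null[np.isfinite(null)]
    if obs.size == 0 or null.size == 0:
        raise ValueError("observed and null NES must be non-empty")
    q = np.full(obs.shape, np.nan)
    for positive in (True, False):
        if positive:
            idx = np.flatnonzero(np.isfinite(obs) & (obs >= 0))
            pool = null[null >= 0]
        else:
            idx = np.flatnonzero(np.isfinite(obs) & (obs < 0))
            pool = null[null < 0]
        if idx.size == 0:
            continue
        vals = obs[idx]
        if positive:
            frac_null = (
                np.array([np.count_nonzero(pool >= v) for v in vals]) / pool.size
                if pool.size else np.zeros(vals.size)
            )
            frac_obs = np.array([np.count_nonzero(vals >= v) for v in vals]) / vals.size
            order = np.argsort(-vals, kind="stable")  # most extreme first
        else:
            frac_null = (
                np.array([np.count_nonzero(pool <= v) for v in vals]) / pool.size
                if pool.size else np.zeros(vals.size)
            )
            frac_obs = np.array([np.count_nonzero(vals <= v) for v in vals]) / vals.size
            order = np.argsort(vals, kind="stable")
        raw = np.clip(frac_null / frac_obs, 0.0, 1.0)
        mono = raw[order][::-1]
        mono = np.minimum.accumulate(mono)[::-1]
        q_side = np.empty(vals.size)
        q_side[order] = mono
        q[idx] = q_side
    return q


def leading_edge(running: RunningSum, ranked: RankedList) -> tuple[str, ...]:
    """Member genes at or before the ES peak (positive ES) or at or after it
    (negative ES, mirror convention), in rank order."""
    if running.es >= 0:
        pos = running.hit_positions[running.hit_positions <= running.peak_position]
    else:
        pos = running.hit_positions[running.hit_positions >= running.peak_position]
    return tuple(ranked.genes[p - 1] for p in pos)


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------

def _filter_sets(
    library: GeneSetLibrary, ranked_genes: set[str], params: EnrichmentParams
) -> tuple[list, list[tuple[str, int, str]]]:
    kept, skipped = [], []
    for gs in library:
        matched = sum(1 for g in gs.members if g in ranked_genes)
        if matched < params.min_set_size:
            skipped.append((gs.name, matched, f"matched size {matched} < min {params.min_set_size}"))
        elif matched > params.max_set_size:
            skipped.append((gs.name, matched, f"matched size {matched} > max {params.max_set_size}"))
        elif matched == len(ranked_genes):
            skipped.append((gs.name, matched, "set covers every ranked gene"))
        else:
            kept.append(gs)
    return kept, skipped


def _assemble(
    ranked: RankedList,
    kept,
    skipped,
    null: NullDistribution,
    params: EnrichmentParams,
) -> EnrichmentResult:
    records = []
    observed_nes = []
    for gs in kept:
        run = running_enrichment(ranked, gs, params.weight_exponent)
        nv = null.per_set_es[gs.name]
        nes = normalize_es(run.es, nv)
        records.append(
            EnrichmentRecord(
                set_name=gs.name,
                matched_size=len(run.hit_positions),
                set_size=len(gs),
                es=run.es,
                nes=nes,
                p_empirical=empirical_pvalue(run.es, nv),
                fdr_q=np.nan,
                leading_edge=leading_edge(run, ranked),
                running=run,
            )
        )
        observed_nes.append(nes)
    pooled = np.concatenate([_normalize_null(null.per_set_es[gs.name]) for gs in kept])
    qs = fdr_qvalues(np.asarray(observed_nes), pooled)
    for rec, q in zip(records, qs):
        rec.fdr_q = float(q)
    return EnrichmentResult(records=records, skipped=skipped, params=params, null=null)


def run_prerank(
    ranked: RankedList, library: GeneSetLibrary, params: EnrichmentParams | None = None
) -> EnrichmentResult:
    """Pre-ranked GSEA: gene-permutation null against a fixed ranked list."""
    params = params or EnrichmentParams()
    if params.permutation_type != "gene_set":
        params = dataclasses.replace(params, permutation_type="gene_set")
    if len(library) == 0:
        raise ValueError("gene set library is empty")
    kept, skipped = _filter_sets(library, set(ranked.genes), params)
    if not kept:
        raise ValueError(
            "all gene sets were filtered out; adjust min_set_size/max_set_size "
            f"(currently {params.min_set_size}..{params.max_set_size})"
        )
    sub = GeneSetLibrary(kept)
    null = build_null(ranked, sub, params)
    return _assemble(ranked, kept, skipped, null, params)


def run_gsea(
    dataset: ExpressionDataset,
    library: GeneSetLibrary,
    params: EnrichmentParams | None = None,
    metric: MetricSpec | None = None,
) -> EnrichmentResult:
    """Two-class GSEA: rank genes by a differential metric, then score the
    library against a phenotype-permutation (default) or gene-permutation null."""
    params = params or EnrichmentParams(permutation_type="phenotype")
    metric = metric or MetricSpec()
    if len(library) == 0:
        raise ValueError("gene set library is empty")
    ranked = score_genes(dataset, metric)
    if params.permutation_type == "gene_set":
        return run_prerank(ranked, library, params)
    kept, skipped = _filter_sets(library, set(ranked.genes), params)
    if not kept:
        raise ValueError(
            "all gene sets were filtered out; adjust min_set_size/max_set_size "
            f"(currently {params.min_set_size}..{params.max_set_size})"
        )
    null = build_null(dataset, GeneSetLibrary(kept), params, metric=metric)
    return _assemble(ranked, kept, skipped, null, params)
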