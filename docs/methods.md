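# Methods

This note records the statistical definitions gseatk implements, the
numerical and design choices made where conventions diverge, what the
synthetic generators do and do not emulate, and known limitations.

## Running-sum enrichment statistic

For a ranked list of `N` genes with scores `r_1 ≥ r_2 ≥ … ≥ r_N` and a gene
set with `m` matched members (`0 < m < N`), the running sum after position
`i` is

```
C(i) = Σ_{j ≤ i, j ∈ S} |r_j|^w / Σ_{j ∈ S} |r_j|^w  −  #{j ≤ i, j ∉ S} / (N − m)
```

The ES is the value of `C` with maximal absolute value; the peak position
is reported 1-based. `w` defaults to 1.0; with `w = 0` every gene carries
unit weight (`|r|^0 := 1`, including `r = 0`) and the statistic is exactly
the signed two-sample KS supremum between member and non-member rank ECDFs.

Numerical choices:

- `C(i)` is computed as `cumsum(hit weights)/total − cumsum(miss
  indicator)/(N − m)` — one rounding per term — so the weight-0 curve is
  bit-identical to a direct ECDF-difference computation.
- **Extreme tie-break.** The positive and negative extremes of `C` can tie
  *exactly* (the miss decrement puts curve values on a rational lattice).
  The positive extreme is chosen whenever `max C ≥ −min C − 1e-12`; the
  tolerance makes every code path (full curve, vectorised null scorer, and
  any reimplementation following this rule) resolve mathematically tied
  cases identically despite differing float arithmetic. In tied cases
  `|ES|` may understate `max |C|` by at most 1e-12.
- If all member weights are zero under `w > 0` (every member has score 0),
  the increment degenerates; the implementation falls back to uniform
  increments with a warning rather than failing or returning NaN.
- Null ES values are computed without materialising curves: between hits
  the curve is linear and decreasing, so only the 2m values just before
  and just after each hit are extremum candidates.

Ranked lists are sorted descending with ties broken by ascending
lexicographic gene symbol — everywhere (RNK input, metric ranking,
within-sample ssGSEA ranking) — so every ordering is total and
reproducible across platforms. Gene symbols are upper-cased on load; all
symbol matching is case-insensitive.

## Ranking metrics

For two classes A (first-named in the CLS header) and B:

| metric | formula | notes |
|---|---|---|
| signal_to_noise (default) | `(μ_A − μ_B)/(σ_A + σ_B)` | each σ floored at `max(0.2·|μ|, 1e-8)` |
| t_test | `(μ_A − μ_B)/√(σ_A²/n_A + σ_B²/n_B)` | denominator floored at 1e-8; needs ≥ 3 per class |
| log2_ratio_of_classes | `log2(μ_A/μ_B)` | requires strictly positive class means |
| difference_of_classes | `μ_A − μ_B` | |

Standard deviations use `ddof = 1`. The relative sd floor (default 0.2)
prevents near-constant genes from dominating the ranking; genes with zero
mean difference score exactly 0 under the signed metrics. signal_to_noise
is the default because it is the convention users of two-class GSEA
expect; the floor fraction is exposed (`--sd-floor`).

## Permutation nulls

- **gene_set** (pre-ranked): each permutation draws a uniform random gene
  subset of the same matched size against the fixed score profile. This is
  equivalent, under exchangeability, to permuting gene labels, and is the
  standard pre-ranked null.
- **phenotype**: each permutation shuffles the sample labels preserving
  class sizes, *recomputes the ranking metric*, re-ranks, and rescores
  every set. Recomputing the metric (rather than merely relabelling) is
  essential: permuting samples invalidates the ranking itself, and the
  resulting null preserves inter-gene correlation.

`n_permutations` defaults to 1000. Randomness derives from a single root
seed: in gene_set mode each set gets its own stream keyed by
`SeedSequence([seed, sha256(set_name)[:8]])`, so results are invariant to
library order and to which other sets are present; in phenotype mode one
stream drives the label shuffles, which are shared by all sets (so again
set order is irrelevant). Identical seeds reproduce null distributions
bit-for-bit, and `--threads` can never change results.

## p-values, NES, FDR

- **Empirical p** uses only same-sign null values
  `S = {x : sign(x) = sign(ES)}` with add-one smoothing:
  `p = (1 + #{x ∈ S : |x| ≥ |ES|}) / (1 + |S|)`. A finite-permutation p of
  exactly 0 is an artifact, so it can never be reported; `ES = 0` and an
  empty same-sign null both give p = 1 (the latter with a warning).
- **NES** = ES / mean(|x|) over same-sign nulls; undefined (NaN, warned)
  when no same-sign null value exists.
- **FDR q** (GSEA convention): null ES vectors are normalised per set by
  their own same-sign mean magnitudes and pooled; for a set with NES* ≥ 0,
  `q_raw = P(null NES ≥ NES*) / P(observed NES ≥ NES*)` over the
  non-negative pools (mirrored for negative NES*), clipped to [0, 1].
  Monotonicity is then enforced q-value-style: each set's q is the minimum
  raw q over same-sign sets at or below its extremity, so q never
  decreases as |NES| shrinks. This is an FDR estimate, not a p-value
  adjustment; q = 0 simply means no pooled null value was as extreme.

Sets are filtered to matched sizes within `[min_set_size, max_set_size]`
(defaults 15 and 500, the desktop convention) before any statistic is
computed; filtered sets are listed in a skipped report rather than
silently dropped.

## ssGSEA

Within one sample, genes are ordered by descending value (ties by symbol);
the gene at 1-based position `i` has rank weight `(N − i + 1)^α` if it is
a member, and the score is the summed difference

```
ES = Σ_i [ P_in(i) − P_out(i) ]
```

with `P_in` the cumulative member weight normalised by the total member
weight and `P_out` the cumulative non-member fraction. Two deliberate
choices where published implementations disagree: the *integrated* form
(not the supremum) — this is what "ssGSEA" names in the literature — and
rank-index weights rather than raw expression values, which makes scores
exactly invariant to any strictly increasing per-sample transform
(documented here because implementations differ). `α` defaults to 0.25.
Cross-sample normalisation divides the finished set × sample matrix by its
global `max − min`; a zero range (degenerate single-score case) skips
normalisation with a warning. Raw scores depend only on their own column;
only the normalisation step couples samples.

## Over-representation analysis

The 2×2 table for a set (intersected with the universe first) is
`(k, n − k, K − k, N − K − n + k)`. The p-value is the exact hypergeometric
upper tail `P[X ≥ k]` (one-sided: ORA asks for enrichment; depletion shows
only as an odds ratio < 1). BH adjustment is applied across the terms of
one library; multiple libraries are adjusted independently. The odds ratio
uses the Haldane 0.5 correction only when a zero cell would make it
undefined (`n = k` or `K = k`); `k = 0` gives an odds ratio of exactly 0
with p = 1. The combined score is `−ln(p)·z` with
`z = (k − nK/N)/σ_hypergeom` — the standardised overlap deviation. This is
a *local surrogate* for the Enrichr service's rank-deviation z (which
depends on precomputed background rankings hosted server-side): Fisher
p-values match Enrichr's, combined scores are comparable within a run but
not numerically identical to the web service's. The default universe is
the union of all library genes, keeping the analysis self-contained; a
custom background file may be supplied.

## Synthetic data generators

The generators emulate the four input kinds with the simplest model whose
downstream behaviour is analytically predictable: a gene universe
`G00000…`, libraries of uniform random sets (sizes uniform over a range),
and Gaussian signal — `Normal(0, σ²)` background with planted sets shifted
by `+effect·σ` (in class A only, for expression; directly on scores, for
ranked lists). Defaults: 1000-gene universe, 20 sets of 15–50 genes,
effect 1.0, σ = 1.0, 10 samples per class. Planted sets may overlap others
by chance, as in real libraries; no de-overlap is performed. All
generators are pure functions of (spec, seed).

What this does *not* emulate: count-distributed (negative binomial) or
zero-inflated single-cell data, correlated co-expression modules,
library-size effects, or curated set structure. Passing tests therefore
demonstrate correctness of the statistics and calibration under
exchangeable Gaussian nulls — not robustness to the messiness of real
expression data, where the phenotype-permutation null exists precisely to
absorb correlation the gene-subset null ignores.

## Verification problem sizes

The acceptance checks run at the following sizes, chosen to make each
property decisive while keeping the full suite around a minute: ES oracle
equivalence on 1000 random instances (lists ≤ 100 genes, sets ≤ 20,
weights 0–2); KS reduction on 100 instances (exact equality); null
calibration on a 2000-gene universe, 200 null sets × 1000 permutations
(tail fraction at 0.05 within [0.03, 0.07] and KS uniformity below the 1%
critical value 1.63/√200); planted recovery with a 30-gene set at effect
2.0 in a 5000-gene universe, 50 sets, 1000 permutations, 20 replicates;
Fisher exactness on all 635 375 tables with N ≤ 60 against integer
enumeration; ssGSEA invariance and oracle agreement on 100 samples;
leading-edge definition on 1000 instances; byte-level determinism across
repeated and multi-thread CLI runs. The phenotype-permutation planted
recovery in the unit suite uses a scaled design (500 genes, 12 sets,
25-gene planted set, effect 1.0, 10 + 10 samples, 200 permutations, 6
replicates) — ample power for a set-level shift of that size.

## Known limitations

- Two-class designs only; no continuous-phenotype correlation metrics or
  multi-class extensions.
- Execution is single-threaded; `--threads` exists so that scripted
  pipelines keep a stable interface, and results are defined to be
  thread-count invariant.
- ssGSEA reports scores only (no per-sample permutation tests, which the
  methodology does not define).
- No network features: gene set libraries must be local GMT files, and no
  identifier conversion is provided.
- p-values are bounded below by `1/(1 + n_permutations)`; users needing
  smaller p must raise `n_permutations` (cost is linear) — no
  tail-fitting refinement is implemented.
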