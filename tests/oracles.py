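"""Independent, deliberately naive reference implementations used to verify
the package's optimised code paths.  Everything here is written as plain
loops from the definitions, sharing no code with gseatk internals.
"""

from __future__ import annotations

import math


def naive_running_es(genes, scores, members, weight):
    """Single-pass running-sum enrichment from the definition.

    Walk the ranked list top to bottom; at a member gene add its normalised
    weight |score|^w / sum(|score|^w over members), at a non-member subtract
    1/(N - n_members).  Return (curve, es, peak 1-based).  When the positive
    and negative extremes tie (within 1e-12) the positive one is reported.
    """
    member_set = {m.upper() for m in members}
    is_hit = [g.upper() in member_set for g in genes]
    n = len(genes)
    n_hits = sum(is_hit)
    assert 0 < n_hits < n
    if weight == 0:
        hit_w = [1.0 for _ in genes]
    else:
        hit_w = [abs(s) ** weight for s in scores]
    total = sum(w for w, h in zip(hit_w, is_hit) if h)
    if total == 0:
        hit_w = [1.0 for _ in genes]
        total = float(n_hits)
    curve = []
    hit_acc = 0.0
    miss_count = 0
    for i in range(n):
        if is_hit[i]:
            hit_acc += hit_w[i]
        else:
            miss_count += 1
        curve.append(hit_acc / total - miss_count / (n - n_hits))
    cmax, cmin = max(curve), min(curve)
    if cmax >= -cmin - 1e-12:
        es, peak = cmax, curve.index(cmax) + 1
    else:
        es, peak = cmin, curve.index(cmin) + 1
    return curve, es, peak


def ks_ecdf_es(genes, scores, members):
    """Signed two-sample ECDF supremum between member and non-member rank
    distributions: the weight-0 statistic computed directly from counts."""
    member_set = {m.upper() for m in members}
    is_hit = [g.upper() in member_set for g in genes]
    n, m = len(genes), sum(is_hit)
    assert 0 < m < n
    diffs = []
    hits = misses = 0
    for h in is_hit:
        if h:
            hits += 1
        else:
            misses += 1
        diffs.append(hits / m - misses / (n - m))
    dmax, dmin = max(diffs), min(diffs)
    return dmax if dmax >= -dmin - 1e-12 else dmin


def naive_ssgsea(values, genes, members, alpha):
    """Two-pass integrated-difference ssGSEA score from the definition."""
    member_set = {m.upper() for m in members}
    order = sorted(range(len(genes)), key=lambda i: (-values[i], genes[i].upper()))
    n = len(genes)
    in_flags = [genes[i].upper() in member_set for i in order]
    n_out = n - sum(in_flags)
    # pass 1: total member rank weight; rank weight at position i (1-based)
    # is (n - i + 1)^alpha
    total_in = 0.0
    for pos, flag in enumerate(in_flags, start=1):
        if flag:
            total_in += (n - pos + 1) ** alpha
    # pass 2: accumulate the summed difference
    es = 0.0
    cum_in = 0.0
    cum_out = 0
    for pos, flag in enumerate(in_flags, start=1):
        if flag:
            cum_in += (n - pos + 1) ** alpha
        else:
            cum_out += 1
        es += cum_in / total_in - cum_out / n_out
    return es


def hypergeom_tail(k, N, K, n):
    """Exact upper-tail P[X >= k] by integer enumeration with math.comb."""
    if k <= 0:
        return 1.0
    hi = min(n, K)
    if k > hi:
        return 0.0
    num = sum(math.comb(K, x) * math.comb(N - K, n - x) for x in range(k, hi + 1))
    return num / math.comb(N, n)
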