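"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately written as literal, loop-based transcriptions
of the definitions (per-base boolean unions, all-pairs scans, exhaustive
enumerations, step-by-step algorithm walks) and shares no code with the
package internals it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.stats import norm as _norm


# --- interval algebra -------------------------------------------------------

def per_base_union(intervals, bound=10_000):
    """Union of intervals as per-chrom boolean base arrays -> merged regions."""
    by_chrom = {}
    for iv in intervals:
        arr = by_chrom.setdefault(iv.chrom, np.zeros(bound, dtype=bool))
        arr[iv.start:iv.end] = True
    out = []
    for chrom in sorted(by_chrom):
        arr = by_chrom[chrom]
        i = 0
        while i < bound:
            if arr[i]:
                j = i
                while j < bound and arr[j]:
                    j += 1
                out.append((chrom, i, j))
                i = j
            else:
                i += 1
    return out


def stitch_partition(peaks, distance, bound=100_000):
    """Partition of peak indices via the padded-union rule: pad every peak by
    distance/2 on both sides, take the per-base union, and group peaks whose
    padded intervals fall in the same union component."""
    pad = distance / 2.0
    by_chrom = {}
    for idx, p in enumerate(peaks):
        iv = p.interval
        lo = max(0, int(math.floor(iv.start - pad)))
        hi = min(bound, int(math.ceil(iv.end + pad)))
        by_chrom.setdefault(iv.chrom, []).append((idx, lo, hi))
    groups = []
    for chrom, items in by_chrom.items():
        arr = np.zeros(bound, dtype=bool)
        for _, lo, hi in items:
            arr[lo:hi] = True
        comp = np.full(bound, -1)
        cid = -1
        prev = False
        for b in range(bound):
            if arr[b]:
                if not prev:
                    cid += 1
                comp[b] = cid
            prev = arr[b]
        by_comp = {}
        for idx, lo, hi in items:
            by_comp.setdefault(comp[lo], []).append(idx)
        groups.extend(frozenset(v) for v in by_comp.values())
    return set(groups)


def window_hits(annotation, regions, window):
    """All-pairs distance scan; distance to the closed hull [start, end]."""
    out = {}
    for r in regions:
        hits = []
        for g in annotation:
            if g.chrom != r.chrom:
                continue
            if r.start <= g.tss <= r.end:
                d = 0
            elif g.tss < r.start:
                d = r.start - g.tss
            else:
                d = g.tss - r.end
            if d <= window:
                hits.append(g.gene_id)
        out[(r.chrom, r.start, r.end)] = hits
    return out


def overlapping_pairs(peaks, mask):
    """Indices of peaks sharing >= 1 base with any mask interval."""
    hit = set()
    for i, p in enumerate(peaks):
        for m in mask:
            if p.interval.chrom == m.chrom and \
                    p.interval.start < m.end and m.start < p.interval.end:
                hit.add(i)
    return hit


# --- hockey stick -----------------------------------------------------------

def hockey_scan(signals):
    """Exhaustive scan over all N candidate points of the scaled curve."""
    y = sorted(float(v) for v in signals)
    n = len(y)
    best_i, best_val = None, None
    for i in range(n):
        val = y[i] / y[-1] - i / (n - 1)
        if best_val is None or val < best_val:  # strict: first minimizer wins
            best_i, best_val = i, val
    return y[best_i], best_i + 1


# --- BH / hypergeometric ----------------------------------------------------

def bh_by_hand(pvals):
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [None] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, pvals[i] * m / rank_from_top)
        adj[i] = running_min
    return adj


def hypergeom_enumerate(universe_size, a_size, b_size, k):
    """P[|A ∩ B| >= k] by enumerating every possible B-draw for a fixed A."""
    universe = range(universe_size)
    a = set(range(a_size))
    total = 0
    hits = 0
    for b in itertools.combinations(universe, b_size):
        total += 1
        if len(a & set(b)) >= k:
            hits += 1
    return hits / total


# --- GSVA -------------------------------------------------------------------

def gsva_by_hand(df, set_genes, tau=1.0):
    """Literal step-by-step transcription of the GSVA algorithm:
    Gaussian-kernel CDF -> per-sample ranking -> weighted KS walk ->
    max-positive + max-negative deviation."""
    genes = list(df.index)
    x = df.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    z = np.zeros_like(x)
    for i in range(n_genes):
        h = max(np.std(x[i], ddof=0) / 4.0, 1e-8)
        for j in range(n_samples):
            z[i, j] = np.mean([_norm.cdf((x[i, j] - x[i, k]) / h)
                               for k in range(n_samples)])
    scores = []
    for j in range(n_samples):
        order = sorted(range(n_genes), key=lambda i: (-z[i, j], i))
        rank = {i: pos + 1 for pos, i in enumerate(order)}
        weight = {i: abs(n_genes / 2.0 - rank[i]) ** tau for i in range(n_genes)}
        in_set = {i: genes[i] in set_genes for i in range(n_genes)}
        sum_in = sum(weight[i] for i in range(n_genes) if in_set[i])
        n_out = n_genes - sum(in_set.values())
        v = max_pos = max_neg = 0.0
        for i in order:
            if in_set[i]:
                v += weight[i] / sum_in
            else:
                v -= 1.0 / n_out
            max_pos = max(max_pos, v)
            max_neg = min(max_neg, v)
        scores.append(max_pos + max_neg)
    return np.array(scores)


# --- survival ---------------------------------------------------------------

def km_by_hand(times, events):
    """Product-limit estimate and Greenwood variance at each distinct death time."""
    order = sorted(set(t for t, e in zip(times, events) if e == 1))
    s = 1.0
    gw = 0.0
    out = []
    for t in order:
        n_at_risk = sum(1 for ti in times if ti >= t)
        d = sum(1 for ti, ei in zip(times, events) if ti == t and ei == 1)
        s *= (n_at_risk - d) / n_at_risk
        gw += d / (n_at_risk * (n_at_risk - d)) if n_at_risk > d else float("inf")
        out.append((t, s, s * s * gw))
    return out


def logrank_by_hand(times_a, events_a, times_b, events_b):
    """Event-by-event O-E tabulation with hypergeometric variance."""
    all_times = sorted(set([t for t, e in zip(times_a, events_a) if e]
                           + [t for t, e in zip(times_b, events_b) if e]))
    o_minus_e = 0.0
    var = 0.0
    for t in all_times:
        na = sum(1 for ti in times_a if ti >= t)
        nb = sum(1 for ti in times_b if ti >= t)
        da = sum(1 for ti, ei in zip(times_a, events_a) if ti == t and ei)
        db = sum(1 for ti, ei in zip(times_b, events_b) if ti == t and ei)
        n, d = na + nb, da + db
        if n == 0:
            continue
        e_a = d * na / n
        o_minus_e += da - e_a
        if n > 1:
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    chi2 = o_minus_e ** 2 / var if var > 0 else 0.0
    return chi2


def cox_grid_search(times, events, covariate, lo=-5.0, hi=5.0, tol=1e-8):
    """Maximize the (Breslow) partial likelihood for a single covariate by
    golden-section search; with no ties this equals the exact MLE."""

    def neg_loglik(beta):
        ll = 0.0
        for i, (t, e) in enumerate(zip(times, events)):
            if not e:
                continue
            risk = [j for j, tj in enumerate(times) if tj >= t]
            denom = sum(math.exp(beta * covariate[j]) for j in risk)
            ll += beta * covariate[i] - math.log(denom)
        return -ll

    golden = (math.sqrt(5) - 1) / 2
    a, b = lo, hi
    c = b - golden * (b - a)
    d = a + golden * (b - a)
    while abs(b - a) > tol:
        if neg_loglik(c) < neg_loglik(d):
            b = d
        else:
            a = c
        c = b - golden * (b - a)
        d = a + golden * (b - a)
    return (a + b) / 2


# --- ANOVA ------------------------------------------------------------------

def anova_by_hand(groups):
    """Textbook between/within mean-square F and its p-value."""
    from scipy.stats import f as f_dist
    all_vals = [v for g in groups for v in g]
    n = len(all_vals)
    k = len(groups)
    grand = sum(all_vals) / n
    ss_between = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ss_within = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    ms_b = ss_between / (k - 1)
    ms_w = ss_within / (n - k)
    f = ms_b / ms_w
    return f, float(f_dist.sf(f, k - 1, n - k))


def ranksum_enumerate(a, b):
    """Two-sided exact rank-sum p by enumerating all group assignments
    (untied data only)."""
    pooled = list(a) + list(b)
    na = len(a)

    def rank_sum(idx):
        ranks = {}
        s = sorted(range(len(pooled)), key=lambda i: pooled[i])
        for r, i in enumerate(s):
            ranks[i] = r + 1
        return sum(ranks[i] for i in idx)

    observed = rank_sum(range(na))
    mean = na * (len(pooled) + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), na):
        total += 1
        if abs(rank_sum(combo) - mean) >= abs(observed - mean) - 1e-12:
            count += 1
    return count / total
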