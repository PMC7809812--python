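"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plainly as possible — explicit Python loops,
no vectorization, no reuse of package internals — so that agreement with
the package is meaningful evidence of correctness.
"""

from __future__ import annotations

import math


def brute_group_stats(values, g1_cols, g2_cols, epsilon=0.01):
    """Per-row means, diff and log2 quotient by explicit loops.

    ``values`` is a pandas DataFrame; returns dict row -> (m1, m2, diff, logq)
    or None where a group has <2 non-missing values.
    """
    out = {}
    for probe in values.index:
        groups = []
        for cols in (g1_cols, g2_cols):
            xs = [values.at[probe, c] for c in cols if not math.isnan(values.at[probe, c])]
            groups.append(xs)
        if len(groups[0]) < 2 or len(groups[1]) < 2:
            out[probe] = None
            continue
        m1 = sum(groups[0]) / len(groups[0])
        m2 = sum(groups[1]) / len(groups[1])
        out[probe] = (m1, m2, m1 - m2, math.log2((m1 + epsilon) / (m2 + epsilon)))
    return out


def brute_average_ranks(scores):
    """Average ranks of ``scores`` ascending (1 = smallest), ties averaged."""
    order = sorted(range(len(scores)), key=lambda i: scores[i])
    ranks = [0.0] * len(scores)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and scores[order[j + 1]] == scores[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def brute_top_k(records, k):
    """records: list of (probe_id, combined_rank, rank_p); returns ordered ids."""
    ordered = sorted(records, key=lambda r: (r[1], r[2], str(r[0])))
    return [r[0] for r in ordered[:k]]


def brute_filter(records, min_abs_diff=0.2, alpha=0.05):
    """records: (probe_id, diff, p) -> (hyper ids, hypo ids)."""
    hyper, hypo = [], []
    for pid, diff, p in records:
        if p < alpha and abs(diff) > min_abs_diff:
            (hyper if diff > 0 else hypo).append(pid)
    return hyper, hypo


def brute_promoter_membership(probes, genes):
    """probes: (probe_id, chrom, pos); genes: (gene_id, chrom, strand, tss).

    Returns the set of (probe_id, gene_id) pairs inside the −2000/+500
    strand-mirrored promoter window, endpoints inclusive, lower bound
    clipped at 1.
    """
    pairs = set()
    for pid, pchrom, pos in probes:
        for gid, gchrom, strand, tss in genes:
            if pchrom != gchrom:
                continue
            if strand == "+":
                lo, hi = tss - 2000, tss + 500
            else:
                lo, hi = tss - 500, tss + 2000
            lo = max(lo, 1)
            if lo <= pos <= hi:
                pairs.add((pid, gid))
    return pairs


def brute_km(times, events):
    """Product-limit estimate by explicit risk-set loops.

    Returns list of (event_time, n_at_risk, n_events, survival) for
    distinct event times (where at least one event occurs), ascending.
    """
    data = sorted(zip(times, events))
    out = []
    s = 1.0
    for t in sorted({t for t, e in data if e == 1}):
        n_at_risk = sum(1 for ti, _ in data if ti >= t)
        d = sum(1 for ti, ei in data if ti == t and ei == 1)
        s *= 1.0 - d / n_at_risk
        out.append((t, n_at_risk, d, s))
    return out


def brute_km_median(times, events):
    """Smallest event time with S(t) <= 0.5, or nan."""
    for t, _, _, s in brute_km(times, events):
        if s <= 0.5:
            return t
    return float("nan")


def brute_logrank(times, events, group):
    """Two-group log-rank chi-square by explicit risk-set tabulation.

    Ties handled through the hypergeometric mean/variance at each distinct
    event time.
    """
    levels = []
    for g in group:
        if g not in levels:
            levels.append(g)
    assert len(levels) == 2
    data = list(zip(times, events, group))
    o_minus_e = 0.0
    var = 0.0
    for t in sorted({t for t, e, _ in data if e == 1}):
        n = sum(1 for ti, _, _ in data if ti >= t)
        n1 = sum(1 for ti, _, gi in data if ti >= t and gi == levels[0])
        d = sum(1 for ti, ei, _ in data if ti == t and ei == 1)
        d1 = sum(1 for ti, ei, gi in data if ti == t and ei == 1 and gi == levels[0])
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var if var > 0 else 0.0


def brute_pearson(x, y):
    """Pearson correlation from the raw definition."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def brute_pooled_t(x1, x2):
    """Classical pooled two-sample t and two-sided p (explicit formulas)."""
    from scipy import stats as sps

    n1, n2 = len(x1), len(x2)
    m1, m2 = sum(x1) / n1, sum(x2) / n2
    ss = sum((v - m1) ** 2 for v in x1) + sum((v - m2) ** 2 for v in x2)
    df = n1 + n2 - 2
    s2 = ss / df
    t = (m1 - m2) / math.sqrt(s2 * (1 / n1 + 1 / n2))
    p = 2 * sps.t.sf(abs(t), df)
    return t, p
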