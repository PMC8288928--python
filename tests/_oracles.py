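"""Independent oracles used by the test suite.

Each function re-derives an expected result by brute force or closed form,
sharing no code with the implementation paths it checks.
"""

from __future__ import annotations

import numpy as np


def brute_force_match(records_a, records_b, threshold=0.5, ins_window=1000,
                      ins_min_len_ratio=0.5):
    """All-pairs candidate generation + greedy 1-to-1 matching.

    Returns the set of (id_a, id_b) pairs.  Mirrors the documented matching
    contract (score = min fraction, ties by smaller start then ids) but
    enumerates every pair quadratically.
    """
    candidates = []
    for a in records_a:
        for b in records_b:
            if a.chrom != b.chrom or a.svtype != b.svtype:
                continue
            if a.svtype.value == "INS":
                if abs(a.start - b.start) > ins_window:
                    continue
                lo, hi = sorted((a.length, b.length))
                ratio = lo / hi
                if ratio < ins_min_len_ratio:
                    continue
                candidates.append((a, b, ratio, ratio))
            else:
                inter = min(a.end, b.end) - max(a.start, b.start)
                if inter <= 0:
                    continue
                fa, fb = inter / a.length, inter / b.length
                if fa >= threshold and fb >= threshold:
                    candidates.append((a, b, fa, fb))
    candidates.sort(key=lambda c: (-min(c[2], c[3]),
                                   min(c[0].start, c[1].start),
                                   min(c[0].id, c[1].id),
                                   max(c[0].id, c[1].id)))
    used_a, used_b, pairs = set(), set(), set()
    for a, b, fa, fb in candidates:
        if a.id in used_a or b.id in used_b:
            continue
        used_a.add(a.id)
        used_b.add(b.id)
        pairs.add((a.id, b.id))
    return pairs


def brute_force_bh(pvals):
    """Step-up BH by direct definition: adj_i = min_{j: p_j >= p_i} p_j*m/rank_j,
    computed with an explicit double loop."""
    p = list(pvals)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        val = min(p[order[j]] * m / (j + 1) for j in range(pos, m))
        adj[i] = min(1.0, val)
    return np.array(adj)


def enumerate_placement_overlap(chrom_length, sv_span, element_intervals):
    """Exact probability that a uniformly placed interval of span ``sv_span``
    overlaps >= 1 bp of any element, by enumerating every start."""
    n_hit = 0
    n_total = chrom_length - sv_span + 1
    for s in range(n_total):
        e = s + sv_span
        if any(s < ee and e > es for es, ee in element_intervals):
            n_hit += 1
    return n_hit / n_total


def ols_slope_r2(x, y):
    """Closed-form simple OLS: slope, intercept, R^2, two-sided slope p."""
    from scipy import stats as st

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    sxy = np.sum((x - xm) * (y - ym))
    syy = np.sum((y - ym) ** 2)
    slope = sxy / sxx
    intercept = ym - slope * xm
    ss_res = syy - slope * sxy
    r2 = 1.0 - ss_res / syy
    se = np.sqrt(ss_res / (n - 2) / sxx)
    t = slope / se
    p = 2 * st.t.sf(abs(t), n - 2)
    return slope, intercept, r2, p


def weighted_variance_vst(groups):
    """Direct V_ST from explicit per-group moment arithmetic.

    ``groups`` is a list of (n_i, mean_i, var_i) with population variances.
    """
    ns = np.array([g[0] for g in groups], dtype=float)
    means = np.array([g[1] for g in groups], dtype=float)
    variances = np.array([g[2] for g in groups], dtype=float)
    w = ns / ns.sum()
    v_s = float(np.sum(w * variances))
    grand = float(np.sum(w * means))
    v_t = v_s + float(np.sum(w * (means - grand) ** 2))
    return (v_t - v_s) / v_t
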