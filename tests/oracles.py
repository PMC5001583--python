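"""Independent reference implementations used only to check the package.

These deliberately use naive per-window loops, direct summation and
exhaustive enumeration rather than the vectorized/production code paths.
"""

import itertools
import math

from hmr_transplant.hmr_detection import PeakCallParams, poisson_tail


def poisson_tail_brute(observed: int, lam: float, k_max_extra: int = 400) -> float:
    """P(X >= observed) by direct pmf summation in log space."""
    total = 0.0
    for k in range(observed, observed + k_max_extra):
        total += math.exp(k * math.log(lam) - lam - math.lgamma(k + 1))
    return total


def call_peaks_exhaustive(treatment, control, params: PeakCallParams):
    """Score every sliding window with plain Python; no candidate pre-filter.

    Returns the final merged peak set as (start, end) pairs.
    """
    bw = params.bandwidth
    t = treatment.values
    c = control.values
    L = len(t)
    fl_t = t.sum() / treatment.total_reads
    fl_c = c.sum() / control.total_reads
    lam_bg = treatment.total_reads * (bw + fl_t) / params.effective_genome_size
    scale = treatment.total_reads / control.total_reads

    significant = []
    for s in range(L - bw + 1):
        obs = int(math.floor(t[s : s + bw].sum() / fl_t + 0.5))
        center = s + bw // 2
        lam = lam_bg
        for w in params.local_lambda_windows:
            lo = max(0, center - w // 2)
            hi = min(L, center + w - w // 2)
            frags = c[lo:hi].sum() / fl_c
            lam = max(lam, frags * (bw + fl_c) / ((hi - lo) + fl_c) * scale)
        if poisson_tail(obs, lam) <= params.pvalue_threshold:
            significant.append(s)

    peaks = []
    for s in significant:
        e = min(s + bw, L)
        if peaks and s - peaks[-1][1] <= params.merge_gap:
            peaks[-1][1] = max(peaks[-1][1], e)
        else:
            peaks.append([s, e])
    return [tuple(p) for p in peaks]


def mann_whitney_exact(x, y):
    """Two-sided exact Mann-Whitney by enumerating every rank assignment."""
    n1, n2 = len(x), len(y)
    u_obs = sum(
        1.0 if xi > yi else (0.5 if xi == yi else 0.0) for xi in x for yi in y
    )
    pooled = list(x) + list(y)
    u_values = []
    for combo in itertools.combinations(range(n1 + n2), n1):
        group1 = [pooled[i] for i in combo]
        group2 = [pooled[i] for i in range(n1 + n2) if i not in combo]
        u = sum(
            1.0 if a > b else (0.5 if a == b else 0.0)
            for a in group1
            for b in group2
        )
        u_values.append(u)
    n = len(u_values)
    p_le = sum(u <= u_obs for u in u_values) / n
    p_ge = sum(u >= u_obs for u in u_values) / n
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def welch_t(x, y):
    """Welch's t statistic and Welch-Satterthwaite df by direct formula."""
    n1, n2 = len(x), len(y)
    m1 = sum(x) / n1
    m2 = sum(y) / n2
    v1 = sum((xi - m1) ** 2 for xi in x) / (n1 - 1)
    v2 = sum((yi - m2) ** 2 for yi in y) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, df
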