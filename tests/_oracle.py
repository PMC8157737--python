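"""Independent, literal transcriptions of the closed-form moderated-t
formulas, written feature-by-feature with scalar arithmetic and a different
root-finder, to serve as oracles for the vectorised implementation."""

import math

from scipy import optimize, special, stats


def oracle_pooled_fit(a_values, b_values):
    """Classical per-feature two-group summary (scalar arithmetic)."""
    a = [v for v in a_values if not math.isnan(v)]
    b = [v for v in b_values if not math.isnan(v)]
    mean_a = sum(a) / len(a)
    mean_b = sum(b) / len(b)
    ss = sum((v - mean_a) ** 2 for v in a) + sum((v - mean_b) ** 2 for v in b)
    df = (len(a) - 1) + (len(b) - 1)
    return mean_a - mean_b, ss / df if df > 0 else float("nan"), df, len(a), len(b)


def oracle_prior(s2_list, df_list):
    """Method-of-moments prior fit via brentq trigamma inversion."""
    pairs = [(s2, df) for s2, df in zip(s2_list, df_list)
             if s2 > 0 and df >= 1 and math.isfinite(s2)]
    n = len(pairs)
    e = [math.log(s2) - special.digamma(df / 2.0) + math.log(df / 2.0)
         for s2, df in pairs]
    e_bar = sum(e) / n
    target = sum(
        (eg - e_bar) ** 2 * n / (n - 1) - special.polygamma(1, df / 2.0)
        for eg, (_, df) in zip(e, pairs)
    ) / n
    if target <= 0:
        return float("inf"), math.exp(e_bar)
    half_d0 = optimize.brentq(
        lambda x: special.polygamma(1, x) - target, 1e-10, 1e10, xtol=1e-12
    )
    s0sq = math.exp(e_bar + special.digamma(half_d0) - math.log(half_d0))
    return 2.0 * half_d0, s0sq


def oracle_moderated_t(log2fc, s2, df, n_a, n_b, d0, s0sq):
    """One feature's moderated t and two-sided p, scalar form."""
    if math.isinf(d0):
        s2_post = s0sq
        df_total = float("inf")
    else:
        s2_post = (d0 * s0sq + df * s2) / (d0 + df)
        df_total = d0 + df
    se = math.sqrt(s2_post * (1.0 / n_a + 1.0 / n_b))
    t = log2fc / se
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(abs(t))
    else:
        p = 2.0 * stats.t.sf(abs(t), df_total)
    return t, p


def oracle_bh(p_list):
    """Literal Benjamini-Hochberg step-up with cumulative minimum."""
    m = len(p_list)
    order = sorted(range(m), key=lambda i: p_list[i])
    adj_sorted = [p_list[order[i]] * m / (i + 1) for i in range(m)]
    for i in range(m - 2, -1, -1):
        adj_sorted[i] = min(adj_sorted[i], adj_sorted[i + 1])
    adj_sorted = [min(v, 1.0) for v in adj_sorted]
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = adj_sorted[rank]
    return out
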