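"""Independent naive re-implementation of the stratified 2x2 machinery.

Plain-Python loops over strata, written directly from the textbook
formulas.  Deliberately shares no code with the vectorized implementation
in :mod:`episcan.association`; used as the oracle in equivalence tests.
"""

import math


def naive_mh_or(strata):
    """Mantel-Haenszel common OR from [(a, b, c, d), ...]."""
    num = 0.0
    den = 0.0
    for a, b, c, d in strata:
        n = a + b + c + d
        if n == 0:
            continue
        num += a * d / n
        den += b * c / n
    if den == 0:
        return float("nan") if num == 0 else float("inf")
    return num / den


def naive_rbg_ci(strata, z=1.96):
    """Robins-Breslow-Greenland 95% CI for the MH odds ratio."""
    R = S = 0.0
    sum_pr = sum_mid = sum_qs = 0.0
    for a, b, c, d in strata:
        n = a + b + c + d
        if n == 0:
            continue
        r_i = a * d / n
        s_i = b * c / n
        p_i = (a + d) / n
        q_i = (b + c) / n
        R += r_i
        S += s_i
        sum_pr += p_i * r_i
        sum_mid += p_i * s_i + q_i * r_i
        sum_qs += q_i * s_i
    if R <= 0 or S <= 0:
        return float("nan"), float("nan")
    var = sum_pr / (2 * R * R) + sum_mid / (2 * R * S) + sum_qs / (2 * S * S)
    log_or = math.log(R / S)
    se = math.sqrt(var)
    return math.exp(log_or - z * se), math.exp(log_or + z * se)


def naive_cmh_statistic(strata, continuity=True):
    """CMH chi-square with hypergeometric mean/variance per stratum."""
    dev = 0.0
    var = 0.0
    for a, b, c, d in strata:
        n = a + b + c + d
        if n == 0:
            continue
        dev += a - (a + b) * (a + c) / n
        if n > 1:
            var += (
                (a + b) * (c + d) * (a + c) * (b + d)
                / (n * n * (n - 1))
            )
    if var == 0:
        return float("nan")
    cc = 0.5 if continuity else 0.0
    return (abs(dev) - cc) ** 2 / var


def naive_bh(pvals):
    """Benjamini-Hochberg step-up from its definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        q[i] = val
        prev = val
    return q
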