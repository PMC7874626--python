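"""Independent brute-force reference implementations.

Everything here is written with plain loops and direct formulas so the
package's vectorized scoring code can be checked against it; nothing in
this module calls into :mod:`hacrp.scoring` or :mod:`hacrp.penalty`.
"""

import math


def decile_bruteforce(pairs):
    """Max-rank deciles by explicit double loop."""
    n = len(pairs)
    out = {}
    for h, v in pairs:
        r = sum(1 for _, u in pairs if u <= v)
        out[h] = math.ceil(10 * r / n)
    return out


def percentile_ceil_bruteforce(values, p):
    """Order statistic at position ceil(p*n), 1-indexed."""
    s = sorted(values)
    return s[max(math.ceil(p * len(s)), 1) - 1]


def winsorize_fit_bruteforce(values):
    """(p5, p95, mean, sd) of the winsorized values, sample (n-1) SD."""
    p5 = percentile_ceil_bruteforce(values, 0.05)
    p95 = percentile_ceil_bruteforce(values, 0.95)
    w = [min(max(v, p5), p95) for v in values]
    m = sum(w) / len(w)
    sd = math.sqrt(sum((x - m) ** 2 for x in w) / (len(w) - 1))
    return p5, p95, m, sd


def penalties_bruteforce(pairs):
    """(threshold, {hospital_id: penalized}) by sort-index-compare."""
    totals = sorted(t for _, t in pairs)
    threshold = totals[math.ceil(0.75 * len(totals)) - 1]
    return threshold, {h: t > threshold for h, t in pairs}
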