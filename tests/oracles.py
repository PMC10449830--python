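"""Independent brute-force reference implementations used only by tests.

Each oracle restates the definition of a statistic in the most direct form
possible (explicit loops, exhaustive enumeration, closed-form algebra) and
deliberately shares no code with the package.
"""

import math

import numpy as np
from scipy.stats import hypergeom


def shannon_entropy_bits(freqs) -> float:
    total = 0.0
    for f in freqs:
        if f > 0:
            total -= f * math.log2(f)
    return total


def clonality(freqs) -> float:
    n = len(freqs)
    if n == 1:
        return 1.0
    return 1.0 - shannon_entropy_bits(freqs) / math.log2(n)


def top_n_clonality(freqs, n) -> float:
    """Sort, truncate to the n largest, renormalize, apply the definition."""
    top = sorted(freqs, reverse=True)[:n]
    total = sum(top)
    return clonality([f / total for f in top])


def jsd_nats(p_map: dict, q_map: dict) -> float:
    """Direct Jensen-Shannon divergence over the union of categories."""
    total = 0.0
    for cat in set(p_map) | set(q_map):
        p = p_map.get(cat, 0.0)
        q = q_map.get(cat, 0.0)
        m = (p + q) / 2.0
        if p > 0:
            total += 0.5 * p * math.log(p / m)
        if q > 0:
            total += 0.5 * q * math.log(q / m)
    return total


def vj_usage(rep) -> dict:
    """Group-by-sum VJ aggregation, one clone at a time."""
    usage: dict = {}
    for _, row in rep.clones.iterrows():
        key = (row["v_gene"], row["j_gene"])
        usage[key] = usage.get(key, 0.0) + row["frequency"]
    total = sum(usage.values())
    return {k: v / total for k, v in usage.items()}


def enrichment_score(expression: dict, weights: dict) -> float:
    present = [g for g in weights if g in expression]
    return sum(expression[g] * weights[g] for g in present) / len(present)


def jaccard(a: set, b: set) -> float:
    if not (a | b):
        return 0.0
    return len(a & b) / len(a | b)


def fisher_two_sided(table) -> tuple:
    """Exact conditional test by full hypergeometric enumeration.

    Conditions on all margins; sums the probabilities of every table whose
    probability does not exceed the observed one (with the standard
    1 + 1e-7 relative guard against ties lost to rounding).
    """
    (a, b), (c, d) = table
    row1 = a + b
    n1 = a + c
    n = a + b + c + d
    dist = hypergeom(n, n1, row1)
    p_obs = dist.pmf(a)
    support = np.arange(max(0, row1 - (n - n1)), min(row1, n1) + 1)
    probs = dist.pmf(support)
    p_value = probs[probs <= p_obs * (1 + 1e-7)].sum()
    odds = (a * d) / (b * c) if b * c > 0 else math.inf
    return odds, float(min(1.0, p_value))


def ols_normal_equations(x, y) -> tuple:
    """Slope/intercept/R^2 from the normal equations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    design = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(design.T @ design, design.T @ y)
    fitted = design @ beta
    ss_res = ((y - fitted) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    return beta[1], beta[0], 1.0 - ss_res / ss_tot


def rtv(volumes, days, ref_day):
    v_ref = volumes[list(days).index(ref_day)]
    return [v / v_ref for v, d in zip(volumes, days) if d >= ref_day]


def classify_response_rules(rtv_vec) -> str:
    """The five response rules, checked one by one in precedence order."""
    end = rtv_vec[-1]
    if end == 0:
        return "MCR"
    if any(r == 0 for r in rtv_vec):
        return "CR"
    if any(0 < r <= 0.5 for r in rtv_vec):
        return "PR"
    if all(r > 0.5 for r in rtv_vec) and end <= 1.25:
        return "SD"
    return "PD"


def logrank_chi2(times, events, group_is_a) -> float:
    """Observed-minus-expected log-rank statistic from an explicit risk table."""
    o_minus_e = 0.0
    var = 0.0
    for t in sorted({t for t, e in zip(times, events) if e}):
        at_risk = [i for i, ti in enumerate(times) if ti >= t]
        n = len(at_risk)
        n_a = sum(1 for i in at_risk if group_is_a[i])
        d = sum(1 for i, ti in enumerate(times) if ti == t and events[i])
        d_a = sum(
            1
            for i, ti in enumerate(times)
            if ti == t and events[i] and group_is_a[i]
        )
        o_minus_e += d_a - d * n_a / n
        if n > 1:
            var += d * (n_a / n) * ((n - n_a) / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var
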