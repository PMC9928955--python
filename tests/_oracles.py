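"""Independent brute-force oracles used to cross-check the implementation.

Everything here is coded from first principles (plain Python loops, closed
formulas, exact rational arithmetic where counts are integers), deliberately
avoiding the code paths of the package itself.
"""

import math
from fractions import Fraction

from scipy import stats  # distribution tail functions only


def student_t(a, b):
    """Pooled-variance two-sample t: (t, df, two-sided p)."""
    n1, n2 = len(a), len(b)
    m1, m2 = sum(a) / n1, sum(b) / n2
    s1 = sum((x - m1) ** 2 for x in a) / (n1 - 1)
    s2 = sum((x - m2) ** 2 for x in b) / (n2 - 1)
    sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    return t, df, 2 * stats.t.sf(abs(t), df)


def welch_t(a, b):
    """Welch two-sample t with Satterthwaite df: (t, df, two-sided p)."""
    n1, n2 = len(a), len(b)
    m1, m2 = sum(a) / n1, sum(b) / n2
    v1 = sum((x - m1) ** 2 for x in a) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in b) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, df, 2 * stats.t.sf(abs(t), df)


def ksea_z(substrate_fcs, all_fcs, ddof=0):
    """z = (s_bar - p_bar) * sqrt(m) / delta with delta the SD of all sites."""
    m = len(substrate_fcs)
    s_bar = sum(substrate_fcs) / m
    p_bar = sum(all_fcs) / len(all_fcs)
    var = sum((x - p_bar) ** 2 for x in all_fcs) / (len(all_fcs) - ddof)
    return (s_bar - p_bar) * math.sqrt(m) / math.sqrt(var)


def cosine(a, b):
    """Binary-vector cosine of two sets."""
    if not a or not b:
        return 0.0
    return len(set(a) & set(b)) / math.sqrt(len(set(a)) * len(set(b)))


def venn(sets):
    """Membership-pattern tally: subset-key -> exact count."""
    labels = sorted(sets)
    union = set().union(*sets.values())
    counts = {}
    for el in union:
        key = "&".join(l for l in labels if el in sets[l])
        counts[key] = counts.get(key, 0) + 1
    return counts


def hypergeom_upper_p(k, M, n, N):
    """Exact P(X >= k) for X ~ Hypergeom(M, n, N), as a float via Fractions."""
    total = Fraction(0)
    denom = math.comb(M, N)
    for i in range(k, min(n, N) + 1):
        total += Fraction(math.comb(n, i) * math.comb(M - n, N - i), denom)
    return float(total)


def filter_edges(rows, min_score):
    """Brute-force confidence filter on (u, v, score-in-[0,1]) triples."""
    return sorted(
        (tuple(sorted((u, v))), s) for u, v, s in rows if s >= min_score and u != v)


def greedy_pairs(pre, post, max_dist):
    """One-to-one ascending-distance greedy matching by exhaustive loops."""
    cand = []
    for i, p in enumerate(pre):
        for j, q in enumerate(post):
            d = math.dist(p, q)
            if d <= max_dist:
                cand.append((d, i, j))
    cand.sort()
    used_i, used_j, pairs = set(), set(), []
    for d, i, j in cand:
        if i not in used_i and j not in used_j:
            used_i.add(i)
            used_j.add(j)
            pairs.append((i, j, d))
    return pairs
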