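"""Independent brute-force oracles, kept deliberately separate from the
package implementation: pure-Python loops, hand-written order statistics and
enumeration, no calls into autobcr internals."""

from __future__ import annotations

import math


def quantile_linear(values, q):
    """Linear-interpolation quantile on a sorted copy (hand-written)."""
    xs = sorted(float(v) for v in values)
    if not xs:
        raise ValueError("empty")
    h = (len(xs) - 1) * q
    lo = int(math.floor(h))
    hi = int(math.ceil(h))
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def median(values):
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 0:
        raise ValueError("empty")
    mid = n // 2
    return xs[mid] if n % 2 else (xs[mid - 1] + xs[mid]) / 2.0


def brute_force_signaling_strength(times, ch405, ch485, protocol):
    """Per-event recomputation of the signaling statistic with plain loops.

    Returns (threshold, u, q, cal, strength).
    """
    events = [
        (float(t), float(a) / float(b)) for t, a, b in zip(times, ch405, ch485)
    ]
    baseline = [s for t, s in events if t < protocol.t_4oht_s]
    threshold = quantile_linear(baseline, protocol.baseline_quantile)

    # peak crosslink bin by maximal median SIR, earlier bin wins ties
    bins = []
    start = protocol.autonomous_end_s
    while start + protocol.bin_width_s <= protocol.crosslink_end_s + 1e-9:
        bins.append((start, start + protocol.bin_width_s))
        start += protocol.bin_width_s
    best, best_med = None, -float("inf")
    for lo, hi in bins:
        sirs = [s for t, s in events if lo <= t < hi]
        if not sirs:
            continue
        m = median(sirs)
        if m > best_med:
            best_med, best = m, (lo, hi)
    peak = [s for t, s in events if best[0] <= t < best[1]]
    u = sum(1 for s in peak if s <= threshold) / len(peak)

    aut = [s for t, s in events if protocol.t_4oht_s <= t < protocol.autonomous_end_s]
    raw = sum(1 for s in aut if s > threshold) / len(aut)
    q = min(raw / (1.0 - u), 1.0)

    responders = [s for s in aut if s > threshold]
    cal = 0.0 if not responders else median(responders) / median(peak)
    return threshold, u, q, cal, q * cal


def fisher_two_sided(a, b, c, d):
    """Two-sided Fisher P by full enumeration over tables with fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_prob(x):
        # hypergeometric: P(X = x) for x successes in row 1
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = table_prob(a)
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    total = 0.0
    for x in range(lo, hi + 1):
        p = table_prob(x)
        if p <= p_obs * (1 + 1e-12):
            total += p
    return total


def naive_bayes_posterior(vector, clusters, loci, freqs, priors, eps):
    """Direct-product posterior (no logs): freqs[l][c], vector maps locus->0/1."""
    unnorm = []
    for ci, _c in enumerate(clusters):
        p = priors[ci]
        for li, locus in enumerate(loci):
            state = vector.get(locus)
            if state is None:
                continue
            f = min(max(freqs[li][ci], eps), 1 - eps)
            p *= f if state else (1 - f)
        unnorm.append(p)
    z = sum(unnorm)
    return [p / z for p in unnorm]


def variant_retained(gene, consequence, sift, polyphen, clinsig, genes, consequences):
    """Boolean filtering rule, re-stated independently."""

    def norm(s):
        return None if s is None or str(s).strip() == "" else str(s).strip().lower().replace(" ", "_")

    cs = norm(clinsig)
    if cs in ("benign", "likely_benign"):
        return False
    if gene not in genes:
        return False
    if norm(consequence) not in {norm(c) for c in consequences}:
        return False
    damaging = (
        norm(sift) == "deleterious"
        or norm(polyphen) in ("possibly_damaging", "probably_damaging")
        or cs in ("likely_pathogenic", "pathogenic")
    )
    return damaging
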