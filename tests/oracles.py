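"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the mathematical definitions, deliberately
avoiding the code paths (and, where practical, the libraries) that the
package itself uses.
"""

import math


def bh_stepup_oracle(pvals):
    """Literal Benjamini-Hochberg step-up: sort, scale, running minimum."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    out = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, pvals[i] * m / rank, 1.0)
        out[i] = val
        prev = val
    return out


def mean_oracle(values):
    return sum(values) / len(values)


def sd_oracle(values):
    n = len(values)
    if n < 2:
        return 0.0
    mu = mean_oracle(values)
    return math.sqrt(sum((v - mu) ** 2 for v in values) / (n - 1))


def quantile_oracle(values, q):
    """Linear interpolation between order statistics."""
    xs = sorted(values)
    n = len(xs)
    h = (n - 1) * q
    lo = math.floor(h)
    hi = math.ceil(h)
    return xs[lo] + (xs[hi] - xs[lo]) * (h - lo)


def normal_sf_oracle(z):
    """Upper-tail standard normal probability via erfc."""
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def runs_oracle(members, pred, min_run):
    """All maximal qualifying windows, found by enumerating every contiguous
    window of the exon-sorted bin list (quadratic, fixtures stay small)."""
    ms = sorted(members, key=lambda b: b.exon_index)
    n = len(ms)
    out = []
    for i in range(n):
        for j in range(i, n):
            win = ms[i : j + 1]
            if len(win) < min_run:
                continue
            if not all(pred(b) for b in win):
                continue
            if any(win[k + 1].exon_index != win[k].exon_index + 1 for k in range(len(win) - 1)):
                continue
            if i > 0 and pred(ms[i - 1]) and ms[i - 1].exon_index == win[0].exon_index - 1:
                continue
            if j < n - 1 and pred(ms[j + 1]) and ms[j + 1].exon_index == win[-1].exon_index + 1:
                continue
            out.append(win)
    return out


def stab_count_oracle(bins, segments):
    """How many bin midpoints fall inside any aberrant segment (direct scan)."""

    def norm(c):
        c = c.lower()
        return c[3:] if c.startswith("chr") else c

    count = 0
    for b in bins:
        mid = (b.start + b.end) // 2
        for s in segments:
            if norm(s.chromosome) == norm(b.chromosome) and s.start <= mid < s.end:
                count += 1
                break
    return count


def loh_windows_oracle(frequencies, window, lo=0.3, hi=0.7, max_het=0.1):
    """Indices i such that window [i, i+window) is het-depleted."""
    n = len(frequencies)
    w = min(window, n)
    flagged = []
    for i in range(0, n - w + 1):
        het = sum(1 for f in frequencies[i : i + w] if lo < f < hi)
        if het / w <= max_het:
            flagged.append((i, i + w))
    return flagged
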