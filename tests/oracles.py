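"""Independent brute-force oracles the implementation is checked against.

Deliberately written in the most literal style possible (per-sample
loops, exhaustive subsequence enumeration, fixpoint merging) and kept
free of any code path shared with the package.
"""

from itertools import combinations


def peak_scan(x, lo, hi, t_start, fs, epochs=None, label=None):
    """Per-sample scan for in-window peaks; returns sample indices.

    Maxima when the window is non-negative, minima when non-positive;
    plateau counts once at its first sample; endpoints excluded.
    """
    negative = hi <= 0
    hits = []
    for i in range(1, len(x) - 1):
        if negative:
            is_peak = x[i - 1] > x[i] and x[i] <= x[i + 1]
        else:
            is_peak = x[i - 1] < x[i] and x[i] >= x[i + 1]
        if not (is_peak and lo <= x[i] <= hi):
            continue
        if label is not None:
            t = t_start + i / fs
            if not any(e.label == label and e.start <= t < e.end for e in epochs):
                continue
        hits.append(i)
    return hits


def burst_enumeration(times, f_init, f_term):
    """Exhaustive contiguous-subsequence burst oracle.

    Enumerates every contiguous subsequence of >= 2 spikes that starts
    with an ISI-frequency >= f_init and continues with ISI-frequencies
    >= f_term, keeps those maximal under right-extension, then selects
    greedily left to right (a new burst may not start at or before the
    previous burst's closing spike).  Returns (start, end, n_spikes)
    tuples.
    """
    n = len(times)

    def qualifies(i, j):
        if 1.0 / (times[i + 1] - times[i]) < f_init:
            return False
        return all(
            1.0 / (times[k + 1] - times[k]) >= f_term for k in range(i + 1, j)
        )

    candidates = [
        (i, j)
        for i in range(n - 1)
        for j in range(i + 1, n)
        if qualifies(i, j) and (j == n - 1 or not qualifies(i, j + 1))
    ]
    selected = []
    last_end = -1
    for i, j in sorted(candidates):
        if i > last_end:
            selected.append((times[i], times[j], j - i + 1))
            last_end = j
    return selected


def merge_fixpoint(epochs, tolerance):
    """Transitive-closure merge: repeatedly coalesce any same-label pair
    whose gap (possibly negative, i.e. overlap) is <= tolerance, until no
    pair qualifies.  Returns sorted (start, end, label) tuples."""
    eps = [(e.start, e.end, e.label) for e in epochs]
    changed = True
    while changed:
        changed = False
        for (ia, a), (ib, b) in combinations(enumerate(eps), 2):
            if a[2] != b[2]:
                continue
            gap = max(b[0] - a[1], a[0] - b[1])
            if gap <= tolerance:
                merged = (min(a[0], b[0]), max(a[1], b[1]), a[2])
                eps = [e for k, e in enumerate(eps) if k not in (ia, ib)]
                eps.append(merged)
                changed = True
                break
    return sorted(eps)
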