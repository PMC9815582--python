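"""Independent brute-force oracles used to cross-check the production code.

Deliberately written as naive loops with no shared code paths with the
package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np


def brute_force_events(
    z, min_prominence: float, reopen_fraction: float = 0.5, window_points: int = 3
):
    """Exhaustive closure-event scan; returns (start, peak, end) index triples.

    A peak is the earliest argmax of its centered window; prominence is peak
    minus the higher of the flanking minima (walking to the nearest strictly
    higher sample or the edge); boundaries are the first samples at or below
    peak - reopen_fraction * prominence; overlapping events merge with union
    span keeping the higher peak.
    """
    z = list(map(float, z))
    n = len(z)
    half = window_points // 2
    raw = []
    for i in range(half, n - half):
        window = z[i - half : i + half + 1]
        m = max(window)
        if z[i] != m:
            continue
        if window.index(m) != half:  # tie broken to the earliest index
            continue
        left_vals = []
        j = i - 1
        while j >= 0 and z[j] <= z[i]:
            left_vals.append(z[j])
            j -= 1
        right_vals = []
        k = i + 1
        while k < n and z[k] <= z[i]:
            right_vals.append(z[k])
            k += 1
        left_base = min(left_vals) if left_vals else z[i]
        right_base = min(right_vals) if right_vals else z[i]
        prom = z[i] - max(left_base, right_base)
        if prom < min_prominence:
            continue
        level = z[i] - reopen_fraction * prom
        j = i - 1
        while j > 0 and z[j] > level:
            j -= 1
        k = i + 1
        while k < n - 1 and z[k] > level:
            k += 1
        raw.append([j, i, k, z[i]])

    raw.sort(key=lambda e: (e[0], e[1]))
    merged = []
    for ev in raw:
        if merged and ev[0] <= merged[-1][2]:
            cur = merged[-1]
            if ev[3] > cur[3]:
                cur[1], cur[3] = ev[1], ev[3]
            cur[0] = min(cur[0], ev[0])
            cur[2] = max(cur[2], ev[2])
        else:
            merged.append(ev)
    return [(s, p, e) for s, p, e, _ in merged]


def exact_ranksum_p(a, b):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)
    ranks = {}
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    # midranks for ties
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        mid = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    obs = sum(ranks[i] for i in range(n1))
    mean = n1 * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        w = sum(ranks[i] for i in combo)
        total += 1
        if abs(w - mean) >= abs(obs - mean) - 1e-12:
            count += 1
    return count / total


def windowed_means(values, times_ns, window_ns):
    """Brute-force non-overlapping window averages keyed by window start."""
    out = {}
    for v, t in zip(values, times_ns):
        if not np.isfinite(v):
            continue
        w = (t // window_ns) * window_ns
        out.setdefault(w, []).append(v)
    return {w: float(np.mean(vs)) for w, vs in out.items()}
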