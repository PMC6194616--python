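"""Independent reference implementations used only as test oracles.

Deliberately written without reusing the package's alignment or
clustering code paths: pure-Python nested loops, explicit candidate
lists, and a textbook O(n^3) agglomerative clusterer.
"""

from __future__ import annotations

import math


def brute_force_align(pa, pb, min_overlap=None):
    """Enumerate every (strand, offset) superposition of two PWMs given as
    nested lists of columns; return (offset, strand, overlap, score)."""
    wa, wb = len(pa), len(pb)
    if min_overlap is None:
        min_overlap = min(4, wa, wb)
    min_overlap = max(1, min(min_overlap, wa, wb))

    def complemented(p):
        # reverse column order, and reverse each column (A<->T, C<->G)
        return [list(reversed(col)) for col in reversed(p)]

    candidates = []
    for strand, b in (("forward", pb), ("reverse", complemented(pb))):
        for off in range(-wb + 1, wa):
            cols = []
            for j in range(wa):
                i = j - off
                if 0 <= i < wb:
                    cols.append((pa[j], b[i]))
            if len(cols) < min_overlap:
                continue
            total = 0.0
            for ca, cb in cols:
                ssd = 0.0
                for x, y in zip(ca, cb):
                    d = x - y
                    ssd += d * d
                total += 1.0 - ssd / 2.0
            score = 100.0 * (total / len(cols))
            candidates.append((off, strand, len(cols), score))

    def rank(c):
        off, strand, ov, score = c
        return (score, ov, strand == "forward", -abs(off), off < 0)

    return max(candidates, key=rank)


def naive_linkage(d, method="average"):
    """O(n^3) agglomerative clustering on a full distance matrix (list of
    lists).  Returns merge rows [left, right, height, size] with SciPy's
    cluster numbering (leaves 0..n-1, new clusters n, n+1, ...)."""
    n = len(d)
    clusters = {i: [i] for i in range(n)}  # cluster id -> leaf members
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d[i][j]
    merges = []
    next_id = n
    while len(clusters) > 1:
        (a, b), h = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        members = clusters[a] + clusters[b]
        del clusters[a], clusters[b]
        dist = {k: v for k, v in dist.items() if a not in k and b not in k}
        for c, mc in clusters.items():
            if method == "average":
                newd = sum(d[x][y] for x in members for y in mc) / (
                    len(members) * len(mc)
                )
            elif method == "complete":
                newd = max(d[x][y] for x in members for y in mc)
            else:  # single
                newd = min(d[x][y] for x in members for y in mc)
            dist[(min(c, next_id), max(c, next_id))] = newd
        clusters[next_id] = members
        merges.append([a, b, h, len(members)])
        next_id += 1
    return merges


def matthews_from_labels(known, predicted):
    """Matthews correlation computed directly from two binary label
    vectors via the covariance form, independent of confusion counting."""
    n = len(known)
    mk = sum(known) / n
    mp = sum(predicted) / n
    cov = sum((k - mk) * (p - mp) for k, p in zip(known, predicted)) / n
    vk = sum((k - mk) ** 2 for k in known) / n
    vp = sum((p - mp) ** 2 for p in predicted) / n
    if vk == 0 or vp == 0:
        return None
    return cov / math.sqrt(vk * vp)
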