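"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they are checked against:
flood-fill labeling vs the production region labeler, sorted-list
interpolation vs the percentile call, a naive O(n^3) Lance-Williams
agglomeration vs the linkage-based Ward clustering, and the closed-form
df=1 chi-squared tail vs the survival-function call.
"""

from __future__ import annotations

import math

import numpy as np


def flood_fill_label(mask: np.ndarray, connectivity: int = 8) -> list[set[tuple[int, int]]]:
    """Connected components by explicit BFS flood fill.

    Returns a list of pixel sets {(x, y), ...} in row-major first-seed
    order.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    seen = np.zeros_like(mask)
    comps = []
    for y in range(h):
        for x in range(w):
            if not mask[y, x] or seen[y, x]:
                continue
            stack = [(y, x)]
            seen[y, x] = True
            comp = set()
            while stack:
                cy, cx = stack.pop()
                comp.add((cx, cy))
                for dy, dx in nbrs:
                    ny, nx = cy + dy, cx + dx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        stack.append((ny, nx))
            comps.append(comp)
    return comps


def quantile_interp(values, q: float) -> float:
    """Quantile by explicit sorted-list linear interpolation.

    Position 1 + q*(n-1) on the 1-based sorted list.
    """
    v = sorted(float(x) for x in values)
    n = len(v)
    pos = q * (n - 1)
    lo = math.floor(pos)
    hi = math.ceil(pos)
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


def ward_lw_merges(d: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Naive O(n^3) agglomeration with the Ward Lance-Williams update
    applied to the dissimilarities as supplied (unsquared).

    Returns the merge sequence as (leaf set A, leaf set B, height).
    Ties break on the smallest (i, j) cluster-id pair.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    members = {i: frozenset([i]) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    dist = {(i, j): d[i, j] for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n
    while len(members) > 1:
        (i, j) = min(dist, key=lambda ij: (dist[ij], ij))
        h = dist[(i, j)]
        merges.append((members[i], members[j], h))
        ni, nj = sizes[i], sizes[j]
        new = {}
        for (a, b), val in dist.items():
            if i in (a, b) or j in (a, b):
                continue
            new[(a, b)] = val
        for k in members:
            if k in (i, j):
                continue
            nk = sizes[k]
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            val = ((ni + nk) * dik + (nj + nk) * djk - nk * h) / (ni + nj + nk)
            new[tuple(sorted((k, next_id)))] = val
        members[next_id] = members[i] | members[j]
        sizes[next_id] = ni + nj
        del members[i], members[j], sizes[i], sizes[j]
        dist = new
        next_id += 1
    return merges


def linkage_merges(z: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Decode a scipy linkage matrix into the same merge-sequence form."""
    z = np.asarray(z, dtype=float)
    n = z.shape[0] + 1
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for row_idx, (a, b, h, _cnt) in enumerate(z):
        fa, fb = members[int(a)], members[int(b)]
        merges.append((fa, fb, float(h)))
        members[n + row_idx] = fa | fb
    return merges


def gof_p_closed_form(chi2_stat: float) -> float:
    """df = 1 upper tail: p = erfc(sqrt(chi2 / 2))."""
    return math.erfc(math.sqrt(chi2_stat / 2.0))


def cmh_statistic(tables: np.ndarray, correction: bool = True) -> float:
    """Classical CMH chi-squared over (K, 2, 2) tables, from the formula."""
    t = np.asarray(tables, dtype=float)
    a = t[:, 0, 0]
    r1 = t[:, 0, :].sum(axis=1)
    r2 = t[:, 1, :].sum(axis=1)
    c1 = t[:, :, 0].sum(axis=1)
    c2 = t[:, :, 1].sum(axis=1)
    n = t.sum(axis=(1, 2))
    expected = r1 * c1 / n
    var = r1 * r2 * c1 * c2 / (n**2 * (n - 1))
    num = abs(a.sum() - expected.sum())
    if correction:
        num = max(num - 0.5, 0.0)
    return float(num**2 / var.sum())
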