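"""Brute-force reference implementations used only to cross-check the
package on small instances.  Deliberately naive: explicit loops, BFS flood
fill, full permutation enumeration."""

from collections import deque
from itertools import permutations


def flood_components(grid, connectivity=8):
    """Label 2-D connected components of a boolean grid by BFS.

    Returns a list of frozensets of (row, col) coordinates.
    """
    if connectivity == 8:
        steps = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    nr, nc = len(grid), len(grid[0])
    seen = [[False] * nc for _ in range(nr)]
    comps = []
    for r in range(nr):
        for c in range(nc):
            if not grid[r][c] or seen[r][c]:
                continue
            comp = set()
            q = deque([(r, c)])
            seen[r][c] = True
            while q:
                cr, cc = q.popleft()
                comp.add((cr, cc))
                for dr, dc in steps:
                    qr, qc = cr + dr, cc + dc
                    if 0 <= qr < nr and 0 <= qc < nc and grid[qr][qc] \
                            and not seen[qr][qc]:
                        seen[qr][qc] = True
                        q.append((qr, qc))
            comps.append(frozenset(comp))
    return comps


def fill_holes(grid):
    """2-D hole filling: everything not 4-connected to the border background
    becomes foreground."""
    nr, nc = len(grid), len(grid[0])
    outside = [[False] * nc for _ in range(nr)]
    q = deque()
    for r in range(nr):
        for c in (0, nc - 1):
            if not grid[r][c] and not outside[r][c]:
                outside[r][c] = True
                q.append((r, c))
    for c in range(nc):
        for r in (0, nr - 1):
            if not grid[r][c] and not outside[r][c]:
                outside[r][c] = True
                q.append((r, c))
    while q:
        cr, cc = q.popleft()
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            qr, qc = cr + dr, cc + dc
            if 0 <= qr < nr and 0 <= qc < nc and not grid[qr][qc] \
                    and not outside[qr][qc]:
                outside[qr][qc] = True
                q.append((qr, qc))
    return [[bool(grid[r][c]) or not outside[r][c] for c in range(nc)]
            for r in range(nr)]


def dice(a, b):
    """Dice coefficient of two same-shape boolean nested lists."""
    inter = na = nb = 0
    for ra, rb in zip(a, b):
        for va, vb in zip(ra, rb):
            na += bool(va)
            nb += bool(vb)
            inter += bool(va) and bool(vb)
    if na + nb == 0:
        return 1.0
    return 2.0 * inter / (na + nb)


def bland_altman_bias(x, y):
    """Mean difference by direct summation."""
    total = 0.0
    for xi, yi in zip(x, y):
        total += xi - yi
    return total / len(x)


def _rho_from_ranks(xr, yr):
    n = len(xr)
    mx = sum(xr) / n
    my = sum(yr) / n
    num = sum((a - mx) * (b - my) for a, b in zip(xr, yr))
    den = (sum((a - mx) ** 2 for a in xr) * sum((b - my) ** 2 for b in yr)) ** 0.5
    return num / den


def ranks(values):
    """Mid-ranks, computed pedestrian-style."""
    out = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        out.append(less + (equal + 1) / 2.0)
    return out


def spearman_exact_p(x, y):
    """Two-sided exact permutation p for Spearman's rho by full enumeration."""
    xr = ranks(x)
    yr = ranks(y)
    observed = abs(_rho_from_ranks(xr, yr))
    count = total = 0
    for perm in permutations(yr):
        total += 1
        if abs(_rho_from_ranks(xr, list(perm))) >= observed - 1e-12:
            count += 1
    return count / total
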