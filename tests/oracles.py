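"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written for clarity at tiny problem sizes and shares no
code path with the package: windows by exhaustive enumeration, trees by
recursive split nesting, BLUP by dense normal equations.
"""

from __future__ import annotations

import numpy as np


# ---------------------------------------------------------------------------
# four-gamete windows
# ---------------------------------------------------------------------------

def all_pairs_compatible(h: np.ndarray, start: int, end: int) -> bool:
    for i in range(start, end):
        for j in range(i + 1, end):
            a, b = h[:, i].astype(bool), h[:, j].astype(bool)
            if (a & b).any() and (a & ~b).any() and (~a & b).any() and (~a & ~b).any():
                return False
    return True


def brute_force_window(panel, focal: int) -> tuple[int, int]:
    """Largest all-pairs-compatible window containing the focal marker.

    Enumerates every candidate window; ties go to the smallest start, the
    same rule the implementation documents.
    """
    lo, hi = panel.markers.chrom_range(focal)
    h = panel.haplotypes
    best = (focal, focal + 1)
    for s in range(lo, focal + 1):
        for e in range(focal + 1, hi + 1):
            if e - s > best[1] - best[0] and all_pairs_compatible(h, s, e):
                best = (s, e)
    return best


# ---------------------------------------------------------------------------
# split-nesting tree + depth cut
# ---------------------------------------------------------------------------

def _oriented_clades(panel, window):
    h = panel.haplotypes
    n = h.shape[0]
    full = frozenset(range(n))
    ones = frozenset(np.flatnonzero(h[:, window.focal]).tolist())
    zeros = full - ones
    clades = set()
    for j in range(window.start, window.end):
        if j == window.focal:
            continue
        s = frozenset(np.flatnonzero(h[:, j]).tolist())
        if not s or len(s) == n:
            continue
        for cand in (s, full - s):
            if cand <= ones or cand <= zeros:
                clades.add(cand)
                break
        else:
            raise ValueError("fixture violates the four-gamete invariant")
    clades.discard(ones)
    clades.discard(zeros)
    return full, ones, zeros, sorted(clades, key=lambda c: (-len(c), sorted(c)))


def _subtree(S: frozenset, clades) -> tuple:
    """Binary subtree over S as nested tuples (set, left, right) / (set,) leaf."""
    inside = [c for c in clades if c < S]
    maximal = [c for c in inside if not any(c < d for d in inside)]
    covered = frozenset().union(*maximal) if maximal else frozenset()
    residual = S - covered
    branches = sorted(maximal, key=lambda c: (-len(c), min(c)))
    if residual:
        branches.append(residual)
        branches.sort(key=lambda c: (-len(c), min(c)))
    if branches == [S]:
        return (S,)
    subtrees = [
        _subtree(b, [c for c in inside if c <= b]) if b in maximal else (b,)
        for b in branches
    ]
    return _caterpillar(S, subtrees)


def _caterpillar(S: frozenset, subtrees: list) -> tuple:
    if len(subtrees) == 1:
        only = subtrees[0]
        return only if only[0] == S else (S, only)  # should not occur for laminar input
    if len(subtrees) == 2:
        return (S, subtrees[0], subtrees[1])
    head, rest = subtrees[0], subtrees[1:]
    rest_set = frozenset().union(*(t[0] for t in rest))
    return (S, head, _caterpillar(rest_set, rest))


def brute_force_partition(panel, window, depth: int = 3) -> set[frozenset]:
    """Depth-cut haplotype partition by explicit path enumeration."""
    full, ones, zeros, clades = _oriented_clades(panel, window)
    left = _subtree(ones, [c for c in clades if c <= ones])
    right = _subtree(zeros, [c for c in clades if c <= zeros])
    root = (full, left, right)
    clusters: list[frozenset] = []

    def walk(node, level):
        if len(node) == 1:
            clusters.append(node[0])
        elif level == depth:
            clusters.append(node[1][0])
            clusters.append(node[2][0])
        else:
            walk(node[1], level + 1)
            walk(node[2], level + 1)

    walk(root, 1)
    return set(clusters)


# ---------------------------------------------------------------------------
# weighted ridge-regression BLUP (RR-BLUP) on centered covariates
# ---------------------------------------------------------------------------

def rrblup_dgv(x_all: np.ndarray, ref: np.ndarray, y: np.ndarray, w: np.ndarray,
               var_g: float, var_e: float) -> np.ndarray:
    """DGV for all rows from a dense weighted ridge solve on the reference rows.

    Covariates are centered by twice their frequency over all rows; the
    per-covariate variance is var_g / s with s = sum_j 2 f_j (1 - f_j).
    """
    x_all = x_all.astype(float)
    f = x_all.mean(axis=0) / 2.0
    mc = x_all - 2.0 * f
    s = float(np.sum(2.0 * f * (1.0 - f)))
    lam = var_e / (var_g / s)
    xr = mc[ref]
    k = xr.shape[1]
    a_mat = np.zeros((k + 1, k + 1))
    a_mat[0, 0] = w.sum()
    a_mat[0, 1:] = w @ xr
    a_mat[1:, 0] = a_mat[0, 1:]
    a_mat[1:, 1:] = xr.T @ (w[:, None] * xr) + lam * np.eye(k)
    rhs = np.concatenate([[w @ y], xr.T @ (w * y)])
    sol = np.linalg.solve(a_mat, rhs)
    return mc @ sol[1:]
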