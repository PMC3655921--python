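"""Local genealogical trees and depth-3 haplotype clustering.

At every focal marker the package finds the largest surrounding marker
window in which all site pairs pass the four-gamete test, so the window is
consistent with a single recombination-free history under the infinite-sites
model. Within that window every marker defines a bipartition (split) of the
2N haplotypes; pairwise compatibility guarantees the splits nest into a
perfect phylogeny. The tree is rooted on the focal marker's own split, so
the two subtrees under the root are exactly the carriers of each focal
allele, and is then cut after its first three levels: level 1 is the root,
level 2 its two children, level 3 the four grandchildren, and every branch
hanging below level 3 becomes one haplotype cluster — at most eight per
tree. An individual's two haplotypes then contribute 0, 1 or 2 copies to
each cluster, and those copy counts replace marker allele counts as the
covariates of genomic prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .panel import PhasedHaplotypePanel

logger = logging.getLogger(__name__)

DEFAULT_CUT_DEPTH = 3


# ---------------------------------------------------------------------------
# four-gamete test and focal windows
# ---------------------------------------------------------------------------

def four_gamete_compatible(col_a, col_b) -> bool:
    """True unless all four gametes 00, 01, 10, 11 occur among paired entries.

    Two bi-allelic sites showing all four combinations cannot share a
    recombination-free, infinite-sites history.
    """
    a = np.asarray(col_a, dtype=bool)
    b = np.asarray(col_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("columns must be 1-D and of equal length")
    return not ((a & b).any() and (a & ~b).any() and (~a & b).any() and (~a & ~b).any())


@dataclass(frozen=True)
class FocalWindow:
    """Half-open marker-index window [start, end) containing the focal marker."""

    focal: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start <= self.focal < self.end:
            raise ValueError("window must contain the focal marker")

    @property
    def size(self) -> int:
        return self.end - self.start


class _PairCompatCache:
    """Memoized four-gamete tests on a boolean haplotype matrix."""

    def __init__(self, haplotypes: np.ndarray):
        self.h = haplotypes.astype(bool)
        self._cache: dict[tuple[int, int], bool] = {}

    def compatible(self, i: int, j: int) -> bool:
        if i == j:
            return True
        key = (i, j) if i < j else (j, i)
        hit = self._cache.get(key)
        if hit is None:
            hit = four_gamete_compatible(self.h[:, key[0]], self.h[:, key[1]])
            self._cache[key] = hit
        return hit


def _max_end_per_start(cache: _PairCompatCache, lo: int, hi: int) -> np.ndarray:
    """For each start s in [lo, hi): largest e with [s, e) all-pairs compatible.

    Validity of a window is antitone (every sub-window of a valid window is
    valid), so the maximal end is non-decreasing in the start and a
    two-pointer sweep suffices.
    """
    maxend = np.empty(hi - lo, dtype=np.int64)
    e = lo
    for s in range(lo, hi):
        if e < s + 1:
            e = s + 1
        while e < hi and all(cache.compatible(e, k) for k in range(s, e)):
            e += 1
        maxend[s - lo] = e
    return maxend


def _best_window(maxend: np.ndarray, lo: int, focal: int) -> FocalWindow:
    best_s, best_size = focal, 1
    for s in range(lo, focal + 1):
        e = int(maxend[s - lo])
        if e <= focal:
            continue
        size = e - s
        if size > best_size:
            best_s, best_size = s, size
    return FocalWindow(focal, best_s, best_s + best_size)


def focal_window(panel: PhasedHaplotypePanel, focal: int) -> FocalWindow:
    """Largest all-pairs four-gamete-compatible window around one focal marker.

    The window never crosses a chromosome boundary; among equally large
    windows the one starting furthest left is returned.
    """
    if not 0 <= focal < panel.n_markers:
        raise IndexError(f"focal marker {focal} out of range")
    lo, hi = panel.markers.chrom_range(focal)
    cache = _PairCompatCache(panel.haplotypes)
    maxend = _max_end_per_start(cache, lo, hi)
    return _best_window(maxend, lo, focal)


def focal_windows(panel: PhasedHaplotypePanel, focal_indices=None) -> list[FocalWindow]:
    """Maximal windows for many focal markers, sharing the pair-test cache."""
    if focal_indices is None:
        focal_indices = range(panel.n_markers)
    focal_indices = sorted(int(f) for f in focal_indices)
    cache = _PairCompatCache(panel.haplotypes)
    out: list[FocalWindow] = []
    bounds = panel.markers.chrom_bounds()
    maxend_by_chrom: dict[int, np.ndarray] = {}
    for f in focal_indices:
        c = int(panel.markers.chromosome[f])
        lo, hi = bounds[c]
        if c not in maxend_by_chrom:
            maxend_by_chrom[c] = _max_end_per_start(cache, lo, hi)
        out.append(_best_window(maxend_by_chrom[c], lo, f))
    return out


# ---------------------------------------------------------------------------
# perfect-phylogeny construction
# ---------------------------------------------------------------------------

class TreeNode:
    """Node of a rooted local genealogy; holds the haplotype rows below it."""

    __slots__ = ("haplotypes", "children")

    def __init__(self, haplotypes, children=None):
        self.haplotypes: frozenset[int] = frozenset(haplotypes)
        self.children: list[TreeNode] = list(children) if children else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode(n={len(self.haplotypes)}, children={len(self.children)})"


@dataclass
class LocalTree:
    """Rooted binary genealogy for one focal marker.

    The root's two children partition the haplotypes by focal-marker allele;
    every other window marker's split appears as the haplotype set of one
    node (or is implicit as a complement).
    """

    focal: int
    window: FocalWindow
    root: TreeNode


def _sort_key(node: TreeNode):
    return (-len(node.haplotypes), min(node.haplotypes))


def _insert_clade(root: TreeNode, clade: frozenset) -> None:
    node = root
    while True:
        nxt = next((ch for ch in node.children if clade <= ch.haplotypes), None)
        if nxt is None:
            break
        node = nxt
    inside, outside = [], []
    for ch in node.children:
        inter = ch.haplotypes & clade
        if not inter:
            outside.append(ch)
        elif ch.haplotypes <= clade:
            inside.append(ch)
        else:
            raise ValueError("no perfect phylogeny: splits are not laminar")
    node.children = outside + [TreeNode(clade, inside)]


def _attach_residual_leaves(node: TreeNode) -> None:
    if node.is_leaf:
        return
    covered: set[int] = set()
    for ch in node.children:
        covered |= ch.haplotypes
        _attach_residual_leaves(ch)
    residual = node.haplotypes - covered
    if residual:
        node.children.append(TreeNode(residual))


def _binarize(node: TreeNode) -> None:
    """Resolve polytomies into a caterpillar, largest branch first.

    Children are ordered by decreasing haplotype count (ties by smallest
    contained row index) and folded so each internal level splits off the
    current largest branch; a deterministic stand-in for the unpublished
    resolution used by genealogy-based association software.
    """
    if node.is_leaf:
        return
    node.children.sort(key=_sort_key)
    while len(node.children) > 2:
        head, *tail = node.children
        rest = TreeNode(frozenset().union(*(t.haplotypes for t in tail)), tail)
        node.children = [head, rest]
    for ch in node.children:
        _binarize(ch)


def build_local_tree(panel: PhasedHaplotypePanel, window: FocalWindow) -> LocalTree:
    """Perfect phylogeny of the window's haplotypes, rooted on the focal split.

    Each non-focal window marker contributes its minor-allele carrier set as
    a split; splits are oriented as clades nested inside the focal-allele
    sides, deduplicated, and assembled into the (unique) laminar hierarchy.
    Identical window sequences collapse onto one leaf.
    """
    n = panel.n_haplotypes
    h = panel.haplotypes
    focal_carriers = frozenset(np.flatnonzero(h[:, window.focal]).tolist())
    full = frozenset(range(n))
    non_carriers = full - focal_carriers
    if not focal_carriers or not non_carriers:
        raise ValueError("focal marker is monomorphic; the local tree cannot be rooted")
    clades: set[frozenset] = set()
    for j in range(window.start, window.end):
        if j == window.focal:
            continue
        split = frozenset(np.flatnonzero(h[:, j]).tolist())
        if not split or len(split) == n:
            continue  # monomorphic within the panel: carries no split
        comp = full - split
        if split <= focal_carriers or split <= non_carriers:
            clade = split
        elif comp <= focal_carriers or comp <= non_carriers:
            clade = comp
        else:
            raise ValueError(
                f"no perfect phylogeny: marker {j} fails the four-gamete test against the focal marker"
            )
        if clade not in (focal_carriers, non_carriers):
            clades.add(clade)
    root = TreeNode(full, [TreeNode(focal_carriers), TreeNode(non_carriers)])
    for clade in sorted(clades, key=lambda c: (-len(c), sorted(c))):
        _insert_clade(root, clade)
    _attach_residual_leaves(root)
    _binarize(root)
    return LocalTree(window.focal, window, root)


# ---------------------------------------------------------------------------
# depth cut -> haplotype clusters
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """Partition of the 2N haplotype rows at one focal marker (labels 1..C)."""

    focal: int
    labels: np.ndarray
    n_clusters: int
    marker_id: str | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.min(initial=1) < 1 or self.labels.max(initial=1) > self.n_clusters:
            raise ValueError("cluster labels must lie in 1..n_clusters")


def cut_clusters(tree: LocalTree, depth: int = DEFAULT_CUT_DEPTH) -> ClusterAssignment:
    """Cut the tree after its first ``depth`` levels into haplotype clusters.

    Branches hanging below the depth-``depth`` node layer become clusters
    (at most 2**depth of them); leaves reached at or above that layer are
    clusters by themselves. Empty branches simply do not occur as clusters
    and labels are renumbered 1..C in traversal order.
    """
    if depth < 1:
        raise ValueError("cut depth must be at least 1")
    clusters: list[frozenset] = []

    def walk(node: TreeNode, level: int) -> None:
        if node.is_leaf:
            clusters.append(node.haplotypes)
        elif level == depth:
            clusters.extend(ch.haplotypes for ch in node.children)
        else:
            for ch in node.children:
                walk(ch, level + 1)

    walk(tree.root, 1)
    n = len(tree.root.haplotypes)
    labels = np.zeros(n, dtype=np.int32)
    for c, members in enumerate(clusters, start=1):
        for row in members:
            labels[row] = c
    if (labels == 0).any():
        raise AssertionError("cluster cut failed to partition all haplotypes")
    return ClusterAssignment(tree.focal, labels, len(clusters))


def cluster_panel(
    panel: PhasedHaplotypePanel,
    focal_indices=None,
    depth: int = DEFAULT_CUT_DEPTH,
) -> list[ClusterAssignment]:
    """Window -> tree -> depth cut for every requested focal marker."""
    windows = focal_windows(panel, focal_indices)
    out: list[ClusterAssignment] = []
    for w in windows:
        assignment = cut_clusters(build_local_tree(panel, w), depth=depth)
        assignment.marker_id = panel.markers.marker_id[w.focal]
        out.append(assignment)
    logger.info("built %d local trees (mean clusters %.2f)", len(out),
                float(np.mean([a.n_clusters for a in out])) if out else 0.0)
    return out


def assignments_to_tsv(panel: PhasedHaplotypePanel, assignments, path) -> None:
    """Export cluster assignments: focal marker, haplotype row, individual, phase, label."""
    with open(path, "w") as fh:
        fh.write("focal_marker_id\thaplotype_row\tindividual_id\tphase\tcluster_label\n")
        for a in assignments:
            mid = a.marker_id or str(a.focal)
            for row, lab in enumerate(a.labels):
                fh.write(f"{mid}\t{row}\t{panel.individual_ids[row // 2]}\t{row % 2}\t{lab}\n")
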