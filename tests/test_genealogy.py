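import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_panel
from oracles import brute_force_partition, brute_force_window
from treehap import genealogy as gn
from treehap.panel import MarkerMap, PhasedHaplotypePanel


# ---------------------------------------------------------------------------
# four-gamete rule
# ---------------------------------------------------------------------------

def test_four_gametes_observed_means_incompatible():
    a = np.array([0, 0, 1, 1])
    b = np.array([0, 1, 0, 1])
    assert gn.four_gamete_compatible(a, b) is False


def test_identical_and_complementary_columns_compatible():
    a = np.array([0, 1, 1, 0, 1])
    assert gn.four_gamete_compatible(a, a) is True
    assert gn.four_gamete_compatible(a, 1 - a) is True


def test_length_mismatch_is_error():
    with pytest.raises(ValueError):
        gn.four_gamete_compatible(np.array([0, 1]), np.array([0, 1, 0]))


@settings(deadline=None, max_examples=60)
@given(st.integers(4, 16), st.integers(0, 10_000))
def test_four_gamete_symmetry_and_flip_invariance(n, seed):
    rng = np.random.default_rng(seed)
    a, b = rng.integers(0, 2, n), rng.integers(0, 2, n)
    r = gn.four_gamete_compatible(a, b)
    assert gn.four_gamete_compatible(b, a) == r
    assert gn.four_gamete_compatible(1 - a, b) == r
    assert gn.four_gamete_compatible(a, 1 - b) == r


# ---------------------------------------------------------------------------
# focal windows
# ---------------------------------------------------------------------------

def test_single_marker_chromosome_window():
    h = np.array([[0], [1], [0], [1]], dtype=np.uint8)
    panel = PhasedHaplotypePanel(h, ["a", "b"], MarkerMap(["m0"], [1], [100]))
    assert gn.focal_window(panel, 0) == gn.FocalWindow(0, 0, 1)


def test_fully_compatible_panel_spans_chromosome():
    # nested carrier sets are pairwise compatible
    h = np.array([
        [1, 1, 1, 1],
        [0, 1, 1, 1],
        [0, 0, 1, 1],
        [0, 0, 0, 1],
        [0, 0, 0, 0],
        [0, 0, 0, 0],
    ], dtype=np.uint8)
    panel = PhasedHaplotypePanel(h, ["a", "b", "c"],
                                 MarkerMap([f"m{j}" for j in range(4)], [1] * 4, np.arange(1, 5)))
    for focal in range(4):
        assert gn.focal_window(panel, focal) == gn.FocalWindow(focal, 0, 4)


def test_engineered_incompatibility_matches_exhaustive_search(small_panel):
    for focal in range(small_panel.n_markers):
        w = gn.focal_window(small_panel, focal)
        assert (w.start, w.end) == brute_force_window(small_panel, focal)


@pytest.mark.parametrize("seed", range(8))
def test_random_panels_match_exhaustive_search(seed):
    panel = random_panel(seed, 10, 9)
    for focal in range(panel.n_markers):
        w = gn.focal_window(panel, focal)
        assert (w.start, w.end) == brute_force_window(panel, focal)


def test_windows_never_cross_chromosomes():
    panel = random_panel(3, 8, 12, n_chromosomes=3)
    for w in gn.focal_windows(panel):
        lo, hi = panel.markers.chrom_range(w.focal)
        assert lo <= w.start <= w.focal < w.end <= hi


# ---------------------------------------------------------------------------
# tree construction
# ---------------------------------------------------------------------------

def test_focal_only_window_gives_two_leaf_children():
    h = np.array([[0], [1], [0], [1]], dtype=np.uint8)
    panel = PhasedHaplotypePanel(h, ["a", "b"], MarkerMap(["m0"], [1], [100]))
    tree = gn.build_local_tree(panel, gn.FocalWindow(0, 0, 1))
    kids = tree.root.children
    assert len(kids) == 2 and all(k.is_leaf for k in kids)
    assert {frozenset(k.haplotypes) for k in kids} == {frozenset({1, 3}), frozenset({0, 2})}


def test_root_splits_on_focal_allele():
    panel = random_panel(11, 12, 8)
    for w in gn.focal_windows(panel):
        tree = gn.build_local_tree(panel, w)
        carriers = frozenset(np.flatnonzero(panel.haplotypes[:, w.focal]).tolist())
        assert {c.haplotypes for c in tree.root.children} == {
            carriers, frozenset(range(panel.n_haplotypes)) - carriers}


def test_incompatible_window_is_rejected(small_panel):
    # markers 0 and 2 exhibit all four gametes
    with pytest.raises(ValueError, match="no perfect phylogeny|four-gamete"):
        gn.build_local_tree(small_panel, gn.FocalWindow(0, 0, 3))


def test_monomorphic_focal_is_rejected():
    h = np.zeros((4, 2), dtype=np.uint8)
    h[:, 1] = [0, 1, 0, 1]
    panel = PhasedHaplotypePanel(h, ["a", "b"], MarkerMap(["m0", "m1"], [1, 1], [1, 2]))
    with pytest.raises(ValueError, match="monomorphic"):
        gn.build_local_tree(panel, gn.FocalWindow(0, 0, 1))


# ---------------------------------------------------------------------------
# depth cut
# ---------------------------------------------------------------------------

def _complete_tree(depth_levels: int) -> gn.LocalTree:
    """Complete binary tree over 2**depth_levels haplotypes."""
    n = 2 ** depth_levels

    def build(lo, hi):
        node = gn.TreeNode(range(lo, hi))
        if hi - lo > 1:
            mid = (lo + hi) // 2
            node.children = [build(lo, mid), build(mid, hi)]
        return node

    return gn.LocalTree(0, gn.FocalWindow(0, 0, 1), build(0, n))


def test_complete_tree_cuts_into_eight_clusters():
    tree = _complete_tree(5)  # deeper than the cut
    assignment = gn.cut_clusters(tree, depth=3)
    assert assignment.n_clusters == 8
    # each cluster is one depth-4 subtree of 4 haplotypes
    assert np.array_equal(np.bincount(assignment.labels)[1:], np.full(8, 4))


def test_two_leaf_tree_gives_two_clusters():
    tree = _complete_tree(1)
    assignment = gn.cut_clusters(tree, depth=3)
    assert assignment.n_clusters == 2


def test_depth_must_be_positive():
    with pytest.raises(ValueError):
        gn.cut_clusters(_complete_tree(2), depth=0)


def _partition(labels) -> set[frozenset]:
    return {frozenset(np.flatnonzero(labels == c).tolist()) for c in np.unique(labels)}


def test_unbalanced_fixture_matches_path_oracle(small_panel):
    w = gn.focal_window(small_panel, 4)
    assignment = gn.cut_clusters(gn.build_local_tree(small_panel, w))
    assert _partition(assignment.labels) == brute_force_partition(small_panel, w)


@pytest.mark.parametrize("seed", range(10))
def test_random_partitions_match_split_nesting_oracle(seed):
    panel = random_panel(seed + 100, 12, 8)
    for w in gn.focal_windows(panel):
        assignment = gn.cut_clusters(gn.build_local_tree(panel, w))
        assert _partition(assignment.labels) == brute_force_partition(panel, w)


@pytest.mark.parametrize("seed", range(6))
def test_cluster_invariants(seed):
    panel = random_panel(seed + 40, 14, 10)
    for w in gn.focal_windows(panel):
        a = gn.cut_clusters(gn.build_local_tree(panel, w))
        labels = a.labels
        assert labels.shape == (panel.n_haplotypes,)
        assert 1 <= a.n_clusters <= 8
        assert set(np.unique(labels)) == set(range(1, a.n_clusters + 1))
        # identical window sequences share a cluster
        seqs = {}
        for row in range(panel.n_haplotypes):
            key = panel.haplotypes[row, w.start:w.end].tobytes()
            seqs.setdefault(key, set()).add(labels[row])
        assert all(len(v) == 1 for v in seqs.values())
        # different focal alleles never share a cluster
        focal = panel.haplotypes[:, w.focal]
        for c in range(1, a.n_clusters + 1):
            assert len(set(focal[labels == c])) == 1


def test_determinism():
    panel = random_panel(77, 16, 12)
    a1 = gn.cluster_panel(panel)
    a2 = gn.cluster_panel(panel)
    for x, y in zip(a1, a2):
        assert np.array_equal(x.labels, y.labels) and x.n_clusters == y.n_clusters


def test_assignment_tsv_export(tmp_path, small_panel):
    w = gn.focal_window(small_panel, 3)
    a = gn.cut_clusters(gn.build_local_tree(small_panel, w))
    a.marker_id = "m3"
    out = tmp_path / "clusters.tsv"
    gn.assignments_to_tsv(small_panel, [a], out)
    lines = out.read_text().splitlines()
    assert lines[0].startswith("focal_marker_id") and len(lines) == 1 + small_panel.n_haplotypes
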