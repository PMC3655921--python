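from __future__ import annotations

import numpy as np
import pytest

from treehap.design import ColumnMeta, CovariateMatrix
from treehap.panel import MarkerMap, PhasedHaplotypePanel


def random_panel(seed: int, n_haplotypes: int, n_markers: int,
                 n_chromosomes: int = 1) -> PhasedHaplotypePanel:
    """Random polymorphic panel (iid columns), minor-allele coded."""
    if n_haplotypes % 2:
        raise ValueError("need an even number of haplotype rows")
    rng = np.random.default_rng(seed)
    while True:
        h = (rng.random((n_haplotypes, n_markers)) < rng.uniform(0.2, 0.8, n_markers)).astype(np.uint8)
        poly = (h.mean(axis=0) > 0) & (h.mean(axis=0) < 1)
        if poly.all():
            break
    per_chrom = n_markers // n_chromosomes
    chrom = np.repeat(np.arange(1, n_chromosomes + 1), per_chrom)
    chrom = np.concatenate([chrom, np.full(n_markers - len(chrom), n_chromosomes)])
    pos = np.concatenate([np.arange(1, int((chrom == c).sum()) + 1) * 1000
                          for c in range(1, n_chromosomes + 1)])
    panel = PhasedHaplotypePanel(
        h,
        [f"I{i:03d}" for i in range(n_haplotypes // 2)],
        MarkerMap([f"m{j}" for j in range(n_markers)], chrom, pos),
    )
    panel.recode_to_minor()
    return panel


def random_design(seed: int, n: int, k: int) -> CovariateMatrix:
    rng = np.random.default_rng(seed)
    x = rng.binomial(2, rng.uniform(0.1, 0.5, k), size=(n, k)).astype(np.int16)
    return CovariateMatrix(x, [f"S{i:03d}" for i in range(n)],
                           [ColumnMeta("marker", f"m{j}") for j in range(k)])


@pytest.fixture
def small_panel() -> PhasedHaplotypePanel:
    """Six haplotypes (three individuals), five markers, one engineered
    four-gamete incompatibility between markers 0 and 2."""
    h = np.array(
        [
            # m0 m1 m2 m3 m4
            [1, 1, 1, 0, 0],
            [1, 1, 0, 0, 0],
            [1, 0, 0, 0, 1],
            [0, 0, 0, 1, 1],
            [0, 0, 0, 1, 0],
            [0, 0, 1, 0, 0],
        ],
        dtype=np.uint8,
    )
    return PhasedHaplotypePanel(
        h,
        ["A", "B", "C"],
        MarkerMap([f"m{j}" for j in range(5)], np.ones(5, int), np.arange(1, 6) * 100),
    )
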