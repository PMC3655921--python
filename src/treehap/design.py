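"""Model-ready covariate matrices (marker allele counts or cluster copy counts)."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genealogy import ClusterAssignment
from .panel import PhasedHaplotypePanel

logger = logging.getLogger(__name__)

DEFAULT_MAF_MIN = 0.01


@dataclass(frozen=True)
class ColumnMeta:
    """Provenance of a design column: source marker and, for clusters, the label."""

    kind: str  # "marker" | "haplotype"
    marker_id: str
    cluster: int | None = None

    def __str__(self) -> str:
        return self.marker_id if self.cluster is None else f"{self.marker_id}:c{self.cluster}"


@dataclass
class CovariateMatrix:
    """N x K counts with per-column provenance.

    Marker columns hold minor-allele counts in {0,1,2}; haplotype columns
    hold cluster copy counts in {0,1,2}, and the columns of one focal
    marker's tree sum to 2 in every row.
    """

    values: np.ndarray
    individual_ids: list[str] = field(repr=False)
    columns: list[ColumnMeta] = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=np.int16)
        self.individual_ids = list(self.individual_ids)
        if self.values.shape != (len(self.individual_ids), len(self.columns)):
            raise ValueError("values shape must be (n individuals, n columns)")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 2):
            raise ValueError("covariate counts must be in {0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def column_freq(self) -> np.ndarray:
        """Per-column allele/cluster frequency f = column mean / 2."""
        return self.values.mean(axis=0) / 2.0

    def rows_for(self, ids: list[str]) -> "CovariateMatrix":
        index = {v: i for i, v in enumerate(self.individual_ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise KeyError(f"individuals absent from design: {missing[:5]}")
        sel = [index[i] for i in ids]
        return CovariateMatrix(self.values[sel], ids, self.columns)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=[str(c) for c in self.columns])
        df.insert(0, "id", self.individual_ids)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CovariateMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"id": str}, comment="#")
        ids = df["id"].tolist()
        cols = []
        for name in df.columns[1:]:
            if ":c" in name:
                mid, lab = name.rsplit(":c", 1)
                cols.append(ColumnMeta("haplotype", mid, int(lab)))
            else:
                cols.append(ColumnMeta("marker", name))
        return cls(df.iloc[:, 1:].to_numpy(), ids, cols)

    def to_triplets(self, path) -> None:
        """Sparse text export: individual_id, column, count (non-zero entries)."""
        rows, cols = np.nonzero(self.values)
        with open(path, "w") as fh:
            fh.write("individual_id\tcolumn\tcount\n")
            for r, c in zip(rows, cols):
                fh.write(f"{self.individual_ids[r]}\t{self.columns[c]}\t{self.values[r, c]}\n")


def marker_design(panel: PhasedHaplotypePanel, maf_min: float = DEFAULT_MAF_MIN) -> CovariateMatrix:
    """Minor-allele counts per individual, dropping markers with MAF below ``maf_min``."""
    freq = panel.allele_freq()
    keep = freq >= maf_min
    removed = int((~keep).sum())
    if removed:
        logger.info("MAF filter removed %d of %d markers (MAF < %g)", removed, panel.n_markers, maf_min)
    counts = panel.genotype_counts()[:, keep]
    columns = [ColumnMeta("marker", panel.markers.marker_id[j]) for j in np.flatnonzero(keep)]
    return CovariateMatrix(counts, panel.individual_ids, columns)


def haplotype_design(
    panel: PhasedHaplotypePanel,
    assignments: list[ClusterAssignment],
    min_freq: float = 0.0,
) -> CovariateMatrix:
    """Cluster copy counts: one column per (focal marker, cluster label).

    Cluster columns are not frequency-filtered by default: within one tree
    they are complementary (rows sum to 2) and dropping would break that.
    An optional ``min_freq`` drop is available for experimentation.
    """
    n = panel.n_individuals
    blocks: list[np.ndarray] = []
    columns: list[ColumnMeta] = []
    seen: dict[bytes, int] = {}
    duplicates = 0
    for a in assignments:
        if a.labels.shape[0] != panel.n_haplotypes:
            raise ValueError(
                f"assignment at focal {a.focal} references {a.labels.shape[0]} haplotype rows, "
                f"panel has {panel.n_haplotypes}"
            )
        mid = a.marker_id or panel.markers.marker_id[a.focal]
        mat = np.zeros((n, a.n_clusters), dtype=np.int16)
        lab_m = a.labels[0::2]
        lab_p = a.labels[1::2]
        for c in range(1, a.n_clusters + 1):
            mat[:, c - 1] = (lab_m == c).astype(np.int16) + (lab_p == c).astype(np.int16)
        for c in range(a.n_clusters):
            col = mat[:, c]
            if min_freq > 0.0 and col.mean() / 2.0 < min_freq:
                continue
            key = col.tobytes()
            duplicates += key in seen
            seen[key] = seen.get(key, 0) + 1
            blocks.append(col)
            columns.append(ColumnMeta("haplotype", mid, c + 1))
    if not blocks:
        raise ValueError("no cluster columns produced")
    if duplicates:
        logger.info("haplotype design contains %d duplicated column(s) from overlapping trees "
                    "(kept; no deduplication)", duplicates)
    return CovariateMatrix(np.column_stack(blocks), panel.individual_ids, columns)
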