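"""Core containers: marker maps, phased haplotype panels and response tables.

The haplotype panel is the substrate for everything downstream: local
genealogical trees are built on its columns, design matrices on its rows.
It stores one row per haplotype (two consecutive rows per individual, in
the phase order of the input) and one column per bi-allelic marker, with
allele 1 being the panel-wide minor allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class MarkerMap:
    """Genomic coordinates of the markers in a panel.

    Positions are 1-based base pairs as in VCF; marker indices used
    everywhere else in the package are 0-based with half-open windows.
    """

    marker_id: list[str]
    chromosome: np.ndarray
    position: np.ndarray

    def __post_init__(self) -> None:
        self.marker_id = list(self.marker_id)
        self.chromosome = np.asarray(self.chromosome, dtype=np.int64)
        self.position = np.asarray(self.position, dtype=np.int64)
        m = len(self.marker_id)
        if self.chromosome.shape != (m,) or self.position.shape != (m,):
            raise ValueError("marker_id, chromosome and position must have equal length")
        if len(set(self.marker_id)) != m:
            raise ValueError("duplicate marker ids in map")
        if np.any(self.position < 0):
            raise ValueError("negative marker position")
        for lo, hi in self.chrom_bounds().values():
            if np.any(np.diff(self.position[lo:hi]) <= 0):
                raise ValueError("positions must be strictly increasing within a chromosome")

    @property
    def n_markers(self) -> int:
        return len(self.marker_id)

    def chrom_bounds(self) -> dict[int, tuple[int, int]]:
        """Half-open marker-index range of each chromosome block.

        Markers must be stored grouped by chromosome (the natural VCF order).
        """
        bounds: dict[int, tuple[int, int]] = {}
        if self.n_markers == 0:
            return bounds
        start = 0
        for j in range(1, self.n_markers):
            if self.chromosome[j] != self.chromosome[start]:
                c = int(self.chromosome[start])
                if c in bounds:
                    raise ValueError("markers of one chromosome are not contiguous")
                bounds[c] = (start, j)
                start = j
        c = int(self.chromosome[start])
        if c in bounds:
            raise ValueError("markers of one chromosome are not contiguous")
        bounds[c] = (start, self.n_markers)
        return bounds

    def chrom_range(self, marker: int) -> tuple[int, int]:
        """Marker-index range of the chromosome containing ``marker``."""
        return self.chrom_bounds()[int(self.chromosome[marker])]

    def subset(self, keep: np.ndarray) -> "MarkerMap":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        ids = [self.marker_id[int(j)] for j in keep]
        return MarkerMap(ids, self.chromosome[keep], self.position[keep])


@dataclass
class PhasedHaplotypePanel:
    """Phased, imputation-complete haplotypes: 2N rows by M binary columns.

    Rows 2i and 2i+1 belong to individual i (first and second allele of the
    GT field; no parental-origin inference is attempted). Entries are 0/1
    with 1 = minor allele after loading.
    """

    haplotypes: np.ndarray
    individual_ids: list[str]
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.haplotypes = np.ascontiguousarray(self.haplotypes, dtype=np.uint8)
        self.individual_ids = list(self.individual_ids)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotype matrix must be 2-D")
        if self.haplotypes.shape[0] != 2 * len(self.individual_ids):
            raise ValueError("panel must have exactly two haplotype rows per individual")
        if self.haplotypes.shape[1] != self.markers.n_markers:
            raise ValueError("haplotype matrix and marker map disagree on marker count")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicate individual ids")
        vals = np.unique(self.haplotypes)
        if vals.size and (vals.min() < 0 or vals.max() > 1):
            raise ValueError("haplotype entries must be 0/1 (missing data not allowed)")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Frequency of allele 1 per marker (≤ 0.5 after minor recoding)."""
        return self.haplotypes.mean(axis=0)

    def recode_to_minor(self) -> np.ndarray:
        """Flip columns so allele 1 is the minor allele; returns flipped mask."""
        flip = self.haplotypes.mean(axis=0) > 0.5
        if flip.any():
            self.haplotypes[:, flip] = 1 - self.haplotypes[:, flip]
        return flip

    def genotype_counts(self) -> np.ndarray:
        """N x M matrix of minor-allele counts per individual (0/1/2)."""
        h = self.haplotypes
        return (h[0::2].astype(np.int16) + h[1::2].astype(np.int16))

    def subset_markers(self, keep: np.ndarray) -> "PhasedHaplotypePanel":
        keep = np.asarray(keep)
        return PhasedHaplotypePanel(self.haplotypes[:, keep], self.individual_ids, self.markers.subset(keep))


REQUIRED_RESPONSE_COLUMNS = ("id", "dre")


@dataclass
class ResponseTable:
    """Deregressed breeding values (DRE) with their information content.

    Each record carries a reliability in [0, 1] (possibly filled in from an
    effective daughter contribution, EDC) and optionally a birth date used
    for the reference/test split.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in REQUIRED_RESPONSE_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"response table missing required column '{col}'")
        if len(df) == 0:
            raise ValueError("no records in response table")
        if "reliability" not in df.columns:
            df["reliability"] = np.nan
        if "edc" not in df.columns:
            df["edc"] = np.nan
        if "birth_date" not in df.columns:
            df["birth_date"] = pd.NaT
        df["id"] = df["id"].astype(str)
        if df["id"].duplicated().any():
            raise ValueError("duplicate ids in response table")
        missing_both = df["reliability"].isna() & df["edc"].isna()
        if missing_both.any():
            bad = df.loc[missing_both, "id"].iloc[0]
            raise ValueError(f"record '{bad}' has neither reliability nor EDC")
        rel = df["reliability"].dropna()
        if ((rel < 0) | (rel > 1)).any():
            raise ValueError("reliability outside [0, 1]")
        edc = df["edc"].dropna()
        if (edc < 0).any():
            raise ValueError("negative EDC")
        df["birth_date"] = pd.to_datetime(df["birth_date"], errors="raise")
        self.data = df.reset_index(drop=True)

    @property
    def ids(self) -> list[str]:
        return self.data["id"].tolist()

    @property
    def dre(self) -> np.ndarray:
        return self.data["dre"].to_numpy(dtype=float)

    @property
    def reliability(self) -> np.ndarray:
        return self.data["reliability"].to_numpy(dtype=float)

    @property
    def birth_date(self) -> pd.Series:
        return self.data["birth_date"]

    def aligned(self, ids: list[str]) -> "ResponseTable":
        """Reorder/subset records to match ``ids`` exactly."""
        indexed = self.data.set_index("id")
        missing = [i for i in ids if i not in indexed.index]
        if missing:
            raise KeyError(f"ids absent from response table: {missing[:5]}")
        return ResponseTable(indexed.loc[ids].reset_index())
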