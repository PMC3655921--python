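"""Readers and writers for phased VCF panels and response tables."""

from __future__ import annotations

import gzip
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .panel import MarkerMap, PhasedHaplotypePanel, ResponseTable
from .weights import reliability_from_edc

logger = logging.getLogger(__name__)


def _chrom_label(chrom: str) -> int:
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    try:
        return int(c)
    except ValueError as exc:
        raise ValueError(f"non-integer chromosome label '{chrom}'") from exc


def read_phased_vcf(path: str | Path) -> PhasedHaplotypePanel:
    """Load a phased, bi-allelic SNP VCF into a haplotype panel.

    Every GT must use the phased '|' separator and be complete; alleles are
    recoded after loading so 1 is the panel-wide minor allele at each marker.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError("VCF contains no samples")
    rows: list[np.ndarray] = []
    ids: list[str] = []
    chroms: list[int] = []
    positions: list[int] = []
    for v in vcf:
        if len(v.ALT) != 1:
            raise ValueError(f"multi-allelic record at {v.CHROM}:{v.POS}; only bi-allelic SNPs supported")
        col = np.empty(2 * len(samples), dtype=np.uint8)
        for s, gt in enumerate(v.genotypes):
            a, b, phased = gt[0], gt[1], gt[-1]
            if a < 0 or b < 0:
                raise ValueError(f"missing genotype at {v.CHROM}:{v.POS} for sample '{samples[s]}'")
            if not phased:
                raise ValueError(f"unphased genotype at {v.CHROM}:{v.POS} for sample '{samples[s]}'")
            col[2 * s] = a
            col[2 * s + 1] = b
        rows.append(col)
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}")
        chroms.append(_chrom_label(v.CHROM))
        positions.append(v.POS)
    if not rows:
        raise ValueError("VCF contains no variant records")
    panel = PhasedHaplotypePanel(
        np.column_stack(rows),
        samples,
        MarkerMap(ids, np.array(chroms), np.array(positions)),
    )
    flipped = panel.recode_to_minor()
    if flipped.any():
        logger.info("recoded %d marker(s) so allele 1 is the minor allele", int(flipped.sum()))
    return panel


def write_phased_vcf(panel: PhasedHaplotypePanel, path: str | Path) -> None:
    """Write a panel as a minimal phased VCF 4.2 (gzip if path ends in .gz).

    Allele 1 (the stored minor allele) is written as ALT, so a round trip
    reproduces the matrix exactly.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    h = panel.haplotypes
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=treehap\n")
        for c, (lo, hi) in panel.markers.chrom_bounds().items():
            fh.write(f"##contig=<ID={c},length={int(panel.markers.position[hi - 1]) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(panel.individual_ids) + "\n")
        for j in range(panel.n_markers):
            gts = "\t".join(f"{h[2 * i, j]}|{h[2 * i + 1, j]}" for i in range(panel.n_individuals))
            fh.write(
                f"{panel.markers.chromosome[j]}\t{panel.markers.position[j]}\t{panel.markers.marker_id[j]}"
                f"\tA\tG\t.\t.\t.\tGT\t{gts}\n"
            )


def read_response_table(path: str | Path, h2: float | None = None) -> ResponseTable:
    """Read a tab-delimited response table (columns: id, dre, reliability|edc, birth_date).

    Where reliability is absent it is filled from EDC via
    reliability = EDC/(EDC + k), k = (4 - h2)/h2, which requires ``h2``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if len(df) == 0:
        raise ValueError("no records in response table")
    if "reliability" not in df.columns and "edc" not in df.columns:
        raise ValueError("response table needs a 'reliability' or 'edc' column")
    if "reliability" not in df.columns:
        df["reliability"] = np.nan
    if "edc" in df.columns:
        fill = df["reliability"].isna() & df["edc"].notna()
        if fill.any():
            if h2 is None:
                raise ValueError("h2 is required to fill reliabilities from EDC")
            df.loc[fill, "reliability"] = reliability_from_edc(df.loc[fill, "edc"].to_numpy(), h2)
    return ResponseTable(df)


def write_response_table(response: ResponseTable, path: str | Path) -> None:
    response.data.to_csv(path, sep="\t", index=False)
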