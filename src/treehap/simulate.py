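"""Forward-in-time synthetic cattle population with known truth.

A small Wright-Fisher founder population (random union of gametes,
recombination at 1 cM/Mb, light mutation) is run for a configurable number
of generations to build up linkage disequilibrium, then a final half-sib
structured generation (few sires, many dams) mimics a progeny-tested bull
population. Traits are additive: either QTL act through a marker's minor
allele count, or — in branch-haplotypic mode — through a depth-3 branch of
the local genealogy at the QTL, so the causal unit is a haplotype cluster
rather than any single SNP. Responses emulate deregressed EBV:
DRE = offset + TBV + eps with var(eps) = var(TBV) (1 - r2)/r2 and the
reliability r2 derived from a simulated effective daughter contribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genealogy
from .panel import MarkerMap, PhasedHaplotypePanel, ResponseTable
from .weights import k_factor, reliability_from_edc

logger = logging.getLogger(__name__)


@dataclass
class SimConfig:
    """Study conditions for the synthetic population.

    Defaults are a desk-scale analogue of a progeny-tested dairy population:
    100 founders drifting for 80 generations over a 100 cM chromosome,
    a final half-sib generation of 500 bulls, 20 additive QTL, and EDC
    distributed so the typical DRE reliability is about 0.75.
    """

    n_individuals: int = 500
    n_markers: int = 600          # per chromosome
    n_chromosomes: int = 1
    ne: int = 100                 # effective founder population size
    generations: int = 80
    h2: float = 0.5
    n_qtl: int = 20
    qtl_mode: str = "marker"      # "marker" | "branch"
    edc_median: float | None = None   # default: 3k, giving reliability 0.75
    edc_sigma: float = 0.5        # lognormal sigma; 0 = constant EDC
    dre_offset: float = 100.0
    reference_fraction: float = 0.75
    split_date: str = "2001-10-01"
    n_sires: int | None = None    # default: max(2, N // 25)
    chrom_length_cm: float = 100.0
    mutation_rate: float = 1e-4   # per site per gamete, burn-in generations only
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_individuals", "n_markers", "n_chromosomes", "ne", "generations", "n_qtl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must be in (0, 1)")
        if self.qtl_mode not in ("marker", "branch"):
            raise ValueError("qtl_mode must be 'marker' or 'branch'")
        if not 0.0 < self.reference_fraction < 1.0:
            raise ValueError("reference_fraction must be in (0, 1)")


@dataclass
class SimTruth:
    """What the generator knows and the models must recover."""

    tbv: np.ndarray | None = None
    qtl_markers: np.ndarray | None = None
    qtl_effects: np.ndarray | None = None
    causal_clusters: list | None = None
    sire_of: np.ndarray | None = None
    dam_of: np.ndarray | None = None


def _meiosis(h0: np.ndarray, h1: np.ndarray, bounds, morgans: float, rng) -> np.ndarray:
    """One gamete from a parent's two haplotypes; Poisson crossovers per chromosome."""
    gamete = np.empty_like(h0)
    for lo, hi in bounds:
        m = hi - lo
        cur = int(rng.integers(2))
        n_co = int(rng.poisson(morgans))
        if n_co == 0 or m < 2:
            gamete[lo:hi] = (h0 if cur == 0 else h1)[lo:hi]
            continue
        cuts = np.sort(rng.integers(1, m, n_co))
        phase = (cur + np.searchsorted(cuts, np.arange(m), side="right")) % 2
        seg = np.where(phase == 0, h0[lo:hi], h1[lo:hi])
        gamete[lo:hi] = seg
    return gamete


def _next_generation(h: np.ndarray, n_off: int, bounds, morgans: float, rng,
                     sires=None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n_par = h.shape[0] // 2
    out = np.empty((2 * n_off, h.shape[1]), dtype=h.dtype)
    if sires is None:
        sire_idx = rng.integers(0, n_par, n_off)
    else:
        sire_idx = rng.choice(sires, n_off)
    dam_idx = rng.integers(0, n_par, n_off)
    clash = dam_idx == sire_idx
    while clash.any():
        dam_idx[clash] = rng.integers(0, n_par, int(clash.sum()))
        clash = dam_idx == sire_idx
    for i in range(n_off):
        s, d = sire_idx[i], dam_idx[i]
        out[2 * i] = _meiosis(h[2 * s], h[2 * s + 1], bounds, morgans, rng)
        out[2 * i + 1] = _meiosis(h[2 * d], h[2 * d + 1], bounds, morgans, rng)
    return out, sire_idx, dam_idx


def simulate_panel(config: SimConfig) -> tuple[PhasedHaplotypePanel, SimTruth]:
    """Phased panel with drift-generated LD and a half-sib final generation."""
    rng = np.random.default_rng(config.seed)
    m_total = config.n_markers * config.n_chromosomes
    bounds = [(c * config.n_markers, (c + 1) * config.n_markers) for c in range(config.n_chromosomes)]
    morgans = config.chrom_length_cm / 100.0
    freq0 = rng.uniform(0.1, 0.9, m_total)
    h = (rng.random((2 * config.ne, m_total)) < freq0).astype(np.uint8)
    for _ in range(config.generations):
        h, _, _ = _next_generation(h, config.ne, bounds, morgans, rng)
        if config.mutation_rate > 0:
            flips = rng.random(h.shape) < config.mutation_rate
            h ^= flips.astype(np.uint8)
    n_sires = config.n_sires or max(2, config.n_individuals // 25)
    sires = rng.choice(config.ne, size=min(n_sires, config.ne), replace=False)
    h, sire_of, dam_of = _next_generation(h, config.n_individuals, bounds, morgans, rng, sires=sires)

    poly = h.mean(axis=0)
    keep = (poly > 0) & (poly < 1)
    if not keep.any():
        raise ValueError("simulated panel is monomorphic; increase ne, generations or initial frequencies")
    if not keep.all():
        logger.info("dropping %d monomorphic marker(s) from the simulated panel", int((~keep).sum()))
    kept_idx = np.flatnonzero(keep)
    length_bp = int(config.chrom_length_cm * 1e6)
    chrom = np.empty(m_total, dtype=np.int64)
    pos = np.empty(m_total, dtype=np.int64)
    names = []
    for c, (lo, hi) in enumerate(bounds, start=1):
        chrom[lo:hi] = c
        pos[lo:hi] = np.linspace(1, length_bp, hi - lo).astype(np.int64)
    names = [f"c{chrom[j]}m{j - (chrom[j] - 1) * config.n_markers}" for j in range(m_total)]
    markers = MarkerMap([names[j] for j in kept_idx], chrom[kept_idx], pos[kept_idx])
    ids = [f"ID{i:05d}" for i in range(config.n_individuals)]
    panel = PhasedHaplotypePanel(h[:, kept_idx], ids, markers)
    panel.recode_to_minor()
    return panel, SimTruth(sire_of=sire_of, dam_of=dam_of)


def _branch_tbv(panel, qtl, effects, rng, depth=genealogy.DEFAULT_CUT_DEPTH):
    """TBV when each QTL's causal allele is one depth-cut genealogy branch."""
    n = panel.n_individuals
    tbv = np.zeros(n)
    causal = []
    windows = genealogy.focal_windows(panel, qtl)
    for w, eff in zip(windows, effects):
        assignment = genealogy.cut_clusters(genealogy.build_local_tree(panel, w), depth=depth)
        freq = np.bincount(assignment.labels, minlength=assignment.n_clusters + 1)[1:] / panel.n_haplotypes
        mid_freq = np.flatnonzero((freq >= 0.05) & (freq <= 0.95)) + 1
        candidates = mid_freq if mid_freq.size else np.arange(1, assignment.n_clusters + 1)
        label = int(rng.choice(candidates))
        copies = ((assignment.labels[0::2] == label).astype(float)
                  + (assignment.labels[1::2] == label).astype(float))
        tbv += eff * copies
        causal.append((w.focal, label))
    return tbv, causal


def simulate_response(panel: PhasedHaplotypePanel, truth: SimTruth, config: SimConfig) -> ResponseTable:
    """Simulate QTL, TBV and DRE-like responses with stated reliabilities.

    Fills ``truth`` in place (tbv, qtl positions/effects, causal clusters).
    """
    rng = np.random.default_rng(config.seed + 1)
    freq = panel.allele_freq()
    eligible = np.flatnonzero(freq >= 0.05)
    if eligible.size < config.n_qtl:
        raise ValueError("not enough polymorphic markers for the requested QTL count")
    qtl = np.sort(rng.choice(eligible, config.n_qtl, replace=False))
    effects = rng.standard_normal(config.n_qtl)
    if config.qtl_mode == "marker":
        tbv = panel.genotype_counts()[:, qtl].astype(float) @ effects
        causal = None
    else:
        tbv, causal = _branch_tbv(panel, qtl, effects, rng)
    if np.var(tbv) <= 0:
        raise ValueError("true breeding values are constant; increase QTL count or panel diversity")
    truth.tbv = tbv
    truth.qtl_markers = qtl
    truth.qtl_effects = effects
    truth.causal_clusters = causal

    k = k_factor(config.h2)
    median = config.edc_median if config.edc_median is not None else 3.0 * k
    if config.edc_sigma > 0:
        edc = rng.lognormal(np.log(median), config.edc_sigma, config.n_individuals)
    else:
        edc = np.full(config.n_individuals, median)
    r2 = reliability_from_edc(edc, config.h2)
    keep = r2 > 0
    if not keep.all():
        logger.warning("excluding %d record(s) with zero reliability", int((~keep).sum()))
    var_tbv = float(np.var(tbv))
    eps = rng.standard_normal(config.n_individuals) * np.sqrt(var_tbv * (1.0 - r2) / np.maximum(r2, 1e-12))
    dre = config.dre_offset + tbv + eps

    split = np.datetime64(config.split_date)
    n_ref = int(round(config.reference_fraction * config.n_individuals))
    perm = rng.permutation(config.n_individuals)
    dates = np.empty(config.n_individuals, dtype="datetime64[D]")
    dates[perm[:n_ref]] = split - rng.integers(30, 3000, n_ref).astype("timedelta64[D]")
    dates[perm[n_ref:]] = split + rng.integers(1, 1500, config.n_individuals - n_ref).astype("timedelta64[D]")

    df = pd.DataFrame({
        "id": panel.individual_ids,
        "dre": dre,
        "reliability": r2,
        "edc": edc,
        "birth_date": dates,
    })[keep]
    return ResponseTable(df)


def simulate_study(config: SimConfig) -> tuple[PhasedHaplotypePanel, SimTruth, ResponseTable]:
    """Convenience: panel + truth + response in one call."""
    panel, truth = simulate_panel(config)
    response = simulate_response(panel, truth, config)
    return panel, truth, response


def truth_to_tsv(truth: SimTruth, ids: list[str], path) -> None:
    df = pd.DataFrame({"id": ids, "tbv": truth.tbv})
    df.to_csv(path, sep="\t", index=False)
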