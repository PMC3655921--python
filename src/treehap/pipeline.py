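"""End-to-end workflow: (simulate) -> cluster -> design -> fit -> validate."""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import BayesFit, ChainSettings, MixturePrior, fit_bayes, predict_dgv
from .design import CovariateMatrix, haplotype_design, marker_design
from .gblup import build_grm, fit_gblup
from .genealogy import assignments_to_tsv, cluster_panel
from .io import read_phased_vcf, read_response_table, write_phased_vcf, write_response_table
from .panel import PhasedHaplotypePanel, ResponseTable
from .simulate import SimConfig, simulate_study, truth_to_tsv
from .validate import ValidationReport, validate_predictions
from .weights import weights as residual_weights

logger = logging.getLogger(__name__)

MODELS = ("gblup", "bayesB", "bayesBpi", "bayesC", "bayesCpi")


@dataclass
class RunConfig:
    """Flat configuration for one pipeline run (readable from a key: value file)."""

    # inputs: either simulate=True or paths to a phased VCF + response TSV
    simulate: bool = True
    panel_path: str | None = None
    response_path: str | None = None
    outdir: str | None = None
    # model
    model: str = "gblup"
    covariate: str = "marker"     # "marker" | "haplotype"
    h2: float = 0.5
    pi: float | None = None       # None: 0.99 for fixed-pi models
    chain_length: int = 10_000
    burn_in: int = 1_000
    maf_min: float = 0.01
    cut_depth: int = 3
    ridge: float = 1e-6
    reml: bool = True
    split_date: str = "2001-10-01"
    seed: int = 0
    # simulation conditions (used when simulate=True)
    n_individuals: int = 500
    n_markers: int = 600
    n_chromosomes: int = 1
    n_qtl: int = 20
    qtl_mode: str = "marker"
    reference_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model '{self.model}'; choose from {MODELS}")
        if self.covariate not in ("marker", "haplotype"):
            raise ValueError("covariate must be 'marker' or 'haplotype'")
        if not self.simulate and (self.panel_path is None or self.response_path is None):
            raise ValueError("panel_path and response_path are required when simulate=False")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config file must be a flat key: value mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: RunConfig
    report: ValidationReport
    dgv: pd.DataFrame = field(repr=False)
    fit: object = field(repr=False)
    pi_used: float | None = None
    counts: dict = field(default_factory=dict)


def _provenance(config: RunConfig) -> str:
    return f"# treehap {__version__} seed={config.seed} config={config.config_hash()}\n"


def _write_tsv(path: Path, config: RunConfig, writer) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config))
    with open(path, "a") as fh:
        writer(fh)


def build_design(panel: PhasedHaplotypePanel, covariate: str, maf_min: float,
                 cut_depth: int = 3):
    """Marker or haplotype design for a panel; returns (X, assignments or None, counts)."""
    xm = marker_design(panel, maf_min=maf_min)
    counts = {"markers_total": panel.n_markers, "markers_kept": xm.n_columns}
    if covariate == "marker":
        return xm, None, counts
    kept_ids = {c.marker_id for c in xm.columns}
    focal = [j for j, mid in enumerate(panel.markers.marker_id) if mid in kept_ids]
    assignments = cluster_panel(panel, focal, depth=cut_depth)
    xh = haplotype_design(panel, assignments)
    counts["trees_built"] = len(assignments)
    counts["cluster_columns"] = xh.n_columns
    counts["covariate_ratio"] = xh.n_columns / xm.n_columns
    return xh, assignments, counts


def _split(response: ResponseTable, split_date: str):
    dates = response.birth_date
    if dates.isna().any():
        raise ValueError("birth_date required for the reference/test split")
    cut = pd.Timestamp(split_date)
    is_ref = (dates < cut).to_numpy()
    if is_ref.sum() < 3 or (~is_ref).sum() < 3:
        raise ValueError("reference/test split leaves fewer than 3 records on one side")
    return is_ref


def fit_model(config: RunConfig, X: CovariateMatrix, response: ResponseTable):
    """Fit the configured model on the reference split; DGV for everyone.

    Returns (fit object, dgv aligned with X rows, pi used for mixture models).
    """
    is_ref = _split(response, config.split_date)
    resp_ref = ResponseTable(response.data[is_ref])
    rel = resp_ref.reliability
    if np.any(rel <= 0):
        keep = rel > 0
        logger.warning("excluding %d zero-reliability reference record(s)", int((~keep).sum()))
        resp_ref = ResponseTable(resp_ref.data[keep])
    y = resp_ref.dre
    w = residual_weights(resp_ref.reliability)
    row_of = {v: i for i, v in enumerate(X.individual_ids)}
    ref_rows = np.array([row_of[i] for i in resp_ref.ids])
    pi_used: float | None = None

    if config.model == "gblup":
        grm = build_grm(X, ridge=config.ridge)
        fit = fit_gblup(y, w, grm, ref=ref_rows, reml=config.reml,
                        var_g=None if config.reml else config.h2 * float(np.var(y)),
                        var_e=None if config.reml else (1 - config.h2) * float(np.var(y)))
        dgv = fit.dgv
    else:
        chain = ChainSettings(config.chain_length, config.burn_in, seed=config.seed)
        x_ref = CovariateMatrix(X.values[ref_rows], resp_ref.ids, X.columns)
        if config.model == "bayesCpi":
            prior = MixturePrior(pi="sampled", h2=config.h2)
            fit = fit_bayes(y, w, x_ref, method="bayesCpi", prior=prior, chain=chain)
            pi_used = fit.pi
        elif config.model == "bayesBpi":
            cpi = fit_bayes(y, w, x_ref, method="bayesCpi",
                            prior=MixturePrior(pi="sampled", h2=config.h2), chain=chain)
            pi_used = cpi.pi
            fit = fit_bayes(y, w, x_ref, method="bayesB",
                            prior=MixturePrior(pi=pi_used, h2=config.h2), chain=chain)
            fit.method = "bayesBpi"
        else:
            pi_used = 0.99 if config.pi is None else config.pi
            method = "bayesB" if config.model == "bayesB" else "bayesC"
            fit = fit_bayes(y, w, x_ref, method=method,
                            prior=MixturePrior(pi=pi_used, h2=config.h2), chain=chain)
        dgv = predict_dgv(fit, X)
    return fit, dgv, pi_used


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full workflow described by ``config``."""
    if config.simulate:
        sim = SimConfig(
            n_individuals=config.n_individuals, n_markers=config.n_markers,
            n_chromosomes=config.n_chromosomes, h2=config.h2, n_qtl=config.n_qtl,
            qtl_mode=config.qtl_mode, reference_fraction=config.reference_fraction,
            split_date=config.split_date, seed=config.seed,
        )
        panel, truth, response = simulate_study(sim)
    else:
        panel = read_phased_vcf(config.panel_path)
        response = read_response_table(config.response_path, h2=config.h2)
        truth = None
        response = ResponseTable(response.data[response.data["id"].isin(panel.individual_ids)])

    X, assignments, counts = build_design(panel, config.covariate, config.maf_min, config.cut_depth)
    logger.info("design: %d individuals x %d columns (%s)", X.n_individuals, X.n_columns, config.covariate)

    fit, dgv, pi_used = fit_model(config, X, response)

    is_ref = _split(response, config.split_date)
    test = response.data[~is_ref]
    row_of = {v: i for i, v in enumerate(X.individual_ids)}
    test_rows = np.array([row_of[i] for i in test["id"]])
    report = validate_predictions(test["dre"].to_numpy(), dgv[test_rows],
                                  test["reliability"].to_numpy())
    logger.info(report.format_log())

    dgv_df = pd.DataFrame({"id": X.individual_ids, "dgv": dgv})
    result = PipelineResult(config, report, dgv_df, fit, pi_used, counts)

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        if config.simulate:
            write_phased_vcf(panel, out / "panel.vcf")
            write_response_table(response, out / "response.tsv")
            if truth is not None and truth.tbv is not None:
                truth_to_tsv(truth, panel.individual_ids, out / "truth.tsv")
        if assignments is not None:
            assignments_to_tsv(panel, assignments, out / "clusters.tsv")
        _write_tsv(out / "dgv.tsv", config, lambda fh: dgv_df.to_csv(fh, sep="\t", index=False))
        _write_tsv(out / "report.tsv", config, lambda fh: fh.write(
            "accuracy\taccuracy_se\tslope\tslope_se\tn_test\tmean_reliability\tpi\n"
            f"{report.accuracy:.6f}\t{report.accuracy_se:.6f}\t{report.slope:.6f}"
            f"\t{report.slope_se:.6f}\t{report.n_test}\t{report.mean_reliability:.6f}"
            f"\t{'' if pi_used is None else f'{pi_used:.4f}'}\n"))
        if isinstance(fit, BayesFit):
            _write_tsv(out / "effects.tsv", config, lambda fh: _effects_body(fit, fh))
            if fit.pi_samples is not None:
                _write_tsv(out / "pi_trace.tsv", config, lambda fh: fh.write(
                    "pi\n" + "\n".join(f"{p:.6f}" for p in fit.pi_samples) + "\n"))
    return result


def _effects_body(fit: BayesFit, fh) -> None:
    fh.write("column\tposterior_mean\tinclusion_frequency\ttrain_mean\n")
    for c, a, d, m in zip(fit.columns, fit.effects, fit.inclusion, fit.column_means):
        fh.write(f"{c}\t{a:.8g}\t{d:.6f}\t{m:.6f}\n")
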