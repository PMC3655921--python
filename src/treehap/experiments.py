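"""Reusable study runners for benchmarking and sanity experiments.

These bundle the package's own components into the standard synthetic
studies used throughout the documentation: a sparse-mixture fixture with
known pi for checking the BayesCpi sampler, and the marker-versus-haplotype
prediction study on the branch-haplotypic population. Problem sizes are
desk-scale defaults chosen once (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bayes import ChainSettings, MixturePrior, fit_bayes, predict_dgv
from .design import ColumnMeta, CovariateMatrix
from .pipeline import build_design
from .simulate import SimConfig, simulate_study
from .validate import validate_predictions
from .weights import weights as residual_weights

# the standard sparse-mixture fixture: 2% of 1000 covariates carry effects
STANDARD_N = 500
STANDARD_K = 1000
STANDARD_NONZERO = 20
STANDARD_H2 = 0.5


def make_mixture_fixture(n: int = STANDARD_N, k: int = STANDARD_K,
                         n_nonzero: int = STANDARD_NONZERO, h2: float = STANDARD_H2,
                         seed: int = 0):
    """Independent 0/1/2 covariates, sparse normal effects, h2-scaled noise.

    Returns (y, w, X, true_effects); weights are 1 (homogeneous records).
    """
    rng = np.random.default_rng(seed)
    f = rng.uniform(0.05, 0.5, k)
    x = rng.binomial(2, f, size=(n, k)).astype(np.int16)
    cols = [ColumnMeta("marker", f"m{j}") for j in range(k)]
    X = CovariateMatrix(x, [f"S{i:04d}" for i in range(n)], cols)
    a = np.zeros(k)
    idx = rng.choice(k, n_nonzero, replace=False)
    a[idx] = rng.standard_normal(n_nonzero)
    xc = x - x.mean(axis=0)
    g = xc @ a
    var_g = float(np.var(g))
    e = rng.standard_normal(n) * np.sqrt(var_g * (1.0 - h2) / h2)
    y = 100.0 + g + e
    return y, np.ones(n), X, a


@dataclass
class StudyResult:
    """Accuracy/bias of one model on one simulated study."""

    accuracy: float
    slope: float
    pi: float | None = None


def _expected_nonzero_pi(k: int, expected: int = 50) -> float:
    """Fixed pi so the prior expected number of non-zero covariates is ``expected``."""
    return max(0.0, 1.0 - expected / k)


def haplotype_vs_marker_study(
    seed: int,
    n_individuals: int = 1000,
    n_markers: int = 2000,
    n_qtl: int = 20,
    h2: float = 0.5,
    chain_length: int = 2000,
    burn_in: int = 400,
    method: str = "bayesC",
) -> dict[str, StudyResult]:
    """One branch-haplotypic simulation, fit with marker and haplotype designs.

    The causal alleles are depth-3 genealogy branches, so the haplotype
    design contains the causal covariates exactly while markers only tag
    them. Returns per-design validation statistics on the date-split test set.
    """
    cfg = SimConfig(n_individuals=n_individuals, n_markers=n_markers, n_qtl=n_qtl,
                    h2=h2, qtl_mode="branch", seed=seed)
    panel, truth, response = simulate_study(cfg)
    is_ref = (response.birth_date < np.datetime64(cfg.split_date)).to_numpy()
    ref = response.data[is_ref]
    test = response.data[~is_ref]
    row_of = {v: i for i, v in enumerate(panel.individual_ids)}
    out: dict[str, StudyResult] = {}
    for kind in ("marker", "haplotype"):
        X, _, _ = build_design(panel, kind, maf_min=0.01)
        ref_rows = np.array([row_of[i] for i in ref["id"]])
        test_rows = np.array([row_of[i] for i in test["id"]])
        x_ref = CovariateMatrix(X.values[ref_rows], ref["id"].tolist(), X.columns)
        y = ref["dre"].to_numpy()
        w = residual_weights(ref["reliability"].to_numpy())
        chain = ChainSettings(chain_length, burn_in, seed=seed)
        if method == "bayesCpi":
            prior = MixturePrior(pi="sampled", h2=h2)
        else:
            prior = MixturePrior(pi=_expected_nonzero_pi(X.n_columns), h2=h2)
        fit = fit_bayes(y, w, x_ref, method=method, prior=prior, chain=chain)
        dgv = predict_dgv(fit, X)
        report = validate_predictions(test["dre"].to_numpy(), dgv[test_rows],
                                      test["reliability"].to_numpy())
        out[kind] = StudyResult(report.accuracy, report.slope,
                                fit.pi if method == "bayesCpi" else None)
    return out
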