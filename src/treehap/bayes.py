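"""Weighted Bayesian mixture models: BayesB, BayesC, BayesCpi, BayesBpi.

The model is y = 1*mu + sum_i z_i a_i + e with e ~ N(0, D sig2_e),
D = diag(1/w_i). Each covariate effect is zero with prior probability pi,
otherwise normal with variance sig2_a that is either shared by all
covariates (BayesC, BayesCpi) or covariate-specific (BayesB, BayesBpi);
both variance structures carry scaled inverse-chi-square priors with 4.2
degrees of freedom. In BayesCpi, pi itself gets a uniform(0,1) prior and is
sampled; BayesBpi is BayesB run with pi fixed at BayesCpi's posterior mean.

Sampling is the indicator-integrated single-site Gibbs scheme with residual
updating: per covariate the inclusion indicator is sampled with the effect
integrated out of the likelihood, then the effect from its normal full
conditional; the variances, overall mean and (for BayesCpi) pi from their
closed-form full conditionals. Direct genomic values are accumulated per
iteration as sum_i z_i a_i over the post-burn-in samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._gibbs import sweep_covariates
from .design import ColumnMeta, CovariateMatrix

logger = logging.getLogger(__name__)

METHODS = ("bayesB", "bayesBpi", "bayesC", "bayesCpi")
DEFAULT_NU_A = 4.2
DEFAULT_NU_E = 4.0


@dataclass
class ChainSettings:
    """Gibbs chain geometry; the defaults match routine practice (10k/1k)."""

    n_iter: int = 10_000
    burn_in: int = 1_000
    seed: int = 0
    thin: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn-in must be shorter than the chain")
        if self.thin < 1:
            raise ValueError("thinning interval must be >= 1")


@dataclass
class MixturePrior:
    """Mixture prior: P(a_i = 0) = pi, else a_i ~ N(0, sig2_a).

    ``pi='sampled'`` puts a uniform(0,1) prior on pi (BayesCpi). When
    ``s2_a`` is None the scale is derived from ``var_target`` (defaulting to
    h2 times the weighted variance of y) via
    S2 = var_target (nu-2) / (nu (1-pi) sum_j 2 f_j (1-f_j)).
    """

    pi: float | str = 0.99
    nu_a: float = DEFAULT_NU_A
    s2_a: float | None = None
    var_target: float | None = None
    h2: float = 0.5

    def __post_init__(self) -> None:
        if isinstance(self.pi, str):
            if self.pi != "sampled":
                raise ValueError("pi must be a fraction or 'sampled'")
        elif not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        if self.nu_a <= 2:
            raise ValueError("nu_a must exceed 2 for the prior scale to exist")


def derive_scale(var_target: float, X: CovariateMatrix, pi: float, nu_a: float = DEFAULT_NU_A) -> float:
    """Prior scale S2 so the mixture's expected genetic variance hits ``var_target``."""
    if nu_a <= 2:
        raise ValueError("nu_a must exceed 2")
    if not 0.0 <= pi < 1.0:
        raise ValueError("pi must lie in [0, 1) to derive a finite scale")
    f = X.column_freq()
    ssq = float(np.sum(2.0 * f * (1.0 - f)))
    if ssq <= 0:
        raise ValueError("all covariate columns are monomorphic")
    return var_target * (nu_a - 2.0) / (nu_a * (1.0 - pi) * ssq)


@dataclass
class BayesFit:
    """Posterior summaries of one chain."""

    method: str
    mu: float
    effects: np.ndarray
    inclusion: np.ndarray
    dgv: np.ndarray
    var_e: float
    pi: float
    pi_samples: np.ndarray | None
    columns: list[ColumnMeta] = field(repr=False)
    column_means: np.ndarray = field(repr=False, default=None)
    n_samples: int = 0
    effect_trace: np.ndarray | None = field(repr=False, default=None)

    def effects_to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("column\tposterior_mean\tinclusion_frequency\n")
            for c, a, d in zip(self.columns, self.effects, self.inclusion):
                fh.write(f"{c}\t{a:.8g}\t{d:.6f}\n")


def _weighted_var(y: np.ndarray, w: np.ndarray) -> float:
    m = float(np.average(y, weights=w))
    return float(np.average((y - m) ** 2, weights=w))


def fit_bayes(
    y,
    w,
    X: CovariateMatrix,
    method: str = "bayesCpi",
    prior: MixturePrior | None = None,
    chain: ChainSettings | None = None,
    fixed_var_a: float | None = None,
    fixed_var_e: float | None = None,
    store_effect_trace: bool = False,
    randomize_order: bool = False,
) -> BayesFit:
    """Run one Gibbs chain and return posterior summaries.

    ``fixed_var_a``/``fixed_var_e`` pin the corresponding variances instead
    of sampling them (used for conjugate cross-checks). For bayesBpi supply
    the BayesCpi posterior mean as ``prior.pi``.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method '{method}'; choose from {METHODS}")
    prior = prior or MixturePrior(pi="sampled" if method == "bayesCpi" else 0.99)
    chain = chain or ChainSettings()
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    n, k = X.values.shape
    if len(y) != n or len(w) != n:
        raise ValueError("y and w must align with the rows of X")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    common_var = method in ("bayesC", "bayesCpi")
    sample_pi = method == "bayesCpi"
    if sample_pi and prior.pi != "sampled":
        logger.info("bayesCpi always samples pi; the prior pi value is used only for initialization")
    pi = 0.5 if prior.pi == "sampled" else float(prior.pi)
    if pi >= 1.0 and not sample_pi:
        logger.warning("pi = 1 excludes every covariate; returning all-zero effects")

    col_means = X.values.mean(axis=0)
    xt = np.ascontiguousarray((X.values - col_means).T, dtype=np.float64)
    ztwz = (xt ** 2) @ w

    var_y = _weighted_var(y, w)
    var_target = prior.var_target if prior.var_target is not None else prior.h2 * var_y
    if prior.s2_a is not None:
        s2_a = prior.s2_a
    else:
        pi_for_scale = min(pi, 1.0 - 1e-6)
        s2_a = derive_scale(var_target, X, pi_for_scale, prior.nu_a)
    nu_a = prior.nu_a
    nu_e = DEFAULT_NU_E
    s2_e = max(var_y - var_target, 0.05 * var_y)

    rng = np.random.default_rng(chain.seed)
    mu = float(np.average(y, weights=w))
    a = np.zeros(k)
    delta = np.zeros(k, dtype=np.int8)
    var_a = np.full(k, fixed_var_a if fixed_var_a is not None else s2_a * nu_a / (nu_a - 2.0))
    var_e = fixed_var_e if fixed_var_e is not None else var_y
    r = y - mu
    sw = w.sum()

    kept = 0
    mu_sum = 0.0
    a_sum = np.zeros(k)
    d_sum = np.zeros(k)
    dgv_sum = np.zeros(n)
    var_e_sum = 0.0
    pi_trace: list[float] = []
    trace = [] if store_effect_trace else None

    def log_odds(p: float) -> float:
        if p <= 0.0:
            return np.inf
        if p >= 1.0:
            return -np.inf
        return float(np.log((1.0 - p) / p))

    lo = log_odds(pi)
    order = np.arange(k)
    for t in range(chain.n_iter):
        u = rng.random(k)
        zn = rng.standard_normal(k)
        if randomize_order:
            order = rng.permutation(k)
            sweep_covariates(xt[order], w, r, a_v := a[order], d_v := delta[order],
                             var_a[order], ztwz[order], var_e, lo, u, zn)
            a[order] = a_v
            delta[order] = d_v
        else:
            sweep_covariates(xt, w, r, a, delta, var_a, ztwz, var_e, lo, u, zn)
        # overall mean
        mu_new = float(w @ (r + mu)) / sw + rng.standard_normal() * np.sqrt(var_e / sw)
        r += mu - mu_new
        mu = mu_new
        # effect variance(s)
        m = int(delta.sum())
        if fixed_var_a is None:
            if common_var:
                ssq = float(a @ a)
                var_a[:] = (nu_a * s2_a + ssq) / rng.chisquare(nu_a + m)
            else:
                chi_in = rng.chisquare(nu_a + 1.0, k)
                chi_out = rng.chisquare(nu_a, k)
                var_a = np.where(delta == 1, (nu_a * s2_a + a ** 2) / chi_in, nu_a * s2_a / chi_out)
        # residual variance
        if fixed_var_e is None:
            sse = float(w @ (r * r))
            var_e = (sse + nu_e * s2_e) / rng.chisquare(nu_e + n)
        if not np.isfinite(var_e) or not np.isfinite(mu):
            raise FloatingPointError(f"non-finite state at iteration {t}")
        # mixture proportion
        if sample_pi:
            pi = float(rng.beta(k - m + 1.0, m + 1.0))
            lo = log_odds(pi)
        if t >= chain.burn_in and (t - chain.burn_in) % chain.thin == 0:
            kept += 1
            # sampling runs on centered covariates; report on the raw 0/1/2
            # scale, where DGV = X a and the intercept absorbs the centering
            cm_a = float(col_means @ a)
            mu_sum += mu - cm_a
            a_sum += a
            d_sum += delta
            dgv_sum += (y - mu - r) + cm_a
            var_e_sum += var_e
            if sample_pi:
                pi_trace.append(pi)
            if trace is not None:
                trace.append(a.copy())

    pi_samples = np.array(pi_trace) if sample_pi else None
    pi_out = float(pi_samples.mean()) if sample_pi else (float(prior.pi) if prior.pi != "sampled" else pi)
    return BayesFit(
        method=method,
        mu=mu_sum / kept,
        effects=a_sum / kept,
        inclusion=d_sum / kept,
        dgv=dgv_sum / kept,
        var_e=var_e_sum / kept,
        pi=pi_out,
        pi_samples=pi_samples,
        columns=list(X.columns),
        column_means=col_means.astype(float),
        n_samples=kept,
        effect_trace=np.array(trace) if trace is not None else None,
    )


def predict_dgv(fit: BayesFit, X_new: CovariateMatrix) -> np.ndarray:
    """DGV for new individuals: X_new times the posterior-mean effects.

    Columns of ``X_new`` must match the training columns by provenance.
    DGV are on the raw covariate scale (an all-zero row has DGV 0); by
    linearity this agrees with the per-iteration training accumulator.
    """
    if list(X_new.columns) != list(fit.columns):
        missing = [str(c) for c in fit.columns if c not in X_new.columns]
        raise ValueError(f"design columns do not match training columns; missing: {missing[:8]}")
    return X_new.values.astype(float) @ fit.effects
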