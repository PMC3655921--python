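"""Genomic relationship matrices and the weighted GBLUP mixed model.

Model: y = 1*mu + Z g + e with g ~ N(0, G sig2_g) and e ~ N(0, D sig2_e),
D = diag(1/w_i). G follows VanRaden's first method: columns of the 0/1/2
covariate matrix are centered by twice their frequency and G = Mc Mc' / s
with s = sum_j 2 f_j (1 - f_j); each haplotype-cluster column is treated
exactly like a bi-allelic locus. Because the cluster columns of one tree
are linearly dependent after centering, a small ridge keeps haplotype-based
G invertible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .design import CovariateMatrix

logger = logging.getLogger(__name__)

DEFAULT_RIDGE = 1e-6


@dataclass
class GRM:
    """Realized genomic relationship matrix with its construction constants."""

    matrix: np.ndarray = field(repr=False)
    scale: float
    ridge: float
    kind: str
    frequencies: np.ndarray = field(repr=False, default=None)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def build_grm(X: CovariateMatrix, ridge: float = DEFAULT_RIDGE) -> GRM:
    """VanRaden method-1 GRM from a 0/1/2 covariate matrix.

    Zero-variance columns are skipped (they contribute neither to Mc nor to
    the scale s). ``ridge`` is added to the diagonal afterwards.
    """
    if X.n_individuals < 2:
        raise ValueError("need at least two individuals")
    vals = X.values.astype(float)
    keep = vals.std(axis=0) > 0
    if not keep.any():
        raise ValueError("all covariate columns have zero variance")
    vals = vals[:, keep]
    f = vals.mean(axis=0) / 2.0
    mc = vals - 2.0 * f
    s = float(np.sum(2.0 * f * (1.0 - f)))
    g = mc @ mc.T / s
    if ridge:
        g[np.diag_indices_from(g)] += ridge
    kind = X.columns[0].kind if X.columns else "marker"
    return GRM(g, s, ridge, kind, f)


def compare_grms(g1: GRM, g2: GRM) -> tuple[float, float]:
    """Pearson correlations of the diagonals and of the strict lower triangles."""
    a, b = g1.matrix, g2.matrix
    if a.shape != b.shape:
        raise ValueError("GRMs must cover the same individuals in the same order")
    diag = float(np.corrcoef(np.diag(a), np.diag(b))[0, 1])
    il = np.tril_indices_from(a, k=-1)
    off = float(np.corrcoef(a[il], b[il])[0, 1])
    return diag, off


@dataclass
class GBLUPFit:
    """Solution of the weighted mixed-model equations."""

    mu: float
    g: np.ndarray
    var_g: float
    var_e: float
    dgv: np.ndarray
    reml_iterations: int = 0
    reml_trajectory: list = field(default_factory=list, repr=False)


def _solve_mme(y, w, grr_inv, lam):
    n = len(y)
    c = np.empty((n + 1, n + 1))
    c[0, 0] = w.sum()
    c[0, 1:] = w
    c[1:, 0] = w
    c[1:, 1:] = np.diag(w) + lam * grr_inv
    rhs = np.concatenate(([w @ y], w * y))
    try:
        cho = linalg.cho_factor(c)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "mixed-model equations not positive definite; increase the GRM ridge"
        ) from exc
    sol = linalg.cho_solve(cho, rhs)
    return sol[0], sol[1:], cho


def fit_gblup(
    y,
    w,
    G: GRM,
    ref=None,
    var_g: float | None = None,
    var_e: float | None = None,
    reml: bool = False,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> GBLUPFit:
    """Weighted GBLUP fit with fixed variance components or EM-REML.

    ``y`` and ``w`` are aligned with the reference individuals indexed by
    ``ref`` into G (default: all of G). DGV of individuals outside ``ref``
    are predicted from the corresponding G blocks, which is identical to
    predicting from the centered covariates when G = Mc Mc' / s.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    n_all = G.n
    ref = np.arange(n_all) if ref is None else np.asarray(ref, dtype=int)
    if len(y) != len(ref) or len(w) != len(ref):
        raise ValueError("y, w and ref must be aligned")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    grr = G.matrix[np.ix_(ref, ref)]
    try:
        cho_g = linalg.cho_factor(grr)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError("reference GRM block is singular; increase the ridge") from exc
    grr_inv = linalg.cho_solve(cho_g, np.eye(len(ref)))

    if reml:
        vy = float(np.var(y))
        floor = 1e-8 * vy
        var_g = vy / 2.0 if var_g is None else var_g
        var_e = vy / 2.0 if var_e is None else var_e
        trajectory = []
        it = 0
        for it in range(1, max_iter + 1):
            lam = var_e / var_g
            mu, g, cho_c = _solve_mme(y, w, grr_inv, lam)
            cinv = linalg.cho_solve(cho_c, np.eye(len(ref) + 1))
            cgg = cinv[1:, 1:]
            resid = y - mu - g
            new_var_e = float(y @ (w * resid)) / (len(ref) - 1)
            new_var_g = float(g @ grr_inv @ g + new_var_e * np.trace(grr_inv @ cgg)) / len(ref)
            trajectory.append((new_var_g, new_var_e))
            if new_var_e <= 0:
                raise RuntimeError(f"EM-REML produced a non-positive residual variance: {trajectory[-3:]}")
            at_floor = new_var_g < floor
            if at_floor:
                logger.warning("EM-REML genetic variance hit its lower bound; no genomic signal")
                new_var_g = floor
            # convergence measured against var(y) so a boundary component cannot stall it
            delta = max(abs(new_var_g - var_g), abs(new_var_e - var_e)) / vy
            var_g, var_e = new_var_g, new_var_e
            if delta < tol or at_floor:
                break
        else:
            raise RuntimeError(f"EM-REML did not converge in {max_iter} iterations; "
                               f"last updates: {trajectory[-5:]}")
        n_iter = it
    else:
        if var_g is None or var_e is None:
            raise ValueError("var_g and var_e are required unless reml=True")
        trajectory, n_iter = [], 0

    lam = var_e / var_g
    mu, g, _ = _solve_mme(y, w, grr_inv, lam)
    dgv = np.zeros(n_all)
    dgv[ref] = g
    others = np.setdiff1d(np.arange(n_all), ref)
    if others.size:
        dgv[others] = G.matrix[np.ix_(others, ref)] @ (grr_inv @ g)
    return GBLUPFit(float(mu), g, float(var_g), float(var_e), dgv, n_iter, trajectory)


def grm_to_triplets(G: GRM, ids: list[str], path) -> None:
    """Whitespace id-id-value export of the (lower-triangle) GRM."""
    with open(path, "w") as fh:
        for i in range(G.n):
            for j in range(i + 1):
                fh.write(f"{ids[i]} {ids[j]} {G.matrix[i, j]:.8g}\n")
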