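"""Numba hot loop for the single-site Gibbs covariate sweep.

All random numbers are drawn by the Python driver from one seeded numpy
Generator and passed in, so chains are bit-identical for a given seed and
the kernel itself is purely deterministic arithmetic.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def sweep_covariates(xt, w, r, a, delta, var_a, ztwz, var_e, log_odds, u, zn):
    """One residual-updating pass over all covariates.

    xt: (K, N) centered covariates (transposed for contiguous row access);
    r: residual y - mu - X a, updated in place; a, delta: current effects and
    inclusion indicators, updated in place; var_a: per-covariate effect
    variances; ztwz: precomputed z_j' W z_j; log_odds: log((1-pi)/pi);
    u, zn: per-covariate uniform and standard-normal draws.
    """
    k, n = xt.shape
    for j in range(k):
        zj = ztwz[j]
        if zj <= 0.0:
            continue
        rhs = zj * a[j]
        for i in range(n):
            rhs += xt[j, i] * w[i] * r[i]
        v0 = zj * var_e
        v1 = zj * zj * var_a[j] + v0
        # inclusion indicator with the effect integrated out
        logr = log_odds + 0.5 * (math.log(v0 / v1) + rhs * rhs * (1.0 / v0 - 1.0 / v1))
        if logr > 35.0:
            include = True
        elif logr < -35.0:
            include = False
        else:
            include = u[j] < 1.0 / (1.0 + math.exp(-logr))
        old = a[j]
        if include:
            c = zj + var_e / var_a[j]
            new = rhs / c + zn[j] * math.sqrt(var_e / c)
            delta[j] = 1
        else:
            new = 0.0
            delta[j] = 0
        if new != old:
            diff = old - new
            for i in range(n):
                r[i] += xt[j, i] * diff
            a[j] = new
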