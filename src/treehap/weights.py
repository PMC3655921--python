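"""Reliabilities and residual weights for deregressed breeding values.

The reliability of a DRE with effective daughter contribution EDC is
EDC / (EDC + k) with k = (4 - h2) / h2. Residual heteroscedasticity is
handled through per-record weights w = r / (1 - r), with r capped at 0.98
so no record's weight exceeds 49.
"""

from __future__ import annotations

import logging

import numpy as np

from .panel import ResponseTable

logger = logging.getLogger(__name__)

RELIABILITY_CAP = 0.98


def k_factor(h2: float) -> float:
    if not 0.0 < h2 <= 1.0:
        raise ValueError(f"heritability must be in (0, 1], got {h2}")
    return (4.0 - h2) / h2


def reliability_from_edc(edc, h2: float):
    """Reliability of a DRE given its EDC and the trait heritability."""
    k = k_factor(h2)
    edc = np.asarray(edc, dtype=float)
    if np.any(edc < 0):
        raise ValueError("EDC must be non-negative")
    out = edc / (edc + k)
    return float(out) if out.ndim == 0 else out


def weights(reliability, cap: float = RELIABILITY_CAP):
    """Residual weight w = r/(1-r) with the reliability capped at ``cap``."""
    r = np.asarray(reliability, dtype=float)
    if np.any(r <= 0):
        raise ValueError("record carries no information (reliability <= 0); exclude it upstream")
    if np.any(r > 1):
        raise ValueError("reliability above 1")
    r = np.minimum(r, cap)
    out = r / (1.0 - r)
    return float(out) if out.ndim == 0 else out


def weight_vector(response: ResponseTable, cap: float = RELIABILITY_CAP):
    """Per-record weights for a response table, dropping zero-information records.

    Returns (kept ids, weight array, capped reliabilities used).
    """
    rel = response.reliability
    keep = rel > 0
    if not keep.all():
        dropped = int((~keep).sum())
        logger.warning("dropping %d record(s) with reliability <= 0 (undefined weight)", dropped)
    ids = [i for i, k in zip(response.ids, keep) if k]
    capped = np.minimum(rel[keep], cap)
    return ids, weights(rel[keep], cap=cap), capped
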