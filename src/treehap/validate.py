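"""Accuracy and bias statistics for genomic predictions on a test set.

Accuracy is the Pearson correlation between DRE and DGV divided by the
square root of the mean DRE reliability in the test set (correcting the
correlation for the noise in the DRE themselves). Bias is the slope of the
ordinary least-squares regression of DRE on DGV; a slope of 1 means the
dispersion of the DGV is neither over- nor under-predicted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


def _check(dre, dgv):
    dre = np.asarray(dre, dtype=float)
    dgv = np.asarray(dgv, dtype=float)
    if dre.shape != dgv.shape or dre.ndim != 1:
        raise ValueError("DRE and DGV must be aligned 1-D vectors")
    if len(dre) < 3:
        raise ValueError("need at least 3 test records")
    if np.var(dgv) == 0:
        raise ValueError("DGV have zero variance")
    return dre, dgv


def accuracy(dre, dgv, reliability) -> tuple[float, float]:
    """(accuracy, SE): cor(DRE, DGV)/sqrt(mean reliability) with a Fisher-type SE.

    The SE is the usual correlation standard error sqrt((1-r^2)/(n-2))
    scaled by the same reliability factor; a convention, since several SE
    choices are defensible here (a bootstrap is available separately).
    """
    dre, dgv = _check(dre, dgv)
    rel = np.asarray(reliability, dtype=float)
    rbar = float(rel.mean())
    if not 0 < rbar <= 1:
        raise ValueError("mean reliability must be in (0, 1]")
    n = len(dre)
    r = float(np.corrcoef(dre, dgv)[0, 1])
    acc = r / np.sqrt(rbar)
    se = float(np.sqrt(max(1.0 - r * r, 0.0) / (n - 2)) / np.sqrt(rbar))
    return acc, se


def bias_regression(dre, dgv) -> tuple[float, float]:
    """(slope, SE) of the OLS regression of DRE on DGV (with intercept)."""
    dre, dgv = _check(dre, dgv)
    res = stats.linregress(dgv, dre)
    return float(res.slope), float(res.stderr)


def bootstrap_accuracy_se(dre, dgv, reliability, n_boot: int = 1000, seed: int = 0) -> float:
    """Bootstrap alternative to the analytic accuracy SE."""
    dre, dgv = _check(dre, dgv)
    rel = np.asarray(reliability, dtype=float)
    rng = np.random.default_rng(seed)
    n = len(dre)
    accs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        if np.var(dgv[idx]) == 0:
            accs[b] = np.nan
            continue
        accs[b] = np.corrcoef(dre[idx], dgv[idx])[0, 1] / np.sqrt(rel[idx].mean())
    return float(np.nanstd(accs, ddof=1))


@dataclass
class ValidationReport:
    accuracy: float
    accuracy_se: float
    slope: float
    slope_se: float
    n_test: int
    mean_reliability: float

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("accuracy\taccuracy_se\tslope\tslope_se\tn_test\tmean_reliability\n")
            fh.write(f"{self.accuracy:.6f}\t{self.accuracy_se:.6f}\t{self.slope:.6f}"
                     f"\t{self.slope_se:.6f}\t{self.n_test}\t{self.mean_reliability:.6f}\n")

    def format_log(self) -> str:
        return (f"validation: n={self.n_test}, mean reliability={self.mean_reliability:.3f}, "
                f"accuracy={self.accuracy:.3f} (SE {self.accuracy_se:.3f}), "
                f"bias slope={self.slope:.3f} (SE {self.slope_se:.3f})")


def validate_predictions(dre, dgv, reliability) -> ValidationReport:
    """Bundle accuracy and bias on one aligned test set."""
    acc, acc_se = accuracy(dre, dgv, reliability)
    slope, slope_se = bias_regression(dre, dgv)
    rel = np.asarray(reliability, dtype=float)
    return ValidationReport(acc, acc_se, slope, slope_se, len(np.asarray(dre)), float(rel.mean()))
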