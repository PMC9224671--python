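"""Linear association machinery.

Per-recording Pearson correlation between paired surface and invasive
feature series, simple linear regression under seeded 10-fold
cross-validation scored by the adjusted coefficient of determination, a
Shapiro-Wilk normality gate that decides between mean and median cohort
aggregation, ablation-induced variation (percent change of per-recording
medians across a procedure transition) and its cross-patient correlation.

Correlations are reported in percent, matching the field's reporting
convention for these analyses.  The regression p-value is the t-test on the
slope of the full-data fit, which for a single predictor coincides exactly
with the Pearson p-value of the same pair — cross-validation changes the
effect-size estimate (R2), not the significance test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

__all__ = [
    "CorrelationResult",
    "RegressionCVResult",
    "pearson",
    "regression_cv",
    "cohort_correlation",
    "shapiro_gate",
    "ca_variation",
    "transition_correlation",
]


@dataclass
class CorrelationResult:
    rho: float      # percent, in [-100, 100]
    p_value: float
    n: int


@dataclass
class RegressionCVResult:
    r2_adjusted: float  # percent, floored at 0
    r2: float           # percent, floored at 0
    p_value: float      # slope t-test == Pearson p for the same pair
    beta0: float
    beta1: float
    eps_var: float      # residual variance of the full-data fit
    k_folds: int
    seed: int


def _clean_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d of equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation in percent, two-sided t-test p."""
    x, y = _clean_pair(x, y)
    if len(x) < 3:
        raise ValueError("need at least 3 finite pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(rho=100.0 * float(r), p_value=float(p), n=len(x))


def regression_cv(x, y, k: int = 10, seed: int = 0) -> RegressionCVResult:
    """Simple linear regression y ~ x under k-fold cross-validation.

    Folds are a seeded random partition of near-equal sizes.  Each training
    fold yields a least-squares line; R2 is computed once from the pooled
    out-of-fold predictions, adjusted for the single predictor as
    ``1 - (1 - R2)(n - 1)/(n - 2)``, and floored at zero before conversion
    to percent (a cross-validated R2 can be negative).  The p-value is the
    slope t-test of the full-data fit.
    """
    x, y = _clean_pair(x, y)
    n = len(x)
    if n < 2 * k:
        raise ValueError(f"n={n} too small for k={k} folds; reduce k")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("regression undefined for zero-variance input")

    pred = np.empty(n)
    kf = KFold(n_splits=k, shuffle=True, random_state=int(seed) % (2 ** 32 - 1))
    for train, test in kf.split(x):
        b1, b0 = np.polyfit(x[train], y[train], 1)
        pred[test] = b0 + b1 * x[test]
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)

    b1_full, b0_full = np.polyfit(x, y, 1)
    resid = y - (b0_full + b1_full * x)
    eps_var = float(np.sum(resid ** 2) / (n - 2))
    p = pearson(x, y).p_value  # slope t-test == Pearson t-test, 1 predictor
    return RegressionCVResult(
        r2_adjusted=100.0 * max(r2_adj, 0.0),
        r2=100.0 * max(r2, 0.0),
        p_value=p, beta0=float(b0_full), beta1=float(b1_full),
        eps_var=eps_var, k_folds=k, seed=int(seed),
    )


def shapiro_gate(values, alpha: float = 0.05) -> tuple[float, float, bool]:
    """Shapiro-Wilk test; returns (W, p, is_normal at alpha)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if not 3 <= len(v) <= 5000:
        raise ValueError("Shapiro-Wilk defined for 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise ValueError("Shapiro-Wilk undefined for a constant vector")
    w, p = stats.shapiro(v)
    return float(w), float(p), bool(p >= alpha)


def cohort_correlation(per_recording: list[CorrelationResult]
                       ) -> tuple[float, float, int]:
    """Aggregate per-recording correlations across a cohort.

    Normality of the correlation values is tested first; the cohort centre
    is their mean when normality holds, else the median (clinical cohorts
    of correlation coefficients rarely pass).  Below 8 recordings the
    Shapiro-Wilk test has essentially no power, so the robust median is
    used unconditionally.  The p-values are aggregated by the same centre.
    Returns (centre rho %, centre p, n recordings).
    """
    if not per_recording:
        raise ValueError("no recordings to aggregate")
    rhos = np.array([r.rho for r in per_recording], dtype=float)
    ps = np.array([r.p_value for r in per_recording], dtype=float)
    centre = np.median
    if len(rhos) >= 8 and np.ptp(rhos) > 0:
        _, _, is_normal = shapiro_gate(rhos)
        if is_normal:
            centre = np.mean
    return float(centre(rhos)), float(centre(ps)), len(rhos)


def ca_variation(before_values, after_values) -> float:
    """Percent ablation-induced change of the per-recording median.

    ``(median(after) / median(before) - 1) * 100``.  Scalar inputs (one
    summary value per recording, e.g. rate-variability indices) are used
    directly.  A zero before-median leaves the variation undefined.
    """
    before = float(np.nanmedian(np.atleast_1d(np.asarray(before_values, float))))
    after = float(np.nanmedian(np.atleast_1d(np.asarray(after_values, float))))
    if before == 0 or not np.isfinite(before) or not np.isfinite(after):
        return float("nan")
    return (after / before - 1.0) * 100.0


def transition_correlation(table: pd.DataFrame, feature: str,
                           transition: str) -> CorrelationResult:
    """Cross-patient correlation of ablation-induced variation.

    ``table`` is tidy with columns (patient, feature, transition,
    cv_surface, cv_invasive); one point per patient.
    """
    sub = table[(table["feature"] == feature)
                & (table["transition"] == transition)]
    x = sub["cv_surface"].to_numpy(dtype=float)
    y = sub["cv_invasive"].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 patients with defined variation pairs")
    return pearson(x[ok], y[ok])
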