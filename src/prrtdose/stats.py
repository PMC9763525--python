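"""Correlation and agreement statistics for paired tracer data.

The battery mirrors what a small imaging cohort with a variable number of
tumours per patient calls for:

* plain Pearson correlation (organs, one point per patient; kidneys enter
  as the left/right mean),
* inter-patient correlation of per-patient tumour means, weighted by the
  number of tumours each patient contributes,
* intra-patient (repeated-measures) correlation: a common slope with
  patient-specific intercepts, the classic analysis-of-covariance
  construction,
* leave-one-out intervals as a stability probe for r,
* Bland-Altman agreement on log ratios, reported as back-transformed
  relative deviations with a normal-based 95% coverage interval,
* the strict tumour-volume filter (PET volume > 5 mL) applied before any
  tumour statistic.

p-values use the t-distribution; sample SDs use the n-1 denominator. The
significance threshold (0.05) is configuration, not baked into the math.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "AgreementResult",
    "P_SIGNIFICANT",
    "pearson",
    "weighted_pearson",
    "rmcorr",
    "loo_interval",
    "log_ratio_bland_altman",
    "filter_tumours",
    "kidney_average",
]

#: Conventional two-sided significance threshold used downstream.
P_SIGNIFICANT = 0.05


@dataclass
class CorrelationResult:
    r: float
    p: float
    slope: float
    intercept: float | None
    n_effective: int
    loo_interval: tuple[float, float] | None = None

    def significant(self, threshold: float = P_SIGNIFICANT) -> bool:
        return self.p < threshold


@dataclass
class AgreementResult:
    """Back-transformed log-ratio agreement, in percent deviation."""

    mean_deviation_pct: float
    ci_low_pct: float
    ci_high_pct: float
    n: int
    level: str
    log_mean: float = 0.0
    log_sd: float = 0.0


def _validate_xy(x, y, min_n=3):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    return x, y


def _p_from_r(r: float, df: int) -> float:
    r = min(max(r, -1.0), 1.0)
    if df <= 0:
        return float("nan")
    if abs(r) == 1.0:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    return float(2.0 * sps.t.sf(abs(t), df))


def pearson(x, y) -> CorrelationResult:
    """Product-moment correlation with OLS slope/intercept and t-test p."""
    x, y = _validate_xy(x, y)
    r, p = sps.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)
    return CorrelationResult(
        r=float(r), p=float(p), slope=float(slope), intercept=float(intercept),
        n_effective=int(x.size),
    )


def weighted_pearson(x, y, w) -> CorrelationResult:
    """Weighted correlation (one mean point per patient, tumour-count weights).

    r is the weighted covariance over the product of weighted SDs;
    slope/intercept come from weighted least squares; p is a t approximation
    with (number of points - 2) degrees of freedom.
    """
    x, y = _validate_xy(x, y)
    w = np.asarray(w, dtype=float)
    if w.shape != x.shape:
        raise ValueError("weights must match x and y")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    wsum = w.sum()
    mx = (w * x).sum() / wsum
    my = (w * y).sum() / wsum
    cov = (w * (x - mx) * (y - my)).sum() / wsum
    vx = (w * (x - mx) ** 2).sum() / wsum
    vy = (w * (y - my) ** 2).sum() / wsum
    r = cov / np.sqrt(vx * vy)
    slope = cov / vx
    intercept = my - slope * mx
    return CorrelationResult(
        r=float(r),
        p=_p_from_r(float(r), x.size - 2),
        slope=float(slope),
        intercept=float(intercept),
        n_effective=int(x.size),
    )


def rmcorr(subject_ids, x, y) -> CorrelationResult:
    """Repeated-measures correlation: common slope, subject intercepts.

    Equivalent to regressing y on x plus subject dummies; r is the signed
    square root of the fraction of the non-subject variance explained by x,
    with N - n_subjects - 1 degrees of freedom. Subjects with a single
    observation cannot inform the slope and are dropped with a warning.
    """
    subject_ids = np.asarray(subject_ids)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (subject_ids.shape == x.shape == y.shape):
        raise ValueError("subject_ids, x and y must have equal length")
    ids, counts = np.unique(subject_ids, return_counts=True)
    singletons = ids[counts < 2]
    if singletons.size:
        warnings.warn(
            f"dropping {singletons.size} subject(s) with a single observation",
            stacklevel=2,
        )
        keep = ~np.isin(subject_ids, singletons)
        subject_ids, x, y = subject_ids[keep], x[keep], y[keep]
        ids = ids[counts >= 2]
    if ids.size < 2:
        raise ValueError("need at least two subjects with repeated observations")

    xc = x.copy()
    yc = y.copy()
    for s in ids:
        sel = subject_ids == s
        xc[sel] -= x[sel].mean()
        yc[sel] -= y[sel].mean()
    sxx = (xc * xc).sum()
    if sxx == 0:
        raise ValueError("no within-subject variation in x")
    slope = (xc * yc).sum() / sxx
    ss_effect = slope * slope * sxx
    ss_resid = ((yc - slope * xc) ** 2).sum()
    if ss_effect + ss_resid == 0:
        raise ValueError("no within-subject variation in y")
    r = np.sign(slope) * np.sqrt(ss_effect / (ss_effect + ss_resid))
    df = x.size - ids.size - 1
    return CorrelationResult(
        r=float(r),
        p=_p_from_r(float(r), df),
        slope=float(slope),
        intercept=None,
        n_effective=int(df),
    )


def loo_interval(units, corr_fn) -> tuple[float, float]:
    """(min r, max r) when recomputing a correlation leaving one unit out.

    ``units`` is a sequence of analysis units (e.g. per-patient tuples);
    ``corr_fn`` maps a list of units to a CorrelationResult. Subsets on
    which the correlation is degenerate are skipped with a warning.
    """
    units = list(units)
    if len(units) < 4:
        raise ValueError("need at least 4 units for a leave-one-out analysis")
    rs = []
    for i in range(len(units)):
        subset = units[:i] + units[i + 1:]
        try:
            rs.append(corr_fn(subset).r)
        except (ValueError, ZeroDivisionError) as err:
            warnings.warn(f"leave-one-out subset {i} degenerate: {err}",
                          stacklevel=2)
    if not rs:
        raise ValueError("all leave-one-out subsets were degenerate")
    return (float(min(rs)), float(max(rs)))


def log_ratio_bland_altman(
    pred,
    meas,
    level: str = "tumour",
    patient_ids=None,
    z: float = 1.959963984540054,
) -> AgreementResult:
    """Agreement of two positive measurements on the log-ratio scale.

    d = ln(pred/meas); the mean and mean +/- z*SD are back-transformed as
    (exp(x) - 1) * 100%. With ``level="patient"`` the per-patient means of
    the tumour values are formed first, so each patient contributes one
    deviation.
    """
    pred = np.asarray(pred, dtype=float)
    meas = np.asarray(meas, dtype=float)
    if pred.shape != meas.shape:
        raise ValueError("pred and meas must have equal length")
    if np.any(pred <= 0) or np.any(meas <= 0):
        raise ValueError("all values must be positive for a log-ratio analysis")
    if level == "patient":
        if patient_ids is None:
            raise ValueError("patient_ids required for patient-level analysis")
        df = pd.DataFrame(
            {"pid": np.asarray(patient_ids), "pred": pred, "meas": meas}
        )
        g = df.groupby("pid").mean()
        pred, meas = g["pred"].to_numpy(), g["meas"].to_numpy()
    elif level != "tumour":
        raise ValueError(f"unknown level {level!r}")
    d = np.log(pred / meas)
    mean = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    to_pct = lambda v: (np.exp(v) - 1.0) * 100.0  # noqa: E731
    return AgreementResult(
        mean_deviation_pct=float(to_pct(mean)),
        ci_low_pct=float(to_pct(mean - z * sd)),
        ci_high_pct=float(to_pct(mean + z * sd)),
        n=int(d.size),
        level=level,
        log_mean=mean,
        log_sd=sd,
    )


def filter_tumours(
    records: pd.DataFrame,
    volume_cutoff_ml: float = 5.0,
    volume_column: str = "volume_pet_ml",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Strictly keep tumours with PET volume above the cutoff.

    Rows with a missing volume are routed to the excluded table with a
    reason column. The boundary is strict: a volume exactly at the cutoff is
    excluded.
    """
    if volume_column not in records.columns:
        raise ValueError(f"records lack a {volume_column!r} column")
    vol = records[volume_column]
    missing = vol.isna()
    kept = records[~missing & (vol > volume_cutoff_ml)].copy()
    excluded = records[missing | (vol <= volume_cutoff_ml)].copy()
    excluded["exclusion_reason"] = np.where(
        missing[missing | (vol <= volume_cutoff_ml)],
        "missing volume",
        f"volume <= {volume_cutoff_ml} mL",
    )
    return kept, excluded


def kidney_average(left, right):
    """Mean of left and right kidney values; single kidneys pass through."""
    if left is None and right is None:
        raise ValueError("at least one kidney value required")
    if left is None or right is None:
        warnings.warn("single kidney: passing the available value through",
                      stacklevel=2)
        return left if left is not None else right
    return 0.5 * (left + right)
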