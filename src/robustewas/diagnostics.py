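"""Post-hoc quality diagnostics for association scans.

Three tools:

* genomic inflation lambda -- the ratio of the median observed 1-df
  chi-square association statistic to the null median (~0.4549); values
  near 1 indicate well-calibrated p-values, values well above 1 indicate
  inflation from confounding or artefacts;
* MAD residual outlier flags -- robust z-scores
  ``|r - median(r)| / (1.4826 * MAD(r))`` exceeding a threshold (default
  3), the standard robust-outlier convention;
* an outlier-sensitivity refit -- reanalyse a significant marker with its
  flagged samples removed and report how much the p-value weakens.  A
  finding whose p-value becomes more than ``ratio_cut`` (default 100)
  times larger on removal is flagged as potentially outlier-driven.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .assoc import fit_marker_association

__all__ = [
    "OutlierSensitivity",
    "inflation_lambda",
    "mad_outlier_flags",
    "outlier_sensitivity",
]

# Median of the 1-df chi-square distribution.
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))

# Normal-consistency constant: MAD * 1.4826 estimates sigma for Gaussians.
MAD_NORMAL_CONSTANT = 1.4826


@dataclass(frozen=True)
class OutlierSensitivity:
    """Before/after comparison of a fit with MAD-flagged samples removed.

    ``p_ratio = p_trimmed / p_full``; ``outlier_driven`` is True when the
    ratio exceeds the cut, i.e. the evidence weakened at least that many
    fold once the flagged samples were dropped.  The direction of the flag
    (larger trimmed p => outlier-driven) is part of the contract so users
    can audit it.
    """

    p_full: float
    p_trimmed: float
    n_flagged: int
    flagged_ids: list
    p_ratio: float
    outlier_driven: bool


def inflation_lambda(stats_or_p: np.ndarray, input_scale: str = "p_value") -> float:
    """Genomic inflation factor from p-values or 1-df chi-square statistics.

    P-values are converted to upper-tail 1-df chi-square quantiles;
    ``lambda = median(observed chi2) / median(chi2_1)``.  Exact zeros on
    the p scale are mapped to the largest finite quantile with a warning.
    """
    v = np.asarray(stats_or_p, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("empty input")
    if input_scale == "p_value":
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("p-values must lie in [0, 1]")
        if np.any(v == 0):
            warnings.warn(
                "p-values equal to 0 mapped to the largest finite chi-square "
                "quantile",
                RuntimeWarning,
                stacklevel=2,
            )
            v = np.where(v == 0, np.finfo(float).tiny, v)
        chi2_obs = stats.chi2.isf(v, df=1)
    elif input_scale == "chisq1":
        if np.any(v < 0):
            raise ValueError("chi-square statistics must be non-negative")
        chi2_obs = v
    else:
        raise ValueError("input_scale must be 'p_value' or 'chisq1'")
    return float(np.median(chi2_obs) / CHI2_1_MEDIAN)


def mad_outlier_flags(residuals: np.ndarray, threshold: float = 3.0) -> np.ndarray:
    """Flag residuals whose robust z-score exceeds ``threshold``.

    The robust z-score of residual ``r_i`` is
    ``|r_i - median(r)| / (1.4826 * MAD(r))``.  When the MAD is zero the
    spread is degenerate: no sample is flagged and a warning is emitted
    rather than dividing by zero.
    """
    r = np.asarray(residuals, dtype=float).ravel()
    if r.shape[0] < 4:
        raise ValueError("need at least 4 residuals for MAD flagging")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    sigma = stats.median_abs_deviation(r, scale=1 / MAD_NORMAL_CONSTANT)
    if sigma == 0:
        warnings.warn(
            "MAD of residuals is zero; no outliers flagged",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.zeros(r.shape[0], dtype=bool)
    return np.abs(r - np.median(r)) / sigma > threshold


def outlier_sensitivity(
    y: np.ndarray,
    x: np.ndarray,
    covariates: np.ndarray | None = None,
    threshold: float = 3.0,
    ratio_cut: float = 100.0,
    model_orientation: str = "marker_as_response",
    sample_ids: list | None = None,
) -> OutlierSensitivity:
    """Refit a marker association with MAD-flagged samples removed.

    Residuals for flagging come from the same full model whose p-value is
    being audited.  If no sample is flagged (including
    ``threshold = inf``), the trimmed fit is skipped and the ratio is
    exactly 1.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    full = fit_marker_association(y, x, covariates, model_orientation)
    if np.isfinite(threshold):
        flags = mad_outlier_flags(full.residuals, threshold)
    else:
        flags = np.zeros(y.shape[0], dtype=bool)
    n_flagged = int(flags.sum())
    if n_flagged == 0:
        return OutlierSensitivity(
            p_full=full.p_two_sided,
            p_trimmed=full.p_two_sided,
            n_flagged=0,
            flagged_ids=[],
            p_ratio=1.0,
            outlier_driven=False,
        )
    keep = ~flags
    cov_keep = None if covariates is None else np.atleast_2d(covariates)[keep]
    trimmed = fit_marker_association(
        y[keep], x[keep], cov_keep, model_orientation
    )
    ratio = trimmed.p_two_sided / full.p_two_sided
    ids = sample_ids if sample_ids is not None else list(range(y.shape[0]))
    flagged_ids = [ids[i] for i in np.flatnonzero(flags)]
    return OutlierSensitivity(
        p_full=full.p_two_sided,
        p_trimmed=trimmed.p_two_sided,
        n_flagged=n_flagged,
        flagged_ids=flagged_ids,
        p_ratio=float(ratio),
        outlier_driven=bool(ratio > ratio_cut),
    )
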