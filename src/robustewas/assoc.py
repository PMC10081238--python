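"""Covariate-adjusted single-marker linear association testing.

This module provides the unit test statistic used everywhere else in the
package: an ordinary-least-squares fit relating one biological marker (a
methylation site or transcript) to one phenotype, optionally adjusting for
covariates, and reporting the t statistic, two-sided p-value and residuals
for the coefficient that links marker and outcome.

Two model orientations are supported.  The conventional EWAS formulation
regresses the marker on the outcome plus covariates
(``marker_as_response``); the reverse regresses the outcome on the marker
(``outcome_as_response``).  Without covariates both give the identical t
statistic (the correlation t), so either is a valid basis for the k-fold
meta-analysis built on top of this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .errors import (
    CollinearityError,
    DegeneratePredictorError,
    InsufficientSampleError,
)

__all__ = ["Dataset", "AssocStat", "fit_marker_association"]

#: Allowed values for the ``model_orientation`` argument.
ORIENTATIONS = ("marker_as_response", "outcome_as_response")


@dataclass
class Dataset:
    """An aligned E/TWAS dataset: outcome, marker matrix, covariates.

    Parameters
    ----------
    outcome
        Phenotype vector of length ``n`` (binary coded 0/1, or continuous).
    markers
        Marker matrix, ``m`` features x ``n`` samples (the EWAS
        features-by-samples convention).
    covariates
        Optional ``n`` x ``c`` covariate matrix.
    sample_ids, feature_ids
        Unique string identifiers; generated as ``s0..s{n-1}`` /
        ``f0..f{m-1}`` when omitted.

    The container requires complete data: missing-value handling is the
    reader's job (see :mod:`robustewas.io`), never performed silently here.
    """

    outcome: np.ndarray
    markers: np.ndarray
    covariates: np.ndarray | None = None
    sample_ids: list[str] = field(default_factory=list)
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.outcome = np.asarray(self.outcome, dtype=float)
        self.markers = np.atleast_2d(np.asarray(self.markers, dtype=float))
        n = self.outcome.shape[0]
        if self.outcome.ndim != 1:
            raise ValueError("outcome must be a 1-D vector")
        if self.markers.shape[1] != n:
            raise ValueError(
                f"markers has {self.markers.shape[1]} samples, outcome has {n}"
            )
        if self.covariates is not None:
            self.covariates = np.atleast_2d(np.asarray(self.covariates, dtype=float))
            if self.covariates.shape[0] != n:
                raise ValueError(
                    f"covariates has {self.covariates.shape[0]} rows, expected {n}"
                )
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(n)]
        if not self.feature_ids:
            self.feature_ids = [f"f{i}" for i in range(self.markers.shape[0])]
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match n")
        if len(self.feature_ids) != self.markers.shape[0]:
            raise ValueError("feature_ids length does not match m")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids are not unique")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature_ids are not unique")
        for name, arr in (
            ("outcome", self.outcome),
            ("markers", self.markers),
            ("covariates", self.covariates),
        ):
            if arr is not None and not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains missing or non-finite values")

    @property
    def n_samples(self) -> int:
        return self.outcome.shape[0]

    @property
    def n_features(self) -> int:
        return self.markers.shape[0]

    @property
    def n_covariates(self) -> int:
        return 0 if self.covariates is None else self.covariates.shape[1]

    @property
    def outcome_is_binary(self) -> bool:
        """True when the outcome takes only the values 0 and 1."""
        return bool(np.isin(np.unique(self.outcome), (0.0, 1.0)).all())


@dataclass(frozen=True)
class AssocStat:
    """Result of a single marker-outcome association fit.

    ``beta``, ``t_stat``, ``df`` and ``p_two_sided`` refer to the
    coefficient linking marker and outcome; ``residuals`` are the fitted
    model's residuals (used downstream for MAD outlier diagnostics).
    """

    beta: float
    t_stat: float
    df: int
    p_two_sided: float
    residuals: np.ndarray

    @property
    def n_used(self) -> int:
        return int(self.residuals.shape[0])


def fit_marker_association(
    y: np.ndarray,
    x: np.ndarray,
    covariates: np.ndarray | None = None,
    model_orientation: str = "marker_as_response",
) -> AssocStat:
    """OLS association test between an outcome ``y`` and a marker ``x``.

    The model always includes an intercept.  Under the default
    ``marker_as_response`` orientation the regression is
    ``x ~ 1 + y + covariates`` and the reported coefficient is the one on
    ``y``; under ``outcome_as_response`` it is ``y ~ 1 + x + covariates``
    with the coefficient on ``x``.  Complete cases are required: the caller
    performs any row-wise deletion.

    Raises
    ------
    DegeneratePredictorError
        If the tested variable has zero variance.
    InsufficientSampleError
        If fewer than ``n_coefficients + 2`` samples are available.
    CollinearityError
        If the design matrix is rank deficient.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if y.shape[0] != x.shape[0]:
        raise ValueError(f"y has length {y.shape[0]} but x has length {x.shape[0]}")
    if model_orientation not in ORIENTATIONS:
        raise ValueError(f"model_orientation must be one of {ORIENTATIONS}")
    n = y.shape[0]
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            raise ValueError(
                f"covariates has {covariates.shape[0]} rows, expected {n}"
            )
    n_cov = 0 if covariates is None else covariates.shape[1]
    n_coef = 2 + n_cov  # intercept + tested variable + covariates

    if model_orientation == "marker_as_response":
        response, tested = x, y
    else:
        response, tested = y, x

    if n < n_coef + 2:
        raise InsufficientSampleError(
            f"need at least {n_coef + 2} samples for {n_coef} coefficients, got {n}"
        )
    if np.ptp(tested) == 0.0:
        raise DegeneratePredictorError("tested variable has zero variance")

    cols = [np.ones(n), tested]
    if covariates is not None:
        cols.extend(covariates.T)
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("design matrix is rank deficient")

    fit = sm.OLS(response, design).fit()
    return AssocStat(
        beta=float(fit.params[1]),
        t_stat=float(fit.tvalues[1]),
        df=int(round(fit.df_resid)),
        p_two_sided=float(fit.pvalues[1]),
        residuals=np.asarray(fit.resid, dtype=float),
    )
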