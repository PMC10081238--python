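"""Baseline strategies the robust k-fold method is evaluated against.

Two comparators: ordinary full-sample association testing, and split-half
replication (random 50/50 split, two-sided discovery test, then a
one-sided replication test in the discovery direction for markers that
pass discovery).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .assoc import Dataset, fit_marker_association
from .errors import RobustEwasError
from .foldmeta import adjust_pvalues

__all__ = ["SplitHalfResult", "full_sample_ewas", "split_half_replication"]


@dataclass(frozen=True)
class SplitHalfResult:
    """Two-stage discovery/replication outcome for one marker.

    ``p_replication_one_sided`` is present exactly when the discovery
    p-value clears the discovery threshold; ``declared`` means the marker
    was both discovered and replicated.
    """

    p_discovery: float
    direction_discovery: int
    tested_in_replication: bool
    p_replication_one_sided: float | None
    declared: bool


def full_sample_ewas(
    data: Dataset,
    adjust: str = "bonferroni",
    model_orientation: str = "marker_as_response",
) -> pd.DataFrame:
    """Ordinary association testing on the entire sample at once."""
    rows = []
    for i, fid in enumerate(data.feature_ids):
        try:
            stat = fit_marker_association(
                data.outcome,
                data.markers[i],
                data.covariates,
                model_orientation=model_orientation,
            )
        except RobustEwasError as err:
            raise type(err)(f"feature {fid}: {err}") from err
        rows.append(
            {
                "feature_id": fid,
                "beta": stat.beta,
                "t_stat": stat.t_stat,
                "df": stat.df,
                "p": stat.p_two_sided,
                "n_used": stat.n_used,
            }
        )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = adjust_pvalues(table["p"].to_numpy(), adjust)
    table.attrs.update({"method": "full", "adjust": adjust})
    return table


def one_sided_replication_p(t_rep: float, df_rep: int, direction: int) -> float:
    """One-sided t-tail p in the discovery direction.

    The replication test asks for evidence of an effect with the same sign
    as the discovery estimate: ``P(T_df > t_rep)`` when the discovery
    direction is positive, ``P(T_df < t_rep)`` when negative.
    """
    if direction not in (-1, 1):
        raise ValueError("direction must be -1 or +1")
    return float(stats.t.sf(direction * t_rep, df_rep))


def split_half_replication(
    data: Dataset,
    alpha_discovery: float = 0.05,
    alpha_replication: float = 0.05,
    seed: int = 0,
    model_orientation: str = "marker_as_response",
) -> pd.DataFrame:
    """Split-half discovery/replication for every feature of a dataset.

    The sample is split at random into two halves whose sizes differ by at
    most one (stratified on a binary outcome).  Each marker is tested
    two-sided in the discovery half; markers with
    ``p < alpha_discovery`` proceed to a one-sided test in the replication
    half assuming the discovery direction of effect, and are ``declared``
    when that one-sided p is below ``alpha_replication``.
    """
    if not (0 < alpha_discovery < 1 and 0 < alpha_replication < 1):
        raise ValueError("alphas must lie in (0, 1)")
    n = data.n_samples
    rng = substream(seed, "split_half")
    if data.outcome_is_binary:
        half = np.empty(n, dtype=np.intp)
        cursor = 0
        for level in np.unique(data.outcome):
            idx = np.flatnonzero(data.outcome == level)
            rng.shuffle(idx)
            half[idx] = (cursor + np.arange(idx.shape[0])) % 2
            cursor += idx.shape[0]
    else:
        perm = rng.permutation(n)
        half = np.zeros(n, dtype=np.intp)
        half[perm[(n + 1) // 2 :]] = 1
    disc = np.flatnonzero(half == 0)
    rep = np.flatnonzero(half == 1)

    rows = []
    for i, fid in enumerate(data.feature_ids):
        x = data.markers[i]
        cov_d = None if data.covariates is None else data.covariates[disc]
        try:
            stat_d = fit_marker_association(
                data.outcome[disc], x[disc], cov_d, model_orientation
            )
        except RobustEwasError as err:
            raise type(err)(f"feature {fid} (discovery stage): {err}") from err
        direction = 1 if stat_d.t_stat >= 0 else -1
        tested = stat_d.p_two_sided < alpha_discovery
        p_rep: float | None = None
        declared = False
        if tested:
            cov_r = None if data.covariates is None else data.covariates[rep]
            try:
                stat_r = fit_marker_association(
                    data.outcome[rep], x[rep], cov_r, model_orientation
                )
            except RobustEwasError as err:
                raise type(err)(
                    f"feature {fid} (replication stage): {err}"
                ) from err
            p_rep = one_sided_replication_p(stat_r.t_stat, stat_r.df, direction)
            declared = p_rep < alpha_replication
        rows.append(
            {
                "feature_id": fid,
                "p_discovery": stat_d.p_two_sided,
                "direction_discovery": direction,
                "tested_in_replication": tested,
                "p_replication_one_sided": p_rep,
                "declared": declared,
            }
        )
    table = pd.DataFrame(rows)
    table.attrs.update(
        {
            "method": "split_half",
            "alpha_discovery": alpha_discovery,
            "alpha_replication": alpha_replication,
            "seed": int(seed),
            "n_discovery": int(disc.shape[0]),
            "n_replication": int(rep.shape[0]),
        }
    )
    return table
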