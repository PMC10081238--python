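"""Readers, writers and dataset assembly for delimited-text E/TWAS files.

Marker matrices follow the EWAS convention of features (rows) by samples
(columns), with feature identifiers in the first column and sample
identifiers in the header; an orientation flag handles transposed files.
Delimiters are inferred from the extension (.csv -> comma, anything else
-> tab).  Missing-data policy is complete-case per feature and is applied
here, with counts logged -- never silently inside a model fit.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .assoc import Dataset

__all__ = [
    "read_marker_matrix",
    "read_phenotype",
    "build_dataset",
    "write_results",
    "read_results",
]

logger = logging.getLogger("robustewas")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_marker_matrix(
    path: str | Path, orientation: str = "features_by_samples"
) -> pd.DataFrame:
    """Read a marker matrix into a features x samples DataFrame.

    Non-numeric cells become missing values; features with any missing
    value are dropped (complete-case policy) and the count logged.
    """
    path = Path(path)
    if orientation not in ("features_by_samples", "samples_by_features"):
        raise ValueError("unknown orientation")
    raw = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    if raw.empty and raw.columns.empty:
        raise ValueError(f"{path}: empty marker file")
    if orientation == "samples_by_features":
        raw = raw.T
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    raw.index.name = "feature_id"
    raw.columns.name = None
    if raw.index.duplicated().any():
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature ids {dupes}")
    if raw.columns.duplicated().any():
        dupes = raw.columns[raw.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate sample ids {dupes}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    incomplete = numeric.isna().any(axis=1)
    if incomplete.any():
        logger.info(
            "dropped %d feature(s) with missing or non-numeric values: %s",
            int(incomplete.sum()),
            ", ".join(numeric.index[incomplete][:10]),
        )
        numeric = numeric.loc[~incomplete]
    return numeric


def read_phenotype(
    path: str | Path,
    outcome_column: str,
    covariate_columns: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Read a phenotype table indexed by sample id.

    The outcome column must be numeric or two-level categorical; two-level
    outcomes are coded 0/1 (levels sorted, first level -> 0) and the
    mapping logged.  Covariate columns are coerced to numeric.
    """
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    table.index = table.index.astype(str)
    if table.index.duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids")
    missing = [c for c in (outcome_column, *covariate_columns) if c not in table]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    out = pd.DataFrame(index=table.index)
    outcome = table[outcome_column]
    numeric = pd.to_numeric(outcome, errors="coerce")
    if numeric.notna().all():
        out[outcome_column] = numeric.astype(float)
    else:
        levels = sorted(outcome.astype(str).unique())
        if len(levels) != 2:
            raise ValueError(
                f"{path}: outcome '{outcome_column}' is non-numeric with "
                f"{len(levels)} levels; need exactly 2"
            )
        mapping = {levels[0]: 0.0, levels[1]: 1.0}
        logger.info("outcome coding: %s", mapping)
        out[outcome_column] = outcome.astype(str).map(mapping)
    for c in covariate_columns:
        cov = pd.to_numeric(table[c], errors="coerce")
        out[c] = cov.astype(float)
    return out


def build_dataset(
    markers: pd.DataFrame,
    phenotype: pd.DataFrame,
    outcome_column: str,
    covariate_columns: tuple[str, ...] = (),
) -> Dataset:
    """Align markers and phenotype by sample id and assemble a Dataset.

    Samples are intersected by id (order taken from the marker matrix);
    samples with a missing outcome or covariate are dropped with a logged
    count.
    """
    pheno = phenotype.dropna(subset=[outcome_column, *covariate_columns])
    dropped = len(phenotype) - len(pheno)
    if dropped:
        logger.info("dropped %d sample(s) with missing phenotype data", dropped)
    shared = [s for s in markers.columns if s in pheno.index]
    if not shared:
        raise ValueError("no overlapping sample ids between markers and phenotype")
    if len(shared) < len(markers.columns):
        logger.info(
            "using %d of %d marker samples present in the phenotype table",
            len(shared),
            len(markers.columns),
        )
    sub = markers[shared]
    pheno = pheno.loc[shared]
    covariates = (
        pheno[list(covariate_columns)].to_numpy() if covariate_columns else None
    )
    return Dataset(
        outcome=pheno[outcome_column].to_numpy(),
        markers=sub.to_numpy(),
        covariates=covariates,
        sample_ids=list(sub.columns),
        feature_ids=list(sub.index),
    )


def write_results(
    table: pd.DataFrame, path: str | Path, metadata: dict | None = None
) -> None:
    """Write a results table as TSV, sorted by p-value ascending.

    A single metadata block of ``# key=value`` comment lines (run
    configuration, seed, software version) precedes the header so any
    results file is self-describing yet still parses with
    ``pandas.read_csv(..., sep="\\t", comment="#")``.
    """
    path = Path(path)
    table = table.copy()
    sort_col = next((c for c in ("p_meta", "p", "p_discovery") if c in table), None)
    if sort_col is not None:
        table = table.sort_values(sort_col, kind="mergesort")
    for col in table.columns:
        if table[col].map(lambda v: isinstance(v, np.ndarray)).any():
            table[col] = table[col].map(
                lambda v: ";".join(f"{z:.6g}" for z in np.atleast_1d(v))
            )
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}={value}\n")
        table.to_csv(fh, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", comment="#")
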