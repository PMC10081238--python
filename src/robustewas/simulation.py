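"""Monte-Carlo evaluation of the robust k-fold method and its comparators.

The study design: draw 10,000 replicate datasets of a single marker and a
single outcome for n=250 individuals from a bivariate normal with
correlation ``rho`` (0 under the null, 0.3 for power), optionally corrupt
each replicate with outliers, run each analysis method, and record the
fraction of replicates rejected at the chosen alpha (0.05 for type-I
error, 0.001 for power).

Outlier types:

* univariate -- an extreme value in EITHER the outcome OR the marker of an
  individual, never both.  These attenuate a true association signal and
  deflate null test statistics.
* bivariate -- extreme values in BOTH variables of the same individual.
  Concordant (same-sign) bivariate outliers manufacture spurious
  association and are the hazardous case.

Outliers REPLACE existing values (the nominal sample size stays fixed)
with a value ``magnitude`` population standard deviations from the
population mean, random sign.  The magnitude is a free parameter of the
design (default 6 SD -- far enough to dominate a fold-level fit at a fold
size of ~25 while remaining plausible for an array artefact).

The per-replicate analyses here are vectorized across replicates for
speed: with one marker and no covariates every method reduces to Pearson
correlation t statistics on (sub)samples, which the test-suite verifies
against the general model-fitting path (:func:`robustewas.robust_ewas`
and friends) replicate by replicate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .assoc import Dataset
from .foldmeta import t_to_signed_z

__all__ = [
    "SimConfig",
    "SimResult",
    "generate_pair",
    "inject_univariate_outliers",
    "inject_bivariate_outlier",
    "run_type1_study",
    "run_power_study",
    "generate_fixture_ewas",
]

METHODS = ("full", "split_half", "robust")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulation experiment.

    Defaults mirror the reference study design: n=250 individuals, 10,000
    replicates, alpha=0.05 for type-I error (rho=0) and alpha=0.001 for
    power (rho=0.3), five univariate or one bivariate outlier of
    magnitude 6 SD, and a fold grid bracketing k=10.
    """

    n: int = 250
    n_sims: int = 10_000
    rho: float = 0.0
    n_univariate_outliers: int = 0
    n_bivariate_outliers: int = 0
    outlier_magnitude: float = 6.0
    concordant_bivariate: bool = True
    univariate_first_variable: str = "random"  # "x", "y" or "random"
    alpha: float = 0.05
    k_values: tuple[int, ...] = (2, 5, 10, 20, 25)
    methods: tuple[str, ...] = ("full", "split_half", "robust")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if not -1 < self.rho < 1:
            raise ValueError("rho must lie in (-1, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_univariate_outliers + 2 * self.n_bivariate_outliers > self.n:
            raise ValueError("more outliers than samples")
        if any(k > self.n // 2 for k in self.k_values):
            raise ValueError("every k must satisfy k <= n/2")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")

    @property
    def scenario(self) -> str:
        parts = []
        if self.n_univariate_outliers:
            parts.append(f"univariate_{self.n_univariate_outliers}")
        if self.n_bivariate_outliers:
            kind = "concordant" if self.concordant_bivariate else "discordant"
            parts.append(f"bivariate_{self.n_bivariate_outliers}_{kind}")
        return "+".join(parts) if parts else "no_outliers"


@dataclass(frozen=True)
class SimResult:
    """Tidy rejection-rate table plus the configuration that produced it.

    ``table`` has one row per (method, k, metric): columns ``method``,
    ``k`` (NA for non-fold methods), ``scenario``, ``alpha``, ``metric``
    (``rejection`` for full/robust; ``conditional`` and ``joint`` for
    split-half), ``rate``, ``se`` (binomial Monte-Carlo standard error on
    the trials actually used) and ``n_used``.
    """

    table: pd.DataFrame
    config: SimConfig = field(repr=False)

    def rate(self, method: str, k: int | None = None, metric: str | None = None) -> float:
        """Convenience lookup of a single rejection rate."""
        t = self.table
        sel = t["method"] == method
        if k is not None:
            sel &= t["k"] == k
        if metric is not None:
            sel &= t["metric"] == metric
        hit = t[sel]
        if len(hit) != 1:
            raise KeyError(
                f"selection (method={method}, k={k}, metric={metric}) "
                f"matched {len(hit)} rows"
            )
        return float(hit["rate"].iloc[0])


def generate_pair(
    n: int, rho: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (outcome, marker) as standard normals with correlation ``rho``.

    Uses the construction ``x = rho*y + sqrt(1 - rho^2)*eps`` so both
    margins are standard normal with population correlation exactly
    ``rho``.
    """
    if not -1 < rho < 1:
        raise ValueError("rho must lie in (-1, 1)")
    y = rng.standard_normal(n)
    x = rho * y + np.sqrt(1.0 - rho * rho) * rng.standard_normal(n)
    return y, x


def _as_2d(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray, bool]:
    y = np.array(y, dtype=float, copy=True)
    x = np.array(x, dtype=float, copy=True)
    if y.shape != x.shape:
        raise ValueError("y and x must have the same shape")
    one_d = y.ndim == 1
    return np.atleast_2d(y), np.atleast_2d(x), one_d


def inject_univariate_outliers(
    y: np.ndarray,
    x: np.ndarray,
    count: int,
    magnitude: float,
    rng: np.random.Generator,
    first_variable: str = "random",
):
    """Replace values in EITHER y OR x of ``count`` distinct individuals.

    The affected variable alternates between consecutive chosen
    individuals (``first_variable`` controls which starts; ``"random"``
    draws it), so with count=5 one variable receives 3 outliers and the
    other 2, and no individual is altered in both variables.  Replacement
    values are ``+/- magnitude`` (the population is standard normal),
    random sign.  Accepts 1-D vectors or (n_sims, n) replicate matrices;
    returns modified copies plus the affected indices.
    """
    Y, X, one_d = _as_2d(y, x)
    n_sims, n = Y.shape
    if count > n:
        raise ValueError(f"count={count} exceeds n={n}")
    if first_variable not in ("x", "y", "random"):
        raise ValueError("first_variable must be 'x', 'y' or 'random'")
    if count == 0:
        affected = np.empty((n_sims, 0), dtype=np.intp)
        return _squeeze(Y, X, affected, one_d)
    idx = np.argsort(rng.random((n_sims, n)), axis=1)[:, :count]
    if first_variable == "random":
        start_x = rng.integers(0, 2, size=n_sims).astype(bool)
    else:
        start_x = np.full(n_sims, first_variable == "x")
    signs = rng.choice([-1.0, 1.0], size=(n_sims, count))
    rows = np.arange(n_sims)
    for j in range(count):
        on_x = start_x ^ bool(j % 2)
        vals = signs[:, j] * magnitude
        X[rows[on_x], idx[on_x, j]] = vals[on_x]
        Y[rows[~on_x], idx[~on_x, j]] = vals[~on_x]
    return _squeeze(Y, X, idx, one_d)


def inject_bivariate_outlier(
    y: np.ndarray,
    x: np.ndarray,
    count: int,
    magnitude: float,
    rng: np.random.Generator,
    concordant: bool = True,
):
    """Replace BOTH y and x of ``count`` distinct individuals with extremes.

    ``concordant=True`` gives the same sign to both variables (this is
    what manufactures a spurious positive association contribution);
    ``concordant=False`` gives opposite signs.  The overall sign is
    random.  Accepts 1-D vectors or replicate matrices, as for
    :func:`inject_univariate_outliers`.
    """
    Y, X, one_d = _as_2d(y, x)
    n_sims, n = Y.shape
    if count > n:
        raise ValueError(f"count={count} exceeds n={n}")
    if count == 0:
        affected = np.empty((n_sims, 0), dtype=np.intp)
        return _squeeze(Y, X, affected, one_d)
    idx = np.argsort(rng.random((n_sims, n)), axis=1)[:, :count]
    signs = rng.choice([-1.0, 1.0], size=(n_sims, count))
    rows = np.repeat(np.arange(n_sims), count)
    cols = idx.ravel()
    s = signs.ravel()
    X[rows, cols] = s * magnitude
    Y[rows, cols] = (s if concordant else -s) * magnitude
    return _squeeze(Y, X, idx, one_d)


def _squeeze(Y, X, affected, one_d):
    if one_d:
        return Y[0], X[0], affected[0]
    return Y, X, affected


# ---------------------------------------------------------------------------
# Vectorized analysis engine (one marker, no covariates).


def _rowwise_corr_t(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, int]:
    """Pearson correlation t statistic for each row of paired matrices."""
    n = Y.shape[1]
    df = n - 2
    Yc = Y - Y.mean(axis=1, keepdims=True)
    Xc = X - X.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", Yc, Xc)
    den = np.sqrt(
        np.einsum("ij,ij->i", Yc, Yc) * np.einsum("ij,ij->i", Xc, Xc)
    )
    r = np.clip(num / den, -1.0 + 1e-15, 1.0 - 1e-15)
    return r * np.sqrt(df / (1.0 - r * r)), df


def _fold_sizes(n: int, k: int) -> np.ndarray:
    sizes = np.full(k, n // k, dtype=np.intp)
    sizes[: n % k] += 1
    return sizes


def _robust_meta_p(Y: np.ndarray, X: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Robust k-fold meta p-value for each replicate row."""
    n_sims, n = Y.shape
    rng = substream(seed, "sim_engine", k)
    perm = np.argsort(rng.random((n_sims, n)), axis=1)
    Yp = np.take_along_axis(Y, perm, axis=1)
    Xp = np.take_along_axis(X, perm, axis=1)
    z = np.empty((n_sims, k))
    start = 0
    for f, size in enumerate(_fold_sizes(n, k)):
        t, df = _rowwise_corr_t(
            Yp[:, start : start + size], Xp[:, start : start + size]
        )
        z[:, f] = t_to_signed_z(t, df)
        start += size
    z_meta = z.sum(axis=1) / np.sqrt(k)
    return 2.0 * stats.norm.sf(np.abs(z_meta))


def _split_half_masks(
    Y: np.ndarray, X: np.ndarray, alpha: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Discovery and replication rejection masks for each replicate row."""
    n_sims, n = Y.shape
    rng = substream(seed, "split_half")
    perm = np.argsort(rng.random((n_sims, n)), axis=1)
    Yp = np.take_along_axis(Y, perm, axis=1)
    Xp = np.take_along_axis(X, perm, axis=1)
    n_disc = (n + 1) // 2
    t_d, df_d = _rowwise_corr_t(Yp[:, :n_disc], Xp[:, :n_disc])
    p_d = 2.0 * stats.t.sf(np.abs(t_d), df_d)
    discovered = p_d < alpha
    t_r, df_r = _rowwise_corr_t(Yp[:, n_disc:], Xp[:, n_disc:])
    direction = np.where(t_d >= 0, 1.0, -1.0)
    p_one = stats.t.sf(direction * t_r, df_r)
    replicated = p_one < alpha
    return discovered, replicated


def _simulate_replicates(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    rng = substream(config.seed, "sim_data")
    Y = rng.standard_normal((config.n_sims, config.n))
    X = config.rho * Y + np.sqrt(1.0 - config.rho**2) * rng.standard_normal(
        (config.n_sims, config.n)
    )
    rng_out = substream(config.seed, "sim_outliers")
    if config.n_univariate_outliers:
        Y, X, _ = inject_univariate_outliers(
            Y,
            X,
            config.n_univariate_outliers,
            config.outlier_magnitude,
            rng_out,
            first_variable=config.univariate_first_variable,
        )
    if config.n_bivariate_outliers:
        Y, X, _ = inject_bivariate_outlier(
            Y,
            X,
            config.n_bivariate_outliers,
            config.outlier_magnitude,
            rng_out,
            concordant=config.concordant_bivariate,
        )
    return Y, X


def _rate_row(method, k, config, metric, hits, n_used):
    rate = hits / n_used if n_used else float("nan")
    return {
        "method": method,
        "k": k,
        "scenario": config.scenario,
        "alpha": config.alpha,
        "metric": metric,
        "rate": rate,
        "se": np.sqrt(rate * (1.0 - rate) / n_used) if n_used else float("nan"),
        "n_used": n_used,
    }


def _run_study(config: SimConfig) -> SimResult:
    Y, X = _simulate_replicates(config)
    rows = []
    if "full" in config.methods:
        t, df = _rowwise_corr_t(Y, X)
        p = 2.0 * stats.t.sf(np.abs(t), df)
        rows.append(
            _rate_row(
                "full", pd.NA, config, "rejection",
                int((p < config.alpha).sum()), config.n_sims,
            )
        )
    if "split_half" in config.methods:
        disc, rep = _split_half_masks(Y, X, config.alpha, config.seed)
        n_disc = int(disc.sum())
        rows.append(
            _rate_row(
                "split_half", pd.NA, config, "conditional",
                int((disc & rep).sum()), n_disc,
            )
        )
        rows.append(
            _rate_row(
                "split_half", pd.NA, config, "joint",
                int((disc & rep).sum()), config.n_sims,
            )
        )
    if "robust" in config.methods:
        for k in config.k_values:
            p = _robust_meta_p(Y, X, k, config.seed)
            rows.append(
                _rate_row(
                    "robust", k, config, "rejection",
                    int((p < config.alpha).sum()), config.n_sims,
                )
            )
    return SimResult(table=pd.DataFrame(rows), config=config)


def run_type1_study(config: SimConfig) -> SimResult:
    """Type-I error study: rejection rates on null (rho=0) replicates."""
    if config.rho != 0:
        raise ValueError("type-I study requires rho=0")
    return _run_study(config)


def run_power_study(config: SimConfig) -> SimResult:
    """Power study: detection rates on associated (rho != 0) replicates.

    Bivariate outliers are excluded by contract: for a marker with a true
    effect they are rare and their impact depends on whether they align
    with the association trend, so only the no-outlier and univariate
    scenarios are studied.
    """
    if config.rho == 0:
        raise ValueError("power study requires rho != 0")
    if config.n_bivariate_outliers:
        raise ValueError("power study excludes bivariate outliers")
    return _run_study(config)


# ---------------------------------------------------------------------------
# Integration-test fixture generator.


def generate_fixture_ewas(
    m: int,
    n: int,
    n_true: int,
    effect_rho: float,
    outlier_spec: dict | None = None,
    covariate_spec: dict | None = None,
    seed: int = 0,
) -> tuple[Dataset, pd.DataFrame]:
    """Generate a small EWAS-like dataset with known truths.

    The first ``n_true`` features are correlated with the (continuous,
    standard-normal) outcome at ``effect_rho``; the rest are null.
    ``covariate_spec = {"n_covariates": c, "loading": a}`` adds ``c``
    standard-normal covariates whose sum, scaled by ``a``, loads onto
    every marker (the association fits then must adjust for them).

    ``outlier_spec = {"kind": "univariate"|"bivariate", "n_features": f,
    "count": c, "magnitude": g, "concordant": True}`` corrupts ``f``
    randomly chosen features.  Because the outcome vector is shared across
    features it is never mutated here: univariate outliers replace marker
    values of random individuals with ``+/- g``; "bivariate" outliers
    place the extreme marker value on the individuals with the most
    extreme outcomes (concordant or discordant with the outcome sign),
    reproducing the hazardous same-individual double-extreme pattern
    without touching the shared outcome.

    Returns the dataset and a truth table (feature_id, is_true,
    effect_rho, outlier_kind, outlier_samples).
    """
    if n_true > m:
        raise ValueError("n_true must not exceed m")
    if not -1 < effect_rho < 1:
        raise ValueError("effect_rho must lie in (-1, 1)")
    rng = substream(seed, "fixture")
    y = rng.standard_normal(n)
    markers = rng.standard_normal((m, n))
    if n_true:
        scale = np.sqrt(1.0 - effect_rho**2)
        markers[:n_true] = effect_rho * y + scale * markers[:n_true]
    covariates = None
    if covariate_spec:
        c = int(covariate_spec.get("n_covariates", 0))
        loading = float(covariate_spec.get("loading", 0.5))
        if c:
            covariates = rng.standard_normal((n, c))
            markers = markers + loading * covariates.sum(axis=1)

    truth = pd.DataFrame(
        {
            "feature_id": [f"f{i}" for i in range(m)],
            "is_true": [i < n_true for i in range(m)],
            "effect_rho": [effect_rho if i < n_true else 0.0 for i in range(m)],
            "outlier_kind": ["none"] * m,
            "outlier_samples": [[] for _ in range(m)],
        }
    )
    if outlier_spec:
        kind = outlier_spec["kind"]
        n_features = int(outlier_spec.get("n_features", 1))
        count = int(outlier_spec.get("count", 1))
        magnitude = float(outlier_spec.get("magnitude", 6.0))
        concordant = bool(outlier_spec.get("concordant", True))
        affected_features = rng.choice(m, size=n_features, replace=False)
        for fi in affected_features:
            if kind == "univariate":
                samples = rng.choice(n, size=count, replace=False)
                markers[fi, samples] = (
                    rng.choice([-1.0, 1.0], size=count) * magnitude
                )
            elif kind == "bivariate":
                # Most extreme outcomes; marker extreme matches their sign.
                samples = np.argsort(-np.abs(y))[:count]
                sign = np.sign(y[samples])
                markers[fi, samples] = (
                    sign if concordant else -sign
                ) * magnitude
            else:
                raise ValueError("kind must be 'univariate' or 'bivariate'")
            truth.loc[fi, "outlier_kind"] = kind
            truth.at[fi, "outlier_samples"] = [int(s) for s in samples]
    data = Dataset(outcome=y, markers=markers, covariates=covariates)
    return data, truth
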