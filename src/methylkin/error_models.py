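"""Observation models linking expected methylation levels to read counts.

Two error models are supported: plain binomial (adequate at moderate
coverage) and a mean/dispersion-reparameterized beta-binomial whose extra
parameter ``gamma`` absorbs the between-replicate over-dispersion seen in
very deep amplicon data.  With ``alpha = p*(1/gamma - 1)`` and
``beta = (1-p)*(1/gamma - 1)`` the count variance is
``n*p*(1-p)*(1 + (n-1)*gamma)``, so ``gamma = 0`` recovers the binomial.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_GAMMA",
    "ErrorModelSpec",
    "CountObservation",
    "binomial_logpmf",
    "betabinomial_logpmf",
    "loglik_binomial",
    "loglik_betabinomial",
    "predicted_sd",
    "fit_gamma",
    "default_gamma_sweep",
]

#: Over-dispersion fitted to deep amplicon day-0 replicate variability.
DEFAULT_GAMMA = 0.0055

_P_CLIP = 1e-12


@dataclass(frozen=True)
class ErrorModelSpec:
    """Choice of count error model: ``binomial`` or ``betabinomial``."""

    kind: str = "betabinomial"
    gamma: float = DEFAULT_GAMMA

    def __post_init__(self) -> None:
        if self.kind not in ("binomial", "betabinomial"):
            raise ValueError(f"unknown error model kind: {self.kind!r}")
        if not 0 <= self.gamma < 1:
            raise ValueError(f"gamma must be in [0,1): {self.gamma}")

    @property
    def effective_gamma(self) -> float:
        return 0.0 if self.kind == "binomial" else self.gamma


@dataclass(frozen=True)
class CountObservation:
    """One methylation call: coverage ``n``, methylated reads ``c``, expected fraction ``p``."""

    n: int
    c: int
    p: float

    def __post_init__(self) -> None:
        if self.n < 0 or not 0 <= self.c <= self.n:
            raise ValueError(f"need 0 <= c <= n, got c={self.c}, n={self.n}")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p must be in [0,1]: {self.p}")


def binomial_logpmf(c, n, p) -> np.ndarray:
    """Vectorized log binomial pmf; degenerate ``p`` in {0,1} yields 0/-inf."""
    c = np.asarray(c, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    pc = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (
            gammaln(n + 1)
            - gammaln(c + 1)
            - gammaln(n - c + 1)
            + c * np.log(pc)
            + (n - c) * np.log1p(-pc)
        )
    # exact handling at the degenerate edges
    out = np.where((p == 0.0) & (c == 0), 0.0, out)
    out = np.where((p == 0.0) & (c > 0), -np.inf, out)
    out = np.where((p == 1.0) & (c == n), 0.0, out)
    out = np.where((p == 1.0) & (c < n), -np.inf, out)
    return out[()] if out.ndim == 0 else out


def betabinomial_logpmf(c, n, p, gamma) -> np.ndarray:
    """Vectorized log beta-binomial pmf in the mean/dispersion parameterization.

    ``gamma = 0`` delegates to the binomial; ``p`` in {0,1} is a point mass.
    """
    if gamma == 0:
        return binomial_logpmf(c, n, p)
    if not 0 < gamma < 1:
        raise ValueError(f"gamma must be in [0,1): {gamma}")
    c = np.asarray(c, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    pc = np.clip(p, _P_CLIP, 1.0 - _P_CLIP)
    s = 1.0 / gamma - 1.0  # alpha + beta
    alpha = pc * s
    beta = (1.0 - pc) * s
    out = (
        gammaln(n + 1)
        - gammaln(c + 1)
        - gammaln(n - c + 1)
        + betaln(c + alpha, n - c + beta)
        - betaln(alpha, beta)
    )
    out = np.where((p == 0.0) & (c == 0), 0.0, out)
    out = np.where((p == 0.0) & (c > 0), -np.inf, out)
    out = np.where((p == 1.0) & (c == n), 0.0, out)
    out = np.where((p == 1.0) & (c < n), -np.inf, out)
    return out[()] if out.ndim == 0 else out


def loglik_binomial(obs: CountObservation) -> float:
    """Log probability of one observation under the binomial model."""
    return float(binomial_logpmf(obs.c, obs.n, obs.p))


def loglik_betabinomial(obs: CountObservation, gamma: float) -> float:
    """Log probability of one observation under the beta-binomial model."""
    return float(betabinomial_logpmf(obs.c, obs.n, obs.p, gamma))


def predicted_sd(n, p, gamma) -> np.ndarray:
    """Standard deviation of the observed fraction ``c/n``.

    ``sqrt(p*(1-p)*(1 + (n-1)*gamma)/n)``; reduces to the binomial
    ``sqrt(p*(1-p)/n)`` at ``gamma = 0``.
    """
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(n < 1):
        raise ValueError("coverage n must be >= 1")
    out = np.sqrt(p * (1.0 - p) * (1.0 + (n - 1.0) * gamma) / n)
    return out[()] if out.ndim == 0 else out


def default_gamma_sweep() -> np.ndarray:
    """Sweep grid for over-dispersion fitting: 0 plus 100 log-spaced values."""
    return np.concatenate([[0.0], np.logspace(-5, -1, 100)])


def fit_gamma(
    day0_table: pd.DataFrame,
    sweep_grid: np.ndarray | None = None,
    coverage_bins: int = 10,
    level_bins: int = 10,
) -> float:
    """Fit the over-dispersion ``gamma`` from day-0 replicate variability.

    Per CpG, the across-replicate variance of the methylation fraction is
    computed; CpGs are then stratified by mean coverage and mean level
    (decile bins on each axis), and ``gamma`` is chosen from ``sweep_grid``
    to minimize the sum of squared errors between each stratum's empirical
    sd (root mean variance) and :func:`predicted_sd` at the stratum's mean
    coverage and level.

    Parameters
    ----------
    day0_table : DataFrame
        Columns ``cpg_id``, ``replicate``, ``coverage``, ``meth_count``;
        if a ``day`` column is present only ``day == 0`` rows are used.
    sweep_grid : array-like, optional
        Candidate gamma values.  ``None`` uses :func:`default_gamma_sweep`;
        an explicitly empty sequence disables the sweep and returns the
        reference default ``0.0055``.
    """
    if sweep_grid is None:
        sweep = default_gamma_sweep()
    else:
        sweep = np.asarray(sweep_grid, dtype=float)
        if sweep.size == 0:
            logger.info("gamma sweep disabled; returning default %.4g", DEFAULT_GAMMA)
            return DEFAULT_GAMMA

    df = day0_table
    if "day" in df.columns:
        df = df[df["day"] == 0]
    if df.empty:
        raise ValueError("no day-0 rows in table")
    df = df.assign(level=df["meth_count"] / df["coverage"])

    per_cpg = df.groupby("cpg_id", observed=True).agg(
        n_rep=("replicate", "nunique"),
        var=("level", "var"),
        mean_level=("level", "mean"),
        mean_cov=("coverage", "mean"),
    )
    per_cpg = per_cpg[per_cpg["n_rep"] >= 2].dropna(subset=["var"])
    if per_cpg.empty:
        raise ValueError("need at least 2 replicates per CpG at day 0")

    def _decile_bin(series: pd.Series, q: int) -> pd.Series:
        if series.nunique() < 2:
            return pd.Series(0, index=series.index)
        return pd.qcut(series, q=q, duplicates="drop")

    cov_bin = _decile_bin(per_cpg["mean_cov"], coverage_bins)
    lvl_bin = _decile_bin(per_cpg["mean_level"], level_bins)
    strata = per_cpg.groupby([cov_bin, lvl_bin], observed=True).agg(
        count=("var", "size"),
        mean_var=("var", "mean"),
        mean_level=("mean_level", "mean"),
        mean_cov=("mean_cov", "mean"),
    )
    strata = strata[strata["count"] > 0]
    if strata.empty:
        warnings.warn("all strata empty; returning default gamma")
        return DEFAULT_GAMMA

    emp_sd = np.sqrt(strata["mean_var"].to_numpy())
    n_bar = strata["mean_cov"].to_numpy()
    p_bar = strata["mean_level"].to_numpy()

    sse = np.array(
        [np.sum((emp_sd - predicted_sd(n_bar, p_bar, g)) ** 2) for g in sweep]
    )
    best = float(sweep[int(np.argmin(sse))])
    logger.info("fitted gamma = %.4g over %d strata", best, len(strata))
    return best
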