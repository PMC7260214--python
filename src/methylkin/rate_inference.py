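"""Brute-force Bayesian inference of per-CpG methylation turnover rates.

The two kinetic rates are discretized on a multiplicative grid (80 values
per axis by default, 6400 combinations).  For each replicate time course the
likelihood of the observed counts is evaluated against the bank of expected
traces under the chosen error model, normalized to a joint posterior under a
uniform prior, and summarized by the maximum-likelihood combination,
marginal credible intervals and a border-mass identifiability flag.
Replicates are combined by medians and root-sum-square interval widths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .error_models import ErrorModelSpec, betabinomial_logpmf, binomial_logpmf
from .model_core import ModelConfig

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterGrid",
    "CpGTimeCourse",
    "PosteriorGrid",
    "CredibleInterval",
    "ReplicateFit",
    "RateEstimate",
    "build_grid",
    "filter_counts",
    "bank_log_likelihood",
    "fit_replicate",
    "credible_interval",
    "is_identifiable",
    "combine_replicates",
    "summarize_replicate",
    "infer_rates",
]


@dataclass(frozen=True)
class ParameterGrid:
    """Multiplicative rate grid shared by both axes.

    ``values`` descend from ``grid_max`` by a constant factor;
    ``combos[i]`` is the ``(k_de, k_me)`` pair with ``k_de`` index
    ``i // n`` and ``k_me`` index ``i % n``.
    """

    values: np.ndarray
    step_factor: float

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def n_combos(self) -> int:
        return self.n * self.n

    @property
    def combos(self) -> np.ndarray:
        de, me = np.meshgrid(self.values, self.values, indexing="ij")
        return np.column_stack([de.ravel(), me.ravel()])

    def combo_index(self, de_index: int, me_index: int) -> int:
        return de_index * self.n + me_index

    def nearest_index(self, rate: float) -> int:
        """Index of the grid value closest to ``rate`` in log space."""
        if rate <= 0:
            raise ValueError("rate must be positive")
        return int(np.argmin(np.abs(np.log(self.values) - np.log(rate))))


def build_grid(config: ModelConfig) -> ParameterGrid:
    """Build the default rate grid: ``v_i = grid_max / step_factor**i``."""
    i = np.arange(config.grid_steps)
    values = config.grid_max / config.grid_step_factor**i
    return ParameterGrid(values=values, step_factor=config.grid_step_factor)


@dataclass
class CpGTimeCourse:
    """Observed counts for one CpG, aligned to the configured timepoints.

    ``coverage`` and ``meth`` are ``(n_replicates, n_timepoints)`` float
    arrays with ``NaN`` marking missing calls.
    """

    cpg_id: str
    chrom: str
    pos: int
    days: np.ndarray
    replicates: list
    coverage: np.ndarray
    meth: np.ndarray

    @classmethod
    def from_frame(cls, df: pd.DataFrame, timepoints) -> "CpGTimeCourse":
        """Build from long-format rows of a single CpG (single condition)."""
        days = np.asarray(timepoints, dtype=float)
        reps = sorted(df["replicate"].unique())
        cov = np.full((len(reps), days.size), np.nan)
        meth = np.full((len(reps), days.size), np.nan)
        day_index = {d: j for j, d in enumerate(days)}
        for row in df.itertuples(index=False):
            j = day_index.get(float(row.day))
            if j is None:
                raise ValueError(
                    f"day {row.day} not in configured timepoints for {row.cpg_id}"
                )
            i = reps.index(row.replicate)
            cov[i, j] = row.coverage
            meth[i, j] = row.meth_count
        first = df.iloc[0]
        return cls(
            cpg_id=str(first["cpg_id"]),
            chrom=str(first["chrom"]),
            pos=int(first["pos"]),
            days=days,
            replicates=reps,
            coverage=cov,
            meth=meth,
        )


@dataclass
class PosteriorGrid:
    """Joint posterior over the rate grid for one replicate fit."""

    grid: ParameterGrid
    joint: np.ndarray  # (n_combos,), sums to 1
    log_like: np.ndarray
    mle_index: int

    @property
    def marginal_de(self) -> np.ndarray:
        return self.joint.reshape(self.grid.n, self.grid.n).sum(axis=1)

    @property
    def marginal_me(self) -> np.ndarray:
        return self.joint.reshape(self.grid.n, self.grid.n).sum(axis=0)

    @property
    def mle(self) -> tuple[float, float]:
        """(k_de, k_me) at the posterior maximum."""
        de, me = divmod(self.mle_index, self.grid.n)
        return float(self.grid.values[de]), float(self.grid.values[me])


@dataclass(frozen=True)
class CredibleInterval:
    """Central (equal-tail) interval on the ordered rate grid."""

    lo_index: int
    hi_index: int
    lo_rate: float
    hi_rate: float
    width_log10: float


@dataclass(frozen=True)
class ReplicateFit:
    k_de: float
    k_me: float
    ci_de_log10: float
    ci_me_log10: float
    identifiable: bool


@dataclass(frozen=True)
class RateEstimate:
    """Replicate-combined rate estimate for one CpG."""

    k_de_hat: float
    k_me_hat: float
    ci_de: float
    ci_me: float
    identifiable: bool
    n_replicates: int


class UnfittableError(ValueError):
    """Raised when a replicate has fewer than two usable timepoints."""


def filter_counts(
    table: pd.DataFrame,
    assay: str,
    min_coverage: int | None = None,
    timepoints=None,
    joint_na: bool = False,
) -> pd.DataFrame:
    """Apply assay-specific coverage/NA filtering to a long count table.

    ``amplicon``: calls below 100x coverage become NA (rows removed); a CpG
    is dropped entirely if any replicate is NA at day 0 or accumulates more
    than one NA over the time course (``joint_na=True`` instead counts NAs
    across all replicates jointly).  ``sureselect``: a CpG is dropped if any
    timepoint/replicate is below 50x.

    Attrition counts per rule are logged.
    """
    from .model_core import DEFAULT_TIMEPOINTS

    if assay not in ("amplicon", "sureselect"):
        raise ValueError(f"unknown assay: {assay!r}")
    days = np.asarray(
        DEFAULT_TIMEPOINTS if timepoints is None else timepoints, dtype=float
    )
    n_days = days.size
    n_in = table["cpg_id"].nunique()

    if assay == "sureselect":
        cutoff = 50 if min_coverage is None else min_coverage
        low = table.loc[table["coverage"] < cutoff, "cpg_id"].unique()
        out = table[~table["cpg_id"].isin(low)]
        logger.info(
            "sureselect filter (<%dx): %d -> %d CpGs", cutoff, n_in, out["cpg_id"].nunique()
        )
        return out.reset_index(drop=True)

    cutoff = 100 if min_coverage is None else min_coverage
    ok = table[table["coverage"] >= cutoff]
    n_masked = len(table) - len(ok)

    drop: set = set()
    for (cpg, _rep), sub in ok.groupby(["cpg_id", "replicate"], observed=True):
        present = set(float(d) for d in sub["day"])
        if 0.0 not in present:
            drop.add(cpg)
    if joint_na:
        na_counts = (
            ok.groupby("cpg_id", observed=True)["day"]
            .count()
            .reindex(table["cpg_id"].unique(), fill_value=0)
        )
        n_rep = table.groupby("cpg_id", observed=True)["replicate"].nunique()
        total_expected = n_rep * n_days
        over = na_counts.index[(total_expected - na_counts) > 1]
        drop.update(over)
    else:
        for (cpg, _rep), sub in ok.groupby(["cpg_id", "replicate"], observed=True):
            if n_days - sub["day"].nunique() > 1:
                drop.add(cpg)

    out = ok[~ok["cpg_id"].isin(drop)].reset_index(drop=True)
    logger.info(
        "amplicon filter (<%dx -> NA, day-0/multi-NA drop): %d -> %d CpGs "
        "(%d calls masked, %d CpGs dropped)",
        cutoff, n_in, out["cpg_id"].nunique(), n_masked, len(drop),
    )
    return out


def bank_log_likelihood(
    coverage: np.ndarray,
    meth: np.ndarray,
    bank: np.ndarray,
    error: ErrorModelSpec,
) -> np.ndarray:
    """Summed log likelihood of one replicate's counts against every bank row.

    ``coverage``/``meth`` are length-T float arrays (NaN = missing call);
    ``bank`` is the ``(n_combos, T)`` matrix of expected levels.  Missing
    timepoints are skipped.
    """
    cov = np.asarray(coverage, dtype=float)
    met = np.asarray(meth, dtype=float)
    keep = ~(np.isnan(cov) | np.isnan(met))
    if keep.sum() < 2:
        raise UnfittableError("need at least 2 non-missing timepoints")
    cov = cov[keep]
    met = met[keep]
    p = bank[:, keep]
    gamma = error.effective_gamma
    if gamma == 0:
        ll = binomial_logpmf(met[None, :], cov[None, :], p)
    else:
        ll = betabinomial_logpmf(met[None, :], cov[None, :], p, gamma)
    return ll.sum(axis=1)


def fit_replicate(
    coverage: np.ndarray,
    meth: np.ndarray,
    bank: np.ndarray,
    error: ErrorModelSpec,
    grid: ParameterGrid,
) -> PosteriorGrid:
    """Posterior over the rate grid for one replicate's time course.

    Uniform prior; the joint posterior is the renormalized likelihood.  Ties
    at the maximum (exactly equal posterior) are broken toward the lower
    total rate ``k_de + k_me`` and logged.
    """
    log_like = bank_log_likelihood(coverage, meth, bank, error)
    if not np.any(np.isfinite(log_like)):
        raise UnfittableError("likelihood is zero everywhere on the grid")
    log_post = log_like - logsumexp(log_like)
    joint = np.exp(log_post)
    joint /= joint.sum()

    best = np.flatnonzero(log_like == log_like.max())
    if best.size > 1:
        totals = grid.combos[best].sum(axis=1)
        logger.info(
            "MLE tie over %d combos; breaking toward lower total rate", best.size
        )
        mle_index = int(best[np.argmin(totals)])
    else:
        mle_index = int(best[0])
    return PosteriorGrid(grid=grid, joint=joint, log_like=log_like, mle_index=mle_index)


def credible_interval(
    marginal: np.ndarray, values: np.ndarray, level: float
) -> CredibleInterval:
    """Central interval covering ``level`` of the marginal mass.

    From each end of the ordered grid, whole points are trimmed while their
    cumulative mass stays within ``(1 - level)/2``.  The width is reported
    in log10 rate units, the natural scale of the multiplicative grid.
    """
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0,1): {level}")
    m = np.asarray(marginal, dtype=float)
    if m.size != values.size:
        raise ValueError("marginal and grid values must align")
    total = m.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        raise ValueError(f"marginal must sum to 1, got {total}")
    alpha = (1.0 - level) / 2.0
    tol = 1e-12
    csum_lo = np.cumsum(m)
    csum_hi = np.cumsum(m[::-1])
    lo = int(np.searchsorted(csum_lo, alpha + tol, side="right"))
    hi_trim = int(np.searchsorted(csum_hi, alpha + tol, side="right"))
    hi = m.size - 1 - hi_trim
    if hi < lo:  # extreme concentration: collapse onto the mode
        lo = hi = int(np.argmax(m))
    width = abs(np.log10(values[lo]) - np.log10(values[hi]))
    return CredibleInterval(
        lo_index=lo,
        hi_index=hi,
        lo_rate=float(values[hi]),
        hi_rate=float(values[lo]),
        width_log10=float(width),
    )


def is_identifiable(posterior: PosteriorGrid, threshold: float) -> bool:
    """True iff both marginals carry less than ``threshold`` mass at each border."""
    m_de = posterior.marginal_de
    m_me = posterior.marginal_me
    borders = (m_de[0], m_de[-1], m_me[0], m_me[-1])
    return bool(all(b < threshold for b in borders))


def summarize_replicate(
    posterior: PosteriorGrid, ci_level: float, border_threshold: float
) -> ReplicateFit:
    """MLE rates, marginal credible-interval widths and the border flag."""
    k_de, k_me = posterior.mle
    ci_de = credible_interval(posterior.marginal_de, posterior.grid.values, ci_level)
    ci_me = credible_interval(posterior.marginal_me, posterior.grid.values, ci_level)
    return ReplicateFit(
        k_de=k_de,
        k_me=k_me,
        ci_de_log10=ci_de.width_log10,
        ci_me_log10=ci_me.width_log10,
        identifiable=is_identifiable(posterior, border_threshold),
    )


def combine_replicates(fits) -> RateEstimate:
    """Combine per-replicate fits: median rates, ``sqrt(sum ci^2)/r`` widths.

    A CpG is identifiable only if every replicate passes the border rule.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("need at least one replicate fit")
    r = len(fits)
    return RateEstimate(
        k_de_hat=float(np.median([f.k_de for f in fits])),
        k_me_hat=float(np.median([f.k_me for f in fits])),
        ci_de=float(np.sqrt(sum(f.ci_de_log10**2 for f in fits)) / r),
        ci_me=float(np.sqrt(sum(f.ci_me_log10**2 for f in fits)) / r),
        identifiable=all(f.identifiable for f in fits),
        n_replicates=r,
    )


def infer_rates(
    table: pd.DataFrame,
    config: ModelConfig,
    error: ErrorModelSpec,
    k_E: float = 0.5,
    border_threshold: float | None = None,
    grid: ParameterGrid | None = None,
    bank: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fit every CpG in a long count table and combine replicates.

    Returns one row per fittable CpG with columns ``cpg_id``, ``chrom``,
    ``pos``, ``k_me``, ``k_de``, ``ci_me_log10``, ``ci_de_log10``,
    ``steady_state``, ``identifiable``, ``n_replicates``.
    """
    from .model_core import build_trace_bank

    if border_threshold is None:
        border_threshold = config.border_threshold_fit
    if grid is None:
        grid = build_grid(config)
    if bank is None:
        bank = build_trace_bank(grid, config, k_E=k_E)

    rows = []
    skipped = 0
    for cpg_id, sub in table.groupby("cpg_id", observed=True, sort=True):
        tc = CpGTimeCourse.from_frame(sub, config.timepoints)
        fits = []
        for i in range(len(tc.replicates)):
            try:
                post = fit_replicate(tc.coverage[i], tc.meth[i], bank, error, grid)
            except UnfittableError:
                continue
            fits.append(summarize_replicate(post, config.ci_level, border_threshold))
        if not fits:
            skipped += 1
            continue
        est = combine_replicates(fits)
        rows.append(
            {
                "cpg_id": tc.cpg_id,
                "chrom": tc.chrom,
                "pos": tc.pos,
                "k_me": est.k_me_hat,
                "k_de": est.k_de_hat,
                "ci_me_log10": est.ci_me,
                "ci_de_log10": est.ci_de,
                "steady_state": est.k_me_hat / (est.k_me_hat + est.k_de_hat),
                "identifiable": est.identifiable,
                "n_replicates": est.n_replicates,
            }
        )
    if skipped:
        logger.info("skipped %d CpGs with no fittable replicate", skipped)
    return pd.DataFrame(rows)
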