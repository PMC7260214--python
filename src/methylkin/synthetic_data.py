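"""Fully synthetic study inputs with the statistical structure the pipeline assumes.

Generates per-CpG true rate pairs, expected decay traces through the forward
model (including excision mixing and conversion error), and count tables
sampled under binomial or beta-binomial noise at configurable coverage —
plus paired wild-type/knockout cohorts with a shared de novo rate and a
demethylation-rate multiplier, for end-to-end recovery tests.

Everything is deterministic under the spec seed, and the per-CpG stream
layout guarantees that enlarging ``n_cpgs`` preserves the generated prefix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .error_models import ErrorModelSpec
from .model_core import ModelConfig, _solve_many

__all__ = [
    "SyntheticCohortSpec",
    "grid_range",
    "sample_true_rates",
    "expected_levels",
    "simulate_counts",
    "simulate_paired_conditions",
]

_REGIMES = ("log_uniform", "fixed", "two_arm")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Recipe for one synthetic cohort.

    ``coverage_dispersion=None`` draws fixed coverage; otherwise coverage is
    gamma-Poisson (negative-binomial-like) with that dispersion.
    ``mock_drift`` is an optional per-timepoint multiplicative drift applied
    to mock-condition levels.
    """

    n_cpgs: int = 100
    rate_regime: str = "log_uniform"
    fixed_rates: tuple = ()  # (k_de, k_me) pairs for the "fixed" regime
    coverage: float = 4000.0
    coverage_dispersion: float | None = None
    replicates: int = 3
    conditions: tuple[str, ...] = ("cre",)
    tet_multiplier: float = 3.0
    mock_drift: tuple[float, ...] | None = None
    k_E: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_regime not in _REGIMES:
            raise ValueError(f"unknown rate regime: {self.rate_regime!r}")
        if self.n_cpgs < 1:
            raise ValueError("n_cpgs must be >= 1")
        unknown = set(self.conditions) - {"cre", "mock", "wt", "ttko"}
        if unknown:
            raise ValueError(f"unknown conditions: {sorted(unknown)}")


def grid_range(config: ModelConfig) -> tuple[float, float]:
    """(min, max) rate representable on the configured grid."""
    lo = config.grid_max / config.grid_step_factor ** (config.grid_steps - 1)
    return lo, config.grid_max


def _cpg_rng(seed: int, i: int, stream: int = 0) -> np.random.Generator:
    # independent stream per CpG so the cohort prefix is stable under n_cpgs
    return np.random.default_rng([seed, stream, i])


def sample_true_rates(spec: SyntheticCohortSpec, config: ModelConfig) -> pd.DataFrame:
    """Draw per-CpG true ``(k_de, k_me)`` pairs under the chosen regime.

    ``log_uniform`` draws each rate log-uniformly over the grid range;
    ``fixed`` cycles through ``spec.fixed_rates``; ``two_arm`` mixes a
    highly methylated arm (steady state 0.7-0.95) with a lowly methylated
    arm (0.05-0.5) over log-uniform total turnover.
    """
    lo, hi = grid_range(config)
    rows = []
    for i in range(spec.n_cpgs):
        rng = _cpg_rng(spec.seed, i, stream=0)
        if spec.rate_regime == "fixed":
            if not spec.fixed_rates:
                raise ValueError("fixed regime requires fixed_rates")
            k_de, k_me = spec.fixed_rates[i % len(spec.fixed_rates)]
        elif spec.rate_regime == "log_uniform":
            k_de = np.exp(rng.uniform(np.log(lo), np.log(hi)))
            k_me = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        else:  # two_arm
            upper = rng.random() < 0.5
            m = rng.uniform(0.70, 0.95) if upper else rng.uniform(0.05, 0.50)
            total = np.exp(rng.uniform(np.log(0.02), np.log(1.0)))
            k_me = np.clip(m * total, lo, hi)
            k_de = np.clip((1.0 - m) * total, lo, hi)
        rows.append(
            {
                "cpg_id": f"cpg_{i:06d}",
                "chrom": "chr1",
                "pos": 1000 + 2 * i,
                "k_de": float(k_de),
                "k_me": float(k_me),
            }
        )
    return pd.DataFrame(rows)


def expected_levels(
    true_rates: pd.DataFrame,
    config: ModelConfig,
    condition: str = "cre",
    k_E: float = 0.5,
    mock_drift: tuple[float, ...] | None = None,
) -> np.ndarray:
    """Expected observable levels, one row per CpG, vectorized over the cohort.

    Deletion conditions (``cre``/``wt``/``ttko``) follow the dampened decay
    with excision mixing; ``mock`` stays at the conversion-corrected steady
    state, optionally times a per-timepoint drift.
    """
    k_de = true_rates["k_de"].to_numpy(dtype=float)
    k_me = true_rates["k_me"].to_numpy(dtype=float)
    t = np.asarray(config.timepoints, dtype=float)
    m_eq = k_me / (k_me + k_de)
    eps = config.conversion_error
    if condition == "mock":
        levels = np.tile(m_eq[:, None], (1, t.size))
        if mock_drift is not None:
            drift = np.asarray(mock_drift, dtype=float)
            if drift.size != t.size:
                raise ValueError("mock_drift must align with timepoints")
            levels = np.clip(levels * drift[None, :], 0.0, 1.0)
    else:
        raw = _solve_many(
            k_me, k_de, k_E, t, m_eq,
            rel_tol=config.ode_rel_tol, abs_tol=config.ode_abs_tol,
        )
        raw = np.clip(raw, 0.0, 1.0)
        levels = (1 - config.excision_residual) * raw + config.excision_residual * m_eq[:, None]
    return (1.0 - 2.0 * eps) * levels + eps


def _sample_counts_one(
    rng: np.random.Generator,
    p_row: np.ndarray,
    spec: SyntheticCohortSpec,
    error: ErrorModelSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Coverage and methylated counts for one CpG/replicate across timepoints."""
    n_t = p_row.size
    if spec.coverage_dispersion is None:
        n = np.full(n_t, int(round(spec.coverage)), dtype=np.int64)
    else:
        shape = 1.0 / spec.coverage_dispersion
        lam = rng.gamma(shape, spec.coverage * spec.coverage_dispersion, size=n_t)
        n = np.maximum(rng.poisson(lam), 1).astype(np.int64)
    gamma = error.effective_gamma
    if gamma == 0:
        c = rng.binomial(n, p_row)
    else:
        s = 1.0 / gamma - 1.0
        p_mix = rng.beta(p_row * s, (1.0 - p_row) * s)
        c = rng.binomial(n, p_mix)
    return n, c.astype(np.int64)


def simulate_counts(
    true_rates: pd.DataFrame,
    spec: SyntheticCohortSpec,
    config: ModelConfig,
    error: ErrorModelSpec,
) -> pd.DataFrame:
    """Sample a long-format count table for the cohort.

    One row per CpG x condition x replicate x timepoint, with columns
    matching the standard count-table schema.
    """
    t = np.asarray(config.timepoints, dtype=float)
    frames = []
    for condition in spec.conditions:
        levels = expected_levels(
            true_rates, config, condition=condition, k_E=spec.k_E,
            mock_drift=spec.mock_drift,
        )
        for i, rec in enumerate(true_rates.itertuples(index=False)):
            rng = _cpg_rng(spec.seed, i, stream=_REGIME_STREAMS[condition])
            for rep in range(1, spec.replicates + 1):
                n, c = _sample_counts_one(rng, levels[i], spec, error)
                frames.append(
                    pd.DataFrame(
                        {
                            "cpg_id": rec.cpg_id,
                            "chrom": rec.chrom,
                            "pos": rec.pos,
                            "condition": condition,
                            "replicate": rep,
                            "day": t,
                            "coverage": n,
                            "meth_count": c,
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)


_REGIME_STREAMS = {"cre": 1, "mock": 2, "wt": 3, "ttko": 4}


def simulate_paired_conditions(
    spec: SyntheticCohortSpec,
    config: ModelConfig,
    error: ErrorModelSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired WT/TTKO cohorts with shared k_me and a k_de multiplier.

    Returns ``(wt_table, ttko_table, truth)``.  The truth table carries all
    generating values, including both steady states, so recovery tests are
    self-contained.
    """
    if spec.tet_multiplier <= 0:
        raise ValueError("tet_multiplier must be positive")
    ttko_rates = sample_true_rates(spec, config)
    wt_rates = ttko_rates.copy()
    wt_rates["k_de"] = ttko_rates["k_de"] * spec.tet_multiplier

    ttko_spec = _with(spec, conditions=("ttko",))
    wt_spec = _with(spec, conditions=("wt",))
    ttko_table = simulate_counts(ttko_rates, ttko_spec, config, error)
    wt_table = simulate_counts(wt_rates, wt_spec, config, error)

    truth = ttko_rates.rename(columns={"k_de": "k_de_ttko"}).copy()
    truth["k_de_wt"] = wt_rates["k_de"].to_numpy()
    truth["m_ttko"] = truth["k_me"] / (truth["k_me"] + truth["k_de_ttko"])
    truth["m_wt"] = truth["k_me"] / (truth["k_me"] + truth["k_de_wt"])
    truth["tet_multiplier"] = spec.tet_multiplier
    return wt_table, ttko_table, truth


def _with(spec: SyntheticCohortSpec, **kwargs) -> SyntheticCohortSpec:
    import dataclasses

    return dataclasses.replace(spec, **kwargs)
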