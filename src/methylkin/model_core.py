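"""Forward model of methylation decay after induced loss of de novo activity.

A CpG's methylation fraction ``m(t)`` follows a two-rate kinetic model in
which unmethylated sites gain methylation at rate ``k_me`` and methylated
sites lose it at rate ``k_de``.  Induced loss of the de novo enzymes is
modelled by exponentially dampening ``k_me`` with rate ``k_E``::

    dm/dt = k_me * exp(-k_E * t) * (1 - m) - k_de * m

Expected observable traces are obtained by composing the ODE solution with
two measurement corrections: mixing of a residual undeleted allele fraction
with the day-0 signal, and symmetric bisulfite conversion / sequencing
error.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "DEFAULT_TIMEPOINTS",
    "RateParams",
    "ModelConfig",
    "MethylationTrace",
    "DegenerateRateError",
    "max_dilution_rate",
    "steady_state",
    "closed_form_trace",
    "solve_trace",
    "apply_excision_mix",
    "apply_conversion_error",
    "expected_trace",
    "build_trace_bank",
]

#: Days sampled in the reference time-course design.
DEFAULT_TIMEPOINTS = (0.0, 4.0, 8.0, 10.0, 13.0, 17.0, 29.0)


class DegenerateRateError(ValueError):
    """Raised when both kinetic rates are zero and no steady state exists."""


@dataclass(frozen=True)
class RateParams:
    """Kinetic parameters of one CpG.

    Parameters
    ----------
    k_me : float
        De novo methylation rate (per day), non-negative.
    k_de : float
        Demethylation rate (per day), non-negative.
    k_E : float
        Dampening rate of de novo enzyme loss (per day).  The default 0.5 is
        half the theoretical maximum dilution rate for a 16-h doubling time.
    """

    k_me: float
    k_de: float
    k_E: float = 0.5

    def __post_init__(self) -> None:
        if self.k_me < 0 or self.k_de < 0:
            raise ValueError(f"rates must be non-negative, got {self}")
        if self.k_E < 0:
            raise ValueError(f"k_E must be non-negative, got {self.k_E}")

    @property
    def m_eq(self) -> float:
        """Undampened steady-state methylation fraction k_me/(k_me+k_de)."""
        return steady_state(self)


@dataclass(frozen=True)
class ModelConfig:
    """Global forward-model and inference constants.

    Defaults reproduce the reference design: 8% residual functional alleles
    after excision, 99.75% conversion efficiency, a multiplicative rate grid
    with 80 values per axis spanning three orders of magnitude below the
    maximum rate of 2/day, central 95% credible intervals and border-mass
    identifiability cutoffs of 0.08 (data fits) and 0.05 (landscape).
    """

    excision_residual: float = 0.08
    conversion_error: float = 0.0025
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    grid_max: float = 2.0
    grid_steps: int = 80
    grid_step_factor: float = 1.1
    ci_level: float = 0.95
    border_threshold_fit: float = 0.08
    border_threshold_landscape: float = 0.05
    ode_rel_tol: float = 1e-8
    ode_abs_tol: float = 1e-8

    def __post_init__(self) -> None:
        if not 0 <= self.excision_residual < 1:
            raise ValueError(f"excision_residual must be in [0,1): {self.excision_residual}")
        if not 0 <= self.conversion_error < 0.5:
            raise ValueError(f"conversion_error must be in [0,0.5): {self.conversion_error}")
        tp = np.asarray(self.timepoints, dtype=float)
        if tp.size == 0 or tp[0] != 0 or np.any(np.diff(tp) <= 0):
            raise ValueError("timepoints must be strictly increasing and start at 0")
        if self.grid_steps < 2:
            raise ValueError("grid_steps must be >= 2")
        if self.grid_max <= 0 or self.grid_step_factor <= 1:
            raise ValueError("grid_max must be > 0 and grid_step_factor > 1")
        if not 0 < self.ci_level < 1:
            raise ValueError(f"ci_level must be in (0,1): {self.ci_level}")

    def replace(self, **kwargs) -> "ModelConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class MethylationTrace:
    """Expected methylation fraction at each sampled day."""

    times: np.ndarray
    levels: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "levels", np.asarray(self.levels, dtype=float))
        if self.times.shape != self.levels.shape:
            raise ValueError("times and levels must have the same shape")


def max_dilution_rate(doubling_time_hours: float = 16.0) -> float:
    """Theoretical maximum daily enzyme-dilution rate for a given doubling time.

    ``log(2) / (doubling_time_hours / 24)`` — the rate ceiling reached if an
    enzyme were lost purely by dilution through cell division.
    """
    if doubling_time_hours <= 0:
        raise ValueError("doubling time must be positive")
    return float(np.log(2.0) / (doubling_time_hours / 24.0))


def steady_state(params: RateParams) -> float:
    """Equilibrium methylation fraction ``k_me / (k_me + k_de)``."""
    total = params.k_me + params.k_de
    if total <= 0:
        raise DegenerateRateError("steady state undefined when k_me + k_de == 0")
    return params.k_me / total


def closed_form_trace(
    k_me: float, k_de: float, m0: float, times: np.ndarray
) -> MethylationTrace:
    """Exact solution of the undampened (constant-rate) model.

    ``m(t) = M_eq + (m0 - M_eq) * exp(-(k_me + k_de) * t)``; when both rates
    are zero the trace is constant at ``m0``.  Serves as the analytic oracle
    for the numeric solver in the ``k_E = 0`` limit.
    """
    t = np.asarray(times, dtype=float)
    total = k_me + k_de
    if total == 0:
        return MethylationTrace(t, np.full_like(t, float(m0)))
    m_eq = k_me / total
    return MethylationTrace(t, m_eq + (m0 - m_eq) * np.exp(-total * t))


def _validate_times(times: np.ndarray) -> np.ndarray:
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    return t


def _solve_many(
    k_me: np.ndarray,
    k_de: np.ndarray,
    k_E: float,
    times: np.ndarray,
    m0: np.ndarray,
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-8,
) -> np.ndarray:
    """Integrate the dampened ODE for many rate pairs as one vector system.

    Returns an array of shape ``(len(k_me), len(times))``.  All trajectories
    share the time axis, so a single adaptive solve covers the whole bank.
    """
    k_me = np.asarray(k_me, dtype=float)
    k_de = np.asarray(k_de, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    t = _validate_times(times)

    order = np.argsort(t, kind="stable")
    t_sorted = t[order]
    t_eval = t_sorted
    prepend_zero = t_eval.size == 0 or t_eval[0] != 0.0
    if prepend_zero:
        t_eval = np.concatenate([[0.0], t_eval])
    # strictly increasing t_eval required by solve_ivp
    t_unique, inverse = np.unique(t_eval, return_inverse=True)

    def rhs(t_: float, m: np.ndarray) -> np.ndarray:
        return k_me * np.exp(-k_E * t_) * (1.0 - m) - k_de * m

    if t_unique[-1] == 0.0:
        sol_y = m0[:, None]
    else:
        sol = solve_ivp(
            rhs,
            (0.0, float(t_unique[-1])),
            m0,
            method="DOP853",
            t_eval=t_unique,
            rtol=rel_tol,
            atol=abs_tol,
            # near-equilibrium trajectories have ~zero error estimates; an
            # unbounded step size would degrade the dense-output interpolation
            max_step=0.5,
        )
        if not sol.success:
            raise RuntimeError(f"ODE solver failed: {sol.message}")
        sol_y = sol.y

    levels_sorted = sol_y[:, inverse]
    if prepend_zero:
        levels_sorted = levels_sorted[:, 1:]
    out = np.empty((m0.size, t.size), dtype=float)
    out[:, order] = levels_sorted
    return out


def solve_trace(
    params: RateParams,
    times: np.ndarray,
    m0: float | None = None,
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-8,
) -> MethylationTrace:
    """Numerically solve the dampened ODE at the requested days.

    Parameters
    ----------
    params : RateParams
        Kinetic rates including the dampening rate ``k_E``.
    times : array-like
        Days at which to evaluate the solution (non-negative, any order).
    m0 : float, optional
        Initial methylation fraction.  Defaults to the undampened steady
        state of ``params`` (the pre-deletion equilibrium).
    """
    t = _validate_times(times)
    if m0 is None:
        m0 = steady_state(params)
    if not 0 <= m0 <= 1:
        raise ValueError(f"m0 must be in [0,1]: {m0}")
    levels = _solve_many(
        np.array([params.k_me]),
        np.array([params.k_de]),
        params.k_E,
        t,
        np.array([float(m0)]),
        rel_tol=rel_tol,
        abs_tol=abs_tol,
    )[0]
    return MethylationTrace(t, levels)


def apply_excision_mix(
    trace: MethylationTrace, day0_level: float, residual: float
) -> MethylationTrace:
    """Mix a residual fraction of the day-0 signal back into a trace.

    Models incomplete genetic excision: each level ``y`` becomes
    ``(1 - residual) * y + residual * day0_level``.
    """
    if not 0 <= residual < 1:
        raise ValueError(f"residual must be in [0,1): {residual}")
    if not 0 <= day0_level <= 1:
        raise ValueError(f"day0_level must be in [0,1]: {day0_level}")
    mixed = (1.0 - residual) * trace.levels + residual * day0_level
    return MethylationTrace(trace.times, mixed)


def apply_conversion_error(trace: MethylationTrace, epsilon: float) -> MethylationTrace:
    """Inject symmetric conversion/sequencing error: ``x -> (1-2e)*x + e``."""
    if not 0 <= epsilon < 0.5:
        raise ValueError(f"epsilon must be in [0,0.5): {epsilon}")
    return MethylationTrace(
        trace.times, (1.0 - 2.0 * epsilon) * trace.levels + epsilon
    )


def expected_trace(
    params: RateParams,
    config: ModelConfig,
    times: np.ndarray | None = None,
) -> MethylationTrace:
    """Full expected observable trace for one rate pair.

    Composition: numeric ODE solution from the steady-state initial
    condition, clamped to [0,1] against solver round-off, then excision
    mixing against the (uncorrected) steady state, then conversion error.
    """
    t = _validate_times(config.timepoints if times is None else times)
    m_eq = steady_state(params)
    trace = solve_trace(
        params, t, m0=m_eq, rel_tol=config.ode_rel_tol, abs_tol=config.ode_abs_tol
    )
    trace = MethylationTrace(trace.times, np.clip(trace.levels, 0.0, 1.0))
    trace = apply_excision_mix(trace, m_eq, config.excision_residual)
    return apply_conversion_error(trace, config.conversion_error)


def build_trace_bank(grid, config: ModelConfig, k_E: float = 0.5) -> np.ndarray:
    """Expected trace for every grid combination, one row per ``(k_de, k_me)``.

    All combinations are integrated in a single vectorized ODE solve.
    Returns an array of shape ``(n_combos, n_timepoints)`` whose entries lie
    within the conversion-error bounds ``[eps, 1 - eps]``.
    """
    combos = np.asarray(grid.combos, dtype=float)
    k_de = combos[:, 0]
    k_me = combos[:, 1]
    t = np.asarray(config.timepoints, dtype=float)
    m0 = k_me / (k_me + k_de)
    raw = _solve_many(
        k_me,
        k_de,
        k_E,
        t,
        m0,
        rel_tol=config.ode_rel_tol,
        abs_tol=config.ode_abs_tol,
    )
    raw = np.clip(raw, 0.0, 1.0)
    mixed = (1.0 - config.excision_residual) * raw + config.excision_residual * m0[:, None]
    eps = config.conversion_error
    return (1.0 - 2.0 * eps) * mixed + eps
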