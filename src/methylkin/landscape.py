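"""Identifiability landscape: inference on noise-free traces at every grid point.

For each of the 6400 rate combinations the expected trace is converted to
noise-free pseudo-counts at a fixed reference coverage, refit with the full
inference machinery, and summarized by its credible-interval widths and the
0.05 border-mass rule.  The result maps where the assay design can and
cannot recover rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaln

from .error_models import ErrorModelSpec
from .model_core import MethylationTrace, ModelConfig, build_trace_bank
from .rate_inference import (
    ParameterGrid,
    build_grid,
    credible_interval,
)

logger = logging.getLogger(__name__)

__all__ = ["Landscape", "pseudo_counts_from_trace", "compute_landscape"]

#: Median amplicon coverage used as the reference n.
DEFAULT_LANDSCAPE_COVERAGE = 3997


@dataclass
class Landscape:
    """CI-width matrices and the unidentifiable mask over the rate grid.

    Matrix element ``[i, j]`` corresponds to ``k_de = values[i]``,
    ``k_me = values[j]``.
    """

    grid: ParameterGrid
    ci_de_matrix: np.ndarray
    ci_me_matrix: np.ndarray
    unidentifiable_mask: np.ndarray
    coverage: int
    replicates: int

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per combo with CI widths and the flag."""
        de, me = np.meshgrid(self.grid.values, self.grid.values, indexing="ij")
        return pd.DataFrame(
            {
                "k_de": de.ravel(),
                "k_me": me.ravel(),
                "ci_de": self.ci_de_matrix.ravel(),
                "ci_me": self.ci_me_matrix.ravel(),
                "identifiable": ~self.unidentifiable_mask.ravel(),
            }
        )


def pseudo_counts_from_trace(
    trace: MethylationTrace, n: int, rounding: str = "half_even"
) -> np.ndarray:
    """Noise-free expected methylated-read counts at coverage ``n``.

    ``c_t = round(n * p_t)``; rounding is round-half-to-even by default
    (``half_up`` is available since the original convention is unstated).
    """
    if n < 1:
        raise ValueError("coverage n must be >= 1")
    x = n * np.asarray(trace.levels, dtype=float)
    if rounding == "half_even":
        c = np.rint(x)
    elif rounding == "half_up":
        c = np.floor(x + 0.5)
    else:
        raise ValueError(f"unknown rounding mode: {rounding!r}")
    return c.astype(np.int64)


def _bank_loglik_batch(
    counts: np.ndarray, n: int, bank: np.ndarray, error: ErrorModelSpec
):
    """Per-observation posterior loop with precomputed bank terms.

    Yields, for each row of ``counts``, the log likelihood (up to a constant
    in the combo index) of those counts against every bank row.  Dropping
    the combo-independent binomial coefficient leaves posteriors unchanged
    and roughly halves the special-function work.
    """
    gamma = error.effective_gamma
    p = np.clip(bank, 1e-12, 1 - 1e-12)
    if gamma == 0:
        logp = np.log(p)
        log1mp = np.log1p(-p)
        for c in counts:
            yield c[None, :] * logp + (n - c)[None, :] * log1mp
    else:
        s = 1.0 / gamma - 1.0
        alpha = p * s
        beta = (1.0 - p) * s
        b0 = betaln(alpha, beta)
        for c in counts:
            yield betaln(c[None, :] + alpha, (n - c)[None, :] + beta) - b0


def compute_landscape(
    config: ModelConfig,
    error: ErrorModelSpec | None = None,
    n: int = DEFAULT_LANDSCAPE_COVERAGE,
    replicates: int = 3,
    k_E: float = 0.5,
    rounding: str = "half_even",
) -> Landscape:
    """Fit every grid combination's own noise-free trace and map confidence.

    The fit of identical pseudo-replicates is deterministic, so a single fit
    per combo is performed and the combined interval width is scaled by
    ``sqrt(r)/r`` (the standard error over ``r`` identical replicates).  The
    mask applies the landscape border rule (default threshold 0.05) to both
    marginals.
    """
    if error is None:
        error = ErrorModelSpec(kind="betabinomial")
    grid = build_grid(config)
    bank = build_trace_bank(grid, config, k_E=k_E)
    t = np.asarray(config.timepoints, dtype=float)
    counts = np.stack(
        [pseudo_counts_from_trace(MethylationTrace(t, row), n, rounding) for row in bank]
    )

    g = grid.n
    ci_de = np.empty(grid.n_combos)
    ci_me = np.empty(grid.n_combos)
    border_fail = np.empty(grid.n_combos, dtype=bool)
    scale = np.sqrt(replicates) / replicates
    threshold = config.border_threshold_landscape

    for idx, ll in enumerate(_bank_loglik_batch(counts, n, bank, error)):
        ll_sum = ll.sum(axis=1)
        ll_sum -= ll_sum.max()
        post = np.exp(ll_sum)
        post /= post.sum()
        post2d = post.reshape(g, g)
        m_de = post2d.sum(axis=1)
        m_me = post2d.sum(axis=0)
        ci_de[idx] = (
            credible_interval(m_de, grid.values, config.ci_level).width_log10 * scale
        )
        ci_me[idx] = (
            credible_interval(m_me, grid.values, config.ci_level).width_log10 * scale
        )
        border_fail[idx] = not (
            m_de[0] < threshold
            and m_de[-1] < threshold
            and m_me[0] < threshold
            and m_me[-1] < threshold
        )

    logger.info(
        "landscape: %d combos, %d unidentifiable under %.2f border rule",
        grid.n_combos, int(border_fail.sum()), threshold,
    )
    return Landscape(
        grid=grid,
        ci_de_matrix=ci_de.reshape(g, g),
        ci_me_matrix=ci_me.reshape(g, g),
        unidentifiable_mask=border_fail.reshape(g, g),
        coverage=n,
        replicates=replicates,
    )
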