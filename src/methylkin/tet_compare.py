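"""Attribution of active-demethylation (TET) activity from paired conditions.

Given a knockout background where only passive demethylation operates and a
wild-type background with full activity, a shared de novo rate plus the two
steady-state methylation levels determine the wild-type demethylation rate:

    k_me       = k_de_ttko * m_ttko / (1 - m_ttko)
    k_de_wt^   = k_de_ttko * m_ttko * (1 - m_wt) / ((1 - m_ttko) * m_wt)

TET activity is reported as ``log2(k_de_wt) - log2(k_de_ttko)``.  A bin-wise
mock normalization removes treatment-protocol drift from the treated time
courses before inference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

logger = logging.getLogger(__name__)

__all__ = [
    "TetComparison",
    "mock_normalize",
    "predict_kde_wt",
    "tet_activity_log2",
    "tet_comparison_table",
    "validate_prediction",
]


@dataclass(frozen=True)
class TetComparison:
    """Steady states, rates and TET activity for one CpG."""

    m_wt: float
    m_ttko: float
    k_de_ttko: float
    k_de_wt_hat: float
    tet_activity: float


def mock_normalize(
    cre_table: pd.DataFrame,
    mock_table: pd.DataFrame,
    n_bins: int = 10,
    direction: str = "divide",
) -> pd.DataFrame:
    """Remove mock-treatment drift from a treated count table.

    CpGs are binned by their mock day-0 mean level in 10% increments
    (half-open bins, the last closed at 1).  For each bin and day, a factor
    ``f = mean_mock(day) / mean_mock(0)`` is computed; each treated level is
    divided by its bin's factor (``direction="multiply"`` flips this) and
    clipped to [0, 1].  Methylated counts are rescaled accordingly at
    unchanged coverage.

    Empty bins get factor 1 with a warning; a day present in the treated
    table but absent from the mock table is an error.
    """
    if direction not in ("divide", "multiply"):
        raise ValueError(f"direction must be 'divide' or 'multiply': {direction!r}")
    cre_days = set(cre_table["day"].unique())
    mock_days = set(mock_table["day"].unique())
    missing = cre_days - mock_days
    if missing:
        raise ValueError(f"mock table lacks timepoints {sorted(missing)}")

    mock = mock_table.assign(level=mock_table["meth_count"] / mock_table["coverage"])
    day0_mean = (
        mock[mock["day"] == 0].groupby("cpg_id", observed=True)["level"].mean()
    )
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bin_of = pd.Series(
        np.clip(np.digitize(day0_mean.to_numpy(), edges[1:-1], right=False), 0, n_bins - 1),
        index=day0_mean.index,
    )

    mock = mock.assign(bin=mock["cpg_id"].map(bin_of), day_f=mock["day"].astype(float))
    bin_day_mean = mock.groupby(["bin", "day_f"], observed=True)["level"].mean()

    factors: dict[tuple[int, float], float] = {}
    for b in range(n_bins):
        base = bin_day_mean.get((b, 0.0), np.nan)
        if not np.isfinite(base) or base == 0:
            logger.warning("mock bin %d empty or zero at day 0; using factor 1", b)
            for d in cre_days:
                factors[(b, float(d))] = 1.0
            continue
        for d in cre_days:
            val = bin_day_mean.get((b, float(d)), np.nan)
            factors[(b, float(d))] = float(val / base) if np.isfinite(val) else 1.0

    out = cre_table.copy()
    level = out["meth_count"] / out["coverage"]
    cre_bins = out["cpg_id"].map(bin_of)
    if cre_bins.isna().any():
        raise ValueError("treated table contains CpGs absent from the mock table")
    f = np.array(
        [factors[(int(b), float(d))] for b, d in zip(cre_bins, out["day"])]
    )
    corrected = level / f if direction == "divide" else level * f
    corrected = np.clip(corrected, 0.0, 1.0)
    out["meth_count"] = np.rint(corrected * out["coverage"]).astype(np.int64)
    return out


def predict_kde_wt(m_wt, m_ttko, k_de_ttko):
    """Predict the wild-type demethylation rate from two steady states.

    Requires both steady-state fractions strictly inside (0, 1); the shared
    de novo rate is eliminated through the steady-state relation.
    """
    m_wt = np.asarray(m_wt, dtype=float)
    m_ttko = np.asarray(m_ttko, dtype=float)
    k = np.asarray(k_de_ttko, dtype=float)
    if np.any((m_wt <= 0) | (m_wt >= 1) | (m_ttko <= 0) | (m_ttko >= 1)):
        raise ValueError("steady-state fractions must lie strictly in (0,1)")
    out = k * m_ttko * (1.0 - m_wt) / ((1.0 - m_ttko) * m_wt)
    return out[()] if out.ndim == 0 else out


def tet_activity_log2(k_de_wt, k_de_ttko):
    """``log2(k_de_wt) - log2(k_de_ttko)``; both rates must be positive."""
    k_wt = np.asarray(k_de_wt, dtype=float)
    k_ko = np.asarray(k_de_ttko, dtype=float)
    if np.any(k_wt <= 0) or np.any(k_ko <= 0):
        raise ValueError("rates must be positive")
    out = np.log2(k_wt) - np.log2(k_ko)
    return out[()] if out.ndim == 0 else out


def tet_comparison_table(
    table: pd.DataFrame,
    clip: float = 1e-6,
) -> pd.DataFrame:
    """Per-CpG TET comparison from columns ``m_wt``, ``m_ttko``, ``k_de_ttko``.

    Steady states exactly at 0 or 1 are clipped inward by ``clip`` and
    flagged in a ``clipped`` column rather than erroring, so genome-scale
    tables with extreme CpGs survive.
    """
    m_wt = table["m_wt"].to_numpy(dtype=float)
    m_ttko = table["m_ttko"].to_numpy(dtype=float)
    clipped = (m_wt <= 0) | (m_wt >= 1) | (m_ttko <= 0) | (m_ttko >= 1)
    m_wt = np.clip(m_wt, clip, 1 - clip)
    m_ttko = np.clip(m_ttko, clip, 1 - clip)
    k_hat = predict_kde_wt(m_wt, m_ttko, table["k_de_ttko"].to_numpy(dtype=float))
    out = table.copy()
    out["k_de_wt_hat"] = k_hat
    out["tet_activity"] = tet_activity_log2(k_hat, table["k_de_ttko"].to_numpy())
    out["clipped"] = clipped
    return out


def validate_prediction(
    inferred_kde_wt: np.ndarray, predicted_kde_wt: np.ndarray
) -> dict:
    """Agreement between time-course-inferred and steady-state-predicted rates.

    Pearson correlation of log10 rates over paired CpGs (both routes must be
    available and positive); returns the correlation, p-value and the paired
    log-rate arrays for scatter export.
    """
    a = np.asarray(inferred_kde_wt, dtype=float)
    b = np.asarray(predicted_kde_wt, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired arrays must have the same shape")
    keep = (a > 0) & (b > 0)
    a, b = a[keep], b[keep]
    if a.size < 3:
        raise ValueError("need at least 3 valid pairs")
    la, lb = np.log10(a), np.log10(b)
    if np.allclose(la, la[0]) or np.allclose(lb, lb[0]):
        r, p = (1.0 if np.allclose(la - la.mean(), lb - lb.mean()) else 0.0), np.nan
    else:
        r, p = pearsonr(la, lb)
    return {"r": float(r), "p_value": float(p) if p == p else float("nan"),
            "n": int(a.size), "log10_inferred": la, "log10_predicted": lb}
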