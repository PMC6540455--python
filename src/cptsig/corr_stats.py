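"""Correlation coefficients and their significance.

This is the statistical kernel every screening stage calls.  Significance
of a Pearson (or Spearman) coefficient is assessed with the classical
t-transformation for a zero-correlation null,

    t = r * sqrt((n - 2) / (1 - r^2)),   t ~ Student-t with n - 2 df,

always two-sided, because the screens filter on |r|.  No multiple-testing
correction is applied anywhere; callers log the expected false-positive
count (feature count x p_max) so the consequence is visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .matrix_io import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CorrelationRecord",
    "DegenerateInputError",
    "pearson",
    "spearman",
    "correlation_p_value",
    "correlate_matrix_to_reference",
    "effective_abs_r_cutoff",
]

_P_FLOOR = np.finfo(float).tiny


class DegenerateInputError(ValueError):
    """A correlation was requested on a zero-variance vector."""


@dataclass(frozen=True)
class CorrelationRecord:
    """One feature's correlation (r), two-sided significance (p) and n.

    ``ok`` is False for features whose correlation is undefined (zero
    variance); such records carry NaN r/p and are excluded downstream
    rather than aborting a whole run.
    """

    feature_id: str
    r: float
    p: float
    n: int
    ok: bool = True

    def passes(self, r_min: float, p_max: float) -> bool:
        """Inclusive on |r| >= r_min, strict on p < p_max."""
        return self.ok and abs(self.r) >= r_min and self.p < p_max


def correlation_p_value(r: float, n: int) -> float:
    """Two-sided p-value for a correlation coefficient under the null rho = 0.

    For |r| == 1 the t statistic diverges; the smallest representable
    positive value is returned with a log note, keeping p in (0, 1].
    """
    if n < 3:
        raise ValueError("need n >= 3 for a correlation p-value")
    if not np.isfinite(r) or abs(r) > 1:
        raise ValueError(f"invalid correlation coefficient {r!r}")
    if abs(r) == 1.0:
        logger.debug("|r| == 1: returning smallest positive p")
        return _P_FLOOR
    df = n - 2
    t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(min(max(p, _P_FLOOR), 1.0))


def _as_vector(x: Sequence[float]) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-D vector")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values in input vector")
    return v


def pearson(x: Sequence[float], y: Sequence[float], feature_id: str = "") -> CorrelationRecord:
    """Sample Pearson product-moment correlation with its t-based p-value."""
    xv, yv = _as_vector(x), _as_vector(y)
    n = xv.size
    if yv.size != n:
        raise ValueError(f"length mismatch: {n} vs {yv.size}")
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    sx = float(np.sqrt(xc @ xc))
    sy = float(np.sqrt(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError("zero variance input to pearson")
    r = float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))
    return CorrelationRecord(feature_id, r, correlation_p_value(r, n), n)


def spearman(x: Sequence[float], y: Sequence[float], feature_id: str = "") -> CorrelationRecord:
    """Spearman rank correlation: Pearson on mid-ranks (ties get average ranks)."""
    xv, yv = _as_vector(x), _as_vector(y)
    rx = stats.rankdata(xv, method="average")
    ry = stats.rankdata(yv, method="average")
    try:
        rec = pearson(rx, ry, feature_id)
    except DegenerateInputError:
        raise DegenerateInputError("zero rank variance input to spearman") from None
    return rec


def correlate_matrix_to_reference(
    m: ExpressionMatrix,
    ref: Sequence[float],
    method: Literal["pearson", "spearman"] = "pearson",
) -> list[CorrelationRecord]:
    """Correlate every feature row of ``m`` against a reference vector.

    Vectorized over rows; order follows the matrix.  Zero-variance rows
    yield a flagged record (``ok=False``, NaN r/p) instead of aborting.
    """
    ref_v = _as_vector(ref)
    n = m.n_samples
    if ref_v.size != n:
        raise ValueError(f"reference length {ref_v.size} != sample count {n}")
    values = m.values
    if method == "spearman":
        values = np.apply_along_axis(stats.rankdata, 1, values)
        ref_v = stats.rankdata(ref_v)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")

    rc = ref_v - ref_v.mean()
    s_ref = np.sqrt(rc @ rc)
    if s_ref == 0.0:
        raise DegenerateInputError("zero variance reference vector")
    xc = values - values.mean(axis=1, keepdims=True)
    s_rows = np.sqrt(np.einsum("ij,ij->i", xc, xc))
    degenerate = s_rows == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ rc) / (s_rows * s_ref)
    r = np.clip(r, -1.0, 1.0)

    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.clip(np.where(np.abs(r) == 1.0, _P_FLOOR, p), _P_FLOOR, 1.0)

    n_degenerate = int(degenerate.sum())
    if n_degenerate:
        logger.info("flagged %d zero-variance features during correlation", n_degenerate)
    records = []
    for i, fid in enumerate(m.feature_ids):
        if degenerate[i]:
            records.append(CorrelationRecord(fid, float("nan"), float("nan"), n, ok=False))
        else:
            records.append(CorrelationRecord(fid, float(r[i]), float(p[i]), n))
    return records


def effective_abs_r_cutoff(n: int, p_max: float, r_min: float = 0.0) -> float:
    """The |r| value a feature must reach to satisfy both screen thresholds.

    Inverts the t map: p < p_max at n - 2 df corresponds to
    |r| > t_crit / sqrt(n - 2 + t_crit^2).  With few samples the p
    criterion binds (e.g. n = 6, p_max = 0.05 requires |r| > ~0.811,
    well above the usual r_min = 0.5); with many samples r_min binds.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    df = n - 2
    t_crit = stats.t.isf(p_max / 2.0, df)
    r_crit = t_crit / np.sqrt(df + t_crit * t_crit)
    return float(max(r_min, r_crit))
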