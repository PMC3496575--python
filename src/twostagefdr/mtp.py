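"""Multiple-testing primitives.

Two-sided p-values for standardized normal test statistics, the
Benjamini-Hochberg (BH) step-up procedure, and a t-test mode in which
t-distribution p-values are mapped back to normal quantiles so that the
downstream sequential machinery (which assumes known variances) can be
applied to raw-data input.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats

# Floor applied before logs/quantiles; Phi^-1(1 - p/2) must stay finite.
MIN_P = 1e-300

__all__ = [
    "MIN_P",
    "BHResult",
    "two_sided_p_from_z",
    "z_from_two_sided_p",
    "bh_stepup",
    "bh_mask",
    "p_from_samples_tapprox",
]


def two_sided_p_from_z(z):
    """Two-sided p-value 2(1 - Phi(|z|)) of a standardized normal statistic.

    Parameters
    ----------
    z : float or array_like
        Standardized test statistic(s); must be finite.

    Returns
    -------
    float or ndarray
        p-values in (0, 1], clipped below at ``MIN_P``.
    """
    z_arr = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z_arr)):
        raise ValueError("test statistics must be finite")
    p = 2.0 * special.ndtr(-np.abs(z_arr))
    p = np.clip(p, MIN_P, 1.0)
    return float(p) if np.isscalar(z) or z_arr.ndim == 0 else p


def z_from_two_sided_p(p, sign=1.0):
    """Invert a two-sided p-value to a signed normal quantile.

    ``z = Phi^-1(1 - p/2) * sign``; used to treat t-test p-values as if they
    came from a known-variance z-test.
    """
    p_arr = np.clip(np.asarray(p, dtype=float), MIN_P, 1.0)
    z = -special.ndtri(p_arr / 2.0) * np.sign(np.asarray(sign, dtype=float))
    return float(z) if np.isscalar(p) else z


@dataclass(frozen=True)
class BHResult:
    """Outcome of the BH step-up procedure.

    Attributes
    ----------
    d : int
        Index of the largest ordered p-value at or below its step threshold
        (0 when nothing is rejected).
    rejected : ndarray of bool
        Rejection mask aligned with the input order.
    alpha : float
        Nominal FDR level.
    m : int
        Number of hypotheses tested.
    threshold : float
        Effective rejection threshold ``d * alpha / m`` (0.0 when d = 0).
    ids : ndarray
        Hypothesis identifiers aligned with ``rejected``.
    """

    d: int
    rejected: np.ndarray
    alpha: float
    m: int
    threshold: float
    ids: np.ndarray = field(repr=False)

    @property
    def rejected_ids(self) -> np.ndarray:
        return self.ids[self.rejected]

    @property
    def n_rejected(self) -> int:
        return int(self.rejected.sum())


def bh_mask(p: np.ndarray, alpha: float) -> tuple[int, np.ndarray]:
    """Fast path of the BH step-up: (d, rejection mask) for a p-value array.

    The rejection set is defined by the threshold d*alpha/m, so hypotheses
    tied at the boundary are rejected together.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    ps = np.sort(p)
    passing = np.nonzero(ps <= alpha * np.arange(1, m + 1) / m)[0]
    if passing.size == 0:
        return 0, np.zeros(m, dtype=bool)
    d = int(passing[-1]) + 1
    return d, p <= d * alpha / m


def bh_stepup(p, alpha: float, ids=None) -> BHResult:
    """Benjamini-Hochberg step-up procedure at FDR level ``alpha``.

    Rejects every hypothesis whose p-value is at or below d*alpha/m where d
    is the largest index i with ordered p_(i) <= i*alpha/m.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    if ids is None:
        ids = np.arange(p.size)
    else:
        ids = np.asarray(ids)
        if ids.size != p.size:
            raise ValueError("ids and p-values must have equal length")
    d, mask = bh_mask(p, alpha)
    return BHResult(
        d=d,
        rejected=mask,
        alpha=float(alpha),
        m=int(p.size),
        threshold=d * alpha / p.size if d else 0.0,
        ids=ids,
    )


def p_from_samples_tapprox(group_a, group_b=None) -> float:
    """Two-sided t-test p-value from raw observations.

    One-sample test of mean zero when ``group_b`` is None, otherwise the
    pooled-variance two-sample test. The caller maps the result back to a
    normal quantile (``z_from_two_sided_p``) for sequential-p computation.
    """
    a = np.asarray(group_a, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 observations per group")
    if group_b is None:
        if np.var(a, ddof=1) <= 0.0:
            raise ValueError("zero variance in sample")
        res = stats.ttest_1samp(a, 0.0)
    else:
        b = np.asarray(group_b, dtype=float)
        if b.size < 2:
            raise ValueError("need at least 2 observations per group")
        if np.var(a, ddof=1) <= 0.0 or np.var(b, ddof=1) <= 0.0:
            raise ValueError("zero variance in sample")
        res = stats.ttest_ind(a, b, equal_var=True)
    return float(np.clip(res.pvalue, MIN_P, 1.0))
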