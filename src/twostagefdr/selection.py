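"""Interim selection rules for two-stage screening designs.

Three rules decide which hypotheses receive second-stage observations:

* fixed threshold -- select every hypothesis with first-stage p <= gamma1;
* FNS (fixed number selection) -- select the m2 hypotheses with the
  smallest first-stage p-values; the effective gamma1 for the sequential
  p-value is the largest selected p-value p_(m2);
* FDRS (FDR-threshold selection) -- select the BH rejections at an interim
  level alpha1 > alpha; if none are rejected the whole experiment stops.
  The effective gamma1 is the BH critical value m2*alpha1/m, floored at the
  m_s-smallest p-value when fewer than m_s hypotheses were selected (the
  floor repairs FDR inflation of the integrated test when the selected set
  is very small; m_s = 6 is the recommended default).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mtp import bh_mask

__all__ = [
    "SelectionRule",
    "InterimSelection",
    "select_fixed_threshold",
    "select_top_k",
    "select_fdrs",
    "select",
]

_KINDS = ("fixed_threshold", "fns", "fdrs")


@dataclass(frozen=True)
class SelectionRule:
    """Parameterization of one interim selection rule.

    Only the fields relevant to ``kind`` may be set: ``gamma1`` for
    fixed_threshold, ``m2`` for fns, ``alpha1`` (and ``ms``) for fdrs.
    """

    kind: str
    gamma1: float | None = None
    m2: int | None = None
    alpha1: float | None = None
    ms: int = 0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.kind == "fixed_threshold":
            if self.gamma1 is None or not (0.0 < self.gamma1 < 1.0):
                raise ValueError("fixed_threshold requires gamma1 in (0, 1)")
            if self.m2 is not None or self.alpha1 is not None or self.ms:
                raise ValueError("fixed_threshold takes only gamma1")
        elif self.kind == "fns":
            if self.m2 is None or self.m2 < 1:
                raise ValueError("fns requires a positive m2")
            if self.gamma1 is not None or self.alpha1 is not None or self.ms:
                raise ValueError("fns takes only m2")
        else:  # fdrs
            if self.alpha1 is None or not (0.0 < self.alpha1 < 1.0):
                raise ValueError("fdrs requires alpha1 in (0, 1)")
            if self.ms < 0:
                raise ValueError("ms must be >= 0")
            if self.gamma1 is not None or self.m2 is not None:
                raise ValueError("fdrs takes only alpha1 and ms")

    @classmethod
    def fixed(cls, gamma1: float) -> "SelectionRule":
        return cls(kind="fixed_threshold", gamma1=gamma1)

    @classmethod
    def fns(cls, m2: int) -> "SelectionRule":
        return cls(kind="fns", m2=m2)

    @classmethod
    def fdrs(cls, alpha1: float, ms: int = 6) -> "SelectionRule":
        return cls(kind="fdrs", alpha1=alpha1, ms=ms)

    def describe(self) -> dict:
        out = {"kind": self.kind}
        if self.kind == "fixed_threshold":
            out["gamma1"] = self.gamma1
        elif self.kind == "fns":
            out["m2"] = self.m2
        else:
            out.update(alpha1=self.alpha1, ms=self.ms)
        return out


@dataclass(frozen=True)
class InterimSelection:
    """Result of an interim analysis.

    ``gamma1_effective`` is the threshold fed into the sequential p-value;
    it is NaN when the trial stopped (no second stage takes place).
    """

    selected: np.ndarray = field(repr=False)
    m2: int
    gamma1_effective: float
    stopped: bool = False

    def __post_init__(self):
        if int(self.selected.sum()) != self.m2:
            raise ValueError("m2 must equal the number of selected hypotheses")
        if self.stopped and self.m2 != 0:
            raise ValueError("a stopped trial selects nothing")


def _validate_p1(p1) -> np.ndarray:
    p1 = np.asarray(p1, dtype=float)
    if p1.size == 0:
        raise ValueError("empty p-value vector")
    if np.any(~np.isfinite(p1)) or np.any(p1 <= 0.0) or np.any(p1 > 1.0):
        raise ValueError("first-stage p-values must lie in (0, 1]")
    return p1


def select_fixed_threshold(p1, gamma1: float) -> InterimSelection:
    """Select every hypothesis with first-stage p-value <= gamma1."""
    p1 = _validate_p1(p1)
    if not (0.0 < gamma1 < 1.0):
        raise ValueError("gamma1 must be in (0, 1)")
    mask = p1 <= gamma1
    return InterimSelection(selected=mask, m2=int(mask.sum()),
                            gamma1_effective=float(gamma1), stopped=False)


def select_top_k(p1, m2_target: int) -> InterimSelection:
    """Select the m2_target hypotheses with smallest first-stage p-values (FNS).

    Boundary ties are broken by the stable original hypothesis order so that
    exactly m2_target hypotheses are selected; the effective gamma1 is the
    largest selected p-value p_(m2).
    """
    p1 = _validate_p1(p1)
    if not (1 <= m2_target <= p1.size):
        raise ValueError(f"m2_target must be in [1, {p1.size}], got {m2_target}")
    order = np.argsort(p1, kind="stable")
    mask = np.zeros(p1.size, dtype=bool)
    mask[order[:m2_target]] = True
    return InterimSelection(selected=mask, m2=int(m2_target),
                            gamma1_effective=float(p1[order[m2_target - 1]]),
                            stopped=False)


def select_fdrs(p1, alpha1: float, ms: int = 0) -> InterimSelection:
    """Select the BH rejections at interim level alpha1 (FDRS).

    With no rejection the trial stops for futility (under the global null
    this happens with probability 1 - alpha1).  Otherwise the effective
    gamma1 is the BH critical value m2*alpha1/m; when 0 < m2 < ms it is
    floored at the ms-smallest first-stage p-value.  The floor raises only
    the threshold used by the sequential p-value -- the selected set itself
    is not enlarged.
    """
    p1 = _validate_p1(p1)
    if not (0.0 < alpha1 < 1.0):
        raise ValueError("alpha1 must be in (0, 1)")
    if ms < 0:
        raise ValueError("ms must be >= 0")
    m = p1.size
    m2, mask = bh_mask(p1, alpha1)
    if m2 == 0:
        return InterimSelection(selected=mask, m2=0,
                                gamma1_effective=float("nan"), stopped=True)
    gamma1 = m2 * alpha1 / m
    if 0 < m2 < ms:
        p_ms = np.partition(p1, min(ms, m) - 1)[min(ms, m) - 1]
        gamma1 = max(gamma1, float(p_ms))
    return InterimSelection(selected=mask, m2=int(m2),
                            gamma1_effective=float(min(gamma1, 1.0)), stopped=False)


def select(p1, rule: SelectionRule) -> InterimSelection:
    """Apply a :class:`SelectionRule` to first-stage p-values."""
    if rule.kind == "fixed_threshold":
        return select_fixed_threshold(p1, rule.gamma1)
    if rule.kind == "fns":
        return select_top_k(p1, rule.m2)
    return select_fdrs(p1, rule.alpha1, rule.ms)
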