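"""Orchestration of a complete two-stage analysis.

Given per-hypothesis standardized stage means, a selection rule and a
nominal FDR level, run either the integrated final test (BH on sequential
p-values from the pooled data of both stages) or the pilot final test (BH
on second-stage p-values of the selected hypotheses only), plus the two
single-stage baselines.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mtp import bh_stepup, p_from_samples_tapprox, two_sided_p_from_z, z_from_two_sided_p
from .selection import InterimSelection, SelectionRule, select
from .seqpval import DEFAULT_SETTINGS, QuadratureSettings, sequential_p_all

__all__ = [
    "DataValidationError",
    "TwoStageDataset",
    "FinalAnalysis",
    "run_integrated",
    "run_pilot",
    "run_single_stage",
    "dataset_from_statistics",
    "dataset_from_observations",
]


class DataValidationError(ValueError):
    """Inconsistent or incomplete input data."""


@dataclass
class TwoStageDataset:
    """Per-hypothesis standardized stage means of a two-stage experiment.

    ``z2`` may contain NaN for hypotheses without second-stage data (real
    experiments only measure the selected ones); the analysis validates that
    every selected hypothesis has a finite ``z2``.  ``is_alternative`` and
    ``mu`` are simulation truth labels and are absent for real data.
    """

    z1: np.ndarray
    z2: np.ndarray | None
    n1: int
    n2: int
    ids: np.ndarray = None
    is_alternative: np.ndarray | None = None
    mu: np.ndarray | None = None

    def __post_init__(self):
        self.z1 = np.asarray(self.z1, dtype=float)
        if self.ids is None:
            self.ids = np.arange(self.m)
        else:
            self.ids = np.asarray(self.ids)
        if self.z2 is not None:
            self.z2 = np.asarray(self.z2, dtype=float)
            if self.z2.shape != self.z1.shape:
                raise DataValidationError("z1 and z2 must have equal length")
        if self.n1 < 1 or self.n2 < 1:
            raise DataValidationError("stage sample sizes must be positive")
        if self.is_alternative is not None:
            self.is_alternative = np.asarray(self.is_alternative, dtype=bool)

    @property
    def m(self) -> int:
        return self.z1.size

    @property
    def w1(self) -> float:
        """Information fraction n1/(n1+n2) of the first stage."""
        return self.n1 / (self.n1 + self.n2)

    def z_pooled(self) -> np.ndarray:
        """Standardized overall mean sqrt(w1)*z1 + sqrt(1-w1)*z2."""
        if self.z2 is None:
            raise DataValidationError("second-stage statistics are missing")
        w1 = self.w1
        return np.sqrt(w1) * self.z1 + np.sqrt(1.0 - w1) * self.z2


@dataclass
class FinalAnalysis:
    """Final test decision with rejection bookkeeping.

    ``final_p`` is aligned with ``p_ids``: all m hypotheses for the
    integrated approach and the single-stage baselines, the m2 selected
    hypotheses for the pilot approach.  ``V``/``S`` (false/true rejections)
    are present only when the dataset carries truth labels.
    """

    approach: str
    final_p: np.ndarray = field(repr=False)
    p_ids: np.ndarray = field(repr=False)
    rejected: np.ndarray = field(repr=False)
    R: int
    V: int | None
    S: int | None
    stopped: bool
    alpha: float
    selection: InterimSelection | None = None

    @property
    def rejected_ids(self) -> np.ndarray:
        return self.p_ids[self.rejected]


def _counts(rejected_mask: np.ndarray, alt: np.ndarray | None):
    """Rejection counts (R, V, S) from a mask aligned with truth labels."""
    R = int(rejected_mask.sum())
    if alt is None:
        return R, None, None
    S = int(alt[rejected_mask].sum())
    return R, R - S, S


def _check_fdrs_level(rule: SelectionRule, alpha: float) -> None:
    if rule.kind == "fdrs" and rule.alpha1 <= alpha:
        raise DataValidationError(
            f"FDRS interim level alpha1={rule.alpha1} must exceed the overall "
            f"level alpha={alpha}")


def run_integrated(data: TwoStageDataset, rule: SelectionRule, alpha: float,
                   settings: QuadratureSettings = DEFAULT_SETTINGS,
                   method: str = "batch") -> FinalAnalysis:
    """Integrated final test: BH at ``alpha`` on sequential p-values of all m.

    Sequential p-values are computed for every hypothesis -- selected ones
    from the pooled statistic at the rule's effective gamma1, non-selected
    ones as their first-stage p-value -- so a non-selected hypothesis can in
    principle be rejected.  A stopped FDRS trial rejects nothing (BH at
    alpha rejects a subset of BH at alpha1 >= alpha on the same p-values).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    _check_fdrs_level(rule, alpha)
    p1 = two_sided_p_from_z(data.z1)
    sel = select(p1, rule)
    if sel.stopped:
        return FinalAnalysis(approach="integrated", final_p=p1, p_ids=data.ids,
                             rejected=np.zeros(data.m, dtype=bool), R=0,
                             V=0 if data.is_alternative is not None else None,
                             S=0 if data.is_alternative is not None else None,
                             stopped=True, alpha=alpha, selection=sel)
    if data.z2 is None or not np.all(np.isfinite(data.z2[sel.selected])):
        bad = data.ids[sel.selected][~np.isfinite(np.nan_to_num(
            data.z2[sel.selected], nan=np.inf))] if data.z2 is not None else data.ids[sel.selected]
        raise DataValidationError(
            f"missing second-stage statistics for selected hypotheses: {list(bad[:5])}")
    zp = np.where(sel.selected, data.z_pooled(), 0.0) if np.isnan(data.z2).any() \
        else data.z_pooled()
    p_seq = sequential_p_all(data.z1, zp, data.w1, sel.gamma1_effective,
                             sel.selected, settings=settings, method=method)
    bh = bh_stepup(p_seq, alpha, ids=data.ids)
    R, V, S = _counts(bh.rejected, data.is_alternative)
    return FinalAnalysis(approach="integrated", final_p=p_seq, p_ids=data.ids,
                         rejected=bh.rejected, R=R, V=V, S=S, stopped=False,
                         alpha=alpha, selection=sel)


def run_pilot(data: TwoStageDataset, rule: SelectionRule, alpha: float) -> FinalAnalysis:
    """Pilot final test: BH on second-stage p-values of the selected set.

    The first stage is used for selection only.  For the FDRS rule the
    interim BH screen at alpha1 already pays part of the error-rate budget,
    so the second-stage BH may run at the larger level alpha/alpha1 while
    still controlling the overall FDR; the other rules test at alpha.
    Non-selected hypotheses can never be rejected.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    _check_fdrs_level(rule, alpha)
    p1 = two_sided_p_from_z(data.z1)
    sel = select(p1, rule)
    level = alpha if rule.kind != "fdrs" else min(alpha / rule.alpha1, 1.0)
    if sel.stopped or sel.m2 == 0:
        empty = np.empty(0)
        return FinalAnalysis(approach="pilot", final_p=empty, p_ids=np.empty(0, dtype=data.ids.dtype),
                             rejected=np.zeros(0, dtype=bool), R=0,
                             V=0 if data.is_alternative is not None else None,
                             S=0 if data.is_alternative is not None else None,
                             stopped=sel.stopped, alpha=level, selection=sel)
    if data.z2 is None or not np.all(np.isfinite(data.z2[sel.selected])):
        raise DataValidationError("missing second-stage statistics for selected hypotheses")
    p2 = two_sided_p_from_z(data.z2[sel.selected])
    bh = bh_stepup(p2, level, ids=data.ids[sel.selected])
    alt_sel = data.is_alternative[sel.selected] if data.is_alternative is not None else None
    R, V, S = _counts(bh.rejected, alt_sel)
    return FinalAnalysis(approach="pilot", final_p=p2, p_ids=data.ids[sel.selected],
                         rejected=bh.rejected, R=R, V=V, S=S, stopped=False,
                         alpha=level, selection=sel)


def run_single_stage(z, alpha: float, ids=None,
                     is_alternative=None, approach: str = "single_stage") -> FinalAnalysis:
    """Single-stage baseline: BH at ``alpha`` on two-sided z-test p-values."""
    z = np.asarray(z, dtype=float)
    p = two_sided_p_from_z(z)
    ids = np.arange(z.size) if ids is None else np.asarray(ids)
    bh = bh_stepup(p, alpha, ids=ids)
    alt = np.asarray(is_alternative, dtype=bool) if is_alternative is not None else None
    R, V, S = _counts(bh.rejected, alt)
    return FinalAnalysis(approach=approach, final_p=p, p_ids=ids,
                         rejected=bh.rejected, R=R, V=V, S=S, stopped=False,
                         alpha=alpha, selection=None)


def dataset_from_statistics(table: pd.DataFrame) -> TwoStageDataset:
    """Build a dataset from a precomputed-statistics table.

    Expects columns ``id, z1, z2, n1, n2``; ``z2`` may be empty/NaN for
    hypotheses without second-stage data.  Per-hypothesis n1/n2 must be
    constant (the design collects the same number of observations for every
    hypothesis in a stage).
    """
    required = {"id", "z1", "z2", "n1", "n2"}
    missing = required - set(table.columns)
    if missing:
        raise DataValidationError(f"statistics table lacks columns: {sorted(missing)}")
    if table["id"].duplicated().any():
        raise DataValidationError("duplicate hypothesis ids in statistics table")
    for col in ("n1", "n2"):
        if table[col].nunique() != 1:
            raise DataValidationError(f"{col} must be constant across hypotheses")
    return TwoStageDataset(z1=table["z1"].to_numpy(float),
                           z2=table["z2"].to_numpy(float),
                           n1=int(table["n1"].iloc[0]), n2=int(table["n2"].iloc[0]),
                           ids=table["id"].to_numpy())


def dataset_from_observations(stage1: pd.DataFrame, stage2: pd.DataFrame,
                              t_approx: bool = False) -> TwoStageDataset:
    """Build a dataset from raw per-observation tables (rows = hypotheses).

    In the default known-variance mode the standardized stage mean is
    ``mean * sqrt(n)`` (unit-variance observations).  With ``t_approx`` each
    stage is summarized by a one-sample t-test whose p-value is mapped to a
    signed normal quantile, after which the known-variance sequential
    machinery applies.  Stage-2 rows are matched to stage-1 rows by id;
    hypotheses absent from stage 2 get NaN.
    """
    if stage1.index.duplicated().any() or stage2.index.duplicated().any():
        raise DataValidationError("duplicate hypothesis ids")
    unknown = stage2.index.difference(stage1.index)
    if len(unknown):
        raise DataValidationError(f"stage-2 ids not present in stage 1: {list(unknown[:5])}")
    n1 = stage1.shape[1]
    n2 = stage2.shape[1]

    def _stage_z(row):
        x = row.to_numpy(float)
        x = x[np.isfinite(x)]
        if t_approx:
            p = p_from_samples_tapprox(x)
            return z_from_two_sided_p(p, sign=np.sign(x.mean()) or 1.0)
        return x.mean() * np.sqrt(x.size)

    z1 = stage1.apply(_stage_z, axis=1).to_numpy(float)
    z2_series = stage2.apply(_stage_z, axis=1)
    z2 = z2_series.reindex(stage1.index).to_numpy(float)
    return TwoStageDataset(z1=z1, z2=z2, n1=n1, n2=n2, ids=stage1.index.to_numpy())
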