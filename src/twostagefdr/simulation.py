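"""Monte-Carlo simulation engine for two-stage FDR designs.

Datasets are simulated at the level of the sufficient statistics: the
standardized stage means z1 ~ N(mu*sqrt(n1), Sigma), z2 ~ N(mu*sqrt(n2),
Sigma) with unit-diagonal correlation Sigma shared within a stage and
independence across stages.  Four correlation structures are supported --
independent, AR(1) auto-correlation rho^|i-j|, compound-symmetric blocks,
and global equi-correlation -- all generated without forming Sigma (one-
factor constructions for equi/block, the recursive construction for AR(1)).
Alternatives (per-observation mean delta, so E z1 = delta*sqrt(n1)) are
re-randomized across positions every run.

Replicates are driven by counter-based substreams seeded from
(seed, run_index), so runs are order-independent and the integrated and
pilot analyses of one run share the same dataset (common random numbers).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from . import pipeline
from .selection import SelectionRule
from .seqpval import DEFAULT_SETTINGS, QuadratureSettings

__all__ = [
    "ScenarioConfig",
    "SimulationSummary",
    "generate_dataset",
    "run_scenario",
    "run_grid",
]

_STRUCTURES = ("independent", "auto", "block", "equi")
_APPROACHES = ("integrated", "pilot")


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario (design + data-generating parameters).

    delta is the per-observation standardized effect size.  Under the
    ``one_sample`` design n1/n2 are total per-stage observations and the
    expected standardized first-stage mean of an alternative is
    delta*sqrt(n1); under the ``two_group`` design n1/n2 count observations
    per group of a balanced two-group comparison, delta is the standardized
    between-group difference, and the expected standardized mean difference
    is delta*sqrt(n1/2).  The information fraction is n1/(n1+n2) either way.
    """

    m: int
    pi0: float
    delta: float
    rule: SelectionRule
    n1: int = 6
    n2: int = 12
    alpha: float = 0.05
    design: str = "one_sample"
    correlation: str = "independent"
    rho: float = 0.0
    block_size: int = 20
    n_runs: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.m < 1:
            raise ValueError("m must be positive")
        if self.design not in ("one_sample", "two_group"):
            raise ValueError("design must be 'one_sample' or 'two_group'")
        if not (0.0 <= self.pi0 <= 1.0):
            raise ValueError("pi0 must be in [0, 1]")
        if self.correlation not in _STRUCTURES:
            raise ValueError(f"correlation must be one of {_STRUCTURES}")
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")
        if self.block_size < 1:
            raise ValueError("block_size must be positive")
        if self.n_runs < 1:
            raise ValueError("n_runs must be positive")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")

    @property
    def m0(self) -> int:
        return int(round(self.m * self.pi0))

    @property
    def m1(self) -> int:
        return self.m - self.m0


@dataclass(frozen=True)
class SimulationSummary:
    """Monte-Carlo estimates for one (scenario, approach) pair.

    fdr_hat is the mean over runs of V/max(R, 1); mean_rejected_alternatives
    the mean of S.  Standard errors are sample SD / sqrt(n_runs) and are NaN
    for a single run.
    """

    approach: str
    fdr_hat: float
    fdr_se: float
    mean_rejected_alternatives: float
    s_se: float
    mean_rejected: float
    mean_m2: float
    stop_rate: float
    n_runs_effective: int
    per_run: pd.DataFrame | None = field(default=None, repr=False, compare=False)


def _correlated_noise(rng: np.random.Generator, m: int, structure: str,
                      rho: float, block_size: int) -> np.ndarray:
    """Unit-variance noise vector with the requested cross-hypothesis correlation."""
    eps = rng.standard_normal(m)
    if structure == "independent" or rho == 0.0:
        return eps
    if structure == "equi":
        return math.sqrt(rho) * rng.standard_normal() + math.sqrt(1.0 - rho) * eps
    if structure == "block":
        n_blocks = -(-m // block_size)
        w = np.repeat(rng.standard_normal(n_blocks), block_size)[:m]
        return math.sqrt(rho) * w + math.sqrt(1.0 - rho) * eps
    # AR(1): e_0 = eps_0, e_i = rho e_{i-1} + sqrt(1-rho^2) eps_i
    x = eps * math.sqrt(1.0 - rho * rho)
    x[0] = eps[0]
    return lfilter([1.0], [1.0, -rho], x)


def generate_dataset(config: ScenarioConfig, run_index: int) -> pipeline.TwoStageDataset:
    """Simulate the sufficient statistics of one two-stage experiment.

    Alternative positions are drawn uniformly without replacement (fresh
    every run, which matters under correlation); stage noises are
    independent across stages but share the correlation structure.
    """
    rng = np.random.default_rng([config.seed, run_index])
    mu = np.zeros(config.m)
    alt = np.zeros(config.m, dtype=bool)
    if config.m1 > 0:
        pos = rng.choice(config.m, size=config.m1, replace=False)
        mu[pos] = config.delta
        alt[pos] = True
    e1 = _correlated_noise(rng, config.m, config.correlation, config.rho, config.block_size)
    e2 = _correlated_noise(rng, config.m, config.correlation, config.rho, config.block_size)
    # per-stage noncentrality scale: sqrt(n) one-sample, sqrt(n/2) two-group
    g = 1.0 if config.design == "one_sample" else 2.0
    return pipeline.TwoStageDataset(
        z1=mu * math.sqrt(config.n1 / g) + e1,
        z2=mu * math.sqrt(config.n2 / g) + e2,
        n1=config.n1, n2=config.n2,
        is_alternative=alt, mu=mu)


def _summarize(approach: str, rows: pd.DataFrame, keep_runs: bool) -> SimulationSummary:
    n = len(rows)
    fdp = rows["V"] / np.maximum(rows["R"], 1)

    def _se(x):
        return float(x.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")

    return SimulationSummary(
        approach=approach,
        fdr_hat=float(fdp.mean()), fdr_se=_se(fdp),
        mean_rejected_alternatives=float(rows["S"].mean()), s_se=_se(rows["S"]),
        mean_rejected=float(rows["R"].mean()),
        mean_m2=float(rows["m2"].mean()),
        stop_rate=float(rows["stopped"].mean()),
        n_runs_effective=n,
        per_run=rows if keep_runs else None)


def run_scenario(config: ScenarioConfig, approach: str = "both",
                 settings: QuadratureSettings = DEFAULT_SETTINGS,
                 keep_runs: bool = False) -> dict[str, SimulationSummary]:
    """Run all replicates of a scenario and summarize each requested approach.

    With ``approach="both"`` the two analyses run on the same simulated
    datasets (common random numbers), which is what makes paired
    integrated-vs-pilot comparisons efficient.
    """
    if approach == "both":
        approaches = _APPROACHES
    elif approach in _APPROACHES:
        approaches = (approach,)
    else:
        raise ValueError(f"approach must be 'integrated', 'pilot' or 'both', got {approach!r}")
    records: dict[str, list] = {a: [] for a in approaches}
    for run_index in range(config.n_runs):
        try:
            data = generate_dataset(config, run_index)
            for a in approaches:
                if a == "integrated":
                    res = pipeline.run_integrated(data, config.rule, config.alpha,
                                                  settings=settings)
                else:
                    res = pipeline.run_pilot(data, config.rule, config.alpha)
                records[a].append((res.R, res.V, res.S,
                                   res.selection.m2 if res.selection else 0,
                                   res.stopped))
        except Exception as exc:
            raise RuntimeError(f"simulation run {run_index} failed") from exc
    out = {}
    for a in approaches:
        rows = pd.DataFrame(records[a], columns=["R", "V", "S", "m2", "stopped"])
        out[a] = _summarize(a, rows, keep_runs)
    return out


def improvement_pct(summaries: dict[str, SimulationSummary]) -> tuple[float, float]:
    """Paired percent power gain 100*(mean S integrated / mean S pilot - 1).

    Requires per-run records from a common-random-numbers run of both
    approaches; the standard error comes from the delta method for a ratio
    of paired means.
    """
    si = summaries["integrated"].per_run
    sp = summaries["pilot"].per_run
    if si is None or sp is None:
        raise ValueError("improvement_pct needs keep_runs=True summaries of both approaches")
    x = si["S"].to_numpy(float)
    y = sp["S"].to_numpy(float)
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    if ybar == 0:
        return float("nan"), float("nan")
    ratio = xbar / ybar
    cov = np.cov(x, y, ddof=1)
    var_ratio = (ratio ** 2) * (cov[0, 0] / xbar ** 2 + cov[1, 1] / ybar ** 2
                                - 2 * cov[0, 1] / (xbar * ybar)) / n
    return 100.0 * (ratio - 1.0), 100.0 * math.sqrt(max(var_ratio, 0.0))


def run_grid(configs: list[ScenarioConfig], approach: str = "both",
             settings: QuadratureSettings = DEFAULT_SETTINGS) -> pd.DataFrame:
    """One summary row per (scenario, approach); adds the paired improvement
    column when both approaches are run."""
    if not configs:
        raise ValueError("empty scenario list")
    rows = []
    for config in configs:
        summaries = run_scenario(config, approach=approach, settings=settings,
                                 keep_runs=(approach == "both"))
        impr = impr_se = float("nan")
        if approach == "both":
            impr, impr_se = improvement_pct(summaries)
        for a, s in summaries.items():
            rule_desc = config.rule.describe()
            rows.append({
                "m": config.m, "pi0": config.pi0, "delta": config.delta,
                "n1": config.n1, "n2": config.n2, "alpha": config.alpha,
                "design": config.design,
                "rule": rule_desc.pop("kind"),
                "rule_params": ";".join(f"{k}={v}" for k, v in rule_desc.items()),
                "correlation": config.correlation, "rho": config.rho,
                "approach": a, "n_runs": s.n_runs_effective,
                "fdr_hat": s.fdr_hat, "fdr_se": s.fdr_se,
                "mean_S": s.mean_rejected_alternatives, "s_se": s.s_se,
                "mean_m2": s.mean_m2, "stop_rate": s.stop_rate,
                "improvement_pct": impr if a == "integrated" else float("nan"),
                "improvement_se": impr_se if a == "integrated" else float("nan"),
                "seed": config.seed,
            })
    return pd.DataFrame(rows)
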