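"""Delimited-file readers/writers, YAML scenario configs and run manifests.

Per-hypothesis tables are TSV, summary grids CSV; UTF-8, '.' decimal
separator, header row mandatory.  Every command writes a JSON manifest next
to its outputs recording the command, seed and output paths.
"""
from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pipeline import DataValidationError, FinalAnalysis, TwoStageDataset
from .selection import InterimSelection, SelectionRule
from .simulation import ScenarioConfig

__all__ = [
    "RunManifest",
    "read_statistics_table",
    "read_observation_matrix",
    "write_analysis_outputs",
    "load_scenarios",
    "write_manifest",
]


@dataclass(frozen=True)
class RunManifest:
    command: str
    config_path: str | None
    seed: int | None
    output_paths: list
    package_version: str
    timestamp: str


def write_manifest(path, command: str, output_paths, seed=None, config_path=None) -> Path:
    from . import __version__

    manifest = RunManifest(
        command=command,
        config_path=str(config_path) if config_path else None,
        seed=seed,
        output_paths=[str(p) for p in output_paths],
        package_version=__version__,
        timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )
    path = Path(path)
    path.write_text(json.dumps(asdict(manifest), indent=2) + "\n")
    return path


def read_statistics_table(path) -> pd.DataFrame:
    """Read a precomputed-statistics TSV (id, z1, z2, n1, n2)."""
    try:
        table = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise DataValidationError(f"cannot parse statistics table {path}: {exc}") from exc
    return table


def read_observation_matrix(path) -> pd.DataFrame:
    """Read a raw observation TSV (first column = hypothesis id, rest = observations)."""
    try:
        table = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise DataValidationError(f"cannot parse observation matrix {path}: {exc}") from exc
    if table.shape[1] < 2:
        raise DataValidationError(f"{path}: need at least 2 observation columns")
    return table


def write_analysis_outputs(out_prefix, data: TwoStageDataset,
                           selection: InterimSelection,
                           results: dict[str, FinalAnalysis],
                           rule: SelectionRule, alpha: float) -> list[Path]:
    """Write the per-hypothesis TSV and the JSON summary of an analysis.

    The TSV has one row per hypothesis (id, p1, p2, p_sequential, selected,
    rejected_integrated, rejected_pilot); columns for approaches that were
    not run are omitted.
    """
    from .mtp import two_sided_p_from_z

    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    p1 = two_sided_p_from_z(data.z1)
    table = pd.DataFrame({"id": data.ids, "p1": p1, "selected": selection.selected})
    if data.z2 is not None:
        p2 = np.full(data.m, np.nan)
        fin = np.isfinite(data.z2)
        if fin.any():
            p2[fin] = two_sided_p_from_z(data.z2[fin])
        table["p2"] = p2
    if "integrated" in results:
        res = results["integrated"]
        table["p_sequential"] = res.final_p
        table["rejected_integrated"] = res.rejected
    if "pilot" in results:
        res = results["pilot"]
        rej = pd.Series(False, index=pd.Index(data.ids))
        rej.loc[res.rejected_ids] = True
        table["rejected_pilot"] = rej.to_numpy()

    tsv_path = out_prefix.with_suffix(".tsv")
    table.to_csv(tsv_path, sep="\t", index=False)

    summary = {
        "m": data.m,
        "m2": selection.m2,
        "gamma1_effective": None if selection.stopped else selection.gamma1_effective,
        "stopped": bool(selection.stopped),
        "rule": rule.describe(),
        "alpha": alpha,
        "approaches": {},
    }
    for name, res in results.items():
        entry = {"R": res.R, "stopped": bool(res.stopped), "level": res.alpha}
        if res.V is not None:
            entry.update(V=res.V, S=res.S)
        summary["approaches"][name] = entry
    json_path = out_prefix.with_suffix(".json")
    json_path.write_text(json.dumps(summary, indent=2, default=float) + "\n")
    return [tsv_path, json_path]


def _rule_from_mapping(doc: dict) -> SelectionRule:
    kind = doc.get("rule")
    if kind in ("fixed", "fixed_threshold"):
        return SelectionRule.fixed(float(doc["gamma1"]))
    if kind == "fns":
        return SelectionRule.fns(int(doc["m2"]))
    if kind == "fdrs":
        return SelectionRule.fdrs(float(doc["alpha1"]), ms=int(doc.get("ms", 6)))
    raise DataValidationError(f"unknown rule {kind!r} (use fixed_threshold, fns or fdrs)")

_SCALAR_KEYS = {"m", "pi0", "delta", "n1", "n2", "alpha", "design", "correlation",
                "rho", "block_size", "n_runs", "seed"}
_RULE_KEYS = {"rule", "gamma1", "m2", "alpha1", "ms"}


def load_scenarios(path) -> list[ScenarioConfig]:
    """Load scenario configs from a YAML file.

    Each YAML document describes one scenario; any ScenarioConfig field (or
    rule parameter) given as a list is expanded into the cross-product of
    scenarios.
    """
    with open(path) as fh:
        docs = [d for d in yaml.safe_load_all(fh) if d]
    if not docs:
        raise DataValidationError(f"no scenario documents in {path}")
    configs = []
    for doc in docs:
        unknown = set(doc) - _SCALAR_KEYS - _RULE_KEYS
        if unknown:
            raise DataValidationError(f"unknown scenario keys: {sorted(unknown)}")
        list_keys = [k for k, v in doc.items() if isinstance(v, list)]
        for combo in itertools.product(*(doc[k] for k in list_keys)):
            entry = dict(doc)
            entry.update(zip(list_keys, combo))
            rule = _rule_from_mapping(entry)
            kwargs = {k: entry[k] for k in _SCALAR_KEYS if k in entry}
            try:
                configs.append(ScenarioConfig(rule=rule, **kwargs))
            except (TypeError, ValueError) as exc:
                raise DataValidationError(f"invalid scenario {entry}: {exc}") from exc
    return configs
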