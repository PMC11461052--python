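"""Configuration files, tabular output and run provenance.

Parameter files are YAML or JSON mappings whose keys match the
:class:`~proofthermo.networks.DiscriminationParams` fields; optimization
configs likewise mirror :class:`~proofthermo.pareto.OptimizationConfig`.
All numeric outputs are plain CSV with a JSON sidecar recording the
scenario, seeds and a hash of the configuration, so every table can be
regenerated or re-plotted with any tool.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from .networks import DiscriminationParams, RateSet, topology
from .observables import Observables
from .pareto import OptimizationConfig, ParetoFront

__all__ = [
    "load_params",
    "load_optimization_config",
    "rates_frame",
    "distribution_frame",
    "observables_frame",
    "front_frame",
    "write_table",
]


def _load_mapping(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def load_params(path: str | Path) -> DiscriminationParams:
    """Read DiscriminationParams from a YAML/JSON mapping."""
    data = _load_mapping(path)
    fields = {f.name for f in dataclasses.fields(DiscriminationParams)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return DiscriminationParams(**data)


def load_optimization_config(path: str | Path) -> OptimizationConfig:
    """Read an OptimizationConfig from a YAML/JSON mapping."""
    data = _load_mapping(path)
    fields = {f.name for f in dataclasses.fields(OptimizationConfig)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("log10_rate_bounds", "energy_bounds"):
        if key in data:
            data[key] = tuple(data[key])
    return OptimizationConfig(**data)


def rates_frame(rates: RateSet) -> pd.DataFrame:
    """One row per edge rate (plus catalysis), for inspection/export."""
    rows = [{"name": k, "value": v} for k, v in sorted(rates.rates.items())]
    rows.append({"name": "F", "value": rates.F})
    return pd.DataFrame(rows)


def distribution_frame(scheme: str, ss) -> pd.DataFrame:
    states, _, _ = topology(scheme)
    return pd.DataFrame({"state": list(states), "probability": list(ss)})


def observables_frame(obs: Observables | list[Observables]) -> pd.DataFrame:
    if isinstance(obs, Observables):
        obs = [obs]
    return pd.DataFrame([o.as_dict() for o in obs])


def evaluate_table(df: pd.DataFrame, scheme: str = "ERPR") -> pd.DataFrame:
    """Evaluate observables for a parameter table, one network per row.

    Columns matching DiscriminationParams fields override the defaults;
    the returned frame has the observable columns appended.
    """
    from .observables import evaluate

    fields = {f.name for f in dataclasses.fields(DiscriminationParams)}
    out_rows = []
    for _, row in df.iterrows():
        kwargs = {k: row[k] for k in df.columns if k in fields}
        obs = evaluate(DiscriminationParams(**kwargs), scheme)
        out_rows.append(obs.as_dict())
    obs_df = pd.DataFrame(out_rows).drop(columns=["scheme"])
    return pd.concat([df.reset_index(drop=True), obs_df], axis=1)


def front_frame(front: ParetoFront) -> pd.DataFrame:
    """Front points with full parameter provenance, sorted by error."""
    front = front.sorted_by(front.objective_names[0])
    df = pd.DataFrame(front.objectives, columns=list(front.objective_names))
    for k, name in enumerate(front.parameter_names):
        df[name] = front.parameters[:, k]
    return df


def _config_hash(obj) -> str:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    *,
    scenario: str,
    config=None,
    seeds=(),
    extra: dict | None = None,
) -> Path:
    """Write CSV plus a JSON provenance sidecar; returns the CSV path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    sidecar = {
        "scenario": scenario,
        "seeds": [int(s) for s in seeds],
        "config_hash": _config_hash(config) if config is not None else None,
        "config": dataclasses.asdict(config)
        if dataclasses.is_dataclass(config) and not isinstance(config, type)
        else config,
        "n_rows": int(len(df)),
        "columns": list(df.columns),
    }
    if extra:
        sidecar.update(extra)
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=2, default=str))
    return path
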