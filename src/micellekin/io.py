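"""Config files, trace tables, state snapshots and run manifests.

Configuration is YAML with nested sections (``model``, ``baseline``,
``setup``); kinetic traces travel as delimited text with columns
``time, signal, replicate``; state snapshots as ``species, size,
concentration`` tables; run manifests as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .model import StateVector
from .observables import KineticTrace
from .parameters import BaselineParameters, ModelParameters
from .simulate import SimulationSetup, Trajectory

__all__ = [
    "load_config",
    "save_config",
    "read_traces",
    "write_traces",
    "write_trajectory",
    "write_state",
    "read_state",
    "write_manifest",
]

_SECTIONS = {
    "model": ModelParameters,
    "baseline": BaselineParameters,
    "setup": SimulationSetup,
}


def load_config(path: str | Path) -> dict[str, Any]:
    """Read a YAML config into typed objects, one per known section.

    Unknown sections are passed through as plain dictionaries.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out: dict[str, Any] = {}
    for key, value in raw.items():
        cls = _SECTIONS.get(key)
        out[key] = cls(**value) if cls is not None and isinstance(value, dict) else value
    return out


def save_config(path: str | Path, **sections: Any) -> None:
    payload = {
        key: dataclasses.asdict(value) if dataclasses.is_dataclass(value) else value
        for key, value in sections.items()
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def read_traces(path: str | Path, sep: str = "\t") -> list[KineticTrace]:
    """Read replicate kinetic traces from a delimited table."""
    df = pd.read_csv(path, sep=sep)
    if "replicate" not in df.columns:
        df["replicate"] = 0
    traces = []
    for rep, grp in df.groupby("replicate", sort=True):
        traces.append(
            KineticTrace(
                times=grp["time"].to_numpy(),
                signal=grp["signal"].to_numpy(),
                replicate=int(rep),
            )
        )
    return traces


def write_traces(path: str | Path, traces: list[KineticTrace], sep: str = "\t") -> None:
    frames = [
        pd.DataFrame({"time": tr.times, "signal": tr.signal, "replicate": tr.replicate})
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)


def write_trajectory(path: str | Path, traj: Trajectory, sep: str = "\t") -> None:
    traj.to_frame().to_csv(path, sep=sep, index=False)


def write_state(path: str | Path, state: StateVector, sep: str = "\t") -> None:
    """Write a state snapshot as a (species, size, concentration) table."""
    rows = [("c", 1, state.c), ("v", 1, state.v)]
    rows += [("m", int(i), x) for i, x in zip(state.micelle_sizes, state.m)]
    rows += [("u", int(j), x) for j, x in zip(state.polymer_sizes, state.u)]
    pd.DataFrame(rows, columns=["species", "size", "concentration"]).to_csv(
        path, sep=sep, index=False
    )


def read_state(path: str | Path, sep: str = "\t") -> StateVector:
    df = pd.read_csv(path, sep=sep)
    m = df[df.species == "m"].sort_values("size")
    u = df[df.species == "u"].sort_values("size")
    return StateVector(
        c=float(df.loc[df.species == "c", "concentration"].iloc[0]),
        v=float(df.loc[df.species == "v", "concentration"].iloc[0]),
        m=m["concentration"].to_numpy(),
        u=u["concentration"].to_numpy(),
    )


def write_manifest(path: str | Path, **entries: Any) -> None:
    """JSON run manifest (parameters, solver settings, diagnostics)."""

    def default(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        raise TypeError(f"cannot serialize {type(obj)}")

    Path(path).write_text(json.dumps(entries, indent=2, default=default) + "\n")
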