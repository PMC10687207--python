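"""File formats and run manifests.

Sweep sets are stored in an HDF5 container (group per sweep, float64, unit
attributes) so determinism tests can require bit-identical round trips;
small outputs mirror to CSV.  Channel/cell configuration uses YAML built
from the lossless dict round trip in :mod:`stellatesim.channels`.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .cable import Trace
from .vclamp import SweepSet

__all__ = [
    "save_sweepset",
    "load_sweepset",
    "trace_to_csv",
    "trace_from_csv",
    "save_config",
    "load_config",
    "RunManifest",
]

_META_KEY = "stimulus_json"


def _write_trace(grp: h5py.Group, tr: Trace) -> None:
    ds = grp.create_dataset("samples", data=tr.samples, dtype="f8")
    ds.attrs["units"] = "pA" if tr.kind == "current" else "mV"
    grp.attrs["dt_ms"] = tr.dt
    grp.attrs["kind"] = tr.kind
    grp.attrs[_META_KEY] = json.dumps(tr.stimulus, sort_keys=True)
    grp.attrs["annotations_json"] = json.dumps(
        {k: v for k, v in tr.annotations.items()
         if isinstance(v, (int, float, str, bool, type(None)))},
        sort_keys=True)


def _read_trace(grp: h5py.Group) -> Trace:
    return Trace(float(grp.attrs["dt_ms"]), grp["samples"][...],
                 str(grp.attrs["kind"]),
                 stimulus=json.loads(grp.attrs[_META_KEY]),
                 annotations=json.loads(grp.attrs.get("annotations_json", "{}")))


def save_sweepset(sset: SweepSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["condition"] = sset.condition
        f.attrs["mode"] = sset.mode
        sw = f.create_group("sweeps")
        for lvl, tr in sset.sweeps.items():
            _write_trace(sw.create_group(f"{lvl:+.3f}"), tr)
        if sset.leak is not None:
            _write_trace(f.create_group("leak"), sset.leak)


def load_sweepset(path) -> SweepSet:
    with h5py.File(path, "r") as f:
        sweeps = {float(name): _read_trace(grp)
                  for name, grp in f["sweeps"].items()}
        leak = _read_trace(f["leak"]) if "leak" in f else None
        return SweepSet(sweeps, leak=leak,
                        condition=str(f.attrs["condition"]),
                        mode=str(f.attrs["mode"]))


def trace_to_csv(tr: Trace, path) -> None:
    col = "current_pA" if tr.kind == "current" else "voltage_mV"
    pd.DataFrame({"time_ms": tr.time, col: tr.samples}).to_csv(path, index=False)


def trace_from_csv(path, kind: str, dt: float | None = None,
                   stimulus: dict | None = None) -> Trace:
    df = pd.read_csv(path)
    col = "current_pA" if kind == "current" else "voltage_mV"
    step = dt if dt is not None else float(df["time_ms"].iloc[1]
                                           - df["time_ms"].iloc[0])
    return Trace(step, df[col].to_numpy(), kind, stimulus=dict(stimulus or {}))


# ---------------------------------------------------------------------------
# Configuration


def save_config(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# Manifest


@dataclass
class RunManifest:
    """Provenance record for a CLI run: command, config hash, seed, outputs."""

    command: str
    seed: int
    config_hash: str = ""
    outputs: list[str] = field(default_factory=list)
    package_version: str = ""
    started: str = ""
    finished: str = ""
    notes: dict = field(default_factory=dict)

    @classmethod
    def start(cls, command: str, seed: int, config_path=None) -> "RunManifest":
        from . import __version__

        h = ""
        if config_path is not None:
            h = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
        return cls(command=command, seed=seed, config_hash=h,
                   package_version=__version__,
                   started=time.strftime("%Y-%m-%dT%H:%M:%S"))

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def finish(self, path) -> None:
        self.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
        self.outputs.append(str(path))
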