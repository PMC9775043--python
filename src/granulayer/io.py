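"""Configuration, trace file formats and run provenance.

Traces travel as tidy CSV (columns trial, time_ms, value) with a mandatory
JSON sidecar (same path, .json suffix) carrying modality, stimulus times,
seed and protocol metadata; write-then-read is lossless to float64.
Configs are YAML/JSON documents validated against a pydantic schema with
unknown keys rejected and the circuit parameter defaults filled in.  Every
CLI run writes a RunManifest sufficient to re-run bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .microcircuit import CircuitConfig, TraceSet

__all__ = [
    "SynapseClassSchema",
    "CircuitSchema",
    "load_config",
    "save_config",
    "read_traces",
    "write_traces",
    "RunManifest",
]


class SynapseClassSchema(BaseModel):
    """Release parameters of one synapse class (overrides)."""

    model_config = ConfigDict(extra="forbid")

    p_init: float = Field(gt=0, le=1)
    tau_rec: float = Field(gt=0)
    tau_facil: float = Field(gt=0)
    tau_inact: float = Field(gt=0)
    n_sites: int = Field(default=1, ge=1)


class CircuitSchema(BaseModel):
    """Validated circuit configuration with the study-condition defaults."""

    model_config = ConfigDict(extra="forbid")

    n_mf: int = Field(default=2, ge=1, le=4)
    n_goc: int = Field(default=2, ge=0, le=4)
    n_release_sites: int = Field(default=6, ge=1)
    stochastic: bool = True
    seed: int = 0
    dt: float = Field(default=0.025, gt=0)
    plasticity: dict[str, str] = Field(default_factory=dict)
    synapses: dict[str, SynapseClassSchema] = Field(default_factory=dict)

    def to_circuit_config(self) -> CircuitConfig:
        from dataclasses import replace as dreplace

        from .microcircuit import default_synapse_specs
        from .presyn import ReleaseParams

        overrides = {}
        if self.synapses:
            base = default_synapse_specs(self.n_release_sites)
            for name, s in self.synapses.items():
                if name not in base:
                    raise ValueError(f"unknown synapse class {name!r}")
                overrides[name] = dreplace(
                    base[name],
                    release=ReleaseParams(
                        p_init=s.p_init, tau_rec=s.tau_rec,
                        tau_facil=s.tau_facil, tau_inact=s.tau_inact,
                        n_sites=s.n_sites),
                )
        return CircuitConfig(
            n_mf=self.n_mf, n_goc=self.n_goc,
            n_release_sites=self.n_release_sites,
            stochastic=self.stochastic, plasticity=dict(self.plasticity),
            seed=self.seed, dt=self.dt, synapse_overrides=overrides,
        )


def load_config(path: str | Path) -> CircuitSchema:
    """Load and validate a circuit config (YAML or JSON)."""
    p = Path(path)
    with open(p) as fh:
        raw = json.load(fh) if p.suffix == ".json" else yaml.safe_load(fh)
    return CircuitSchema.model_validate(raw or {})


def save_config(config: CircuitSchema, path: str | Path) -> None:
    p = Path(path)
    data = config.model_dump()
    with open(p, "w") as fh:
        if p.suffix == ".json":
            json.dump(data, fh, indent=2)
        else:
            yaml.safe_dump(data, fh, sort_keys=False)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_traces(traces: TraceSet, path: str | Path) -> None:
    """Tidy CSV (trial, time_ms, value) plus mandatory JSON sidecar."""
    p = Path(path)
    traces.to_frame().to_csv(p, index=False, float_format="%.17g")
    meta = {
        "modality": traces.modality,
        "stim_times_ms": list(map(float, traces.stim_times)),
        "seed": traces.seed,
        "n_trials": int(traces.n_trials),
        "dt_ms": traces.dt,
        "meta": _jsonable(traces.meta),
    }
    with open(_sidecar(p), "w") as fh:
        json.dump(meta, fh, indent=2)


def read_traces(path: str | Path) -> TraceSet:
    p = Path(path)
    sc = _sidecar(p)
    if not sc.exists():
        raise FileNotFoundError(f"missing metadata sidecar {sc}")
    with open(sc) as fh:
        meta = json.load(fh)
    df = pd.read_csv(p, float_precision="round_trip")
    if df.empty:
        return TraceSet(time_ms=np.zeros(0), data=np.zeros((0, 0)),
                        modality=meta["modality"],
                        stim_times=np.asarray(meta["stim_times_ms"]),
                        seed=meta.get("seed"), meta=meta.get("meta", {}))
    trials = sorted(df["trial"].unique())
    time_ms = df.loc[df["trial"] == trials[0], "time_ms"].to_numpy()
    data = np.stack([df.loc[df["trial"] == k, "value"].to_numpy() for k in trials])
    return TraceSet(time_ms=time_ms, data=data, modality=meta["modality"],
                    stim_times=np.asarray(meta["stim_times_ms"], dtype=float),
                    seed=meta.get("seed"), meta=meta.get("meta", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


class RunManifest:
    """Provenance record written next to every CLI output."""

    def __init__(self, command: str, params: dict, seed: int | None,
                 outputs: list[str]):
        from . import __version__

        self.record = {
            "command": command,
            "params": _jsonable(params),
            "seed": seed,
            "version": __version__,
            "timestamp": datetime.now(timezone.utc).isoformat(),
            "outputs": list(map(str, outputs)),
        }

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.record, fh, indent=2)
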