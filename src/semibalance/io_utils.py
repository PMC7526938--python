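"""Configuration files, tabular exports and run manifests."""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .meanfield import PopulationSpec, SemiBalancedSolution
from .synthetic import FixtureConfig

__all__ = [
    "RunManifest",
    "spec_to_yaml",
    "spec_from_yaml",
    "fixture_to_yaml",
    "fixture_from_yaml",
    "solution_table",
    "write_table",
    "export_spikes",
]

_SPEC_KEYS = {"names", "sizes", "signs", "j", "p"}


def spec_to_yaml(spec: PopulationSpec, path) -> None:
    d = {"names": list(spec.names), "sizes": spec.sizes.tolist(),
         "signs": list(spec.signs), "j": spec.j.tolist(), "p": spec.p.tolist()}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def spec_from_yaml(path) -> PopulationSpec:
    d = yaml.safe_load(Path(path).read_text())
    unknown = set(d) - _SPEC_KEYS
    if unknown:
        raise ValueError(f"unknown keys in population spec: {sorted(unknown)}")
    missing = _SPEC_KEYS - set(d)
    if missing:
        raise ValueError(f"population spec missing keys: {sorted(missing)}")
    return PopulationSpec(**d)


def fixture_to_yaml(fx: FixtureConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(fx.to_dict(), sort_keys=False))


def fixture_from_yaml(path) -> FixtureConfig:
    return FixtureConfig.from_dict(yaml.safe_load(Path(path).read_text()))


def solution_table(names, sol: SemiBalancedSolution) -> str:
    """Delimited text: population, rate_Hz, residual_mV, in_support."""
    lines = ["population\trate_Hz\tresidual_mV\tin_support"]
    for k, name in enumerate(names):
        lines.append(f"{name}\t{sol.r[k]:.6g}\t{sol.residual[k]:.6g}"
                     f"\t{int(k in sol.support)}")
    return "\n".join(lines) + "\n"


def write_table(path, header: list[str], columns: list[np.ndarray]) -> None:
    arr = np.column_stack([np.asarray(c) for c in columns])
    np.savetxt(path, arr, delimiter="\t", header="\t".join(header), comments="")


def export_spikes(path, record) -> None:
    """Two-column text: neuron_id, time_ms."""
    write_table(path, ["neuron_id", "time_ms"],
                [record.spike_ids, record.spike_times])


@dataclass
class RunManifest:
    """Provenance record for a scenario run."""

    scenario: str
    seed: int
    config: dict
    outputs: list[str] = field(default_factory=list)
    started: str = ""
    finished: str = ""
    version: str = __version__

    def start(self) -> "RunManifest":
        self.started = datetime.datetime.now().isoformat(timespec="seconds")
        return self

    def finish(self, outdir) -> Path:
        self.finished = datetime.datetime.now().isoformat(timespec="seconds")
        path = Path(outdir) / "manifest.json"
        path.write_text(json.dumps(self.__dict__, indent=2, default=str))
        return path

    def add(self, path) -> None:
        self.outputs.append(str(path))
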