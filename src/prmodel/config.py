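"""Flat key-value run configuration and run manifests.

The configuration file is flat YAML (``key: value`` per line).  Model
parameters use the field names of the parameter types (``g_na`` ... ``e_k``)
in the package's unit convention; numerical and protocol settings use
prefixed keys (``cable_dx``, ``tissue_dt``, ...).  Every default equals the
nominal model values and reference numerical settings, so an empty config
reproduces the standard runs.  Unknown keys are a hard error.
"""

from __future__ import annotations

import datetime
import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import yaml

from .engine import SimulationConfig
from .model_core import (
    InvalidParameterError,
    PotassiumParams,
    SodiumParams,
    params_from_config,
    params_to_config,
)
from .spatial import CableConfig, TissueConfig

__all__ = ["RunConfig", "RunManifest", "load_config", "save_config"]

_MODEL_KEYS = set(SodiumParams.__dataclass_fields__) | set(
    PotassiumParams.__dataclass_fields__
)

_DEFAULTS: dict[str, float | int | str] = {
    # 0D numerics
    "dt": 0.001,
    "record_stride": 10,
    "cm": 1.0,
    # pacing stimulus
    "stim_amplitude": -20.0,
    "stim_duration": 2.0,
    # cable
    "cable_length": 4.0,
    "cable_dx": 0.01,
    "cable_diffusion": 0.001,
    "cable_dt": 0.001,
    # tissue
    "tissue_width": 5.0,
    "tissue_height": 5.0,
    "tissue_dx": 0.02,
    "tissue_dt": 0.02,
    "tissue_diffusion": 0.001,
    "tissue_snapshot_interval": 2.0,
    "tissue_t_end": 1645.0,
    "s2_time": 145.0,
    "s2_quadrant": "lower_left",
    # protocol settings
    "bcl_min": 195.0,
    "bcl_max": 215.0,
    "bcl_step": 1.0,
    "beats": 60,
    "n_cells": 6,
    "sweep_mode": "cell",
    "g_k_values": "0.1,0.3,0.5",
    "b_values": "0.035,0.0425,0.05",
}


@dataclass
class RunConfig:
    """Resolved configuration: model parameters plus run settings."""

    na: SodiumParams
    k: PotassiumParams
    settings: dict = field(default_factory=dict)

    def sim(self) -> SimulationConfig:
        s = self.settings
        return SimulationConfig(
            dt=float(s["dt"]), record_stride=int(s["record_stride"]),
            cm=float(s["cm"]),
        )

    def cable(self) -> CableConfig:
        s = self.settings
        return CableConfig(
            length=float(s["cable_length"]), dx=float(s["cable_dx"]),
            diffusion=float(s["cable_diffusion"]), dt=float(s["cable_dt"]),
        )

    def tissue(self) -> TissueConfig:
        s = self.settings
        return TissueConfig(
            width=float(s["tissue_width"]), height=float(s["tissue_height"]),
            dx=float(s["tissue_dx"]), dt=float(s["tissue_dt"]),
            diffusion=float(s["tissue_diffusion"]),
            snapshot_interval=float(s["tissue_snapshot_interval"]),
        )

    def as_flat_dict(self) -> dict:
        out = params_to_config(self.na, self.k)
        out.update(self.settings)
        return out


def load_config(path=None) -> RunConfig:
    """Load a flat YAML config; missing keys fall back to the defaults."""
    raw: dict = {}
    if path is not None:
        text = pathlib.Path(path).read_text()
        try:
            loaded = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            mark = getattr(exc, "problem_mark", None)
            line = f" (line {mark.line + 1})" if mark is not None else ""
            raise ValueError(f"config parse error{line}: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError("config must be a flat key-value mapping")
        raw = loaded
    unknown = set(raw) - _MODEL_KEYS - set(_DEFAULTS)
    if unknown:
        raise InvalidParameterError(
            f"unknown config keys: {sorted(unknown)}"
        )
    model = {k: v for k, v in raw.items() if k in _MODEL_KEYS}
    na, k = params_from_config(model)
    settings = dict(_DEFAULTS)
    settings.update({k_: v for k_, v in raw.items() if k_ in _DEFAULTS})
    return RunConfig(na=na, k=k, settings=settings)


def save_config(cfg: RunConfig, path) -> None:
    pathlib.Path(path).write_text(
        yaml.safe_dump(cfg.as_flat_dict(), sort_keys=True)
    )


def _sha256(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one run: config, seed, version, timing, output checksums."""

    config: dict
    seed: int
    version: str
    started: str
    finished: str = ""
    outputs: dict = field(default_factory=dict)

    @classmethod
    def start(cls, config: RunConfig, seed: int) -> "RunManifest":
        from . import __version__

        return cls(
            config=config.as_flat_dict(),
            seed=seed,
            version=__version__,
            started=datetime.datetime.now().isoformat(timespec="seconds"),
        )

    def add_output(self, path) -> None:
        p = pathlib.Path(path)
        self.outputs[p.name] = _sha256(p)

    def finish(self, out_dir) -> pathlib.Path:
        self.finished = datetime.datetime.now().isoformat(timespec="seconds")
        target = pathlib.Path(out_dir) / "manifest.json"
        target.write_text(json.dumps(self.__dict__, indent=1))
        return target

    def verify(self, out_dir) -> None:
        """Check all listed outputs exist and match their checksums."""
        base = pathlib.Path(out_dir)
        for name, digest in self.outputs.items():
            p = base / name
            if not p.exists():
                raise FileNotFoundError(f"manifest output missing: {name}")
            if _sha256(p) != digest:
                raise ValueError(f"checksum mismatch for {name}")
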