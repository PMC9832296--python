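"""Flat key-value configuration: loading, validation, serialization.

A configuration is a flat mapping (YAML or JSON) naming the model and
its parameters, the forcing, and the integration settings, e.g.::

    model: kim_forger
    sigma: 0.005
    n: 1000
    T: 1.0
    Imax: 0.05
    events:
      - {type: phase_shift, time: 15.0, shift: 0.5}

Unknown keys and cross-field inconsistencies (such as a sigma that
contradicts omega_size) are rejected with errors naming the field.
Anything not supplied falls back to the model defaults (A = 0.1,
dt = 0.001, ...).  Experiment-specific options live under the
``experiment`` sub-mapping and are validated by the CLI subcommands.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Union

import yaml

from .models import (
    AmplitudePhaseParams,
    ForcingProgram,
    KimForgerParams,
    ParameterError,
    PhaseShift,
    Pulse,
    VanDerPolParams,
    vdp_preset,
)
from .simulate import SimConfig

__all__ = ["ConfigError", "FullConfig", "load_config", "parse_config",
           "serialize_config"]


class ConfigError(ValueError):
    """Malformed or inconsistent configuration."""


_MODEL_KEYS = {
    "kim_forger": {"A", "sigma", "omega_size"},
    "van_der_pol": {"d", "B", "sigma", "preset"},
    "amplitude_phase": {"lam", "amp", "omega", "sigma"},
}
_FORCING_KEYS = {"T", "Imax", "events"}
_SIM_KEYS = {"dt", "t_end", "transient", "seed", "method", "n",
             "record_members", "state_floor"}


@dataclass(frozen=True)
class FullConfig:
    """A validated configuration: model + forcing + integration settings."""

    model: str
    params: Union[KimForgerParams, VanDerPolParams, AmplitudePhaseParams]
    forcing: ForcingProgram
    sim: SimConfig
    experiment: Dict = field(default_factory=dict)


def _parse_events(raw) -> tuple:
    events = []
    for i, ev in enumerate(raw or []):
        if not isinstance(ev, dict) or "type" not in ev:
            raise ConfigError(f"events[{i}] must be a mapping with a 'type'")
        kind = ev["type"]
        try:
            if kind == "pulse":
                events.append(Pulse(start=float(ev["time"]),
                                    duration=float(ev["duration"]),
                                    amplitude=float(ev["amplitude"])))
            elif kind == "phase_shift":
                events.append(PhaseShift(time=float(ev["time"]),
                                         shift=float(ev["shift"])))
            else:
                raise ConfigError(
                    f"events[{i}].type must be 'pulse' or 'phase_shift', "
                    f"got {kind!r}")
        except KeyError as exc:
            raise ConfigError(f"events[{i}] missing field {exc.args[0]!r}") from None
    return tuple(events)


def parse_config(data: Dict) -> FullConfig:
    """Validate a flat mapping and build the typed configuration."""
    if not isinstance(data, dict) or not data:
        raise ConfigError("empty configuration; required field: model "
                          "(one of kim_forger, van_der_pol, amplitude_phase)")
    data = dict(data)
    experiment = data.pop("experiment", {}) or {}
    model = data.pop("model", None)
    if model not in _MODEL_KEYS:
        raise ConfigError(
            f"field 'model' must be one of {sorted(_MODEL_KEYS)}, got {model!r}")

    known = _MODEL_KEYS[model] | _FORCING_KEYS | _SIM_KEYS
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")

    mkw = {k: data[k] for k in _MODEL_KEYS[model] if k in data}
    try:
        if model == "kim_forger":
            params = KimForgerParams(**mkw)
        elif model == "van_der_pol":
            preset = mkw.pop("preset", None)
            if preset is not None:
                if "d" in mkw or "B" in mkw:
                    raise ConfigError("give either 'preset' or explicit d/B, not both")
                params = vdp_preset(preset, sigma=mkw.get("sigma", 0.0))
            else:
                params = VanDerPolParams(**mkw)
        else:
            params = AmplitudePhaseParams(**mkw)
        forcing = ForcingProgram(
            T=float(data.get("T", 1.0)),
            Imax=float(data.get("Imax", 0.0)),
            events=_parse_events(data.get("events")),
        )
        sim = SimConfig(**{k: data[k] for k in _SIM_KEYS if k in data})
    except ParameterError as exc:
        raise ConfigError(str(exc)) from exc
    return FullConfig(model=model, params=params, forcing=forcing, sim=sim,
                      experiment=dict(experiment))


def load_config(path) -> FullConfig:
    """Load and validate a YAML/JSON configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix not in (".json",) else json.loads(text)
    return parse_config(data)


def serialize_config(cfg: FullConfig) -> Dict:
    """Flatten a configuration back to the key-value form (round-trips)."""
    out: Dict = {"model": cfg.model}
    pd_ = asdict(cfg.params)
    out.update({k: v for k, v in pd_.items() if v is not None})
    out["T"] = cfg.forcing.T
    out["Imax"] = cfg.forcing.Imax
    events = []
    for ev in cfg.forcing.events:
        if isinstance(ev, Pulse):
            events.append({"type": "pulse", "time": ev.start,
                           "duration": ev.duration, "amplitude": ev.amplitude})
        else:
            events.append({"type": "phase_shift", "time": ev.time,
                           "shift": ev.shift})
    if events:
        out["events"] = events
    sim = asdict(cfg.sim)
    out.update({k: v for k, v in sim.items() if v is not None})
    if cfg.experiment:
        out["experiment"] = dict(cfg.experiment)
    return out
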