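"""Run configuration: a flat, serialisable record of everything a run needs.

A run is reproducible from its manifest alone: the model is deterministic
(no random number generator anywhere), so identical configurations produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field

import yaml

from .parameters import DimensionlessParameters

__all__ = ["RunConfig"]

_PARAM_KEYS = ("rho", "gamma", "nu", "eta", "theta", "lam", "kappa", "a_sigma")

_DEFAULT_PARAMS = {
    "rho": 0.8, "gamma": 0.25, "nu": 0.8, "eta": 1.5,
    "theta": 0.4, "lam": 0.1, "kappa": 5.0, "a_sigma": 2.0,
}


@dataclass
class RunConfig:
    """Parameters, grid, solver settings and output schedule for one run."""

    params: dict = field(default_factory=lambda: dict(_DEFAULT_PARAMS))
    q: int = 20
    a_max: int = 100
    t_end: float = 200.0
    rtol: float = 1e-6
    atol: float = 1e-9
    ode_rtol: float = 1e-8
    ode_atol: float = 1e-10
    p0_ratio: float = 0.5
    mass_relaxation: float = 5.0
    n_snapshots: int = 81
    experiment: str = "run"

    def nd(self) -> DimensionlessParameters:
        return DimensionlessParameters(**{k: float(self.params[k]) for k in _PARAM_KEYS})

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown config keys: {sorted(extra)}")
        return cls(**data)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def digest(self) -> str:
        """Stable content hash for the run manifest."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def override(self, **kwargs) -> "RunConfig":
        data = self.to_dict()
        for key, value in kwargs.items():
            if value is None:
                continue
            if key in _PARAM_KEYS:
                data["params"][key] = value
            else:
                data[key] = value
        return RunConfig.from_dict(data)
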