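"""Run configuration: one serializable object covering every analysis knob."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .exceptions import ConfigurationError
from .hemodynamics import DEFAULT_VARIABLES


@dataclass
class RunConfig:
    """All tunables of a complexity-analysis run.

    Serializes losslessly to/from YAML (load -> save -> load identity);
    ``config_hash`` stamps outputs for provenance.
    """

    window: int = 100                # beats per sliding window
    step: int = 1                    # beats between window starts
    alpha: float = 0.05              # pair-test significance level
    n_surrogates: int = 200          # permutation surrogates per pair
    min_valid_fraction: float = 0.5  # gap policy: min pairwise-complete share
    variables: tuple[str, ...] = DEFAULT_VARIABLES
    seed: int = 0
    cvp_assumed: float = 6.0         # mmHg, constant CVP for SVR
    vept_correction: float = 1.0
    heather_index_form: str = "product"   # product | quotient
    profile_method: str = "leave_one_out"  # leave_one_out | eigenvector
    surge_k: float = 6.0             # MAD multiplier for the surge detector
    surge_sustain: int = 5           # consecutive points above threshold
    baseline_span: float = 300.0     # s of trend used as baseline
    d_mbp: float = 20.0              # mmHg drop defining the MBP event
    d_hr: float = 15.0               # bpm drop defining the HR event

    def __post_init__(self) -> None:
        self.variables = tuple(self.variables)
        if self.window < 4:
            raise ConfigurationError("window must be >= 4 beats")
        if self.step < 1:
            raise ConfigurationError("step must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.n_surrogates < 1 / self.alpha - 1:
            raise ConfigurationError("n_surrogates too small for alpha")
        if not 0.0 <= self.min_valid_fraction <= 1.0:
            raise ConfigurationError("min_valid_fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["variables"] = list(self.variables)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
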