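"""YAML configuration for CLI runs.

A config file can set the nodata sentinel, class count, the MCA weights
and the Jenks/quantile choice; every CLI option falls back to these
defaults. Weights are an ordered mapping (variable name -> weight) for
the eight vulnerability layers and a two-element mapping for risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .mca import WeightScheme
from .vulnerability import VULNERABILITY_VARIABLES

__all__ = ["RunConfig", "load_config"]

_DEFAULTS = {
    "nodata": -9999.0,
    "k": 9,
    "method": "jenks",
    "breaks_domain": "zones",
    "vulnerability_weights": {v: 1.0 / 8 for v in VULNERABILITY_VARIABLES},
    "risk_weights": {"vulnerability": 0.5, "exposure": 0.5},
}


@dataclass
class RunConfig:
    nodata: float = -9999.0
    k: int = 9
    method: str = "jenks"
    breaks_domain: str = "zones"
    vulnerability_weights: dict = field(
        default_factory=lambda: dict(_DEFAULTS["vulnerability_weights"])
    )
    risk_weights: dict = field(
        default_factory=lambda: dict(_DEFAULTS["risk_weights"])
    )

    def weight_scheme(self) -> WeightScheme:
        vw = tuple(self.vulnerability_weights[v] for v in VULNERABILITY_VARIABLES)
        rw = (self.risk_weights["vulnerability"], self.risk_weights["exposure"])
        return WeightScheme(vulnerability_weights=vw, risk_weights=rw, k=self.k)


def load_config(path=None) -> RunConfig:
    """RunConfig from a YAML file; missing keys take the defaults."""
    cfg = dict(_DEFAULTS)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for key, val in user.items():
            if key not in cfg:
                raise KeyError(f"unknown config key {key!r}")
            if isinstance(cfg[key], dict):
                merged = dict(cfg[key])
                merged.update(val)
                val = merged
            cfg[key] = val
    return RunConfig(**cfg)
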