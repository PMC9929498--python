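"""Run configuration shared by the CLI and batch pipelines.

A single validated record of every knob that affects measurement, so each
output can carry a provenance sidecar from which the run is reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All measurement and analysis parameters for one run.

    sigma: Gaussian smoothing scale in pixels applied before the sweep.
    invert: whether input photographs need inversion into the
        marking-intensity convention (dark markings on a light shell do).
    n_levels: number of thresholds in the sweep.
    perimeter: ``crofton4`` or ``boundary_edges``.
    connectivity: foreground connectivity for the Euler characteristic.
    seed: master RNG seed for anything stochastic.
    fda_basis / fda_scheme: classifier basis and assignment-rate scheme.
    """

    sigma: float = 2.0
    invert: bool = True
    n_levels: int = 80
    perimeter: str = "crofton4"
    connectivity: int = 8
    seed: int = 0
    fda_basis: str = "linear"
    fda_scheme: str = "resubstitution"
    n_bands: int = 8
    axis: str | None = None

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.perimeter not in ("crofton4", "boundary_edges"):
            raise ValueError(f"unknown perimeter method {self.perimeter!r}")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.fda_basis not in ("linear", "polynomial2"):
            raise ValueError(f"unknown FDA basis {self.fda_basis!r}")
        if self.fda_scheme not in ("resubstitution", "leave_one_out"):
            raise ValueError(f"unknown assignment scheme {self.fda_scheme!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def write_sidecar(self, out_path: str | Path, extra: dict | None = None) -> Path:
        """Write a JSON provenance sidecar next to an output file."""
        out_path = Path(out_path)
        sidecar = out_path.with_suffix(out_path.suffix + ".prov.json")
        payload = {"config": self.to_dict(), **(extra or {})}
        sidecar.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return sidecar
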