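"""Run configuration: every tunable threshold of the pipeline in one place,
serialized into outputs for provenance."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    # calibration (explicit; no literature constants assumed)
    tau0_us: float | None = None
    kq_per_us_mmhg: float | None = None
    # lifetime
    discard_head_us: float = 5.0
    min_photons: float = 500.0
    decay_bin_width_us: float = 0.5
    # flux / QC
    min_dip_cycles: int = 3
    smooth_window: int = 5
    rbc_path_length_um: float = 6.0
    frac_of_baseline: float = 0.5
    min_separation: float = 0.2
    min_contrast_snr: float = 3.0
    # stalls
    hypoxic_below_mmhg: float = 10.0
    severe_below_mmhg: float = 5.0
    # EAT
    eat_bin_width_um: float = 1.0
    plateau_min_um: float = 10.0
    # geometry
    half_extent_vox: int = 75
    density_bin_um: float = 1.0
    median_filter_size: int = 3
    # seeds
    seed: int = 0

    def __post_init__(self) -> None:
        if self.discard_head_us < 0 or self.min_photons < 0:
            raise ValueError("thresholds must be nonnegative")
        if self.hypoxic_below_mmhg <= self.severe_below_mmhg:
            raise ValueError("hypoxic threshold must exceed the severe threshold")
        if self.half_extent_vox < 1 or self.density_bin_um <= 0:
            raise ValueError("geometry parameters out of range")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown RunConfig keys: {sorted(unknown)}")
        return cls(**data)
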