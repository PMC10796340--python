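"""Run configuration and provenance hashing.

A single dataclass gathers every tunable the generator exposes; it can be
loaded from a YAML file (nested keys flattened by section) and is hashed
canonically so any change to configuration or seed changes the provenance
hash recorded in manifests and results.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["SimConfig", "provenance_hash"]


@dataclass
class SimConfig:
    """All generator tunables with their defaults.

    rate_hz : sampling rate of trajectories and simulations (100 Hz, a
        typical optical motion-capture rate; 6 s -> 601 frames).
    duration_s / peak_time_s : round-trip movement timing (6 s total,
        full range of motion at 3 s).
    kernel : interpolation kernel between keyframes (min_jerk | cosine |
        linear).
    rom_overrides : per-movement range-of-motion override in degrees; must
        stay within each movement's tolerance band.
    noise_sigma_mm : isotropic Gaussian marker noise added to exported TRC
        files (0 disables; simulations always use the noise-free motion).
    baseline_excitation : voluntary drive added to every muscle; 0 models
        a fully relaxed patient under passive mobilisation.
    scale_force_by_tone : optional hook scaling max isometric force by
        tone_pct / 50 (off by default; tone is bookkeeping otherwise).
    """

    rate_hz: float = 100.0
    duration_s: float = 6.0
    peak_time_s: float = 3.0
    kernel: str = "min_jerk"
    rom_overrides: dict = field(default_factory=dict)
    noise_sigma_mm: float = 0.0
    baseline_excitation: float = 0.0
    scale_force_by_tone: bool = False
    trc_units: str = "mm"
    rotate_y_deg: float = -90.0
    align_pelvis: bool = True

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls().to_dict())
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def provenance_hash(config: SimConfig, seed: int | None = None) -> str:
    """Short hex digest over the canonical config dict plus the seed."""
    payload = {"config": config.to_dict(), "seed": seed}
    blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
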