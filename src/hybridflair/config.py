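"""Run configuration and the reference acquisition protocol.

The default configuration mirrors the reference 3 T protocol: FLAIR
timing TR 10 s / TI 2.8 s / TE 120 ms / 90 degrees, keyhole acceleration
R = 8 with Tukey ratio r = 0.25, brain-extraction fractional threshold
0.5, and a 30-slice 224 x 224 grid (1 x 1 x 3 mm plus gap).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .exceptions import InputError
from .physics_synth import SequenceParams

__all__ = ["RunConfig", "SCAN_SECONDS", "added_scan_time_fraction"]

#: scan durations (seconds) of the reference protocol: the quantitative
#: acquisition, the fully sampled conventional FLAIR, and the 12.5%-sampled
#: keyhole FLAIR (20 s preparation/calibration + 20 s k-space data)
SCAN_SECONDS = {
    "quantitative": 300.0,
    "flair_full": 200.0,
    "flair_keyhole": 40.0,
}


def added_scan_time_fraction(
    keyhole_s: float = SCAN_SECONDS["flair_keyhole"],
    quantitative_s: float = SCAN_SECONDS["quantitative"],
) -> float:
    """Relative scan-time cost of adding the keyhole FLAIR to the
    quantitative protocol (0.133 for the reference timings)."""
    if quantitative_s <= 0 or keyhole_s < 0:
        raise InputError("scan times must be positive")
    return keyhole_s / quantitative_s


_SEQUENCE_KEYS = {"tr", "ti", "te", "flip_deg"}
_FUSION_KEYS = {"accel", "taper_ratio", "per_slice_norm", "final_magnitude"}
_PREPROCESS_KEYS = {"frac_threshold"}
_PHANTOM_KEYS = {"shape", "lesion_mismatch", "mt_wm", "mt_gm", "noise_sigma",
                 "texture_sigma", "rigid_offset"}
_TOP_KEYS = {"sequence", "fusion", "preprocess", "phantom", "seed",
             "magnitude_synthesis"}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of the end-to-end pipeline."""

    sequence: SequenceParams = field(default_factory=SequenceParams)
    accel: int = 8
    taper_ratio: float = 0.25
    per_slice_norm: bool = True
    final_magnitude: bool = False
    magnitude_synthesis: bool = False
    frac_threshold: float = 0.5
    shape: tuple[int, int, int] = (30, 224, 224)
    lesion_mismatch: float = 1.8
    mt_wm: float = 0.88
    mt_gm: float = 0.94
    noise_sigma: float = 0.02
    texture_sigma: float = 0.02
    rigid_offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.accel < 1:
            raise InputError(f"accel must be >= 1, got {self.accel}")
        if not (0.0 <= self.taper_ratio <= 1.0):
            raise InputError(
                f"taper_ratio must be in [0, 1], got {self.taper_ratio}")
        if not (0.0 <= self.frac_threshold <= 1.0):
            raise InputError(
                f"frac_threshold must be in [0, 1], got {self.frac_threshold}")
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise InputError(f"shape must be 3 positive ints, got {self.shape}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "rigid_offset",
                           tuple(float(v) for v in self.rigid_offset))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _TOP_KEYS
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {}
        if "sequence" in d:
            sub = dict(d["sequence"])
            bad = set(sub) - _SEQUENCE_KEYS
            if bad:
                raise InputError(f"unknown sequence keys: {sorted(bad)}")
            kwargs["sequence"] = SequenceParams(**sub)
        for block, keys in (("fusion", _FUSION_KEYS),
                            ("preprocess", _PREPROCESS_KEYS),
                            ("phantom", _PHANTOM_KEYS)):
            if block in d:
                sub = dict(d[block])
                bad = set(sub) - keys
                if bad:
                    raise InputError(f"unknown {block} keys: {sorted(bad)}")
                kwargs.update(sub)
        if "seed" in d:
            kwargs["seed"] = int(d["seed"])
        if "magnitude_synthesis" in d:
            kwargs["magnitude_synthesis"] = bool(d["magnitude_synthesis"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise InputError(f"config file {path} is not a mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sequence"] = asdict(self.sequence)
        d["shape"] = list(self.shape)
        d["rigid_offset"] = list(self.rigid_offset)
        return d

    def content_hash(self) -> str:
        """SHA-256 of the canonical JSON form, for provenance records."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
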