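"""Run configuration: every analysis constant in one serializable place.

The fixed settings of the analysis protocol (minimum four calls per caller
and call type, one-hour sequence independence, 100 balanced selections and
1000 permutations for the permuted DFA, the 0.45 loading cutoff feeding the
mixed models, alpha = 0.05) are defaults here, never hard-coded elsewhere.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .audio import CALL_TYPES, DEFAULT_BAND_RATES
from .features import DEFAULT_BAND_THRESHOLD_DB, DEFAULT_NOISY_CUT, DEFAULT_TONAL_CUT

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    # inputs: either audio_dir + meta_csv, or a precomputed feature table
    audio_dir: str = ""
    meta_csv: str = ""
    features_csv: str = ""
    out_dir: str = "vocalid_out"

    call_types: list[str] = field(default_factory=lambda: list(CALL_TYPES))
    min_calls: int = 4
    min_gap_s: float = 3600.0

    # spectrogram / features
    window: str = "hamming"
    rate_map: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_BAND_RATES))
    band_threshold_db: float = DEFAULT_BAND_THRESHOLD_DB
    tonal_cut: float = DEFAULT_TONAL_CUT
    noisy_cut: float = DEFAULT_NOISY_CUT

    # discriminant analysis
    f_to_enter: float = 3.84
    f_to_remove: float = 2.71
    loading_cutoff: float = 0.45
    n_selections: int = 100
    n_permutations: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.band_threshold_db < 0):
            raise ValueError("band_threshold_db must be negative")
        if not (0 <= self.tonal_cut < self.noisy_cut <= 1):
            raise ValueError("need 0 <= tonal_cut < noisy_cut <= 1")
        if self.min_calls < 2:
            raise ValueError("min_calls must be at least 2")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_permutations < 1 or self.n_selections < 1:
            raise ValueError("permutation settings must be positive")

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in the run log."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
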