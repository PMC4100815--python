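"""Call-segment audio handling.

Reads mono WAV call segments, downsamples each call type into its analysis
band, computes the fixed-settings spectrogram used throughout the feature
extraction, and applies the dataset inclusion filters (recording quality,
one-hour sequence independence, minimum calls per caller and call type).

The spectrogram contract is deliberately rigid: 256-sample analysis frames
zero-padded to a 1024-point FFT, frames advanced by 93% overlap of the
256-sample frame (hop = round(256 * 0.07) = 18 samples). All downstream
features are defined on this grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.io import wavfile
from scipy.signal import get_window, resample_poly

__all__ = [
    "CALL_TYPES",
    "REPEATED_SEGMENT_TYPES",
    "DEFAULT_BAND_RATES",
    "CallRecord",
    "Waveform",
    "Spectrogram",
    "read_wav",
    "write_wav",
    "select_band_rate",
    "resample",
    "spectrogram",
    "filter_call_records",
]

#: The eight call types of the female repertoire under analysis.
CALL_TYPES = (
    "single_grunt",
    "double_grunt",
    "grumble",
    "threat_grunt",
    "copulation_grunt",
    "hum",
    "hoot_series",
    "scream",
)

#: Call types uttered as sequences of repeated similar segments; only these
#: are subject to the sequence-independence (1 h gap) rule.
REPEATED_SEGMENT_TYPES = frozenset({"threat_grunt", "copulation_grunt", "hoot_series"})

#: Default call-type -> analysis sampling rate map. The three band rates are
#: fixed; the assignment follows each call type's typical frequency range
#: (wideband for loud high-frequency calls, narrow for low-pitched grunts)
#: and can be overridden via the ``rate_map`` argument / run config.
DEFAULT_BAND_RATES: Mapping[str, int] = {
    "scream": 22050,
    "hoot_series": 22050,
    "hum": 11025,
    "threat_grunt": 11025,
    "single_grunt": 4000,
    "double_grunt": 4000,
    "grumble": 4000,
    "copulation_grunt": 4000,
}

FRAME_LEN = 256
FFT_LEN = 1024
OVERLAP = 0.93
HOP = round(FRAME_LEN * (1.0 - OVERLAP))  # = 18 samples


@dataclass(frozen=True)
class CallRecord:
    """Metadata for one call segment (the analysis unit)."""

    segment_id: str
    caller_id: str
    call_type: str
    sequence_id: str
    timestamp: float  # seconds since epoch
    audio_path: str = ""  # empty when features are supplied directly
    quality_ok: bool = True

    def __post_init__(self) -> None:
        if self.call_type not in CALL_TYPES:
            raise ValueError(
                f"unknown call type {self.call_type!r}; expected one of {CALL_TYPES}"
            )


@dataclass(frozen=True)
class Waveform:
    """Mono audio samples in [-1, 1] at a given sampling rate."""

    samples: np.ndarray
    rate: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=np.float64))
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate


@dataclass(frozen=True)
class Spectrogram:
    """Short-time magnitude spectrogram on the fixed 256/1024/93% grid.

    ``magnitudes`` is (n_frames, n_bins) with n_bins = FFT_LEN//2 + 1;
    ``bin_hz`` = rate / FFT_LEN; ``frame_times`` are frame-centre times in
    seconds, strictly increasing.
    """

    magnitudes: np.ndarray
    bin_hz: float
    frame_times: np.ndarray
    rate: int
    n_samples: int
    window: str = "hamming"

    @property
    def n_frames(self) -> int:
        return self.magnitudes.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        return np.arange(self.magnitudes.shape[1]) * self.bin_hz


def read_wav(path: str | Path) -> Waveform:
    """Read a RIFF WAV file as a mono waveform scaled to [-1, 1].

    Multichannel files are reduced to their first channel. Integer PCM is
    scaled by the full-scale value of its dtype; float data is taken as is.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such audio file: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except ValueError as exc:
        raise IOError(f"cannot parse WAV file {path}: {exc}") from exc
    data = np.atleast_1d(np.asarray(data))
    if data.size == 0:
        raise ValueError(f"zero-length audio in {path}")
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        # symmetric full-scale convention (matches write_wav), clipped so the
        # most negative code still maps inside [-1, 1]
        scale = float(np.iinfo(data.dtype).max)
        samples = np.clip(data.astype(np.float64) / scale, -1.0, 1.0)
    else:
        samples = data.astype(np.float64)
    return Waveform(samples=samples, rate=int(rate))


def write_wav(path: str | Path, w: Waveform) -> None:
    """Write a waveform as 16-bit PCM WAV (synthesis/testing helper)."""
    clipped = np.clip(w.samples, -1.0, 1.0)
    pcm = np.round(clipped * 32767.0).astype(np.int16)
    wavfile.write(str(path), w.rate, pcm)


def select_band_rate(
    call_type: str, rate_map: Mapping[str, int] | None = None
) -> int:
    """Analysis sampling rate (22050, 11025 or 4000 Hz) for a call type."""
    rate_map = DEFAULT_BAND_RATES if rate_map is None else rate_map
    if call_type not in CALL_TYPES:
        raise ValueError(f"unknown call type {call_type!r}")
    rate = rate_map.get(call_type)
    if rate is None:
        raise ValueError(f"no band rate configured for call type {call_type!r}")
    return int(rate)


def resample(w: Waveform, target: int) -> Waveform:
    """Downsample to ``target`` Hz with a polyphase anti-aliasing filter.

    Upsampling is rejected: the analysis bands are always at or below the
    recording rate.
    """
    if target > w.rate:
        raise ValueError(f"cannot upsample from {w.rate} Hz to {target} Hz")
    if target == w.rate:
        return w
    g = math.gcd(int(target), int(w.rate))
    out = resample_poly(w.samples, target // g, w.rate // g)
    return Waveform(samples=out, rate=int(target))


def spectrogram(w: Waveform, window: str = "hamming") -> Spectrogram:
    """Magnitude spectrogram with 256-sample frames zero-padded to 1024 points.

    Frame count follows the closed form floor((N - 256)/18) + 1; a signal
    shorter than one frame is rejected.
    """
    n = len(w.samples)
    if n < FRAME_LEN:
        raise ValueError(f"signal too short for spectrogram: {n} < {FRAME_LEN} samples")
    n_frames = (n - FRAME_LEN) // HOP + 1
    starts = np.arange(n_frames) * HOP
    idx = starts[:, None] + np.arange(FRAME_LEN)[None, :]
    frames = w.samples[idx] * get_window(window, FRAME_LEN, fftbins=True)
    mags = np.abs(np.fft.rfft(frames, n=FFT_LEN, axis=1))
    times = (starts + FRAME_LEN / 2.0) / w.rate
    return Spectrogram(
        magnitudes=mags,
        bin_hz=w.rate / FFT_LEN,
        frame_times=times,
        rate=w.rate,
        n_samples=n,
        window=window,
    )


def filter_call_records(
    records: Sequence[CallRecord],
    min_gap_s: float = 3600.0,
    min_calls: int = 4,
    repeated_types: Iterable[str] = REPEATED_SEGMENT_TYPES,
) -> list[CallRecord]:
    """Apply the dataset inclusion rules.

    1. Records flagged with ``quality_ok=False`` are dropped.
    2. For call types uttered as repeated-segment sequences, only independent
       sequences are kept: within each (caller, call type), a sequence is
       retained only if it starts at least ``min_gap_s`` after the start of
       the previously retained sequence.
    3. Any (caller, call type) pair left with fewer than ``min_calls``
       segments is removed entirely.

    The operation is idempotent.
    """
    repeated_types = frozenset(repeated_types)
    kept = [r for r in records if r.quality_ok]

    # sequence independence per (caller, call_type)
    by_group: dict[tuple[str, str], list[CallRecord]] = {}
    for r in kept:
        by_group.setdefault((r.caller_id, r.call_type), []).append(r)

    surviving: list[CallRecord] = []
    for (caller, ctype), group in by_group.items():
        group = sorted(group, key=lambda r: (r.timestamp, r.segment_id))
        if ctype not in repeated_types:
            surviving.extend(group)
            continue
        seq_start: dict[str, float] = {}
        for r in group:
            seq_start.setdefault(r.sequence_id, r.timestamp)
        retained_seqs: set[str] = set()
        last_start: float | None = None
        for seq in sorted(seq_start, key=seq_start.get):
            start = seq_start[seq]
            if last_start is None or start - last_start >= min_gap_s:
                retained_seqs.add(seq)
                last_start = start
        surviving.extend(r for r in group if r.sequence_id in retained_seqs)

    counts: dict[tuple[str, str], int] = {}
    for r in surviving:
        counts[(r.caller_id, r.call_type)] = counts.get((r.caller_id, r.call_type), 0) + 1
    out = [r for r in surviving if counts[(r.caller_id, r.call_type)] >= min_calls]
    out.sort(key=lambda r: (r.call_type, r.caller_id, r.timestamp, r.segment_id))
    return out
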