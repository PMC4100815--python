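"""Per-segment acoustic parameters.

Twenty parameters describing time, frequency, energy distribution, dominant
frequency-band structure, relative amplitude and tonality are computed from
the fixed-grid spectrogram of a call segment. Every spectral threshold is
relative (to each frame's maximum), so the whole feature set is invariant to
rescaling the waveform amplitude.

Frame-level primitives
----------------------
* energy-quartile frequencies: the frequency below which 25% / 50% of the
  frame's spectral energy (squared magnitude) lies;
* dominant frequency bands: maximal runs of contiguous bins whose magnitude
  exceeds ``band_threshold_db`` relative to the frame maximum, each band
  summarised at its peak bin;
* first spectral peak (fp1): the lowest-frequency local maximum above the
  same relative threshold;
* tonality class: tonal / noisy / neither by spectral flatness (Wiener
  entropy, the geometric over arithmetic mean of the power spectrum).

Frames with zero energy are excluded from every aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np

from .audio import Spectrogram

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "FrameSpectrum",
    "energy_quartile_frequency",
    "dominant_bands",
    "frame_tonality",
    "extract_features",
]

#: Canonical order of the 20 acoustic parameters.
FEATURE_NAMES = (
    "duration",
    "dfa1mean",
    "dfa1maloc",
    "dfa2mean",
    "dfa2maloc",
    "df1max",
    "df1min",
    "df1mean",
    "diffmean",
    "diffreq",
    "ampratio1",
    "fp1max",
    "fp1mean",
    "fp1amean",
    "ranmean",
    "pfmax",
    "pfmin",
    "pfmean",
    "noise",
    "tonality",
)

#: Default dominant-band threshold relative to each frame's spectral maximum.
#: This is the single most consequential free parameter of the extraction:
#: it decides what counts as a dominant band, the first peak, and the frame
#: frequency range.
DEFAULT_BAND_THRESHOLD_DB = -24.0

#: Spectral-flatness cuts for the tonal / noisy classification. A pure tone
#: frame has flatness near 0; the flatness of a white-noise frame on this
#: spectrogram grid concentrates near e**(-gamma) ~ 0.56 (exponential
#: periodogram bins), so the noisy cut sits below that mass while a frame of
#: tone plus equal-power noise (~0.31) stays in "neither".
DEFAULT_TONAL_CUT = 0.10
DEFAULT_NOISY_CUT = 0.45


@dataclass(frozen=True)
class FrameSpectrum:
    """One spectrogram frame plus its derived frame-level values."""

    magnitudes: np.ndarray
    bin_hz: float
    frame_index: int

    @property
    def frequencies(self) -> np.ndarray:
        return np.arange(len(self.magnitudes)) * self.bin_hz

    @property
    def energy(self) -> float:
        return float(np.sum(self.magnitudes**2))


@dataclass(frozen=True)
class FeatureVector:
    """The 20 acoustic parameters of one call segment.

    ``diffmean`` and ``ampratio1`` are NaN when no frame shows at least two
    dominant bands; such rows are removed listwise before discriminant
    analysis.
    """

    duration: float  # ms
    dfa1mean: float  # Hz
    dfa1maloc: float  # relative position in [0, 1]
    dfa2mean: float  # Hz
    dfa2maloc: float
    df1max: float  # Hz
    df1min: float  # Hz
    df1mean: float  # Hz
    diffmean: float  # Hz (NaN if undefined)
    diffreq: float  # mean number of dominant bands
    ampratio1: float  # band1/band2 amplitude ratio (NaN if undefined)
    fp1max: float  # Hz
    fp1mean: float  # Hz
    fp1amean: float  # relative amplitude in (0, 1]
    ranmean: float  # Hz
    pfmax: float  # Hz
    pfmin: float  # Hz
    pfmean: float  # Hz
    noise: float  # % of frames
    tonality: float  # % of frames

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def energy_quartile_frequency(s: FrameSpectrum, q: float) -> float:
    """Smallest bin-centre frequency at which the cumulative spectral energy
    (squared magnitude) reaches fraction ``q`` of the frame total."""
    power = s.magnitudes.astype(np.float64) ** 2
    total = power.sum()
    if total <= 0:
        raise ValueError("zero-energy frame has no energy-quartile frequency")
    cum = np.cumsum(power)
    idx = int(np.searchsorted(cum, q * total))
    return idx * s.bin_hz


def dominant_bands(
    s: FrameSpectrum, threshold_db: float = DEFAULT_BAND_THRESHOLD_DB
) -> list[tuple[float, float]]:
    """Dominant frequency bands of a frame.

    Returns (peak frequency Hz, peak magnitude) for every maximal run of
    contiguous bins whose magnitude is at least ``threshold_db`` (negative,
    dB) below the frame maximum, ordered by ascending frequency.
    """
    if threshold_db >= 0:
        raise ValueError("band threshold must be negative dB relative to frame max")
    mags = s.magnitudes
    peak = mags.max()
    if peak <= 0:
        return []
    thresh = peak * 10.0 ** (threshold_db / 20.0)
    above = mags >= thresh
    bands: list[tuple[float, float]] = []
    i = 0
    n = len(mags)
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            k = i + int(np.argmax(mags[i : j + 1]))
            bands.append((k * s.bin_hz, float(mags[k])))
            i = j + 1
        else:
            i += 1
    return bands


def spectral_flatness(s: FrameSpectrum) -> float:
    """Wiener entropy: geometric / arithmetic mean of the power spectrum.

    0 for a line spectrum, approaching 1 for a flat one. Zero bins are
    excluded from the geometric mean only when all others are positive;
    an all-zero frame raises.
    """
    power = s.magnitudes.astype(np.float64) ** 2
    am = power.mean()
    if am <= 0:
        raise ValueError("zero-energy frame has no spectral flatness")
    pos = power[power > 0]
    if len(pos) < len(power):
        # any exact-zero bin drives the geometric mean to 0
        return 0.0
    gm = np.exp(np.mean(np.log(pos)))
    return float(gm / am)


def frame_tonality(
    s: FrameSpectrum,
    tonal_cut: float = DEFAULT_TONAL_CUT,
    noisy_cut: float = DEFAULT_NOISY_CUT,
) -> str:
    """Classify a frame as ``"tonal"``, ``"noisy"`` or ``"neither"``."""
    flat = spectral_flatness(s)
    if flat <= tonal_cut:
        return "tonal"
    if flat >= noisy_cut:
        return "noisy"
    return "neither"


def _first_peak(
    s: FrameSpectrum, threshold_db: float
) -> tuple[float, float] | None:
    """Lowest-frequency local spectral maximum above the band threshold.

    Returns (frequency Hz, amplitude relative to frame max). Endpoints count
    as peaks; plateau ties break toward the lower frequency. Falls back to
    the global maximum when no local maximum clears the threshold.
    """
    mags = s.magnitudes
    peak = mags.max()
    if peak <= 0:
        return None
    thresh = peak * 10.0 ** (threshold_db / 20.0)
    padded = np.concatenate(([-np.inf], mags, [-np.inf]))
    is_max = (padded[1:-1] >= padded[:-2]) & (padded[1:-1] > padded[2:])
    candidates = np.nonzero(is_max & (mags >= thresh))[0]
    if len(candidates) == 0:
        k = int(np.argmax(mags))
    else:
        k = int(candidates[0])
    return k * s.bin_hz, float(mags[k] / peak)


def extract_features(
    spec: Spectrogram,
    band_threshold_db: float = DEFAULT_BAND_THRESHOLD_DB,
    tonal_cut: float = DEFAULT_TONAL_CUT,
    noisy_cut: float = DEFAULT_NOISY_CUT,
) -> FeatureVector:
    """Compute the 20-parameter feature vector of one call segment.

    Aggregation over frames: means / extrema are taken over frames with
    positive energy; the two "location" parameters report the relative
    temporal position (0 = first analysed frame, 1 = last) of the frame
    holding the maximum energy-quartile frequency.
    """
    frames = [
        FrameSpectrum(magnitudes=spec.magnitudes[i], bin_hz=spec.bin_hz, frame_index=i)
        for i in range(spec.n_frames)
    ]
    frames = [f for f in frames if f.energy > 0]
    if not frames:
        raise ValueError("all-silent segment: no frame with positive energy")

    n = len(frames)
    dfa1 = np.array([energy_quartile_frequency(f, 0.25) for f in frames])
    dfa2 = np.array([energy_quartile_frequency(f, 0.50) for f in frames])
    bands = [dominant_bands(f, band_threshold_db) for f in frames]
    flags = [frame_tonality(f, tonal_cut, noisy_cut) for f in frames]
    peaks = [_first_peak(f, band_threshold_db) for f in frames]
    pf = np.array([np.argmax(f.magnitudes) * f.bin_hz for f in frames])

    def rel_loc(values: np.ndarray) -> float:
        if n == 1:
            return 0.5
        return float(np.argmax(values)) / (n - 1)

    df1 = np.array([b[0][0] for b in bands])  # every frame has >= 1 band
    n_bands = np.array([len(b) for b in bands], dtype=float)
    two_plus = [b for b in bands if len(b) >= 2]
    if two_plus:
        diffs = np.array([b[1][0] - b[0][0] for b in two_plus])
        ratios = np.array([b[0][1] / b[1][1] for b in two_plus])
        diffmean = float(diffs.min())
        ampratio1 = float(ratios.mean())
    else:
        diffmean = float("nan")
        ampratio1 = float("nan")

    # frame frequency range spans from the lowest to the highest bin above
    # threshold, i.e. across all dominant bands of the frame
    ranges = np.array([_frame_range(f, band_threshold_db) for f in frames])

    fp1f = np.array([p[0] for p in peaks])
    fp1a = np.array([p[1] for p in peaks])

    return FeatureVector(
        duration=1000.0 * spec.n_samples / spec.rate,
        dfa1mean=float(dfa1.mean()),
        dfa1maloc=rel_loc(dfa1),
        dfa2mean=float(dfa2.mean()),
        dfa2maloc=rel_loc(dfa2),
        df1max=float(df1.max()),
        df1min=float(df1.min()),
        df1mean=float(df1.mean()),
        diffmean=diffmean,
        diffreq=float(n_bands.mean()),
        ampratio1=ampratio1,
        fp1max=float(fp1f.max()),
        fp1mean=float(fp1f.mean()),
        fp1amean=float(fp1a.mean()),
        ranmean=float(ranges.mean()),
        pfmax=float(pf.max()),
        pfmin=float(pf.min()),
        pfmean=float(pf.mean()),
        noise=100.0 * sum(f == "noisy" for f in flags) / n,
        tonality=100.0 * sum(f == "tonal" for f in flags) / n,
    )


def _frame_range(f: FrameSpectrum, threshold_db: float) -> float:
    mags = f.magnitudes
    peak = mags.max()
    thresh = peak * 10.0 ** (threshold_db / 20.0)
    above = np.nonzero(mags >= thresh)[0]
    if len(above) == 0:
        return 0.0
    return float((above[-1] - above[0]) * f.bin_hz)


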