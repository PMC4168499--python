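"""Per-channel time- and frequency-domain features for decision-level fusion.

Heart rate, CO2 and SpO2 contribute time statistics plus low/high-frequency
spectral power (LF 0.04-0.15 Hz, HF 0.15-0.4 Hz, and their ratio — the
standard autonomic-balance index); respiration contributes mean, standard
deviation and the dominant respiration frequency in 0.1-1.5 Hz; finger
temperature contributes time statistics and linear-fit slopes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .signal_model import ChannelSeries, resample

__all__ = [
    "FeatureVector",
    "PsdEstimate",
    "LF_BAND",
    "HF_BAND",
    "DRF_BAND",
    "time_domain_stats",
    "psd_fft",
    "band_power",
    "lf_hf_features",
    "dominant_respiration_frequency",
    "ft_slope_features",
    "build_channel_case",
]

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)
DRF_BAND = (0.1, 1.5)

#: HR series are brought to this rate before spectral estimation.
SPECTRAL_FS = 4.0


@dataclass(frozen=True)
class FeatureVector:
    """Ordered, uniquely named real-valued features.

    A NaN value marks a feature flagged undefined (e.g. an LF/HF ratio with
    zero high-frequency power); case libraries reject such vectors.
    """

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "names", tuple(self.names))
        if len(self.names) != values.size:
            raise ValueError("names and values must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError(f"feature names must be unique: {self.names}")

    @classmethod
    def from_dict(cls, mapping: dict) -> "FeatureVector":
        return cls(tuple(mapping.keys()), np.array(list(mapping.values()), dtype=float))

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values.tolist()))

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])

    def __len__(self) -> int:
        return len(self.names)

    def prefixed(self, prefix: str) -> "FeatureVector":
        return FeatureVector(tuple(f"{prefix}.{n}" for n in self.names), self.values)

    def concat(self, other: "FeatureVector") -> "FeatureVector":
        return FeatureVector(self.names + other.names, np.concatenate([self.values, other.values]))


@dataclass(frozen=True)
class PsdEstimate:
    """One-sided power spectral density on a uniform frequency grid."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self) -> None:
        freqs = np.asarray(self.freqs, dtype=float)
        power = np.asarray(self.power, dtype=float)
        object.__setattr__(self, "freqs", freqs)
        object.__setattr__(self, "power", power)
        if freqs.size != power.size:
            raise ValueError("freqs and power must have equal length")
        if np.any(np.diff(freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(power < 0):
            raise ValueError("PSD values must be nonnegative")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def time_domain_stats(s: ChannelSeries) -> FeatureVector:
    """max, min, arithmetic mean and sample standard deviation (n-1)."""
    if s.n < 2:
        raise ValueError("need at least 2 samples for a standard deviation")
    x = s.samples
    return FeatureVector.from_dict(
        {
            "max": float(np.max(x)),
            "min": float(np.min(x)),
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)),
        }
    )


def psd_fft(s: ChannelSeries) -> PsdEstimate:
    """Single-window periodogram: mean removal, zero-padding to the next
    power of two, squared DFT amplitude scaled by 1/(fs*N), one-sided with
    interior bins doubled so the integral matches the signal variance."""
    if s.n < 8:
        raise ValueError("need at least 8 samples for a PSD estimate")
    x = s.samples - np.mean(s.samples)
    n = s.n
    m = 1 << (n - 1).bit_length()  # next power of two >= n
    spec = np.fft.rfft(x, m)
    psd = (np.abs(spec) ** 2) / (s.fs * n)
    psd[1:-1] *= 2.0  # fold negative frequencies; DC and Nyquist appear once
    freqs = np.fft.rfftfreq(m, d=1.0 / s.fs)
    return PsdEstimate(freqs=freqs, power=psd)


def band_power(psd: PsdEstimate, lo: float, hi: float) -> float:
    """Trapezoidal integral of the PSD over [lo, hi] Hz.

    Band edges falling between grid points are linearly interpolated, which
    makes band powers exactly additive over adjacent bands.
    """
    fmax = float(psd.freqs[-1])
    fmin = float(psd.freqs[0])
    if not (fmin <= lo < hi <= fmax):
        raise ValueError(
            f"band [{lo}, {hi}] outside the PSD grid [{fmin}, {fmax}]"
        )
    inner = (psd.freqs > lo) & (psd.freqs < hi)
    grid = np.concatenate(([lo], psd.freqs[inner], [hi]))
    vals = np.interp(grid, psd.freqs, psd.power)
    return float(np.trapezoid(vals, grid))


def lf_hf_features(psd: PsdEstimate) -> FeatureVector:
    """LF power, HF power and LF/HF ratio.

    With zero HF power the ratio is flagged as NaN (never infinity).
    """
    if psd.freqs[-1] < HF_BAND[1]:
        raise ValueError(f"PSD grid must reach {HF_BAND[1]} Hz")
    lf = band_power(psd, *LF_BAND)
    hf = band_power(psd, *HF_BAND)
    ratio = lf / hf if hf > 0 else math.nan
    return FeatureVector.from_dict({"lf_power": lf, "hf_power": hf, "lf_hf_ratio": ratio})


def dominant_respiration_frequency(psd: PsdEstimate) -> float:
    """Frequency of maximal spectral power within 0.1-1.5 Hz."""
    if psd.freqs[-1] < DRF_BAND[1]:
        raise ValueError(
            f"PSD grid reaches only {psd.freqs[-1]:.3g} Hz; the dominant "
            f"respiration frequency needs the band up to {DRF_BAND[1]} Hz"
        )
    sel = (psd.freqs >= DRF_BAND[0]) & (psd.freqs <= DRF_BAND[1])
    idx = np.flatnonzero(sel)
    return float(psd.freqs[idx[np.argmax(psd.power[idx])]])


def ft_slope_features(s: ChannelSeries, window_seconds: float = 60.0) -> FeatureVector:
    """Least-squares linear-fit gradients in units/second: one slope over the
    whole series plus one per consecutive non-overlapping window."""
    if s.n < 2:
        raise ValueError("need at least 2 samples to fit a slope")
    win = int(round(window_seconds * s.fs))
    if win > s.n:
        raise ValueError(
            f"window of {window_seconds} s ({win} samples) exceeds series length {s.n}"
        )
    t = np.arange(s.n) / s.fs
    feats = {"slope": _ols_slope(t, s.samples)}
    if win >= 2:
        n_win = s.n // win
        for w in range(n_win):
            seg = slice(w * win, (w + 1) * win)
            feats[f"slope_w{w + 1}"] = _ols_slope(t[seg], s.samples[seg])
    return FeatureVector.from_dict(feats)


def _ols_slope(t: np.ndarray, x: np.ndarray) -> float:
    tc = t - t.mean()
    return float(np.dot(tc, x - x.mean()) / np.dot(tc, tc))


def build_channel_case(s: ChannelSeries, channel: str | None = None) -> FeatureVector:
    """Channel-appropriate feature menu, with names ``<channel>.<feature>``.

    HR/CO2/SPO2: time statistics + LF/HF triple (HR resampled to 4 Hz before
    spectral estimation); RR: mean, sd and dominant respiration frequency;
    FT: time statistics + slope features.
    """
    channel = (channel or s.name).upper()
    if channel in ("HR", "CO2", "SPO2"):
        spectral = s
        if channel == "HR" and s.fs != SPECTRAL_FS:
            spectral = resample(s, SPECTRAL_FS)
        fv = time_domain_stats(s).concat(lf_hf_features(psd_fft(spectral)))
    elif channel == "RR":
        stats = time_domain_stats(s)
        drf = dominant_respiration_frequency(psd_fft(s))
        fv = FeatureVector.from_dict(
            {"mean": stats["mean"], "sd": stats["sd"], "drf": drf}
        )
    elif channel == "FT":
        fv = time_domain_stats(s).concat(ft_slope_features(s))
    else:
        raise ValueError(
            f"unknown channel {channel!r}: expected one of HR, RR, FT, CO2, SPO2"
        )
    return fv.prefixed(channel)
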