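"""Recording data model, delimited-text I/O and the pre-processing chain.

A recording is a set of aligned physiological channel series (heart rate,
finger temperature, respiration, CO2, SpO2 ...) sampled at a common rate.
Pre-processing follows the order: artifact replacement (sample-and-hold),
causal IIR low-pass filtering, centered running-average smoothing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "ChannelSeries",
    "MultichannelRecording",
    "PreprocessConfig",
    "read_recording",
    "write_recording",
    "replace_artifacts",
    "iir_lowpass",
    "running_average",
    "resample",
    "preprocess_channel",
    "preprocess_recording",
]

STANDARD_CHANNELS = ("HR", "FT", "RR", "CO2", "SPO2")


@dataclass(frozen=True)
class ChannelSeries:
    """One named channel: ordered samples at a fixed sampling rate.

    ``samples`` may contain NaN before artifact replacement; every
    downstream numeric operation requires finite samples.
    """

    name: str
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1 or samples.size < 1:
            raise ValueError(f"channel {self.name!r}: need a 1-D series with >= 1 sample")
        if not self.fs > 0:
            raise ValueError(f"channel {self.name!r}: fs must be > 0, got {self.fs}")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n / self.fs

    def with_samples(self, samples: np.ndarray) -> "ChannelSeries":
        return _dc_replace(self, samples=np.asarray(samples, dtype=float))


@dataclass
class MultichannelRecording:
    """p aligned channel series plus free-form subject metadata and an
    optional class label ("Stressed" / "Relaxed" / None for queries)."""

    channels: list[ChannelSeries]
    subject_meta: dict = field(default_factory=dict)
    label: str | None = None

    def __post_init__(self) -> None:
        if len(self.channels) < 1:
            raise ValueError("recording needs at least one channel")
        names = [c.name for c in self.channels]
        if len(set(names)) != len(names):
            raise ValueError(f"channel names must be unique, got {names}")

    @property
    def p(self) -> int:
        return len(self.channels)

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def fs(self) -> float:
        return self.channels[0].fs

    def channel(self, name: str) -> ChannelSeries:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(f"no channel named {name!r}; have {self.channel_names}")

    def equal_length(self) -> bool:
        return len({c.n for c in self.channels}) == 1

    def to_array(self) -> np.ndarray:
        """Stack channels into a (p, N) array; requires equal lengths."""
        if not self.equal_length():
            raise ValueError(
                f"channels have unequal lengths {[c.n for c in self.channels]}"
            )
        return np.vstack([c.samples for c in self.channels])


def read_recording(path, fs: float | None = None) -> MultichannelRecording:
    """Read a delimited-text recording: header row of channel names, one row
    per sample, optional leading comment line ``# fs=<Hz>``.

    Non-numeric or empty cells become NaN, to be handled by
    :func:`replace_artifacts`. Ragged rows raise a parse error naming the row.
    """
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    lines = text.splitlines()
    data_lines = []
    for ln in lines:
        stripped = ln.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.lower().startswith("fs"):
                try:
                    file_fs = float(body.split("=", 1)[1])
                except (IndexError, ValueError) as exc:
                    raise ValueError(f"unparseable fs comment line: {ln!r}") from exc
                if fs is None:
                    fs = file_fs
            continue
        data_lines.append(ln)
    if not data_lines:
        raise ValueError(f"{path}: empty file (no header row)")
    if fs is None:
        raise ValueError(f"{path}: sampling rate not given and no '# fs=' comment")

    header = [h.strip() for h in data_lines[0].split(",")]
    ncol = len(header)
    rows = []
    for row_idx, ln in enumerate(data_lines[1:], start=1):
        cells = ln.split(",")
        if len(cells) != ncol:
            raise ValueError(
                f"{path}: ragged row {row_idx}: expected {ncol} cells, got {len(cells)}"
            )
        rows.append(cells)
    if not rows:
        raise ValueError(f"{path}: no samples (header-only file)")

    frame = pd.DataFrame(rows, columns=header)
    channels = []
    for name in header:
        values = pd.to_numeric(frame[name].str.strip(), errors="coerce").to_numpy()
        channels.append(ChannelSeries(name=name, samples=values, fs=fs))
    return MultichannelRecording(channels=channels)


def write_recording(rec: MultichannelRecording, path) -> None:
    """Write the same dialect :func:`read_recording` consumes.

    Values are printed with 17 significant digits so a read/write cycle
    round-trips float64 exactly.
    """
    if not rec.equal_length():
        raise ValueError("cannot write a recording with unequal channel lengths")
    buf = io.StringIO()
    buf.write(f"# fs={rec.fs!r}\n")
    buf.write(",".join(rec.channel_names) + "\n")
    data = np.column_stack([c.samples for c in rec.channels])
    for row in data:
        buf.write(",".join("" if np.isnan(v) else format(v, ".17g") for v in row) + "\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


def replace_artifacts(s: ChannelSeries) -> tuple[ChannelSeries, int]:
    """Replace every missing/non-finite sample by the nearest preceding valid
    sample (sample-and-hold); a leading missing run is back-filled from the
    first valid sample. Returns the repaired series and the replacement count.
    """
    x = s.samples.copy()
    bad = ~np.isfinite(x)
    n_replaced = int(bad.sum())
    if n_replaced == x.size:
        raise ValueError(f"channel {s.name!r}: all samples missing")
    if n_replaced:
        first_valid = int(np.flatnonzero(~bad)[0])
        x[:first_valid] = x[first_valid]
        # forward fill the interior
        idx = np.arange(x.size)
        valid_idx = np.where(~bad, idx, 0)
        np.maximum.accumulate(valid_idx, out=valid_idx)
        x = x[valid_idx]
    return s.with_samples(x), n_replaced


def iir_lowpass(s: ChannelSeries, cutoff: float, order: int = 4) -> ChannelSeries:
    """Causal (forward-only) Butterworth low-pass filter with unit DC gain."""
    nyq = s.fs / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must lie in (0, fs/2) = (0, {nyq}), got {cutoff}")
    if order < 1:
        raise ValueError("order must be >= 1")
    sos = sps.butter(order, cutoff, btype="low", fs=s.fs, output="sos")
    # start the filter from the initial value so constant inputs stay constant
    zi = sps.sosfilt_zi(sos) * s.samples[0]
    y, _ = sps.sosfilt(sos, s.samples, zi=zi)
    return s.with_samples(y)


def running_average(s: ChannelSeries, window: int = 5) -> ChannelSeries:
    """Centered moving mean; edge windows truncate to the available samples.

    The window must be odd so the smoother is symmetric (no phase shift).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window > s.n:
        raise ValueError(f"window {window} exceeds series length {s.n}")
    kernel = np.ones(window)
    sums = np.convolve(s.samples, kernel, mode="same")
    counts = np.convolve(np.ones(s.n), kernel, mode="same")
    return s.with_samples(sums / counts)


def resample(s: ChannelSeries, target_fs: float) -> ChannelSeries:
    """Fourier-domain resampling to ``target_fs``; output length is
    round(N * target_fs / fs). Band content below the new Nyquist is kept."""
    if not target_fs > 0:
        raise ValueError("target_fs must be > 0")
    if target_fs == s.fs:
        return s
    n_out = int(round(s.n * target_fs / s.fs))
    if n_out < 1:
        raise ValueError("resampling would produce an empty series")
    y = sps.resample(s.samples, n_out)
    return ChannelSeries(name=s.name, samples=y, fs=target_fs)


@dataclass(frozen=True)
class PreprocessConfig:
    """Artifact replacement -> causal IIR low-pass -> running average.

    ``cutoff_hz`` maps channel name to low-pass cutoff; channels not listed
    are filtered at ``default_cutoff_hz`` (None disables filtering for them).
    """

    cutoff_hz: dict = field(default_factory=dict)
    default_cutoff_hz: float | None = 0.5
    order: int = 4
    window: int = 5


def preprocess_channel(s: ChannelSeries, config: PreprocessConfig | None = None) -> ChannelSeries:
    config = config or PreprocessConfig()
    s, _ = replace_artifacts(s)
    cutoff = config.cutoff_hz.get(s.name, config.default_cutoff_hz)
    if cutoff is not None:
        s = iir_lowpass(s, cutoff, order=config.order)
    if config.window > 1:
        s = running_average(s, window=config.window)
    return s


def preprocess_recording(
    rec: MultichannelRecording, config: PreprocessConfig | None = None
) -> MultichannelRecording:
    return MultichannelRecording(
        channels=[preprocess_channel(c, config) for c in rec.channels],
        subject_meta=dict(rec.subject_meta),
        label=rec.label,
    )
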