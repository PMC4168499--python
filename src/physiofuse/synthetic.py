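"""Deterministic generator of five-channel recordings with a controllable
Relaxed/Stressed multiscale-complexity contrast.

The five channels of one synthetic subject share a single latent dynamic
(same-subject autonomic/respiratory coupling) plus a small independent
sensor noise per channel:

* Relaxed latent: band-limited 1/f-like noise — fractal variability whose
  complexity persists across coarse-graining scales.
* Stressed latent: a (1 - gap)/gap mixture of that noise with a regular
  dynamic — a paced-respiration oscillator (0.33 Hz) riding on a strongly
  autocorrelated smooth trend, plus low-amplitude white noise. The regular
  dynamic is far more predictable at every temporal scale, so multivariate
  multiscale entropy drops (the complexity-loss signature), most reliably
  at the coarsest scales.

``complexity_gap`` interpolates between the two regimes: at 0 the classes
are drawn from the same distribution (exchangeable); at 1 the stressed
latent is fully regular. Stress also shifts channel baselines (heart rate
up, finger temperature, CO2 and SpO2 down) in proportion to the gap, which
is what the traditional per-channel features pick up.

Every draw is fully determined by (seed, class, index): each recording owns
a spawned seed stream, so generating more recordings never changes earlier
ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cbr import CaseLibrary, Case
from .features import FeatureVector
from .fusion import build_data_level_library, build_decision_level_libraries
from .mmse import EmbeddingConfig
from .signal_model import ChannelSeries, MultichannelRecording

__all__ = [
    "ChannelParams",
    "SimulationSpec",
    "generate_recording",
    "generate_recordings",
    "generate_library",
    "reference_case_library",
]

RELAXED = "Relaxed"
STRESSED = "Stressed"


@dataclass(frozen=True)
class ChannelParams:
    """Cosmetic base rhythm of one channel: baseline mean, dynamic
    amplitude, per-second drift, and the baseline shift a fully stressed
    (gap = 1) subject shows."""

    mean: float
    amp: float
    drift: float = 0.0
    stress_shift: float = 0.0


#: Plausible resting baselines; not calibrated to any real cohort.
DEFAULT_CHANNEL_PARAMS = {
    "HR": ChannelParams(mean=70.0, amp=3.0, stress_shift=+10.0),     # bpm
    "FT": ChannelParams(mean=30.0, amp=0.3, drift=-5e-4, stress_shift=-1.5),  # degC
    "RR": ChannelParams(mean=0.0, amp=1.0),                          # airflow, a.u.
    "CO2": ChannelParams(mean=5.0, amp=0.3, stress_shift=-0.4),      # percent
    "SPO2": ChannelParams(mean=97.0, amp=0.5, stress_shift=-1.0),    # percent
}


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic cohort.

    Defaults mirror an 8 + 8 case collection of 2700-sample channels at
    4 Hz, long enough for entropy at scale 9 to rest on 300 coarse-grained
    points.
    """

    n_per_class: int = 8
    n_samples: int = 2700
    fs: float = 4.0
    seed: int = 0
    complexity_gap: float = 0.8
    channel_params: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_PARAMS))
    noise_band_hz: float = 0.5      # upper edge of the 1/f-like latent band
    spectral_exponent: float = 1.0  # 1/f^beta target for the relaxed latent
    paced_freq_hz: float = 0.33     # stressed paced-respiration oscillator
    trend_exponent: float = 2.2     # 1/f^beta of the smooth stressed trend
    regular_white: float = 0.03     # white-noise amplitude in the regular dynamic
    sensor_noise: float = 0.02      # independent per-channel measurement noise

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if not 0 <= self.complexity_gap <= 1:
            raise ValueError("complexity_gap must lie in [0, 1]")
        if self.n_samples < 1 or self.fs <= 0:
            raise ValueError("need n_samples >= 1 and fs > 0")


def _unit(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate zero-variance component")
    return (x - x.mean()) / sd


def _shaped_noise(rng: np.random.Generator, n: int, fs: float, beta: float, f_hi: float) -> np.ndarray:
    """Gaussian noise with a 1/f^beta spectrum inside (0, f_hi], synthesized
    by spectral shaping of seeded random phases."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    sel = (freqs > 0) & (freqs <= f_hi)
    amp[sel] = freqs[sel] ** (-beta / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, freqs.size)
    x = np.fft.irfft(amp * np.exp(1j * phases), n)
    return _unit(x)


def _latent(spec: SimulationSpec, klass: str, rng: np.random.Generator) -> np.ndarray:
    """Shared latent dynamic of one subject (unit variance)."""
    # mild subject-to-subject heterogeneity in spectral slope and pacing
    beta = float(np.clip(spec.spectral_exponent + 0.1 * rng.standard_normal(), 0.7, 1.3))
    fractal = _shaped_noise(rng, spec.n_samples, spec.fs, beta, spec.noise_band_hz)
    if klass == RELAXED or spec.complexity_gap == 0:
        return fractal
    t = np.arange(spec.n_samples) / spec.fs
    osc = np.sin(2.0 * np.pi * spec.paced_freq_hz * t + rng.uniform(0.0, 2.0 * np.pi))
    trend = _shaped_noise(rng, spec.n_samples, spec.fs, spec.trend_exponent, spec.noise_band_hz)
    regular = _unit(
        0.6 * trend
        + 0.6 * _unit(osc)
        + spec.regular_white * rng.standard_normal(spec.n_samples)
    )
    g = spec.complexity_gap
    return _unit((1.0 - g) * fractal + g * regular)


def generate_recording(spec: SimulationSpec, klass: str, index: int) -> MultichannelRecording:
    """One synthetic five-channel recording, fully determined by
    (spec.seed, klass, index)."""
    if klass not in (RELAXED, STRESSED):
        raise ValueError(f"class must be {RELAXED!r} or {STRESSED!r}, got {klass!r}")
    class_code = 0 if klass == RELAXED else 1
    ss = np.random.SeedSequence(entropy=(int(spec.seed), class_code, int(index)))
    children = ss.spawn(1 + len(spec.channel_params))
    u = _latent(spec, klass, np.random.default_rng(children[0]))
    t = np.arange(spec.n_samples) / spec.fs
    g = spec.complexity_gap
    channels = []
    for child, (name, cp) in zip(children[1:], spec.channel_params.items()):
        rng = np.random.default_rng(child)
        dynamics = _unit(u + spec.sensor_noise * rng.standard_normal(spec.n_samples))
        baseline = cp.mean + (g * cp.stress_shift if klass == STRESSED else 0.0)
        samples = baseline + cp.drift * t + cp.amp * dynamics
        channels.append(ChannelSeries(name=name, samples=samples, fs=spec.fs))
    meta = {"generator": "physiofuse.synthetic", "seed": spec.seed, "index": index,
            "complexity_gap": g}
    return MultichannelRecording(channels=channels, subject_meta=meta, label=klass)


def generate_recordings(spec: SimulationSpec) -> tuple[list[MultichannelRecording], list[str]]:
    """The full cohort: n_per_class recordings per class with stable ids."""
    recordings, case_ids = [], []
    for klass in (RELAXED, STRESSED):
        for i in range(spec.n_per_class):
            recordings.append(generate_recording(spec, klass, i))
            case_ids.append(f"{klass}-{i + 1}")
    return recordings, case_ids


def generate_library(
    spec: SimulationSpec,
    mode: str = "data",
    cfg: EmbeddingConfig | None = None,
    eps_max: int = 9,
):
    """Synthetic case library: ``mode='data'`` yields one library of entropy
    profiles; ``mode='decision'`` yields five aligned per-channel libraries
    sharing case_ids."""
    recordings, case_ids = generate_recordings(spec)
    if mode == "data":
        return build_data_level_library(recordings, cfg=cfg, eps_max=eps_max, case_ids=case_ids)
    if mode == "decision":
        return build_decision_level_libraries(recordings, case_ids=case_ids)
    raise ValueError(f"mode must be 'data' or 'decision', got {mode!r}")


#: Printed reference profiles of four stored cases (entropy features F1..F9
#: with expert class labels), used for worked retrieval examples.
_REFERENCE_CASES = [
    ("case4", RELAXED, [1.6929, 1.7180, 1.7163, 1.7482, 1.7438, 1.7416, 1.7577, 1.7583, 1.7641]),
    ("case14", STRESSED, [1.6420, 1.6712, 1.6964, 1.7172, 1.7366, 1.7491, 1.7648, 1.7779, 1.7907]),
    ("case13", STRESSED, [1.3867, 1.4066, 1.4203, 1.2950, 1.4338, 1.4421, 1.4472, 1.4452, 1.4474]),
    ("case15", STRESSED, [1.2992, 1.3087, 1.3161, 1.3229, 1.3233, 1.3299, 1.3284, 1.3274, 1.3296]),
]


def reference_case_library() -> CaseLibrary:
    """Four-profile worked-example library with known similarity ordering."""
    schema = tuple(f"F{i}" for i in range(1, 10))
    cases = [
        Case(case_id=cid, features=FeatureVector(schema, np.array(vals)), solution=klass)
        for cid, klass, vals in _REFERENCE_CASES
    ]
    return CaseLibrary(schema=schema, cases=cases)
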