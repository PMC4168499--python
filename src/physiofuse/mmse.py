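"""Multivariate multiscale entropy (MMSE) for data-level sensor fusion.

The p channels of a recording are z-scored once at full resolution, block
averaged (coarse-grained) at scales 1..eps_max, and multivariate sample
entropy (MSampEn) is computed at each scale from composite delay vectors,
yielding one entropy value per scale. The resulting profile is the joint
feature vector of the recording.

MSampEn follows the multivariate extension of sample entropy: composite
delay vectors concatenate per-channel delay embeddings (dimension m_k, lag
tau_k); matches are pairs of vectors within Chebyshev distance r; the
(m+1)-dimensional vector set is the union over channels of vectors with that
channel's dimension incremented; MSampEn = -ln(B^{m+1}/B^m).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .signal_model import MultichannelRecording

__all__ = [
    "EmbeddingConfig",
    "EntropyProfile",
    "UndefinedEntropyError",
    "coarse_grain",
    "composite_delay_vectors",
    "msampen",
    "mmse_profile",
]

#: Coarse-grained series shorter than this give unstable entropy estimates.
MIN_RELIABLE_LENGTH = 300

#: Default tolerance in units of the full-resolution channel SD. The common
#: univariate choice 0.15 starves the pair counts once the composite
#: dimension reaches sum(m_k) = 10 for five channels; 0.5 keeps B^m and
#: B^{m+1} well populated at every scale for smooth physiological signals.
DEFAULT_R = 0.5


class UndefinedEntropyError(ValueError):
    """Raised when a pair-count frequency is zero, carrying diagnostics."""

    def __init__(self, message: str, b_m: float, b_m1: float, n_vectors: int):
        super().__init__(message)
        self.b_m = b_m
        self.b_m1 = b_m1
        self.n_vectors = n_vectors


@dataclass(frozen=True)
class EmbeddingConfig:
    """Per-channel embedding dimensions/lags and the match tolerance r."""

    m: tuple[int, ...]
    tau: tuple[int, ...]
    r: float = DEFAULT_R

    def __post_init__(self) -> None:
        object.__setattr__(self, "m", tuple(int(v) for v in np.atleast_1d(self.m)))
        object.__setattr__(self, "tau", tuple(int(v) for v in np.atleast_1d(self.tau)))
        if len(self.m) != len(self.tau):
            raise ValueError("m and tau must have one entry per channel")
        if any(v < 1 for v in self.m) or any(v < 1 for v in self.tau):
            raise ValueError("embedding dimensions and lags must be >= 1")
        if not self.r > 0:
            raise ValueError("tolerance r must be > 0")

    @classmethod
    def uniform(cls, p: int, m: int = 2, tau: int = 1, r: float = DEFAULT_R) -> "EmbeddingConfig":
        """Same dimension and lag for every one of ``p`` channels."""
        return cls(m=(m,) * p, tau=(tau,) * p, r=r)

    @property
    def p(self) -> int:
        return len(self.m)

    @property
    def m_total(self) -> int:
        return int(sum(self.m))


@dataclass(frozen=True)
class EntropyProfile:
    """MSampEn per scale 1..eps_max; undefined scales hold NaN and are
    listed in ``undefined_scales`` (never silently dropped)."""

    scales: tuple[int, ...]
    values: np.ndarray
    n_effective: tuple[int, ...]
    undefined_scales: tuple[int, ...] = ()
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if len(self.scales) != self.values.size or len(self.scales) != len(self.n_effective):
            raise ValueError("scales, values and n_effective must align")

    def as_feature_dict(self, prefix: str = "F") -> dict:
        """Scale-indexed feature map, F1..F<eps_max> by default."""
        return {f"{prefix}{s}": float(v) for s, v in zip(self.scales, self.values)}


def coarse_grain(x: np.ndarray, eps: int) -> np.ndarray:
    """Non-overlapping block means at scale ``eps``; the tail remainder of
    fewer than ``eps`` samples is discarded (output length floor(N/eps))."""
    x = np.asarray(x, dtype=float)
    if eps < 1:
        raise ValueError("scale factor must be >= 1")
    n_out = x.size // eps
    if n_out < 1:
        raise ValueError(f"scale {eps} exceeds series length {x.size}")
    if eps == 1:
        return x.copy()
    return x[: n_out * eps].reshape(n_out, eps).mean(axis=1)


def _delay_matrix(X: np.ndarray, cfg: EmbeddingConfig, count: int, extend: int | None) -> np.ndarray:
    """Stack composite delay vectors row-wise for indices 0..count-1.

    ``extend`` increments channel ``extend``'s dimension by one (None for the
    base dimension).
    """
    cols = []
    for k in range(X.shape[0]):
        mk = cfg.m[k] + (1 if k == extend else 0)
        for j in range(mk):
            start = j * cfg.tau[k]
            cols.append(X[k, start : start + count])
    return np.column_stack(cols)


def composite_delay_vectors(
    X: np.ndarray, cfg: EmbeddingConfig, extended: bool = False
) -> np.ndarray:
    """Composite delay vectors of a (p, N) array.

    Base mode: one vector of length sum(m_k) per valid start index, the
    range being N - max_k((m_k - 1) tau_k). Extended mode: the union over
    channels h of vectors with channel h's dimension incremented, each over
    the common range N - max_k(m_k tau_k).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != cfg.p:
        raise ValueError(f"data has {X.shape[0]} channels but config expects {cfg.p}")
    N = X.shape[1]
    if not extended:
        span = max((mk - 1) * tk for mk, tk in zip(cfg.m, cfg.tau))
        count = N - span
        if count < 1:
            raise ValueError(f"series of length {N} too short for embedding span {span}")
        return _delay_matrix(X, cfg, count, extend=None)
    span = max(mk * tk for mk, tk in zip(cfg.m, cfg.tau))
    count = N - span
    if count < 1:
        raise ValueError(f"series of length {N} too short for extended span {span}")
    return np.vstack([_delay_matrix(X, cfg, count, extend=h) for h in range(cfg.p)])


def _pair_fraction(vectors: np.ndarray, r: float) -> float:
    """Fraction of unordered vector pairs (i < j) within Chebyshev distance r."""
    n = vectors.shape[0]
    if n < 2:
        raise ValueError("need at least 2 delay vectors")
    tree = cKDTree(vectors)
    pairs = (tree.count_neighbors(tree, r, p=np.inf) - n) // 2
    return pairs / (n * (n - 1) / 2)


def msampen(X: np.ndarray, cfg: EmbeddingConfig) -> float:
    """Multivariate sample entropy -ln(B^{m+1}/B^m) of a (p, N) array.

    Both frequencies are computed over the common start-index range
    N - max_k(m_k tau_k) so that base and extended vector sets describe the
    same stretch of signal. Zero frequency at either dimension raises
    :class:`UndefinedEntropyError` with the counts as diagnostics.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != cfg.p:
        raise ValueError(f"data has {X.shape[0]} channels but config expects {cfg.p}")
    N = X.shape[1]
    span = max(mk * tk for mk, tk in zip(cfg.m, cfg.tau))
    count = N - span
    if count < 2:
        raise ValueError(
            f"series of length {N} yields {max(count, 0)} delay vectors; need >= 2"
        )
    base = _delay_matrix(X, cfg, count, extend=None)
    ext = np.vstack([_delay_matrix(X, cfg, count, extend=h) for h in range(cfg.p)])
    b_m = _pair_fraction(base, cfg.r)
    b_m1 = _pair_fraction(ext, cfg.r)
    if b_m == 0.0 or b_m1 == 0.0:
        raise UndefinedEntropyError(
            f"undefined entropy: B^m={b_m:.3g}, B^(m+1)={b_m1:.3g} over "
            f"{count} base vectors (r={cfg.r})",
            b_m=b_m,
            b_m1=b_m1,
            n_vectors=count,
        )
    return float(-math.log(b_m1 / b_m))


def mmse_profile(
    rec: MultichannelRecording | np.ndarray,
    cfg: EmbeddingConfig | None = None,
    eps_max: int = 9,
) -> EntropyProfile:
    """Entropy-vs-scale profile of a recording.

    Channels are z-scored once over the full-resolution record (so r keeps
    one meaning across scales and the profile is invariant to channel-wise
    affine rescaling), then coarse-grained and fed to :func:`msampen` at
    scales 1..eps_max. Scales whose entropy is undefined are recorded as NaN
    in the profile and listed in ``undefined_scales``.
    """
    if isinstance(rec, MultichannelRecording):
        X = rec.to_array()
    else:
        X = np.atleast_2d(np.asarray(rec, dtype=float))
    p, N = X.shape
    if cfg is None:
        cfg = EmbeddingConfig.uniform(p)
    if cfg.p != p:
        raise ValueError(f"config expects {cfg.p} channels, data has {p}")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        zero = [int(i) for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"cannot normalize zero-variance channel(s) {zero}")
    Z = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]

    if N // eps_max < MIN_RELIABLE_LENGTH:
        warnings.warn(
            f"coarse-grained length {N // eps_max} at scale {eps_max} is below "
            f"{MIN_RELIABLE_LENGTH}; entropy estimates may be unstable",
            stacklevel=2,
        )

    values, n_eff, undefined = [], [], []
    for eps in range(1, eps_max + 1):
        Xc = np.vstack([coarse_grain(z, eps) for z in Z])
        n_eff.append(Xc.shape[1])
        try:
            values.append(msampen(Xc, cfg))
        except UndefinedEntropyError:
            values.append(math.nan)
            undefined.append(eps)
    return EntropyProfile(
        scales=tuple(range(1, eps_max + 1)),
        values=np.array(values),
        n_effective=tuple(n_eff),
        undefined_scales=tuple(undefined),
        params={"m": cfg.m, "tau": cfg.tau, "r": cfg.r, "eps_max": eps_max},
    )
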