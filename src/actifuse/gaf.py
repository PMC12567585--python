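"""Gramian Angular Field encoding of wrist-accelerometer signals.

The pipeline turns a triaxial recording into model-ready image sequences:

1. ENMO — Euclidean norm of the (x, y, z) acceleration vector minus 1 g,
   removing the static gravity component from activity intensity.
2. Piecewise aggregate approximation (PAA) down to the image side length.
3. Min-max normalisation of each window to [-1, 1].
4. Polar encoding: angle theta = arccos(v), radius = normalised time index.
5. Gramian matrix G[i, j] = cos(theta_i + theta_j), then affinely rescaled to
   [0, 1] so images are comparable across windows.

Windows are half-open ``[start, end)`` in 0-based sample indices; consecutive
non-overlapping windows are grouped into fixed-length image sequences (default
five frames) for the downstream sequence encoder.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TriaxialSeries", "EnmoSeries", "NormalisedSeries", "PolarSeries",
    "GafImage", "ImageSequence", "WindowingConfig",
    "compute_enmo", "minmax_normalise", "polar_encode", "gaf_matrix",
    "rescale_unit", "paa_downsample", "window_to_sequence",
]

_CLAMP_TOL = 1e-9


@dataclass
class TriaxialSeries:
    """Timestamped triaxial acceleration in g at a fixed sampling rate."""

    timestamps: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    rate_hz: float = 100.0

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.z = np.asarray(self.z, dtype=np.float64)
        n = len(self.x)
        if not (len(self.y) == len(self.z) == len(self.timestamps) == n):
            raise ValueError("timestamps, x, y, z must have identical length")
        if n < 2:
            raise ValueError(f"series needs at least 2 samples, got {n}")
        if self.rate_hz <= 0:
            raise ValueError(f"rate_hz must be positive, got {self.rate_hz}")
        for name in ("timestamps", "x", "y", "z"):
            arr = getattr(self, name)
            bad = np.flatnonzero(~np.isfinite(arr))
            if bad.size:
                raise ValueError(f"non-finite value in {name} at sample index {bad[0]}")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self):
        return len(self.x)


@dataclass
class EnmoSeries:
    """Acceleration magnitude minus 1 g, per sample (dimensionless, in g)."""

    values: np.ndarray
    rate_hz: float = 100.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)

    def __len__(self):
        return len(self.values)


@dataclass
class NormalisedSeries:
    values: np.ndarray
    source_min: float
    source_max: float


@dataclass
class PolarSeries:
    theta: np.ndarray
    radius: np.ndarray


@dataclass
class GafImage:
    """T x T unit-interval Gramian image plus its source window (half-open)."""

    matrix: np.ndarray
    window_start: int
    window_end: int


@dataclass
class ImageSequence:
    """Fixed-length sequence of 3-channel GAF frames for one subject.

    ``frames`` has shape (n_frames, 3, size, size); frames cover consecutive
    non-overlapping windows of the source signal.
    """

    frames: np.ndarray
    subject_id: str
    windows: list = field(default_factory=list)  # (start, end) sample indices


@dataclass
class WindowingConfig:
    """How raw signal maps to image sequences; all knobs the encoder exposes."""

    window_seconds: float = 10.0
    image_size: int = 224
    frames_per_sequence: int = 5
    channel_mode: str = "replicate"  # or "per_axis"
    clip_negative_enmo: bool = False

    def __post_init__(self):
        if self.window_seconds <= 0:
            raise ValueError("window_seconds must be positive")
        if self.image_size < 2:
            raise ValueError("image_size must be at least 2")
        if self.frames_per_sequence < 1:
            raise ValueError("frames_per_sequence must be at least 1")
        if self.channel_mode not in ("replicate", "per_axis"):
            raise ValueError(f"unknown channel_mode {self.channel_mode!r}")


def compute_enmo(series: TriaxialSeries, clip_negative: bool = False) -> EnmoSeries:
    """Euclidean Norm Minus One: sqrt(x^2 + y^2 + z^2) - 1 per sample.

    With ``clip_negative`` the (physically rare) negative values — norm below
    1 g — are truncated at zero, as common accelerometry pipelines do.
    """
    values = np.sqrt(series.x ** 2 + series.y ** 2 + series.z ** 2) - 1.0
    if clip_negative:
        values = np.maximum(values, 0.0)
    return EnmoSeries(values=values, rate_hz=series.rate_hz)


def minmax_normalise(values) -> NormalisedSeries:
    """Affinely map a sequence onto [-1, 1]; both endpoints are attained."""
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("need a 1-D sequence of length >= 2")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        raise ValueError(f"degenerate constant sequence (min = max = {lo}); cannot normalise")
    out = (values - lo) / (hi - lo) * 2.0 - 1.0
    return NormalisedSeries(values=out, source_min=lo, source_max=hi)


def polar_encode(norm: NormalisedSeries, tol: float = _CLAMP_TOL) -> PolarSeries:
    """Map normalised values to polar angles theta = arccos(v) and radii t/T."""
    v = np.asarray(norm.values, dtype=np.float64)
    over = np.max(np.abs(v)) - 1.0
    if over > tol:
        raise ValueError(f"normalised value outside [-1, 1] by {over:.3g}")
    v = np.clip(v, -1.0, 1.0)
    T = len(v)
    theta = np.arccos(v)
    radius = np.arange(1, T + 1, dtype=np.float64) / T
    return PolarSeries(theta=theta, radius=radius)


def gaf_matrix(polar: PolarSeries) -> np.ndarray:
    """Gramian angular field G[i, j] = cos(theta_i + theta_j), in [-1, 1]."""
    theta = np.asarray(polar.theta, dtype=np.float64)
    if theta.size == 0:
        raise ValueError("empty polar series")
    return np.cos(theta[:, None] + theta[None, :])


def rescale_unit(G: np.ndarray, window: tuple = (0, 0), tol: float = _CLAMP_TOL) -> GafImage:
    """Affine [−1, 1] → [0, 1] rescale (G + 1) / 2, preserving symmetry.

    Data-independent by design: equal Gramian values map to equal pixel values
    in every image, keeping images comparable across windows and subjects.
    """
    G = np.asarray(G, dtype=np.float64)
    over = float(np.max(np.abs(G))) - 1.0 if G.size else 0.0
    if over > tol:
        raise ValueError(f"matrix entry outside [-1, 1] by {over:.3g}")
    img = (np.clip(G, -1.0, 1.0) + 1.0) / 2.0
    return GafImage(matrix=img, window_start=int(window[0]), window_end=int(window[1]))


def paa_downsample(values, target_len: int) -> np.ndarray:
    """Piecewise aggregate approximation over equal-measure bins.

    Each output value is the mean of the input over one of ``target_len``
    equal-width bins in continuous sample index; samples straddling a bin
    boundary contribute fractionally, so the overall mean is preserved.
    """
    values = np.asarray(values, dtype=np.float64)
    n = len(values)
    if target_len < 1:
        raise ValueError("target_len must be at least 1")
    if target_len > n:
        raise ValueError(f"cannot upsample: target_len {target_len} > length {n}")
    if target_len == n:
        return values.copy()
    # weight of sample j in bin k = overlap of [j, j+1) with [k*n/m, (k+1)*n/m)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    edges = np.arange(target_len + 1) * (n / target_len)
    lo_idx = np.floor(edges[:-1]).astype(int)
    hi_idx = np.minimum(np.ceil(edges[1:]).astype(int), n)
    out = np.empty(target_len)
    for k in range(target_len):
        a, b = edges[k], edges[k + 1]
        i, j = lo_idx[k], hi_idx[k]
        total = csum[j] - csum[i]
        total -= (a - i) * values[i]            # partial sample at the left edge
        if j > b:
            total -= (j - b) * values[j - 1]    # partial sample at the right edge
        out[k] = total / (b - a)
    return out


def _encode_window(window_values: np.ndarray, cfg: WindowingConfig,
                   start: int, end: int) -> GafImage:
    v = paa_downsample(window_values, cfg.image_size)
    norm = minmax_normalise(v)
    G = gaf_matrix(polar_encode(norm))
    return rescale_unit(G, window=(start, end))


def window_to_sequence(enmo: EnmoSeries, cfg: WindowingConfig,
                       subject_id: str = "", axes: tuple = None) -> list:
    """Cut a signal into GAF frames and group them into image sequences.

    Returns a list of :class:`ImageSequence`; trailing windows that do not
    fill a complete sequence are dropped (floor rule). In ``per_axis`` channel
    mode, ``axes`` must supply the (x, y, z) arrays and each channel is the GAF
    of one axis; the default replicates the ENMO-GAF across 3 channels.
    """
    window_len = int(round(cfg.window_seconds * enmo.rate_hz))
    if window_len < 2:
        raise ValueError("window shorter than 2 samples")
    if cfg.image_size > window_len:
        raise ValueError(f"image_size {cfg.image_size} exceeds window length {window_len}")
    n = len(enmo)
    n_windows = n // window_len
    n_sequences = n_windows // cfg.frames_per_sequence
    if n_sequences == 0:
        logger.warning("series of %d samples too short for one sequence "
                       "(%d windows of %d samples needed); returning no sequences",
                       n, cfg.frames_per_sequence, window_len)
        return []
    if cfg.channel_mode == "per_axis":
        if axes is None:
            raise ValueError("per_axis channel mode needs the axes=(x, y, z) arrays")
        channels = [np.asarray(a, dtype=np.float64) for a in axes]
        if any(len(c) != n for c in channels):
            raise ValueError("axis arrays must match the ENMO length")
    sequences = []
    for s in range(n_sequences):
        frames = np.empty((cfg.frames_per_sequence, 3, cfg.image_size, cfg.image_size))
        windows = []
        for f in range(cfg.frames_per_sequence):
            w = s * cfg.frames_per_sequence + f
            start, end = w * window_len, (w + 1) * window_len
            if cfg.channel_mode == "replicate":
                img = _encode_window(enmo.values[start:end], cfg, start, end)
                frames[f] = img.matrix[None, :, :]
                windows.append((start, end))
            else:
                for c, axis_values in enumerate(channels):
                    img = _encode_window(axis_values[start:end], cfg, start, end)
                    frames[f, c] = img.matrix
                windows.append((start, end))
        sequences.append(ImageSequence(frames=frames, subject_id=subject_id, windows=windows))
    return sequences
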