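"""Movie containers and preprocessing: z-flattening, bleach correction, stage splitting.

Live-imaging movies of syncytial embryos arrive as multi-channel z-stack time
series (green = nascent-transcription dots, red = nuclear envelopes).  The
quantitative pipeline operates on 2D movies obtained by maximum-intensity
projection, rescaled for photobleaching, and cut into nuclear-cycle stages
(nc12/nc13/nc14) given user-supplied frame ranges.

All quantitative processing is carried out in floating point; conversion to
8-bit happens only at the detection boundary (see :func:`to_uint8`), because
the detection threshold is defined on the 8-bit intensity scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger("burstquant")

#: channel index layout used throughout: index 0 = green (dots), 1 = red (nuclei)
CHANNEL_INDEX = {"green": 0, "red": 1}
DEFAULT_CHANNEL_ROLES = {"green": "dots", "red": "nuclei"}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class MovieStack:
    """Raw T x Z x Y x X x C intensity array with acquisition metadata."""

    pixels: np.ndarray
    pixel_size_um: float = 0.1
    frame_interval_s: float = 1.77
    bit_depth: int = 8
    channel_roles: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_ROLES))

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 5:
            raise ValueError(
                f"MovieStack pixels must be T x Z x Y x X x C, got shape {self.pixels.shape}"
            )
        t, z, y, x, c = self.pixels.shape
        if min(t, y, x) < 1 or z < 1 or c < 1:
            raise ValueError("empty movie stack")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        if "green" not in self.channel_roles:
            raise ValueError("channel_roles must cover the green (dot) channel")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    def channel(self, name: str) -> int:
        return CHANNEL_INDEX[name]


@dataclass
class Movie2D:
    """Flattened T x Y x X x C movie plus provenance of how it was produced."""

    pixels: np.ndarray
    pixel_size_um: float = 0.1
    frame_interval_s: float = 1.77
    bit_depth: int = 8
    channel_roles: dict = field(default_factory=lambda: dict(DEFAULT_CHANNEL_ROLES))
    provenance: tuple = ()
    bleach_factors: np.ndarray | None = None
    stage_label: str | None = None
    frame_offset: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError(
                f"Movie2D pixels must be T x Y x X x C, got shape {self.pixels.shape}"
            )
        if self.bleach_factors is not None:
            self.bleach_factors = np.asarray(self.bleach_factors, dtype=float)
            if len(self.bleach_factors) != self.pixels.shape[0]:
                raise ValueError("bleach_factors length must equal frame count")
            if not np.all(self.bleach_factors > 0):
                raise ValueError("bleach_factors must be positive")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    def channel(self, name: str) -> int:
        return CHANNEL_INDEX[name]


@dataclass
class StagePartition:
    """Ordered nuclear-cycle labels mapped to half-open frame intervals.

    Intervals are 0-based ``[start, end)``, must be ascending and
    non-overlapping.  Stage identity is assigned by the experimenter
    (counting cycles backward from nc14); no automatic mitosis detection
    is attempted.
    """

    entries: list  # of (label, start, end)

    def __post_init__(self) -> None:
        cleaned = []
        prev_end = None
        for label, start, end in self.entries:
            start, end = int(start), int(end)
            if start < 0 or end <= start:
                raise ValueError(f"invalid interval for stage {label!r}: [{start}, {end})")
            if prev_end is not None and start < prev_end:
                raise ValueError(f"stage intervals overlap or are out of order at {label!r}")
            prev_end = end
            cleaned.append((str(label), start, end))
        if not cleaned:
            raise ValueError("stage partition must contain at least one entry")
        self.entries = cleaned

    @property
    def labels(self) -> list:
        return [label for label, _, _ in self.entries]

    def validate_for(self, n_frames: int) -> None:
        if self.entries[-1][2] > n_frames:
            raise ValueError(
                f"stage partition extends to frame {self.entries[-1][2]} "
                f"but movie has only {n_frames} frames"
            )

    def covered_frames(self) -> np.ndarray:
        return np.concatenate([np.arange(s, e) for _, s, e in self.entries])


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def max_project(stack: MovieStack) -> Movie2D:
    """Flatten a z-stack movie by per-pixel maximum-intensity projection."""
    flat = stack.pixels.max(axis=1)
    return Movie2D(
        pixels=flat,
        pixel_size_um=stack.pixel_size_um,
        frame_interval_s=stack.frame_interval_s,
        bit_depth=stack.bit_depth,
        channel_roles=dict(stack.channel_roles),
        provenance=("max_projection",),
    )


def _exp_decay(t, a, b, c):
    return a * np.exp(-b * t) + c


def bleach_correct(movie: Movie2D, channel: str = "green",
                   method: str = "simple_ratio") -> Movie2D:
    """Rescale one channel of a 2D movie to undo photobleaching decay.

    ``simple_ratio`` scales each frame so its mean matches the frame-0 mean
    (the lightest CorrectBleach-style mode, robust on short stage movies).
    ``exponential_fit`` fits ``mean_t = a * exp(-b t) + c`` to the per-frame
    means and divides by the fitted decay normalized to t = 0; if the fit
    fails to converge it falls back to ``simple_ratio`` with a warning.

    The applied per-frame scale factors are recorded in ``bleach_factors``.
    """
    if method not in ("simple_ratio", "exponential_fit"):
        raise ValueError(f"unknown bleach-correction method {method!r}")
    ci = movie.channel(channel)
    data = movie.pixels.astype(np.float64, copy=True)
    means = data[..., ci].mean(axis=(1, 2))
    if means[0] <= 0:
        raise ValueError("reference frame (frame 0) has non-positive mean; cannot normalize")

    if method == "exponential_fit":
        t = np.arange(len(means), dtype=float)
        try:
            span = max(means[0] - means[-1], 1e-12)
            p0 = (span, 1.0 / max(len(means), 2), float(means[-1]))
            popt, _ = curve_fit(_exp_decay, t, means, p0=p0, maxfev=5000)
            a, b, c = popt
            fitted = _exp_decay(t, a, b, c)
            if np.any(fitted <= 0):
                raise RuntimeError("fitted decay non-positive")
            factors = fitted[0] / fitted
        except (RuntimeError, ValueError) as exc:
            warnings.warn(
                f"exponential bleach fit failed ({exc}); falling back to simple_ratio",
                RuntimeWarning,
                stacklevel=2,
            )
            logger.warning("exponential bleach fit failed; using simple_ratio")
            method = "simple_ratio"
    if method == "simple_ratio":
        safe = np.where(means > 0, means, 1.0)
        factors = means[0] / safe

    data[..., ci] *= factors[:, None, None]
    return replace(
        movie,
        pixels=data,
        provenance=movie.provenance + (f"bleach_corrected:{method}:{channel}",),
        bleach_factors=factors,
    )


def split_stages(movie: Movie2D, partition: StagePartition) -> list:
    """Cut a movie into per-stage sub-movies following a stage partition.

    Returns a list of ``Movie2D`` (one per stage, in order), each carrying its
    ``stage_label`` and the ``frame_offset`` of its first frame in the parent
    movie.  Frames covered by no interval are excluded and reported via an
    INFO log; concatenating the outputs plus those frames reconstructs the
    input exactly.
    """
    partition.validate_for(movie.n_frames)
    stages = []
    for label, start, end in partition.entries:
        stages.append(
            replace(
                movie,
                pixels=movie.pixels[start:end],
                bleach_factors=(None if movie.bleach_factors is None
                                else movie.bleach_factors[start:end]),
                stage_label=label,
                frame_offset=start,
                provenance=movie.provenance + (f"stage:{label}",),
            )
        )
    covered = set(partition.covered_frames().tolist())
    dropped = sorted(set(range(movie.n_frames)) - covered)
    if dropped:
        logger.info("split_stages: %d frames not assigned to any stage: %s",
                    len(dropped), _summarize_frames(dropped))
    return stages


def _summarize_frames(frames: list) -> str:
    if len(frames) <= 8:
        return str(frames)
    return f"[{frames[0]}..{frames[-1]}] ({len(frames)} frames)"


def to_uint8(image: np.ndarray, bit_depth: int = 8) -> np.ndarray:
    """Convert a float or integer image to the 8-bit scale used for detection.

    16-bit data is linearly rescaled by 257 (= 65535/255); float data already
    on the 8-bit scale is clipped and rounded.
    """
    img = np.asarray(image, dtype=np.float64)
    if bit_depth == 16:
        img = img / 257.0
    elif bit_depth != 8:
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)
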