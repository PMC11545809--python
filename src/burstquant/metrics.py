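"""Burst statistics at tissue (frame/stage) and nucleus (track) level.

Frame metrics count and size the detected dots per frame; stage metrics
summarize the activation dynamics of a nuclear cycle (time of first dot,
first peak in active-nucleus count, saturation time, initiation-window
totals); track features describe single-nucleus bursting (ON runs, OFF gaps,
transition counts, brightness/size summaries).

A burst is a maximal ON run of a track, i.e. a maximal interval of
consecutive frames with the dot detected.  ``estimate_switching_rates``
additionally recovers the telegraph rates from frame-sampled presence
sequences by inverting the exact two-state sampled-chain transition
probabilities, which is consistent under discretization (naive averaging of
frame run lengths overestimates durations because sub-frame runs and gaps
are invisible at the acquisition cadence).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class FrameMetrics:
    frame: int
    n_dots: int
    mean_size_px: float        # NaN when no dots
    total_size_px: int
    mean_brightness: float     # NaN when no dots
    mean_norm_brightness: float


@dataclass
class StageMetrics:
    stage_label: str | None
    t_first_dot_s: float       # NaN when the stage has no dots
    t_first_peak_s: float
    t_all_dots_s: float
    max_n_dots: int
    avg_transcription_rate: float   # stage-mean of per-frame mean dot size (px)
    init_total_pixels: int
    init_active_nuclei: int
    intensity_peak_sd: float   # SD across tracks of per-track peak brightness


@dataclass
class TrackFeatures:
    track_id: int
    start_time_s: float
    n_frames_present: int
    avg_size_px: float
    avg_brightness: float
    max_brightness: float
    n_bursts: int
    on_run_durations_s: list
    off_gap_durations_s: list
    n_transitions: int


def frame_metrics(dots_by_frame: list) -> list:
    """Per-frame aggregates over detected dots.

    Empty frames yield ``n_dots = 0``, ``total_size_px = 0`` and NaN means.
    """
    out = []
    for t, dots in enumerate(dots_by_frame):
        if dots:
            areas = np.array([d.area_px for d in dots])
            bright = np.array([d.mean_brightness for d in dots])
            norm = np.array([np.nan if d.norm_brightness is None else d.norm_brightness
                             for d in dots])
            out.append(FrameMetrics(
                frame=t, n_dots=len(dots),
                mean_size_px=float(areas.mean()),
                total_size_px=int(areas.sum()),
                mean_brightness=float(bright.mean()),
                mean_norm_brightness=float(np.nanmean(norm)) if np.any(~np.isnan(norm))
                else float("nan"),
            ))
        else:
            out.append(FrameMetrics(frame=t, n_dots=0, mean_size_px=float("nan"),
                                    total_size_px=0, mean_brightness=float("nan"),
                                    mean_norm_brightness=float("nan")))
    return out


def frame_metrics_table(fm: list) -> pd.DataFrame:
    return pd.DataFrame([vars(f) for f in fm])


def _smooth(x: np.ndarray, w: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    if w <= 1:
        return x.astype(float)
    half = w // 2
    out = np.empty(len(x), dtype=float)
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def stage_metrics(frames: list, tracks: list, frame_interval_s: float,
                  init_window_frac: float = 0.25, smooth_w: int = 3,
                  stage_label: str | None = None) -> StageMetrics:
    """Stage-level activation and bursting summary.

    Times are seconds from the stage start.  The first peak is the first local
    maximum of the dot count after moving-average smoothing (window
    ``smooth_w``); the "initiation window" covers the first
    ``ceil(init_window_frac * stage length)`` frames starting at first
    detection.  ``init_active_nuclei`` counts the distinct tracks active in
    that window; ``intensity_peak_sd`` is the SD across tracks of each
    track's maximum mean brightness.
    """
    if not frames:
        raise ValueError("stage has no frames")
    n_dots = np.array([f.n_dots for f in frames])
    total_px = np.array([f.total_size_px for f in frames])
    mean_size = np.array([f.mean_size_px for f in frames])
    dt = frame_interval_s
    max_n = int(n_dots.max())

    if max_n == 0:
        return StageMetrics(stage_label, float("nan"), float("nan"), float("nan"),
                            0, float("nan"), 0, 0, float("nan"))

    f_first = int(np.argmax(n_dots > 0))
    smoothed = _smooth(n_dots.astype(float), smooth_w)
    f_peak = _first_local_max_from(smoothed, start=f_first)
    f_all = int(np.argmax(n_dots == max_n))

    window_len = int(math.ceil(init_window_frac * len(frames)))
    w0, w1 = f_first, min(len(frames), f_first + window_len)
    init_px = int(total_px[w0:w1].sum())
    init_active = sum(1 for t in tracks
                      if np.any((t.frames >= w0) & (t.frames < w1)))

    peaks = np.array([max(o.mean_brightness for o in t.observations)
                      for t in tracks]) if tracks else np.array([])
    peak_sd = float(np.std(peaks, ddof=1)) if len(peaks) > 1 else float("nan")

    with np.errstate(invalid="ignore"):
        avg_rate = float(np.nanmean(mean_size))

    return StageMetrics(
        stage_label=stage_label,
        t_first_dot_s=f_first * dt,
        t_first_peak_s=f_peak * dt,
        t_all_dots_s=f_all * dt,
        max_n_dots=max_n,
        avg_transcription_rate=avg_rate,
        init_total_pixels=init_px,
        init_active_nuclei=init_active,
        intensity_peak_sd=peak_sd,
    )


def _first_local_max_from(x: np.ndarray, start: int = 0) -> int:
    n = len(x)
    for i in range(start, n):
        left_ok = i == start or x[i] >= x[i - 1]
        right_ok = i == n - 1 or x[i] >= x[i + 1]
        if left_ok and right_ok:
            # skip flat leading zeros: require a positive value to call a peak
            if x[i] > 0:
                return i
    return n - 1


def track_features(track, frame_interval_s: float) -> TrackFeatures:
    """Single-nucleus burst features from one track's run structure."""
    runs = track.on_runs
    gaps = track.off_gaps
    dt = frame_interval_s
    areas = np.array([o.area_px for o in track.observations])
    bright = np.array([o.mean_brightness for o in track.observations])
    return TrackFeatures(
        track_id=track.track_id,
        start_time_s=track.first_frame * dt,
        n_frames_present=len(track.observations),
        avg_size_px=float(areas.mean()),
        avg_brightness=float(bright.mean()),
        max_brightness=float(bright.max()),
        n_bursts=len(runs),
        on_run_durations_s=[(b - a + 1) * dt for a, b in runs],
        off_gap_durations_s=[(b - a + 1) * dt for a, b in gaps],
        n_transitions=2 * (len(runs) - 1),
    )


def track_features_table(tracks: list, frame_interval_s: float) -> pd.DataFrame:
    """Scalar per-track feature table (run/gap lists summarized by their means)."""
    rows = []
    for t in tracks:
        f = track_features(t, frame_interval_s)
        rows.append({
            "track_id": f.track_id,
            "start_time_s": f.start_time_s,
            "n_frames_present": f.n_frames_present,
            "avg_size_px": f.avg_size_px,
            "avg_brightness": f.avg_brightness,
            "max_brightness": f.max_brightness,
            "n_bursts": f.n_bursts,
            "mean_on_run_s": float(np.mean(f.on_run_durations_s)),
            "mean_off_gap_s": (float(np.mean(f.off_gap_durations_s))
                               if f.off_gap_durations_s else float("nan")),
            "n_transitions": f.n_transitions,
        })
    return pd.DataFrame(rows, columns=["track_id", "start_time_s", "n_frames_present",
                                       "avg_size_px", "avg_brightness", "max_brightness",
                                       "n_bursts", "mean_on_run_s", "mean_off_gap_s",
                                       "n_transitions"])


def dispersion_stats(values) -> tuple:
    """Sample SD (n-1 denominator), SEM = SD/sqrt(n), and n.

    A single value yields NaN SD/SEM (flagged by the caller as undefined
    rather than zero); empty input is an error.
    """
    v = np.asarray(list(values), dtype=float)
    n = len(v)
    if n == 0:
        raise ValueError("dispersion_stats requires at least one value")
    if n == 1:
        return float("nan"), float("nan"), 1
    sd = float(np.std(v, ddof=1))
    return sd, sd / math.sqrt(n), n


def estimate_switching_rates(presence, frame_interval_s: float) -> dict:
    """Recover telegraph rates from frame-sampled ON/OFF sequences.

    ``presence`` is a sequence of boolean arrays (one per nucleus/track).
    Transitions between consecutive frames are pooled and the exact sampled
    two-state chain is inverted::

        p01 + p10 = 1 - exp(-(k_on + k_off) dt)
        k_on / (k_on + k_off) = p01 / (p01 + p10)

    giving consistent estimates of ``k_on``, ``k_off`` and the mean ON/OFF
    durations ``1/k_off``, ``1/k_on``.  Standard errors are propagated from
    the binomial errors of the transition fractions by the delta method
    (numerical gradient).

    Returns a dict with keys ``k_on``, ``k_off``, ``mean_on_s``,
    ``mean_off_s``, ``mean_on_se``, ``mean_off_se``, ``n_transitions``.
    """
    n01 = n00 = n10 = n11 = 0
    for seq in presence:
        s = np.asarray(seq, dtype=bool)
        a, b = s[:-1], s[1:]
        n01 += int(np.sum(~a & b))
        n00 += int(np.sum(~a & ~b))
        n10 += int(np.sum(a & ~b))
        n11 += int(np.sum(a & b))
    n0, n1 = n01 + n00, n10 + n11
    if n0 == 0 or n1 == 0:
        raise ValueError("need both ON and OFF dwell frames to estimate rates")
    p01, p10 = n01 / n0, n10 / n1

    def invert(p01_, p10_):
        s = p01_ + p10_
        if not 0 < s < 1:
            return float("nan"), float("nan")
        r = -math.log1p(-s) / frame_interval_s
        return r * p01_ / s, r * p10_ / s

    k_on, k_off = invert(p01, p10)
    se01 = math.sqrt(p01 * (1 - p01) / n0)
    se10 = math.sqrt(p10 * (1 - p10) / n1)

    def se_of(fn):
        h1, h2 = max(se01, 1e-9) * 1e-3, max(se10, 1e-9) * 1e-3
        g1 = (fn(p01 + h1, p10) - fn(p01 - h1, p10)) / (2 * h1)
        g2 = (fn(p01, p10 + h2) - fn(p01, p10 - h2)) / (2 * h2)
        return math.sqrt((g1 * se01) ** 2 + (g2 * se10) ** 2)

    mean_on_se = se_of(lambda a, b: 1.0 / invert(a, b)[1])
    mean_off_se = se_of(lambda a, b: 1.0 / invert(a, b)[0])
    return {
        "k_on": k_on, "k_off": k_off,
        "mean_on_s": 1.0 / k_off, "mean_off_s": 1.0 / k_on,
        "mean_on_se": mean_on_se, "mean_off_se": mean_off_se,
        "n_transitions": n01 + n10,
    }
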