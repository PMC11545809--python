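"""Synthetic two-channel movie generator with telegraph-model transcription dots.

The generator emulates live imaging of a syncytial embryo in which each
nucleus carries at most one nascent-transcription focus (an MS2/MCP-GFP dot).
Promoter activity follows the two-state telegraph model: each nucleus
switches ON at rate ``k_on`` and OFF at rate ``k_off`` (a continuous-time
Markov chain, sampled exactly via exponential holding times).  While ON,
transcripts initiate as a Poisson process at ``loading_rate``; each nascent
transcript contributes fluorescence for a fixed dwell time, so the dot
intensity at a frame is proportional to the number of initiation events in
the trailing dwell window.

The rendered movie has a green channel (Gaussian-PSF dots over background,
optional z-defocus, Gaussian read noise, exponential photobleaching) and a
red channel (nuclear disks).  Mitosis at stage boundaries resets every
promoter to OFF and re-jitters nucleus positions; no lineage is tracked,
because the analysis pipeline restarts tracking per stage anyway.

Full ground truth (per-frame state, transcript count, and true centroid per
nucleus, plus the applied bleach factor per frame) is retained so the
detection/tracking/metrics stages can be validated without any microscopy
data.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .preprocess import DEFAULT_CHANNEL_ROLES, MovieStack, StagePartition


@dataclass
class SimConfig:
    """Parameters of the synthetic movie generator.

    Geometry is a scaled-down field (256 px, 4x4 nuclei by default) that
    preserves the inter-nucleus-spacing-to-link-distance ratio of the late
    nuclear cycles; kinetic defaults (k_on = 0.02/s, k_off = 0.05/s) give
    ~20 s bursts separated by ~50 s silent gaps at the 1.77 s frame cadence
    of super-resolution acquisition.
    """

    n_nuclei_side: int = 4
    field_size_px: int = 256
    n_z_planes: int = 3
    z_step_um: float = 0.5
    frame_interval_s: float = 1.77
    n_frames_per_stage: int = 100
    stage_labels: tuple = ("nc12", "nc13", "nc14")
    k_on: float = 0.02
    k_off: float = 0.05
    p_init_on: float = 0.0           # probability a nucleus starts ON at a stage start
    loading_rate: float = 0.2        # transcripts/s while ON
    transcript_dwell_s: float = 50.0
    psf_sigma_px: float = 1.5
    z_defocus_per_plane: float = 0.8  # extra PSF sigma fraction per plane off focus
    amp_per_transcript: float = 12.0
    background_level: float = 20.0
    noise_sd: float = 3.0
    poisson_noise: bool = False
    bleach_halflife_s: float = 1800.0
    dot_diffusion_px: float = 1.0
    nucleus_radius_px: float = 9.0
    nucleus_intensity: float = 120.0
    pixel_size_um: float = 0.19
    bit_depth: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "loading_rate", "transcript_dwell_s",
                     "noise_sd", "dot_diffusion_px"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.field_size_px <= 0:
            raise ValueError("field_size_px must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if not self.stage_labels:
            raise ValueError("stage_labels must be nonempty")
        if self.bleach_halflife_s <= 0:
            raise ValueError("bleach_halflife_s must be positive (use inf to disable)")
        if not 0 <= self.p_init_on <= 1:
            raise ValueError("p_init_on must be in [0, 1]")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def n_stages(self) -> int:
        return len(self.stage_labels)

    @property
    def n_frames_total(self) -> int:
        return self.n_frames_per_stage * self.n_stages

    def stage_partition(self) -> StagePartition:
        n = self.n_frames_per_stage
        return StagePartition(
            [(lab, i * n, (i + 1) * n) for i, lab in enumerate(self.stage_labels)]
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stage_labels"] = list(d["stage_labels"])
        return d


@dataclass
class GroundTruth:
    """Simulator ground truth: per-nucleus trajectories and per-frame bleach.

    ``states``, ``transcripts`` are (n_nuclei, T) arrays; ``centroids`` is
    (n_nuclei, T, 2) in (row, col) pixels; ``stage_bounds`` lists
    (label, start, end) half-open frame intervals whose boundaries are the
    mitotic division events.
    """

    states: np.ndarray          # bool, ON/OFF per frame
    transcripts: np.ndarray     # int, nascent transcripts contributing signal
    centroids: np.ndarray       # float, (row, col) per frame
    nucleus_home: np.ndarray    # (n_nuclei, n_stages, 2) base positions per stage
    stage_bounds: list          # (label, start, end)
    bleach_factors: np.ndarray  # (T,)
    config: SimConfig

    def __post_init__(self) -> None:
        if np.any(self.transcripts < 0):
            raise ValueError("transcript counts must be nonnegative")
        if self.states.shape != self.transcripts.shape:
            raise ValueError("states and transcripts shapes differ")
        if self.states.shape[1] != len(self.bleach_factors):
            raise ValueError("state trajectory length must equal total frames")
        fs = self.config.field_size_px
        if np.any(self.centroids < 0) or np.any(self.centroids > fs - 1):
            raise ValueError("centroids must lie inside the field")

    @property
    def n_nuclei(self) -> int:
        return self.states.shape[0]

    @property
    def n_frames(self) -> int:
        return self.states.shape[1]

    def visible_count(self) -> np.ndarray:
        """Number of nuclei with at least one nascent transcript, per frame."""
        return (self.transcripts > 0).sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: one row per (nucleus, frame)."""
        n, t = self.states.shape
        return pd.DataFrame({
            "nucleus_id": np.repeat(np.arange(n), t),
            "frame": np.tile(np.arange(t), n),
            "state": self.states.ravel().astype(int),
            "transcript_count": self.transcripts.ravel(),
            "row": self.centroids[..., 0].ravel(),
            "col": self.centroids[..., 1].ravel(),
        })


# ---------------------------------------------------------------------------
# telegraph simulation
# ---------------------------------------------------------------------------

def _sample_switch_times(rng, k_on, k_off, init_on, duration):
    """Exact CTMC path: returns (initial state, sorted switch times in (0, duration))."""
    switches = []
    t, on = 0.0, init_on
    while True:
        rate = k_off if on else k_on
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        switches.append(t)
        on = not on
    return init_on, switches


def simulate_telegraph(config: SimConfig, nucleus_count: int | None = None) -> GroundTruth:
    """Sample per-nucleus telegraph trajectories and nascent-transcript counts.

    Each nucleus runs an independent two-state chain per stage (mitosis resets
    the promoter to OFF — or ON with probability ``p_init_on`` — at every
    stage boundary).  The chain is sampled in continuous time and discretized
    by the state at each frame midpoint.  The nascent-transcript count at a
    frame is the number of Poisson initiation events inside the trailing
    window ``(t_mid - transcript_dwell_s, t_mid]``.
    """
    if nucleus_count is None:
        nucleus_count = config.n_nuclei_side ** 2
    if nucleus_count < 1:
        raise ValueError("nucleus_count must be >= 1")

    ss = np.random.SeedSequence(config.seed)
    rng_kinetics, rng_geometry = [np.random.default_rng(c) for c in ss.spawn(2)]

    dt = config.frame_interval_s
    n_stage_frames = config.n_frames_per_stage
    t_total = config.n_frames_total
    stage_duration = n_stage_frames * dt

    states = np.zeros((nucleus_count, t_total), dtype=bool)
    transcripts = np.zeros((nucleus_count, t_total), dtype=np.int64)
    mids = (np.arange(n_stage_frames) + 0.5) * dt

    stage_bounds = []
    for s, label in enumerate(config.stage_labels):
        f0 = s * n_stage_frames
        stage_bounds.append((label, f0, f0 + n_stage_frames))
        for nuc in range(nucleus_count):
            init_on = bool(rng_kinetics.random() < config.p_init_on)
            init_on, switches = _sample_switch_times(
                rng_kinetics, config.k_on, config.k_off, init_on, stage_duration)
            sw = np.asarray(switches)
            idx = np.searchsorted(sw, mids, side="right")
            on_mid = np.where(idx % 2 == 0, init_on, not init_on)
            states[nuc, f0:f0 + n_stage_frames] = on_mid

            # Poisson initiation events on each ON interval of the path
            events = []
            bounds = np.concatenate([[0.0], sw, [stage_duration]])
            on = init_on
            for a, b in zip(bounds[:-1], bounds[1:]):
                if on and config.loading_rate > 0 and b > a:
                    k = rng_kinetics.poisson(config.loading_rate * (b - a))
                    if k:
                        events.append(rng_kinetics.uniform(a, b, size=k))
                on = not on
            ev = np.sort(np.concatenate(events)) if events else np.empty(0)
            # count events in (t_mid - dwell, t_mid]
            hi = np.searchsorted(ev, mids, side="right")
            lo = np.searchsorted(ev, mids - config.transcript_dwell_s, side="right")
            transcripts[nuc, f0:f0 + n_stage_frames] = hi - lo

    centroids, home = _sample_positions(config, nucleus_count, rng_geometry)

    t_seconds = np.arange(t_total) * dt
    if math.isinf(config.bleach_halflife_s):
        bleach = np.ones(t_total)
    else:
        bleach = 2.0 ** (-t_seconds / config.bleach_halflife_s)

    return GroundTruth(states=states, transcripts=transcripts, centroids=centroids,
                       nucleus_home=home, stage_bounds=stage_bounds,
                       bleach_factors=bleach, config=config)


def _sample_positions(config: SimConfig, nucleus_count: int, rng) -> tuple:
    """Nucleus home positions on a jittered grid (re-jittered at each mitosis)
    plus per-frame dot centroids (home + per-frame diffusion jitter)."""
    side = config.n_nuclei_side
    if nucleus_count > side * side:
        side = int(math.ceil(math.sqrt(nucleus_count)))
    spacing = config.field_size_px / side
    if spacing < 4 * config.psf_sigma_px:
        raise ValueError(
            f"field of {config.field_size_px} px too small for {nucleus_count} nuclei"
        )
    grid = [((i + 0.5) * spacing, (j + 0.5) * spacing)
            for i in range(side) for j in range(side)][:nucleus_count]
    grid = np.asarray(grid)

    n_stages, tps = config.n_stages, config.n_frames_per_stage
    home = np.empty((nucleus_count, n_stages, 2))
    for s in range(n_stages):
        home[:, s, :] = grid + rng.normal(0.0, 0.04 * spacing, size=grid.shape)

    cent = np.empty((nucleus_count, n_stages * tps, 2))
    for s in range(n_stages):
        jitter = rng.normal(0.0, config.dot_diffusion_px, size=(nucleus_count, tps, 2))
        cent[:, s * tps:(s + 1) * tps, :] = home[:, s, None, :] + jitter
    np.clip(cent, 0.0, config.field_size_px - 1, out=cent)
    np.clip(home, 0.0, config.field_size_px - 1, out=home)
    return cent, home


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _add_gaussian(plane: np.ndarray, row: float, col: float, amp: float, sigma: float):
    """Accumulate a 2D Gaussian into ``plane`` over a +/- 4 sigma window."""
    h, w = plane.shape
    r = int(math.ceil(4 * sigma))
    r0, r1 = max(0, int(row) - r), min(h, int(row) + r + 1)
    c0, c1 = max(0, int(col) - r), min(w, int(col) + r + 1)
    if r0 >= r1 or c0 >= c1:
        return
    yy = np.arange(r0, r1)[:, None] - row
    xx = np.arange(c0, c1)[None, :] - col
    plane[r0:r1, c0:c1] += amp * np.exp(-(yy ** 2 + xx ** 2) / (2.0 * sigma ** 2))


def render_movie(truth: GroundTruth, config: SimConfig) -> MovieStack:
    """Forward-render ground truth into a T x Z x Y x X x 2 movie stack.

    Green channel: per dot, a Gaussian of amplitude
    ``amp_per_transcript * transcript_count * bleach_factor`` (defocused and
    attenuated on off-focus z planes), plus uniform background and Gaussian
    read noise (Poisson shot noise optional).  Red channel: filled nuclear
    disks at the stage's home positions.  Output is clipped to the sample
    bit depth.
    """
    if truth.n_frames != config.n_frames_total:
        raise ValueError("truth and config disagree on total frame count")
    fs = config.field_size_px
    nz = max(1, config.n_z_planes)
    zc = (nz - 1) / 2.0
    t_total = truth.n_frames
    maxval = float(2 ** config.bit_depth - 1)

    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(3)[2])

    # red channel is static within a stage: render once per stage per z plane
    red_by_stage = {}
    for s, (_, f0, _) in enumerate(truth.stage_bounds):
        plane = np.zeros((fs, fs), dtype=np.float32)
        yy, xx = np.mgrid[0:fs, 0:fs]
        for nuc in range(truth.n_nuclei):
            r0, c0 = truth.nucleus_home[nuc, s]
            disk = (yy - r0) ** 2 + (xx - c0) ** 2 <= config.nucleus_radius_px ** 2
            plane[disk] = config.nucleus_intensity
        red_by_stage[s] = plane

    stage_of_frame = np.empty(t_total, dtype=int)
    for s, (_, f0, f1) in enumerate(truth.stage_bounds):
        stage_of_frame[f0:f1] = s

    movie = np.empty((t_total, nz, fs, fs, 2),
                     dtype=np.uint8 if config.bit_depth == 8 else np.uint16)
    for t in range(t_total):
        s = stage_of_frame[t]
        for z in range(nz):
            defocus = abs(z - zc)
            sigma = config.psf_sigma_px * (1.0 + config.z_defocus_per_plane * defocus)
            att = (config.psf_sigma_px / sigma) ** 2
            green = np.full((fs, fs), config.background_level, dtype=np.float32)
            for nuc in range(truth.n_nuclei):
                count = truth.transcripts[nuc, t]
                if count == 0:
                    continue
                amp = config.amp_per_transcript * count * truth.bleach_factors[t] * att
                row, col = truth.centroids[nuc, t]
                _add_gaussian(green, row, col, amp, sigma)
            red = red_by_stage[s] * truth.bleach_factors[t]
            if config.poisson_noise:
                green = rng.poisson(np.maximum(green, 0)).astype(np.float32)
                red = rng.poisson(np.maximum(red, 0)).astype(np.float32)
            if config.noise_sd > 0:
                green = green + rng.normal(0.0, config.noise_sd, size=green.shape)
                red = red + rng.normal(0.0, config.noise_sd, size=red.shape)
            movie[t, z, :, :, 0] = np.clip(np.rint(green), 0, maxval)
            movie[t, z, :, :, 1] = np.clip(np.rint(red), 0, maxval)

    return MovieStack(pixels=movie, pixel_size_um=config.pixel_size_um,
                      frame_interval_s=config.frame_interval_s,
                      bit_depth=config.bit_depth,
                      channel_roles=dict(DEFAULT_CHANNEL_ROLES))


def simulate_movie(config: SimConfig, nucleus_count: int | None = None):
    """Convenience: sample ground truth and render it. Returns (movie, truth)."""
    truth = simulate_telegraph(config, nucleus_count)
    return render_movie(truth, config), truth


# ---------------------------------------------------------------------------
# fixture I/O
# ---------------------------------------------------------------------------

def write_fixture(movie: MovieStack, truth: GroundTruth, out_dir) -> dict:
    """Write a movie + ground truth fixture to disk; round-trips losslessly.

    Layout: ``movie.tif`` (multi-page TIFF, TZYXC), ``truth.csv`` (one row per
    nucleus x frame), ``stages.csv``, ``bleach.csv``, and ``config.json``
    (verbatim config echo).  Returns the path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "movie": out / "movie.tif",
        "truth": out / "truth.csv",
        "stages": out / "stages.csv",
        "bleach": out / "bleach.csv",
        "config": out / "config.json",
    }
    tifffile.imwrite(paths["movie"], movie.pixels, metadata={"axes": "TZYXC"})
    truth.to_frame().to_csv(paths["truth"], index=False)
    pd.DataFrame(truth.stage_bounds, columns=["label", "start", "end"]).to_csv(
        paths["stages"], index=False)
    pd.DataFrame({"frame": np.arange(truth.n_frames),
                  "bleach_factor": truth.bleach_factors}).to_csv(
        paths["bleach"], index=False)
    paths["config"].write_text(json.dumps(truth.config.to_dict(), indent=2,
                                          sort_keys=True) + "\n")
    return paths


def read_fixture(in_dir) -> tuple:
    """Read back a fixture written by :func:`write_fixture`.

    Returns ``(MovieStack, truth_table, StagePartition, SimConfig)``.
    """
    src = Path(in_dir)
    cfg = SimConfig(**{**json.loads((src / "config.json").read_text()),
                       "stage_labels": tuple(
                           json.loads((src / "config.json").read_text())["stage_labels"])})
    pixels = tifffile.imread(src / "movie.tif")
    if pixels.ndim == 4:  # single z plane squeezed by the reader
        pixels = pixels[:, None]
    movie = MovieStack(pixels=pixels, pixel_size_um=cfg.pixel_size_um,
                       frame_interval_s=cfg.frame_interval_s, bit_depth=cfg.bit_depth)
    truth_table = pd.read_csv(src / "truth.csv")
    stages = pd.read_csv(src / "stages.csv")
    partition = StagePartition(list(stages.itertuples(index=False, name=None)))
    return movie, truth_table, partition, cfg
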