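"""Transcription-dot detection by green-channel thresholding.

A dot is a connected component of pixels strictly above a fixed threshold
(default 55 on the 8-bit scale) in the green channel.  Per dot we record the
pixel area, the unweighted centroid, and the mean original intensity over the
filled component; brightness is then min-max normalized across all dots of a
nuclear-cycle stage (all frames of the stage pooled).

An optional nuclear mask (Otsu threshold of the red channel, holes filled)
can discard dots whose centroid falls outside any nucleus; it is off by
default because the baseline procedure is a pure green-channel threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

logger = logging.getLogger("burstquant")


@dataclass
class DetectionParams:
    green_threshold: int = 55     # strict ">" on the 8-bit scale
    connectivity: int = 8         # 4 or 8 (pixel neighborhood)
    min_area_px: int = 1
    use_nuclear_mask: bool = False
    nuclear_mask_method: str = "otsu"

    def __post_init__(self) -> None:
        if not 0 < self.green_threshold < 255:
            raise ValueError("green_threshold must be in (0, 255)")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")


@dataclass
class DotObservation:
    """One detected contour in one frame."""

    frame: int
    centroid: tuple          # (row, col), float pixels
    area_px: int
    mean_brightness: float
    norm_brightness: float | None = None
    stage_label: str | None = None
    track_id: int | None = None


def detect_dots(frame_image: np.ndarray, params: DetectionParams,
                frame: int = 0, stage_label: str | None = None,
                nuclear_mask_image: np.ndarray | None = None) -> list:
    """Detect dots in a single 8-bit green-channel frame.

    Pixels strictly above ``green_threshold`` are grouped into connected
    components at the requested connectivity; components smaller than
    ``min_area_px`` are dropped.  Area is the member-pixel count, the centroid
    the unweighted mean of member pixel coordinates, and mean brightness the
    mean original intensity over the filled component.

    ``norm_brightness`` is left unset; apply :func:`normalize_stage` once all
    frames of a stage have been detected.
    """
    img = np.asarray(frame_image)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D frame, got shape {img.shape}")
    if img.dtype != np.uint8:
        raise ValueError(
            "detect_dots requires 8-bit input; convert with preprocess.to_uint8")
    mask = img > params.green_threshold
    lab = label(mask, connectivity=1 if params.connectivity == 4 else 2)
    dots = []
    for rp in regionprops(lab, intensity_image=img):
        if rp.area < params.min_area_px:
            continue
        centroid = (float(rp.centroid[0]), float(rp.centroid[1]))
        if nuclear_mask_image is not None and params.use_nuclear_mask:
            r, c = int(round(centroid[0])), int(round(centroid[1]))
            if not nuclear_mask_image[r, c]:
                continue
        dots.append(DotObservation(
            frame=frame,
            centroid=centroid,
            area_px=int(rp.area),
            mean_brightness=float(rp.intensity_mean),
            stage_label=stage_label,
        ))
    return dots


def detect_movie(green_frames: np.ndarray, params: DetectionParams,
                 stage_label: str | None = None,
                 red_frames: np.ndarray | None = None) -> list:
    """Run :func:`detect_dots` over a T x Y x X stack; returns per-frame lists."""
    out = []
    for t in range(green_frames.shape[0]):
        mask_img = None
        if params.use_nuclear_mask and red_frames is not None:
            mask_img = nuclear_mask(red_frames[t], params.nuclear_mask_method)
        out.append(detect_dots(green_frames[t], params, frame=t,
                               stage_label=stage_label,
                               nuclear_mask_image=mask_img))
    return out


def normalize_stage(dots: list) -> list:
    """Set ``norm_brightness`` by min-max over every dot of one stage.

    ``norm = (mean - min_stage) / (max_stage - min_stage)`` with min/max taken
    over all dots of the stage, frames pooled.  If max equals min (e.g. a
    single dot in the stage) every norm is set to 0.  Accepts either a flat
    list of dots or per-frame lists; returns the same structure.
    """
    nested = bool(dots) and isinstance(dots[0], list)
    flat = [d for fr in dots for d in fr] if nested else list(dots)
    if not flat:
        return dots
    labels = {d.stage_label for d in flat}
    if len(labels) > 1:
        raise ValueError(f"dots span multiple stages: {sorted(map(str, labels))}")
    vals = np.array([d.mean_brightness for d in flat])
    lo, hi = vals.min(), vals.max()
    span = hi - lo
    new = [replace(d, norm_brightness=0.0 if span == 0
                   else float((d.mean_brightness - lo) / span))
           for d in flat]
    if not nested:
        return new
    out, i = [], 0
    for fr in dots:
        out.append(new[i:i + len(fr)])
        i += len(fr)
    return out


def nuclear_mask(red_image: np.ndarray, method: str = "otsu") -> np.ndarray:
    """Binary nucleus mask from the red channel: Otsu threshold + hole fill.

    A blank (constant) red channel yields a full-field mask with a warning,
    so masking degrades to a no-op rather than discarding every dot.
    """
    if method != "otsu":
        raise ValueError(f"unknown nuclear mask method {method!r}")
    img = np.asarray(red_image)
    if img.ndim != 2:
        raise ValueError("red channel image must be 2D")
    if img.max() == img.min():
        warnings.warn("blank red channel; nuclear mask covers the full field",
                      RuntimeWarning, stacklevel=2)
        return np.ones_like(img, dtype=bool)
    mask = img > threshold_otsu(img)
    return ndimage.binary_fill_holes(mask)


def dots_to_table(dots) -> pd.DataFrame:
    """Flatten dots (flat or per-frame lists) into the dots CSV schema."""
    flat = [d for fr in dots for d in fr] if dots and isinstance(dots[0], list) else dots
    return pd.DataFrame([{
        "stage": d.stage_label,
        "frame": d.frame,
        "row": d.centroid[0],
        "col": d.centroid[1],
        "area_px": d.area_px,
        "mean_brightness": d.mean_brightness,
        "norm_brightness": d.norm_brightness,
        "track_id": d.track_id,
    } for d in flat],
        columns=["stage", "frame", "row", "col", "area_px",
                 "mean_brightness", "norm_brightness", "track_id"])
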