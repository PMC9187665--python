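"""Spot detection and nearest-neighbor particle tracking.

Detection follows the classic single-molecule recipe: band-pass the
projected frame to highlight diffraction-limited particles in a 1-7 px size
band, binarize within the cell mask, take 8-connected components, filter by
area and eccentricity, and report component centroids.  Tracking links each
detected mRNA to the closest mRNA in the next frame, with a maximum step of
10 px and a minimum track length of 5 frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import binary_erosion
from skimage.filters import difference_of_gaussians, threshold_otsu
from skimage.measure import label, regionprops

from tnt.stack import ImageStack

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.355


@dataclass
class DetectionParams:
    band_low_px: float = 1.0
    band_high_px: float = 7.0
    threshold_policy: str = "otsu"  # or "mean_plus_k_sd"
    k_sd: float = 3.0
    min_area_px: int = 2
    max_area_px: int = 49
    max_eccentricity: float = 0.9
    # hysteresis-style second threshold: a component is kept only if its
    # peak band-passed value clears mean + peak_k_sd * SD
    peak_k_sd: float = 3.5

    def __post_init__(self):
        if not (0 < self.band_low_px < self.band_high_px):
            raise ValueError("require 0 < band_low_px < band_high_px")
        if self.min_area_px > self.max_area_px:
            raise ValueError("min_area_px must be <= max_area_px")
        if self.threshold_policy not in ("otsu", "mean_plus_k_sd"):
            raise ValueError(f"unknown threshold policy {self.threshold_policy!r}")
        if not (0.0 <= self.max_eccentricity <= 1.0):
            raise ValueError("max_eccentricity must lie in [0, 1]")


@dataclass
class Spot:
    frame_index: int
    channel: str
    centroid_xy: Tuple[float, float]  # (x, y) in px
    area_px: int
    component_pixels: np.ndarray  # (n, 2) array of (row, col)
    raw_peak: float


@dataclass
class Track:
    track_id: int
    times_s: List[float] = field(default_factory=list)
    spots: List[Optional[Spot]] = field(default_factory=list)
    traces: dict = field(default_factory=dict)  # channel -> IntensityTrace

    def positions(self) -> np.ndarray:
        return np.array([s.centroid_xy for s in self.spots if s is not None])

    def __len__(self) -> int:
        return len(self.spots)


def project_stack(stack: ImageStack, mode: str = "max_z"):
    """Z-project each frame of each channel.

    ``max_z`` returns the per-pixel maximum across planes as a (T, C, Y, X)
    array.  ``best_z`` defers the plane choice to quantification (best-Z
    selection needs the tracked position) and returns the stack unchanged.
    """
    if stack.n_planes < 1 or stack.data.size == 0:
        raise ValueError("empty stack")
    if mode == "max_z":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN frames
            return np.nanmax(stack.data, axis=1)
    if mode == "best_z":
        return stack
    raise ValueError(f"unknown projection mode {mode!r}")


def bandpass(image: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Difference-of-Gaussians band-pass tuned to the particle size band.

    Sigmas map from the FWHM size band: sigma = size / 2.355.  The output has
    zero-mean background (the DC component is rejected).
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("bandpass expects a 2-D image")
    return difference_of_gaussians(
        image, params.band_low_px / FWHM_TO_SIGMA, params.band_high_px / FWHM_TO_SIGMA
    )


def detect_spots(
    image: np.ndarray,
    cell_mask: Optional[np.ndarray] = None,
    params: Optional[DetectionParams] = None,
    frame_index: int = 0,
    channel: str = "mrna",
) -> List[Spot]:
    """Detect diffraction-limited particles in one projected frame.

    Pipeline: band-pass, threshold (Otsu or mean + k*SD of the band-passed
    pixels inside the mask), 8-connected components, area/eccentricity
    filter, centroid per component.  Components touching the mask border are
    discarded (their background estimate would be contaminated).
    """
    params = params or DetectionParams()
    image = np.asarray(image, dtype=float)
    if cell_mask is None:
        cell_mask = np.ones(image.shape, dtype=bool)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if cell_mask.shape != image.shape:
        raise ValueError("cell_mask shape must match image shape")
    if not cell_mask.any():
        warnings.warn("empty cell mask: no spots detected", stacklevel=2)
        return []

    filt = bandpass(image, params)
    vals = filt[cell_mask]
    mu, sd = float(vals.mean()), float(vals.std())
    if params.threshold_policy == "otsu":
        thr = threshold_otsu(vals)
    else:
        thr = mu + params.k_sd * sd
    peak_thr = mu + params.peak_k_sd * sd
    binary = (filt > thr) & cell_mask

    interior = binary_erosion(cell_mask)
    labels = label(binary, connectivity=2)
    spots: List[Spot] = []
    for region in regionprops(labels, intensity_image=filt):
        if region.intensity_max < peak_thr:
            continue
        if not (params.min_area_px <= region.area <= params.max_area_px):
            continue
        # second-moment shape is unstable below ~3x3 px; apply the
        # eccentricity cut only where it is meaningful (aggregate rejection)
        if region.area >= 9 and region.eccentricity > params.max_eccentricity:
            continue
        coords = region.coords
        if not interior[coords[:, 0], coords[:, 1]].all():
            continue  # touches the mask border
        cy, cx = region.centroid_weighted  # band-passed-intensity weighted
        spots.append(Spot(
            frame_index=frame_index,
            channel=channel,
            centroid_xy=(cx, cy),
            area_px=int(region.area),
            component_pixels=coords,
            raw_peak=float(image[coords[:, 0], coords[:, 1]].max()),
        ))
    return spots


def link_tracks(
    spotsets: Sequence[Sequence[Spot]],
    max_step_px: float = 10.0,
    min_track_len: int = 5,
    times_s: Optional[Sequence[float]] = None,
) -> List[Track]:
    """Greedy nearest-neighbor linking of per-frame spot sets into tracks.

    For each consecutive frame pair, candidate links are sorted globally by
    distance and accepted greedily (each spot used once, ties broken by lower
    spot index); links longer than ``max_step_px`` are forbidden.  Unlinked
    spots start new tracks; a missed frame terminates a track (no gap
    closing).  Tracks shorter than ``min_track_len`` frames are discarded.
    """
    if times_s is None:
        times_s = list(range(len(spotsets)))
    if len(times_s) != len(spotsets):
        raise ValueError("times_s length must match number of frames")

    open_tracks: dict = {}  # spot index in current frame -> track
    finished: List[Track] = []
    next_id = 0
    prev_spots: Sequence[Spot] = []

    for f, spots in enumerate(spotsets):
        assigned_prev: dict = {}
        if prev_spots and spots:
            pa = np.array([s.centroid_xy for s in prev_spots])
            pb = np.array([s.centroid_xy for s in spots])
            d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
            cands = [
                (d[i, j], i, j)
                for i in range(len(prev_spots))
                for j in range(len(spots))
                if d[i, j] <= max_step_px
            ]
            cands.sort()  # distance, then lower prev index, then lower next index
            used_prev, used_next = set(), set()
            for dist, i, j in cands:
                if i in used_prev or j in used_next:
                    continue
                used_prev.add(i)
                used_next.add(j)
                assigned_prev[j] = i

        new_open: dict = {}
        for j, spot in enumerate(spots):
            if j in assigned_prev and assigned_prev[j] in open_tracks:
                tr = open_tracks.pop(assigned_prev[j])
            else:
                tr = Track(track_id=next_id)
                next_id += 1
            tr.times_s.append(float(times_s[f]))
            tr.spots.append(spot)
            new_open[j] = tr
        finished.extend(open_tracks.values())  # tracks with no continuation
        open_tracks = new_open
        prev_spots = spots

    finished.extend(open_tracks.values())
    kept = [t for t in finished if len(t) >= min_track_len]
    kept.sort(key=lambda t: t.track_id)
    for new, t in enumerate(kept):
        t.track_id = new
    return kept
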