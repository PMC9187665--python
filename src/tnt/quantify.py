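"""Local-background-subtracted intensity measurement and classification.

Each detected particle is quantified inside a small crop: the central
signal is the mean over a centered disc, the background is estimated either
from the median of four 3x3 corner quadrants of the crop (max-Z geometry:
15x15 crop, disc of diameter 3) or from the mean over a surrounding ring
(best-Z geometry: disc 6, ring of diameter 10 and width 1; confocal: disc 5,
ring 15x2), and the particle's intensity is central minus background.
Best-Z traces pick, per time point, the plane maximizing the mRNA-channel
disc mean and max-project that plane with its two neighbors before
measuring every channel at the same xy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.segmentation import clear_border

from tnt.detect import Track
from tnt.stack import ImageStack


@dataclass
class CropGeometry:
    crop_size_px: int = 15
    central_disc_diameter_px: int = 3
    background_mode: str = "corner_quadrants"  # or "ring"
    ring_diameter_px: int = 10
    ring_width_px: int = 1
    quadrant_size_px: int = 3

    def __post_init__(self):
        if self.crop_size_px % 2 != 1:
            raise ValueError("crop_size_px must be odd")
        if self.central_disc_diameter_px > self.crop_size_px:
            raise ValueError("disc must fit inside the crop")
        if self.background_mode not in ("corner_quadrants", "ring"):
            raise ValueError(f"unknown background mode {self.background_mode!r}")
        if self.background_mode == "ring" and self.ring_diameter_px > self.crop_size_px:
            raise ValueError("ring must fit inside the crop")

    @classmethod
    def hilo_maxz(cls) -> "CropGeometry":
        """15x15 crop, disc 3, median of four 3x3 corner quadrants."""
        return cls()

    @classmethod
    def hilo_bestz(cls) -> "CropGeometry":
        """11x11 crop, disc 6, ring of diameter 10 and width 1."""
        return cls(crop_size_px=11, central_disc_diameter_px=6,
                   background_mode="ring", ring_diameter_px=10, ring_width_px=1)

    @classmethod
    def confocal(cls) -> "CropGeometry":
        """17x17 crop, disc 5, ring of diameter 15 and width 2."""
        return cls(crop_size_px=17, central_disc_diameter_px=5,
                   background_mode="ring", ring_diameter_px=15, ring_width_px=2)


@dataclass
class SpotMeasurement:
    intensity: float  # central - background
    central_mean: float
    background: float
    background_sd: float
    missing: bool = False

    @classmethod
    def missing_value(cls) -> "SpotMeasurement":
        return cls(np.nan, np.nan, np.nan, np.nan, missing=True)


@dataclass
class IntensityTrace:
    track_id: int
    channel: str
    times_s: List[float] = field(default_factory=list)
    intensity: List[float] = field(default_factory=list)
    central_mean: List[float] = field(default_factory=list)
    background: List[float] = field(default_factory=list)
    background_sd: List[float] = field(default_factory=list)
    z_best: List[Optional[int]] = field(default_factory=list)

    def as_arrays(self):
        return np.asarray(self.times_s, dtype=float), np.asarray(self.intensity, dtype=float)


@dataclass
class SpotClassification:
    track_id: int
    tethered: bool
    translating: bool
    snr: Dict[str, float] = field(default_factory=dict)


def _geometry_masks(geometry: CropGeometry):
    """Boolean disc / background masks on the crop grid.

    A pixel belongs to the disc iff its center lies strictly within d/2 of
    the crop center; to the ring iff its distance lies in
    [ring_d/2 - width, ring_d/2).
    """
    n = geometry.crop_size_px
    c = n // 2
    yy, xx = np.mgrid[0:n, 0:n]
    dist = np.hypot(yy - c, xx - c)
    disc = dist < geometry.central_disc_diameter_px / 2.0
    if geometry.background_mode == "ring":
        outer = geometry.ring_diameter_px / 2.0
        inner = outer - geometry.ring_width_px
        bg = (dist >= inner) & (dist < outer)
    else:
        q = geometry.quadrant_size_px
        bg = np.zeros((n, n), dtype=bool)
        bg[:q, :q] = bg[:q, n - q:] = bg[n - q:, :q] = bg[n - q:, n - q:] = True
    return disc, bg


def measure_spot(image: np.ndarray, center_xy, geometry: Optional[CropGeometry] = None
                 ) -> SpotMeasurement:
    """Background-subtracted intensity of one particle in a 2-D frame.

    The crop is centered on the tracked centroid rounded to the nearest
    pixel; a crop clipped by the image edge yields a missing measurement.
    """
    geometry = geometry or CropGeometry.hilo_maxz()
    image = np.asarray(image, dtype=float)
    cx, cy = int(round(center_xy[0])), int(round(center_xy[1]))
    half = geometry.crop_size_px // 2
    y0, y1 = cy - half, cy + half + 1
    x0, x1 = cx - half, cx + half + 1
    if y0 < 0 or x0 < 0 or y1 > image.shape[0] or x1 > image.shape[1]:
        return SpotMeasurement.missing_value()
    crop = image[y0:y1, x0:x1]
    if np.isnan(crop).all():
        return SpotMeasurement.missing_value()
    disc, bg_mask = _geometry_masks(geometry)
    central = float(np.nanmean(crop[disc]))
    bg_vals = crop[bg_mask]
    if geometry.background_mode == "corner_quadrants":
        background = float(np.nanmedian(bg_vals))
    else:
        background = float(np.nanmean(bg_vals))
    bg_sd = float(np.nanstd(bg_vals, ddof=1))
    return SpotMeasurement(central - background, central, background, bg_sd)


def best_z_plane(volume: np.ndarray, center_xy, disc_diameter_px: int = 6) -> int:
    """Plane index maximizing the mean intensity in a centered disc."""
    nz = volume.shape[0]
    cx, cy = int(round(center_xy[0])), int(round(center_xy[1]))
    r = disc_diameter_px / 2.0
    half = int(np.ceil(r))
    y0, y1 = max(0, cy - half), min(volume.shape[1], cy + half + 1)
    x0, x1 = max(0, cx - half), min(volume.shape[2], cx + half + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    disc = np.hypot(yy - cy, xx - cx) < r
    if not disc.any():
        return 0
    means = np.array([np.nanmean(volume[z, y0:y1, x0:x1][disc]) for z in range(nz)])
    if np.isnan(means).all():
        return 0
    return int(np.nanargmax(means))


def best_z_trace(stack: ImageStack, track: Track,
                 geometry: Optional[CropGeometry] = None,
                 channel_transform=None) -> Dict[str, IntensityTrace]:
    """Best-Z intensity trace of one track in every channel.

    At each track time point the mRNA channel picks Z_best (maximal disc
    mean); the planes Z_best +/- 1 (clamped at the stack edges) are max-Z
    projected and every channel exposed at that time is measured with the
    disc/ring geometry at the tracked xy.  When the translation/tethering
    channels sit on a second camera, ``channel_transform`` (a registration
    :class:`~tnt.register.ChannelTransform` mapping mRNA-camera coordinates
    onto that camera) is applied to the xy before measuring those channels.
    """
    geometry = geometry or CropGeometry.hilo_bestz()
    if stack.n_planes < 3:
        raise ValueError("best-Z projection needs a stack with >= 3 planes")
    traces = {c: IntensityTrace(track_id=track.track_id, channel=c)
              for c in stack.channels}
    frame_of_time = {t: i for i, t in enumerate(np.asarray(stack.frame_times_s))}
    sampled = {c: set(np.asarray(stack.channel_times_s[c])) for c in stack.channels}

    for t, spot in zip(track.times_s, track.spots):
        if spot is None or t not in frame_of_time:
            continue
        fi = frame_of_time[t]
        xy = spot.centroid_xy
        mrna_vol = stack.get(fi, "mrna")
        zb = best_z_plane(mrna_vol, xy, geometry.central_disc_diameter_px)
        z0, z1 = max(0, zb - 1), min(stack.n_planes, zb + 2)
        for c in stack.channels:
            if t not in sampled[c]:
                continue
            vol = stack.get(fi, c)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                proj = np.nanmax(vol[z0:z1], axis=0)
            xy_c = xy
            if channel_transform is not None and c in ("translation", "tether"):
                xy_c = tuple(channel_transform.apply([xy])[0])
            m = measure_spot(proj, xy_c, geometry)
            tr = traces[c]
            tr.times_s.append(float(t))
            tr.intensity.append(m.intensity)
            tr.central_mean.append(m.central_mean)
            tr.background.append(m.background)
            tr.background_sd.append(m.background_sd)
            tr.z_best.append(zb)
    return traces


def classify_spot(measurements: Dict[str, SpotMeasurement], k: float = 3.0,
                  track_id: int = -1) -> SpotClassification:
    """Tethered/translating call from per-channel measurements.

    A channel is positive iff its background-subtracted intensity strictly
    exceeds k times the local background SD (an intensity exactly at the
    threshold is negative).
    """
    def positive(m: Optional[SpotMeasurement]) -> bool:
        if m is None or m.missing or not np.isfinite(m.intensity):
            return False
        return m.intensity > k * m.background_sd

    snr = {c: (m.intensity / m.background_sd if m is not None and not m.missing
               and m.background_sd > 0 else np.nan)
           for c, m in measurements.items()}
    return SpotClassification(
        track_id=track_id,
        tethered=positive(measurements.get("tether")),
        translating=positive(measurements.get("translation")),
        snr=snr,
    )


def fraction_translating(classifications: List[SpotClassification],
                         scope: str = "tethered_only") -> Optional[float]:
    """Per-cell fraction of (tethered) mRNAs actively translating."""
    if scope == "tethered_only":
        pool = [c for c in classifications if c.tethered]
    elif scope == "all":
        pool = list(classifications)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    if not pool:
        return None
    return sum(c.translating for c in pool) / len(pool)


def colocalization_fraction(spots_a, mask_b=None, spots_b=None,
                            distance_threshold_px: float = 2.0) -> Optional[float]:
    """Fraction of A spots colocalized with a mask or with B spots.

    Mask mode: an A spot colocalizes iff its (rounded) center lies inside
    the mask.  Spot mode: iff any B spot lies within the distance threshold.
    Both inputs must already be in the same registered coordinate frame.
    """
    pts = np.atleast_2d(np.array([getattr(s, "centroid_xy", s) for s in spots_a],
                                 dtype=float)) if len(spots_a) else np.empty((0, 2))
    if len(pts) == 0:
        return None
    if mask_b is not None:
        mask_b = np.asarray(mask_b, dtype=bool)
        xi = np.clip(np.round(pts[:, 0]).astype(int), 0, mask_b.shape[1] - 1)
        yi = np.clip(np.round(pts[:, 1]).astype(int), 0, mask_b.shape[0] - 1)
        hits = mask_b[yi, xi]
    elif spots_b is not None and len(spots_b):
        ptsb = np.atleast_2d(np.array(
            [getattr(s, "centroid_xy", s) for s in spots_b], dtype=float))
        d = np.linalg.norm(pts[:, None, :] - ptsb[None, :, :], axis=2)
        hits = (d.min(axis=1) <= distance_threshold_px)
    else:
        hits = np.zeros(len(pts), dtype=bool)
    return float(hits.mean())


def segment_nuclei(dna_image: np.ndarray, intensity_image: np.ndarray,
                   threshold: Optional[float] = None,
                   min_area_px: int = 50, max_area_px: int = 100_000,
                   max_eccentricity: float = 0.95) -> pd.DataFrame:
    """Segment whole single nuclei and total a second channel per nucleus.

    Threshold (Otsu unless given), 8-connected components, discard nuclei
    crossing the image edge, select by area and eccentricity, then sum the
    second channel's intensity inside each surviving mask.
    """
    dna = np.asarray(dna_image, dtype=float)
    other = np.asarray(intensity_image, dtype=float)
    if dna.shape != other.shape:
        raise ValueError("channel images must share a shape")
    thr = threshold_otsu(dna) if threshold is None else threshold
    binary = clear_border(dna > thr)
    labels = label(binary, connectivity=2)
    rows = []
    for region in regionprops(labels):
        if not (min_area_px <= region.area <= max_area_px):
            continue
        if region.eccentricity > max_eccentricity:
            continue
        coords = region.coords
        total = float(other[coords[:, 0], coords[:, 1]].sum())
        cy, cx = region.centroid
        rows.append((region.label, int(region.area), cx, cy, total))
    return pd.DataFrame(
        rows, columns=["label", "area_px", "x_px", "y_px", "total_intensity"])
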