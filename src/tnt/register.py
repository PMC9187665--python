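"""Channel registration from fiducial beads.

A two-camera microscope introduces a small geometric offset between the
mRNA camera and the translation/tethering camera.  Images of multi-color
beads taken at the end of a session provide matched point pairs from which
a projective transformation matrix is estimated (normalized DLT, as in
scikit-image's ProjectiveTransform) and applied to detected particle
positions to bring all channels into one reference frame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
from skimage.transform import ProjectiveTransform

from tnt.detect import Spot


@dataclass
class ChannelTransform:
    matrix: np.ndarray  # 3x3 homogeneous
    residual_rms_px: float
    n_points: int

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3) or abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("transform matrix must be nonsingular 3x3")
        if self.residual_rms_px < 0:
            raise ValueError("residual must be non-negative")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        hom = np.column_stack([pts, np.ones(len(pts))]) @ self.matrix.T
        return hom[:, :2] / hom[:, 2:3]

    def inverse(self) -> "ChannelTransform":
        return ChannelTransform(
            matrix=np.linalg.inv(self.matrix),
            residual_rms_px=self.residual_rms_px,
            n_points=self.n_points,
        )


def fit_registration(points_a: np.ndarray, points_b: np.ndarray) -> ChannelTransform:
    """Least-squares projective transform mapping A onto B (normalized DLT)."""
    a = np.atleast_2d(np.asarray(points_a, dtype=float))
    b = np.atleast_2d(np.asarray(points_b, dtype=float))
    if a.shape != b.shape or a.shape[1] != 2:
        raise ValueError("point sets must be matching (n, 2) arrays")
    if len(a) < 4:
        raise ValueError(f"projective registration needs >= 4 point pairs, got {len(a)}")
    tf = ProjectiveTransform.from_estimate(a, b)
    if not tf or not np.all(np.isfinite(tf.params)):
        raise ValueError("degenerate bead configuration: transform estimation failed")
    resid = tf(a) - b
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return ChannelTransform(matrix=tf.params, residual_rms_px=rms, n_points=len(a))


def apply_registration(spots: Iterable[Spot], transform: ChannelTransform):
    """Map spot centroids into the reference channel's coordinate frame."""
    spots = list(spots)
    if not spots:
        return []
    pts = np.array([s.centroid_xy for s in spots])
    mapped = transform.apply(pts)
    out = []
    for s, (x, y) in zip(spots, mapped):
        out.append(Spot(
            frame_index=s.frame_index, channel=s.channel,
            centroid_xy=(float(x), float(y)), area_px=s.area_px,
            component_pixels=s.component_pixels, raw_peak=s.raw_peak,
        ))
    return out
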