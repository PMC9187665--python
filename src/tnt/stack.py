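"""The in-memory movie container.

An :class:`ImageStack` holds a T,Z,C,Y,X float array together with the
calibration metadata needed to interpret it (pixel size, z step, channel
names and per-channel sample times).  Channels acquired on a slower time
grid hold NaN at the union-grid frames where they were not exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tnt.config import CHANNELS


@dataclass
class ImageStack:
    data: np.ndarray  # (T, Z, C, Y, X)
    pixel_size_nm: float = 130.0
    z_step_nm: float = 500.0
    channels: tuple = CHANNELS
    frame_times_s: np.ndarray | None = None  # union grid, length T
    channel_times_s: dict = field(default_factory=dict)  # channel -> sampled times

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 5:
            raise ValueError(f"stack must be 5-D (T,Z,C,Y,X); got {self.data.ndim}-D")
        if self.frame_times_s is None:
            self.frame_times_s = np.arange(self.data.shape[0], dtype=float)
        else:
            self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if len(self.frame_times_s) != self.data.shape[0]:
            raise ValueError("frame_times_s length must match T axis")
        if len(self.channels) != self.data.shape[2]:
            raise ValueError("channel list length must match C axis")
        if not self.channel_times_s:
            self.channel_times_s = {c: self.frame_times_s.copy() for c in self.channels}

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_planes(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self):
        return self.data.shape

    def channel_index(self, channel: str) -> int:
        return list(self.channels).index(channel)

    def channel_frame_indices(self, channel: str) -> np.ndarray:
        """Union-grid frame indices at which `channel` was actually exposed."""
        times = np.asarray(self.channel_times_s[channel], dtype=float)
        idx = np.searchsorted(self.frame_times_s, times)
        idx = idx[idx < self.n_frames]
        ok = np.isclose(self.frame_times_s[idx], times[: len(idx)])
        return idx[ok]

    def get(self, frame: int, channel: str) -> np.ndarray:
        """One (Z, Y, X) volume."""
        return self.data[frame, :, self.channel_index(channel)]
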