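"""Simulation and kinetics configuration objects.

Defaults reproduce the acquisition geometry of a HILO single-molecule
experiment: 512x512 px field at 130 nm/px, 13 Z planes at 500 nm step, the
mRNA channel sampled every 10 s and the translation/tethering channels every
100 s (staggered acquisition minimizes photobleaching of the slower
channels).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Tuple

CHANNELS = ("mrna", "translation", "tether")


def _channel_dict(value) -> dict:
    """Broadcast a scalar (or pass through a dict) to all three channels."""
    if isinstance(value, dict):
        missing = set(CHANNELS) - set(value)
        if missing:
            raise ValueError(f"missing channels in per-channel value: {sorted(missing)}")
        return {c: float(value[c]) for c in CHANNELS}
    return {c: float(value) for c in CHANNELS}


@dataclass
class SimulationConfig:
    """Acquisition geometry, optics, diffusion and camera parameters."""

    field_size_px: Tuple[int, int] = (512, 512)  # (ny, nx)
    pixel_size_nm: float = 130.0
    n_z_planes: int = 13
    z_step_nm: float = 500.0
    frame_interval_s: dict = field(
        default_factory=lambda: {"mrna": 10.0, "translation": 100.0, "tether": 100.0}
    )
    duration_s: float = 600.0
    n_mrna: int = 20
    diffusion_coeff_um2_s: float = 0.05
    psf_sigma_px: dict = field(
        default_factory=lambda: {"mrna": 1.3, "translation": 1.3, "tether": 1.3}
    )
    # axial PSF sigma as a multiple of the z step; only best-Z plane selection
    # consumes axial shape so a Gaussian of sigma 1.4 x z_step suffices
    axial_sigma_z_steps: float = 1.4
    photons_per_mrna_probe: float = 500.0
    photons_per_translation_unit: float = 300.0
    photons_per_tether_unit: float = 300.0
    camera_gain: float = 2.0
    read_noise_sd: float = 1.5
    background_level: float = 10.0
    bleach_rate_per_exposure: dict = field(
        default_factory=lambda: {"mrna": 0.0, "translation": 0.0, "tether": 0.0}
    )
    rng_seed: int = 0
    # optional 3x3 homogeneous matrix emulating the two-camera offset of the
    # translation/tethering path relative to the mRNA camera
    camera_offset_matrix: Optional[Sequence[Sequence[float]]] = None
    max_voxels: int = 400_000_000

    def __post_init__(self):
        self.frame_interval_s = _channel_dict(self.frame_interval_s)
        self.psf_sigma_px = _channel_dict(self.psf_sigma_px)
        self.bleach_rate_per_exposure = _channel_dict(self.bleach_rate_per_exposure)
        ny, nx = self.field_size_px
        if ny <= 0 or nx <= 0:
            raise ValueError("field_size_px must be positive")
        if self.pixel_size_nm <= 0 or self.z_step_nm <= 0:
            raise ValueError("pixel_size_nm and z_step_nm must be positive")
        if self.n_z_planes < 1:
            raise ValueError("n_z_planes must be >= 1")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.n_mrna < 0:
            raise ValueError("n_mrna must be >= 0")
        if self.diffusion_coeff_um2_s < 0:
            raise ValueError("diffusion coefficient must be non-negative")
        if self.read_noise_sd < 0 or self.background_level < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.camera_gain <= 0:
            raise ValueError("camera_gain must be positive")
        for c in CHANNELS:
            if self.frame_interval_s[c] <= 0:
                raise ValueError("frame intervals must be positive")
            if self.psf_sigma_px[c] <= 0:
                raise ValueError("psf sigma must be positive")
            if self.bleach_rate_per_exposure[c] < 0:
                raise ValueError("bleach rates must be non-negative")
        # staggered acquisition must be representable: the fast (mRNA)
        # interval has to divide the slow (translation/tether) intervals
        dt = self.frame_interval_s["mrna"]
        for c in ("translation", "tether"):
            ratio = self.frame_interval_s[c] / dt
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError(
                    "mRNA frame interval must divide the "
                    f"{c} interval ({self.frame_interval_s[c]} / {dt})"
                )

    @property
    def sample_times(self):
        """Union of all channel sampling grids (the mRNA grid, by divisibility)."""
        import numpy as np

        dt = self.frame_interval_s["mrna"]
        n = int(np.floor(self.duration_s / dt)) + 1
        return np.arange(n) * dt

    def channel_times(self, channel: str):
        import numpy as np

        dt = self.frame_interval_s[channel]
        n = int(np.floor(self.duration_s / dt)) + 1
        return np.arange(n) * dt

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class KineticsConfig:
    """Ribosome initiation/elongation and tether binding kinetics.

    The reporter ORF is 1885 aa with an N-terminal epitope cassette; a
    ribosome's contribution to the translation signal ramps linearly while it
    traverses the epitope region and saturates at 1 beyond it.  Initiation is
    a Poisson process that can be gated: a hard stop at ``silencing_time_s``
    (runoff assays), an exponential decline at ``init_decay_rate_per_s``
    (gradual silencing), or an explicit on/off ``burst_schedule``.
    """

    orf_length_aa: int = 1885
    epitope_region_end_aa: int = 318
    init_rate_per_s: float = 1.0 / 30.0
    elongation_rate_aa_s: float = 2.0
    silencing_time_s: Optional[float] = None
    init_decay_rate_per_s: float = 0.0
    burst_schedule: Optional[Sequence[Tuple[float, float]]] = None
    n_tether_sites: int = 15
    tether_on_rate_per_s: float = 0.0
    tether_off_rate_per_s: float = 0.0
    # start with the steady-state ribosome load already on the mRNA
    preload_steady_state: bool = True

    def __post_init__(self):
        if self.orf_length_aa <= 0:
            raise ValueError("orf_length_aa must be positive")
        if not (0 < self.epitope_region_end_aa <= self.orf_length_aa):
            raise ValueError("epitope_region_end_aa must lie in (0, orf_length_aa]")
        if self.init_rate_per_s < 0:
            raise ValueError("init_rate_per_s must be non-negative")
        if self.elongation_rate_aa_s <= 0:
            raise ValueError("elongation_rate_aa_s must be positive")
        if self.init_decay_rate_per_s < 0:
            raise ValueError("init_decay_rate_per_s must be non-negative")
        if self.n_tether_sites < 0:
            raise ValueError("n_tether_sites must be >= 0")
        if self.tether_on_rate_per_s < 0 or self.tether_off_rate_per_s < 0:
            raise ValueError("tether rates must be non-negative")
        if self.burst_schedule is not None:
            sched = [(float(a), float(b)) for a, b in self.burst_schedule]
            prev_end = -float("inf")
            for on, off in sched:
                if not (on < off):
                    raise ValueError("burst intervals must satisfy on < off")
                if on < prev_end:
                    raise ValueError("burst intervals must be disjoint and ordered")
                prev_end = off
            self.burst_schedule = sched

    def to_dict(self) -> dict:
        return asdict(self)
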