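"""Synthetic three-color live-cell movie generation with ground truth.

The simulator emulates the statistical structure the downstream analysis
assumes: reporter mRNAs diffusing freely in the imaging field, a translation
signal driven by ribosomes that initiate stochastically and elongate
deterministically along the ORF, a tethering signal from a birth-death
process on a fixed number of stem-loop sites, per-exposure photobleaching,
staggered channel sampling, Poisson/Gaussian camera noise, and an optional
projective inter-camera offset.  Every stochastic layer exports its ground
truth so detection, tracking, quantification and kinetics can each be tested
against what was actually simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import erf

from tnt.config import CHANNELS, KineticsConfig, SimulationConfig
from tnt.stack import ImageStack

TRUTH_COLUMNS = [
    "molecule_id",
    "time_s",
    "x_px",
    "y_px",
    "z_plane",
    "n_ribosomes",
    "translation_signal",
    "tether_count",
    "mrna_signal",
]


@dataclass
class SimulationTruth:
    """Ground truth for one simulated movie."""

    config: SimulationConfig
    times: np.ndarray  # union sampling grid, seconds
    positions: np.ndarray  # (n_mrna, T, 3): x_px, y_px, z_plane (continuous)
    kinetics: Optional[KineticsConfig] = None
    # ribosome_positions[m][t] is the array of codon positions on mRNA m at times[t]
    ribosome_positions: Optional[list] = None
    translation_signal: Optional[np.ndarray] = None  # (n_mrna, T), epitope units
    tether_count: Optional[np.ndarray] = None  # (n_mrna, T), integer
    mrna_signal: Optional[np.ndarray] = None  # (n_mrna, T), probe units

    @property
    def n_mrna(self) -> int:
        return self.positions.shape[0]

    def n_ribosomes(self) -> np.ndarray:
        if self.ribosome_positions is None:
            raise ValueError("signals not simulated yet")
        return np.array(
            [[len(r) for r in per_mrna] for per_mrna in self.ribosome_positions]
        )


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold coordinates back into [lo, hi] (specular reflection at both walls)."""
    if hi <= lo:
        raise ValueError("degenerate reflection interval")
    width = hi - lo
    y = np.mod(x - lo, 2.0 * width)
    y = np.where(y > width, 2.0 * width - y, y)
    return y + lo


def simulate_trajectories(config: SimulationConfig) -> SimulationTruth:
    """Brownian trajectories for all mRNAs on the union sampling grid.

    Displacements per axis are Gaussian with SD sqrt(2 D dt); lateral
    coordinates are in pixels, the axial coordinate in (continuous) z-plane
    units.  Trajectories reflect at the field boundaries.
    """
    rng_traj = np.random.default_rng(
        np.random.SeedSequence(config.rng_seed).spawn(3)[0]
    )
    times = config.sample_times
    n_t = len(times)
    ny, nx = config.field_size_px
    px_um = config.pixel_size_nm / 1000.0
    z_um = config.z_step_nm / 1000.0

    pos = np.empty((config.n_mrna, n_t, 3))
    if config.n_mrna == 0:
        return SimulationTruth(config=config, times=times, positions=pos)

    pos[:, 0, 0] = rng_traj.uniform(0, nx - 1, size=config.n_mrna)
    pos[:, 0, 1] = rng_traj.uniform(0, ny - 1, size=config.n_mrna)
    pos[:, 0, 2] = rng_traj.uniform(0, config.n_z_planes - 1, size=config.n_mrna)

    d = config.diffusion_coeff_um2_s
    for t in range(1, n_t):
        dt = times[t] - times[t - 1]
        sd_um = np.sqrt(2.0 * d * dt)
        step = rng_traj.normal(0.0, 1.0, size=(config.n_mrna, 3))
        step[:, 0] *= sd_um / px_um
        step[:, 1] *= sd_um / px_um
        step[:, 2] *= sd_um / z_um
        raw = pos[:, t - 1] + step
        pos[:, t, 0] = _reflect(raw[:, 0], 0.0, nx - 1.0)
        pos[:, t, 1] = _reflect(raw[:, 1], 0.0, ny - 1.0)
        if config.n_z_planes > 1:
            pos[:, t, 2] = _reflect(raw[:, 2], 0.0, config.n_z_planes - 1.0)
        else:
            pos[:, t, 2] = 0.0

    return SimulationTruth(config=config, times=times, positions=pos)


def ribosome_signal(positions_aa: np.ndarray, epitope_end_aa: float) -> float:
    """Epitope-weighted translation signal of a set of ribosome positions.

    Each ribosome contributes min(position, E)/E: a linear ramp while it
    traverses the N-terminal epitope cassette, saturating at 1 past it.
    """
    p = np.asarray(positions_aa, dtype=float)
    if p.size == 0:
        return 0.0
    return float(np.sum(np.minimum(p, epitope_end_aa) / epitope_end_aa))


def _initiation_gate(kin: KineticsConfig, t: float) -> float:
    """Relative initiation rate (0..1) at time t."""
    if kin.burst_schedule is not None:
        for on, off in kin.burst_schedule:
            if on <= t < off:
                return 1.0
        return 0.0
    if kin.silencing_time_s is not None and t >= kin.silencing_time_s:
        return 0.0
    if kin.init_decay_rate_per_s > 0:
        return float(np.exp(-kin.init_decay_rate_per_s * t))
    return 1.0


def _sample_initiations(kin: KineticsConfig, t_end: float, rng) -> np.ndarray:
    """Initiation times on [0, t_end) by thinning a homogeneous Poisson process."""
    if kin.init_rate_per_s <= 0:
        return np.empty(0)
    n = rng.poisson(kin.init_rate_per_s * t_end)
    cand = np.sort(rng.uniform(0.0, t_end, size=n))
    keep = rng.uniform(size=n) < np.array([_initiation_gate(kin, t) for t in cand])
    return cand[keep]


def _tether_trace(kin: KineticsConfig, times: np.ndarray, rng) -> np.ndarray:
    """Birth-death occupancy of the tether sites, sampled on `times` (Gillespie)."""
    n_sites = kin.n_tether_sites
    out = np.zeros(len(times), dtype=int)
    if n_sites == 0 or (kin.tether_on_rate_per_s == 0 and kin.tether_off_rate_per_s == 0):
        return out
    t, n, idx = 0.0, 0, 0
    t_end = times[-1]
    while idx < len(times):
        rate_on = kin.tether_on_rate_per_s * (n_sites - n)
        rate_off = kin.tether_off_rate_per_s * n
        total = rate_on + rate_off
        t_next = t + rng.exponential(1.0 / total) if total > 0 else np.inf
        while idx < len(times) and times[idx] < t_next:
            out[idx] = n
            idx += 1
        if t_next > t_end or not np.isfinite(t_next):
            break
        t = t_next
        n += 1 if rng.uniform() * total < rate_on else -1
    return out


def simulate_signals(
    truth: SimulationTruth,
    kin: KineticsConfig,
    config: Optional[SimulationConfig] = None,
    preloaded_positions: Optional[Sequence[np.ndarray]] = None,
) -> SimulationTruth:
    """Fill ribosome, translation, tether, and mRNA signals into `truth`.

    Ribosomes initiate as a (gated) Poisson process, advance deterministically
    at the elongation rate and leave the transcript at the ORF end.  If
    ``preloaded_positions`` is given it overrides the steady-state preload:
    entry m is the array of ribosome codon positions on mRNA m at t=0.
    """
    config = config or truth.config
    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(3)[1])
    times = truth.times
    n_mrna = truth.n_mrna
    L = float(kin.orf_length_aa)
    E = float(kin.epitope_region_end_aa)
    v = kin.elongation_rate_aa_s

    ribo_pos: list = []
    trans = np.zeros((n_mrna, len(times)))
    tether = np.zeros((n_mrna, len(times)), dtype=int)
    for m in range(n_mrna):
        if preloaded_positions is not None:
            x0 = np.asarray(preloaded_positions[m], dtype=float)
        elif kin.preload_steady_state and kin.init_rate_per_s > 0:
            n0 = rng.poisson(kin.init_rate_per_s * L / v)
            x0 = np.sort(rng.uniform(0.0, L, size=n0))
        else:
            x0 = np.empty(0)
        t_init = np.concatenate([-x0 / v, _sample_initiations(kin, times[-1] + 1e-9, rng)])
        t_init.sort()

        per_time = []
        for i, t in enumerate(times):
            p = v * (t - t_init[t_init <= t])
            p = np.sort(p[p < L])
            per_time.append(p)
            trans[m, i] = ribosome_signal(p, E)
        ribo_pos.append(per_time)
        tether[m] = _tether_trace(kin, times, rng)

    truth.kinetics = kin
    truth.ribosome_positions = ribo_pos
    truth.translation_signal = trans
    truth.tether_count = tether
    truth.mrna_signal = np.ones((n_mrna, len(times)))
    return truth


# ---------------------------------------------------------------------------
# rendering


def _pixel_gaussian_1d(n: int, center: float, sigma: float) -> np.ndarray:
    """Integral of a unit Gaussian over each pixel [i-0.5, i+0.5)."""
    edges = np.arange(n + 1) - 0.5
    cdf = 0.5 * (1.0 + erf((edges - center) / (sigma * np.sqrt(2.0))))
    return np.diff(cdf)


def _axial_weights(n_planes: int, z_center: float, sigma_planes: float) -> np.ndarray:
    z = np.arange(n_planes, dtype=float)
    w = np.exp(-0.5 * ((z - z_center) / sigma_planes) ** 2)
    s = w.sum()
    return w / s if s > 0 else w


def _render_emitter(
    volume: np.ndarray, x: float, y: float, z: float, photons: float,
    sigma_xy: float, sigma_z_planes: float,
):
    """Add one 3-D Gaussian emitter (photon-conserving) into (Z, Y, X) volume."""
    if photons <= 0:
        return
    nz, ny, nx = volume.shape
    half = int(np.ceil(5 * sigma_xy)) + 1
    x0, x1 = max(0, int(np.floor(x)) - half), min(nx, int(np.ceil(x)) + half + 1)
    y0, y1 = max(0, int(np.floor(y)) - half), min(ny, int(np.ceil(y)) + half + 1)
    if x0 >= x1 or y0 >= y1:
        return
    gx = _pixel_gaussian_1d(x1 - x0, x - x0, sigma_xy)
    gy = _pixel_gaussian_1d(y1 - y0, y - y0, sigma_xy)
    wz = _axial_weights(nz, z, sigma_z_planes)
    volume[:, y0:y1, x0:x1] += (
        photons * wz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    )


def _channel_photon_scale(config: SimulationConfig, channel: str) -> float:
    return {
        "mrna": config.photons_per_mrna_probe,
        "translation": config.photons_per_translation_unit,
        "tether": config.photons_per_tether_unit,
    }[channel]


def render_movie(
    truth: SimulationTruth, config: Optional[SimulationConfig] = None, noise: bool = True
) -> ImageStack:
    """Render the simulated molecules into a T,Z,C,Y,X movie.

    Channels are exposed only on their own time grids; union-grid frames at
    which a channel was not exposed are NaN.  Pixel values follow the camera
    model Poisson(signal + background) * gain + N(0, read_noise); with
    ``noise=False`` the noiseless expectation (signal + background) * gain is
    returned instead.
    """
    config = config or truth.config
    if truth.translation_signal is None:
        raise ValueError("run simulate_signals before render_movie")
    times = truth.times
    ny, nx = config.field_size_px
    n_vox = len(times) * config.n_z_planes * len(CHANNELS) * ny * nx
    if n_vox > config.max_voxels:
        raise MemoryError(
            f"configuration would allocate {n_vox} voxels "
            f"(> max_voxels={config.max_voxels}); reduce field/duration"
        )

    rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(3)[2])
    data = np.full((len(times), config.n_z_planes, len(CHANNELS), ny, nx),
                   np.nan, dtype=np.float32)
    signals = {
        "mrna": truth.mrna_signal,
        "translation": truth.translation_signal,
        "tether": truth.tether_count.astype(float),
    }
    offset = None
    if config.camera_offset_matrix is not None:
        offset = np.asarray(config.camera_offset_matrix, dtype=float)
        if offset.shape != (3, 3) or abs(np.linalg.det(offset)) < 1e-12:
            raise ValueError("camera_offset_matrix must be a nonsingular 3x3 matrix")

    for ci, channel in enumerate(CHANNELS):
        ch_times = config.channel_times(channel)
        frame_idx = np.searchsorted(times, ch_times)
        frame_idx = frame_idx[frame_idx < len(times)]
        scale = _channel_photon_scale(config, channel)
        bleach = config.bleach_rate_per_exposure[channel]
        sigma = config.psf_sigma_px[channel]
        sigma_z = config.axial_sigma_z_steps
        for k, fi in enumerate(frame_idx):
            vol = np.zeros((config.n_z_planes, ny, nx), dtype=float)
            fade = np.exp(-bleach * k)
            for m in range(truth.n_mrna):
                x, y, z = truth.positions[m, fi]
                if offset is not None and channel in ("translation", "tether"):
                    hx = offset @ np.array([x, y, 1.0])
                    x, y = hx[0] / hx[2], hx[1] / hx[2]
                photons = scale * signals[channel][m, fi] * fade
                _render_emitter(vol, x, y, z, photons, sigma, sigma_z)
            vol += config.background_level
            if noise:
                frame = (rng.poisson(vol).astype(float) * config.camera_gain
                         + rng.normal(0.0, config.read_noise_sd, size=vol.shape))
            else:
                frame = vol * config.camera_gain
            data[fi, :, ci] = frame.astype(np.float32)

    return ImageStack(
        data=data,
        pixel_size_nm=config.pixel_size_nm,
        z_step_nm=config.z_step_nm,
        channels=CHANNELS,
        frame_times_s=times,
        channel_times_s={c: config.channel_times(c) for c in CHANNELS},
    )


# ---------------------------------------------------------------------------
# fiducial beads


def generate_bead_pair(
    transform_matrix,
    n_beads: int = 20,
    jitter_sd_px: float = 0.0,
    field_size_px=(256, 256),
    rng_seed: int = 0,
    psf_sigma_px: float = 1.3,
    photons: float = 2000.0,
):
    """Fiducial bead fields related by a known projective transform.

    Returns ``(points_a, points_b, stack_a, stack_b)``: (n, 2) xy point sets
    with B = transform(A) (+ optional localization jitter) and single-plane,
    single-channel rendered bead images of both sets.
    """
    h = np.asarray(transform_matrix, dtype=float)
    if h.shape != (3, 3) or abs(np.linalg.det(h)) < 1e-12:
        raise ValueError("transform must be a nonsingular 3x3 homogeneous matrix")
    rng = np.random.default_rng(rng_seed)
    ny, nx = field_size_px
    a = np.column_stack([
        rng.uniform(0.15 * nx, 0.85 * nx, size=n_beads),
        rng.uniform(0.15 * ny, 0.85 * ny, size=n_beads),
    ])
    hom = np.column_stack([a, np.ones(n_beads)]) @ h.T
    b = hom[:, :2] / hom[:, 2:3]
    if jitter_sd_px > 0:
        b = b + rng.normal(0.0, jitter_sd_px, size=b.shape)

    stacks = []
    for pts in (a, b):
        img = np.zeros((1, ny, nx))
        for x, y in pts:
            _render_emitter(img, x, y, 0.0, photons, psf_sigma_px, 1.0)
        stacks.append(ImageStack(data=img[None, :, None, :, :], channels=("mrna",)))
    return a, b, stacks[0], stacks[1]


# ---------------------------------------------------------------------------
# truth export / import


def export_truth(truth: SimulationTruth, path) -> None:
    """Write ground truth as plain tables under directory `path`.

    ``truth.csv`` has one row per molecule per time point; ``ribosomes.csv``
    holds the per-ribosome codon positions; ``config.json`` the configuration
    snapshot.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if truth.translation_signal is None:
        raise ValueError("signals not simulated; nothing to export")
    n_ribo = truth.n_ribosomes()
    rows = []
    for m in range(truth.n_mrna):
        for i, t in enumerate(truth.times):
            rows.append((
                m, t,
                truth.positions[m, i, 0], truth.positions[m, i, 1],
                truth.positions[m, i, 2],
                n_ribo[m, i], truth.translation_signal[m, i],
                truth.tether_count[m, i], truth.mrna_signal[m, i],
            ))
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path / "truth.csv", index=False)

    ribo_rows = []
    for m in range(truth.n_mrna):
        for i, t in enumerate(truth.times):
            for j, p in enumerate(truth.ribosome_positions[m][i]):
                ribo_rows.append((m, t, j, p))
    pd.DataFrame(
        ribo_rows, columns=["molecule_id", "time_s", "ribosome_index", "position_aa"]
    ).to_csv(path / "ribosomes.csv", index=False)

    with open(path / "config.json", "w") as fh:
        json.dump(
            {"simulation": truth.config.to_dict(), "kinetics": truth.kinetics.to_dict()},
            fh, indent=2,
        )


def import_truth(path) -> SimulationTruth:
    """Re-read a truth directory written by :func:`export_truth`."""
    path = Path(path)
    try:
        df = pd.read_csv(path / "truth.csv")
    except Exception as exc:  # noqa: BLE001 - report file-level failures with path
        raise ValueError(f"cannot read {path / 'truth.csv'}: {exc}") from exc
    missing = [c for c in TRUTH_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"truth.csv is missing column(s): {', '.join(missing)}")
    bad = df[TRUTH_COLUMNS].isna()
    if bad.any().any():
        rows = (np.nonzero(bad.any(axis=1).to_numpy())[0] + 2).tolist()
        raise ValueError(f"truth.csv has malformed values at file row(s) {rows[:10]}")

    with open(path / "config.json") as fh:
        cfg = json.load(fh)
    sim = cfg["simulation"]
    sim["field_size_px"] = tuple(sim["field_size_px"])
    if sim.get("camera_offset_matrix") is not None:
        sim["camera_offset_matrix"] = [list(r) for r in sim["camera_offset_matrix"]]
    kin_d = cfg["kinetics"]
    if kin_d.get("burst_schedule") is not None:
        kin_d["burst_schedule"] = [tuple(x) for x in kin_d["burst_schedule"]]
    config = SimulationConfig(**sim)
    kin = KineticsConfig(**kin_d)

    mols = np.sort(df["molecule_id"].unique())
    times = np.sort(df["time_s"].unique())
    n, n_t = len(mols), len(times)
    df = df.sort_values(["molecule_id", "time_s"])
    pos = df[["x_px", "y_px", "z_plane"]].to_numpy().reshape(n, n_t, 3)
    trans = df["translation_signal"].to_numpy().reshape(n, n_t)
    teth = df["tether_count"].to_numpy().reshape(n, n_t).astype(int)
    mrna = df["mrna_signal"].to_numpy().reshape(n, n_t)

    ribo = [[np.empty(0) for _ in range(n_t)] for _ in range(n)]
    rdf = pd.read_csv(path / "ribosomes.csv")
    for rcol in ("molecule_id", "time_s", "ribosome_index", "position_aa"):
        if rcol not in rdf.columns:
            raise ValueError(f"ribosomes.csv is missing column(s): {rcol}")
    if len(rdf):
        t_index = {t: i for i, t in enumerate(times)}
        m_index = {m: i for i, m in enumerate(mols)}
        for (m, t), grp in rdf.groupby(["molecule_id", "time_s"]):
            ribo[m_index[m]][t_index[t]] = (
                grp.sort_values("ribosome_index")["position_aa"].to_numpy()
            )

    return SimulationTruth(
        config=config, times=times, positions=pos, kinetics=kin,
        ribosome_positions=ribo, translation_signal=trans,
        tether_count=teth, mrna_signal=mrna,
    )
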