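"""Time-series analyses: ribosome runoff, photobleaching, track averaging.

After translation initiation is blocked (Harringtonine, or silencing by a
tethered repressor), elongating ribosomes run off the transcript one by one
and the translation signal decays.  The normalized per-cell runoff curve is
fit to the phenomenological model

    I(v, t) = 1/2 * (1 - tanh(2 v (t - t_half) / L))

where L is the ORF length in amino acids (1885 aa for the reporter used
here), v the average elongation rate (aa/s), and t_half the halftime at
which I = 0.5.  The slope of the model at t_half is -v/L, so the fitted v
estimates the total elongation time L/v.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

ORF_LENGTH_AA = 1885.0  # reporter ORF length


@dataclass
class RunoffFit:
    v_aa_s: float
    t_half_s: float
    L_aa: float
    stderr_v: float
    stderr_t_half: float
    rss: float
    n_points: int


@dataclass
class BleachModel:
    amplitude: float
    decay_rate_per_frame: float

    def __post_init__(self):
        if self.amplitude <= 0:
            raise ValueError("fitted bleach amplitude must be positive")
        if self.decay_rate_per_frame < 0:
            raise ValueError("decay rate must be non-negative")

    def __call__(self, k: np.ndarray) -> np.ndarray:
        """Model normalized to 1 at frame 0."""
        return np.exp(-self.decay_rate_per_frame * np.asarray(k, dtype=float))


def runoff_model(t, v: float, t_half: float, L: float = ORF_LENGTH_AA):
    """Normalized runoff intensity; 0.5 at t = t_half, slope -v/L there."""
    if v <= 0 or L <= 0:
        raise ValueError("v and L must be positive")
    t = np.asarray(t, dtype=float)
    out = 0.5 * (1.0 - np.tanh(2.0 * v * (t - t_half) / L))
    return float(out) if out.ndim == 0 else out


def fit_photobleach(trace: Sequence[float], frames: Optional[Sequence[float]] = None
                    ) -> BleachModel:
    """Least-squares single-exponential fit of a whole-cell intensity trace."""
    y = np.asarray(trace, dtype=float)
    if len(y) < 5:
        raise ValueError("photobleach fit needs at least 5 time points")
    k = np.arange(len(y), dtype=float) if frames is None else np.asarray(frames, float)
    a0 = max(y[0], np.abs(y).max() * 0.5, 1e-12)
    with np.errstate(over="ignore"):
        popt, _ = optimize.curve_fit(
            lambda x, a, r: a * np.exp(-r * x), k, y,
            p0=[a0, 1e-3], bounds=([1e-12, 0.0], [np.inf, np.inf]), maxfev=10_000,
        )
    return BleachModel(amplitude=float(popt[0]), decay_rate_per_frame=float(popt[1]))


def correct_photobleach(trace: Sequence[float], model: BleachModel,
                        frames: Optional[Sequence[float]] = None) -> np.ndarray:
    """Divide a trace by the bleach model (normalized to 1 at frame 0)."""
    y = np.asarray(trace, dtype=float)
    k = np.arange(len(y), dtype=float) if frames is None else np.asarray(frames, float)
    return y / model(k)


def normalize_runoff(times_s: Sequence[float], trace: Sequence[float],
                     baseline_window_s: Tuple[float, float] = (2400.0, 3600.0)
                     ) -> np.ndarray:
    """Normalize a runoff curve to start at 1 and plateau at 0.

    The mean of the first three points maps to 1; the mean over the late
    baseline window (default 40-60 min) is subtracted so persistent
    artifactual signal plateaus at 0.
    """
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(trace, dtype=float)
    if len(t) != len(y) or len(y) < 4:
        raise ValueError("times and trace must match and hold >= 4 points")
    lo, hi = baseline_window_s
    in_base = (t >= lo) & (t <= hi)
    if not in_base.any():
        raise ValueError(f"trace does not cover the baseline window [{lo}, {hi}] s")
    first3 = float(np.mean(y[:3]))
    baseline = float(np.mean(y[in_base]))
    if first3 <= baseline:
        raise ValueError(
            "degenerate runoff curve: mean of first three points "
            f"({first3:.4g}) does not exceed the baseline ({baseline:.4g})"
        )
    return (y - baseline) / (first3 - baseline)


def fit_runoff(times_s: Sequence[float], normalized_trace: Sequence[float],
               L: float = ORF_LENGTH_AA, n_fit_points: int = 30) -> RunoffFit:
    """Fit (v, t_half) of the runoff model to the first `n_fit_points` points.

    Bounds: v in (0, 50] aa/s, t_half in [0, last fitted time].  Initial
    guess: t_half from the first 0.5 downward crossing (linear
    interpolation), v = L / (2 t_half) clipped into bounds.
    """
    t = np.asarray(times_s, dtype=float)[:n_fit_points]
    y = np.asarray(normalized_trace, dtype=float)[:n_fit_points]
    ok = np.isfinite(t) & np.isfinite(y)
    t, y = t[ok], y[ok]
    if len(t) < 10:
        raise ValueError(f"runoff fit needs >= 10 usable points, got {len(t)}")
    if np.ptp(y) < 1e-12:
        raise RuntimeError("runoff fit did not converge: trace is constant "
                           "(no decay to fit)")

    t_end = float(t[-1])
    th0 = silencing_halftime(t, y)
    if th0 is None or not np.isfinite(th0):
        th0 = 0.5 * t_end
    th0 = float(np.clip(th0, 0.0, t_end))
    v0 = float(np.clip(L / (2.0 * max(th0, 1e-9)), 1e-3, 50.0))

    try:
        popt, pcov = optimize.curve_fit(
            lambda x, v, th: runoff_model(x, v, th, L), t, y,
            p0=[v0, th0], bounds=([1e-9, 0.0], [50.0, t_end]), maxfev=20_000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"runoff fit did not converge (p0=(v={v0:.3g}, t_half={th0:.3g}), "
            f"n={len(t)}): {exc}"
        ) from exc
    resid = y - runoff_model(t, popt[0], popt[1], L)
    err = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan, np.nan]
    return RunoffFit(
        v_aa_s=float(popt[0]), t_half_s=float(popt[1]), L_aa=float(L),
        stderr_v=float(err[0]), stderr_t_half=float(err[1]),
        rss=float(np.sum(resid**2)), n_points=len(t),
    )


def average_renormalized_tracks(
    traces: Sequence[Tuple[Sequence[float], Sequence[float]]],
    renorm_points: int = 4,
    grid: Optional[np.ndarray] = None,
    n_boot: int = 1000,
    rng_seed: int = 0,
):
    """Equal-weight mean of per-track signals renormalized to their start.

    Each (times, values) trace is divided by the mean of its first
    ``renorm_points`` points (traces with a non-positive renormalization mean
    are excluded with a warning), resampled onto a common grid by linear
    interpolation (NaN outside a trace's support), and averaged with equal
    weight per track.  A bootstrap over tracks gives a pointwise 95% CI.

    Returns (grid, mean, ci_low, ci_high).
    """
    import warnings

    if len(traces) < 2:
        raise ValueError("averaging needs >= 2 traces")
    kept = []
    for t, y in traces:
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        denom = float(np.mean(y[:renorm_points]))
        if denom <= 0:
            warnings.warn("excluding trace with non-positive renormalization mean",
                          stacklevel=2)
            continue
        kept.append((t, y / denom))
    if len(kept) < 2:
        raise ValueError("fewer than 2 usable traces after renormalization")

    if grid is None:
        grid = np.unique(np.concatenate([t for t, _ in kept]))
    mat = np.full((len(kept), len(grid)), np.nan)
    for i, (t, y) in enumerate(kept):
        inside = (grid >= t[0]) & (grid <= t[-1])
        mat[i, inside] = np.interp(grid[inside], t, y)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(mat, axis=0)
        rng = np.random.default_rng(rng_seed)
        boots = np.empty((n_boot, len(grid)))
        for b in range(n_boot):
            idx = rng.integers(0, len(kept), size=len(kept))
            boots[b] = np.nanmean(mat[idx], axis=0)
        lo = np.nanpercentile(boots, 2.5, axis=0)
        hi = np.nanpercentile(boots, 97.5, axis=0)
    return grid, mean, lo, hi


def silencing_halftime(times_s: Sequence[float], curve: Sequence[float]
                       ) -> Optional[float]:
    """Time of the first downward 0.5-crossing (linear interpolation)."""
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(curve, dtype=float)
    for i in range(1, len(y)):
        if y[i - 1] >= 0.5 > y[i]:
            if y[i - 1] == y[i]:
                return float(t[i])
            frac = (y[i - 1] - 0.5) / (y[i - 1] - y[i])
            return float(t[i - 1] + frac * (t[i] - t[i - 1]))
    return None


class TrackClass(enum.Enum):
    RUNOFF = "runoff"
    BURST = "burst"
    LOW_OFF = "low_off"
    SPLIT = "split"
    UNCLASSIFIED = "unclassified"


def _burst_excursion(on: np.ndarray, min_on: int = 2, min_silent: int = 2) -> bool:
    """At least one off->on->off excursion of >= min_on positive frames
    following a silent stretch of >= min_silent frames."""
    i = 0
    n = len(on)
    while i < n:
        if not on[i]:
            j = i
            while j < n and not on[j]:
                j += 1
            silent_len = j - i
            k = j
            while k < n and on[k]:
                k += 1
            on_len = k - j
            if silent_len >= min_silent and on_len >= min_on and k < n:
                return True
            i = k
        else:
            i += 1
    return False


def classify_track(
    translation_trace: Sequence[float],
    translation_positive: Sequence[bool],
    mrna_xy: Optional[np.ndarray] = None,
    translation_xy: Optional[np.ndarray] = None,
    max_step_px: float = 10.0,
    low_fraction: float = 0.10,
    min_len: int = 5,
    alpha: float = 0.05,
) -> TrackClass:
    """Phenotype of one tracked mRNA's translation behavior.

    Precedence: split (translation and mRNA centroids separate by more than
    ``max_step_px`` while both persist) > low_off (translation positive in
    fewer than 10% of frames) > burst (an off->on->off excursion of >= 2
    positive frames after a silent stretch) > runoff (significant monotone
    decline of the translation trace; one-sided Mann-Kendall via Kendall's
    tau against time at alpha).  Tracks matching no rule, or shorter than
    ``min_len``, are unclassified.
    """
    y = np.asarray(translation_trace, dtype=float)
    on = np.asarray(translation_positive, dtype=bool)
    if len(y) < min_len:
        return TrackClass.UNCLASSIFIED

    if mrna_xy is not None and translation_xy is not None:
        a = np.asarray(mrna_xy, dtype=float)
        b = np.asarray(translation_xy, dtype=float)
        n = min(len(a), len(b))
        if n > 0:
            sep = np.linalg.norm(a[:n] - b[:n], axis=1)
            if np.any(sep > max_step_px):
                return TrackClass.SPLIT

    if on.mean() < low_fraction:
        return TrackClass.LOW_OFF
    if _burst_excursion(on):
        return TrackClass.BURST
    res = stats.kendalltau(np.arange(len(y)), y, alternative="less")
    if np.isfinite(res.pvalue) and res.pvalue < alpha and res.statistic < 0:
        return TrackClass.RUNOFF
    return TrackClass.UNCLASSIFIED
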