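"""Scalar and summary metrics.

Degree of labeling of a dye-conjugated Fab from absorbance spectra, nuclear
accumulation of a reporter between an early and a late time point, the
normalized mRNA clustering curve, and the Spearman correlation between
tethering and translation intensities.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class LabelingMeasurement:
    """Absorbance measurement of a dye-labeled Fab.

    Defaults are for Cy3-labeled Fab: extinction coefficients 70,000 (Fab at
    280 nm) and 150,000 (dye at its peak) M^-1 cm^-1, and a dye correction
    factor of 0.08 (the dye's own A280 as a fraction of its peak absorbance).
    """

    a280: float
    a_dye: float
    epsilon_fab: float = 70_000.0
    epsilon_dye: float = 150_000.0
    cf: float = 0.08

    def __post_init__(self):
        for name in ("a280", "a_dye", "epsilon_fab", "epsilon_dye", "cf"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class AccumulationMeasurement:
    i_nuc_early: float
    i_nuc_late: float
    i_cyto_early: float
    i_cyto_late: float

    def __post_init__(self):
        for name in ("i_nuc_early", "i_nuc_late", "i_cyto_early", "i_cyto_late"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


RELABEL_DOL_THRESHOLD = 0.8  # Fabs below this are re-labeled to reach DOL ~1


def degree_of_labeling(m: LabelingMeasurement) -> float:
    """Average number of dye molecules per Fab.

    DOL = (eps_Fab / eps_dye) * 1 / (A280/A_dye - CF).  The correction
    factor removes the dye's own contribution to A280.
    """
    ratio = m.a280 / m.a_dye
    if ratio <= m.cf:
        raise ValueError(
            f"A280/A_dye = {ratio:.4g} must exceed the dye correction factor "
            f"{m.cf:.4g} for a finite positive DOL"
        )
    return (m.epsilon_fab / m.epsilon_dye) / (ratio - m.cf)


def needs_relabeling(dol: float) -> bool:
    return dol < RELABEL_DOL_THRESHOLD


def nuclear_accumulation(m: AccumulationMeasurement) -> float:
    """Fold nuclear enrichment relative to the cytoplasmic change:
    (I_nuc_late / I_nuc_early) / (I_cyto_late / I_cyto_early)."""
    return (m.i_nuc_late / m.i_nuc_early) / (m.i_cyto_late / m.i_cyto_early)


def clustering_curve(foci: pd.DataFrame, n_boot: int = 1000, rng_seed: int = 0,
                     per_cell: bool = False) -> pd.DataFrame:
    """Mean per-focus mRNA intensity over time, normalized to 1 at t0.

    `foci` needs columns time_s and intensity (and cell_id when
    ``per_cell=True``, which averages per cell first instead of pooling all
    foci with equal weight).  Returns time_s, mean_norm, ci_low, ci_high,
    n_foci with a bootstrap 95% CI over foci (or cells).
    """
    required = {"time_s", "intensity"} | ({"cell_id"} if per_cell else set())
    missing = required - set(foci.columns)
    if missing:
        raise ValueError(f"foci table is missing column(s): {sorted(missing)}")
    times = np.sort(foci["time_s"].unique())
    if len(times) == 0 or not len(foci[foci["time_s"] == times[0]]):
        raise ValueError("no detected foci at the first time point")
    rng = np.random.default_rng(rng_seed)

    def units_at(t):
        sub = foci[foci["time_s"] == t]
        if per_cell:
            return sub.groupby("cell_id")["intensity"].mean().to_numpy()
        return sub["intensity"].to_numpy()

    ref = float(np.mean(units_at(times[0])))
    rows = []
    for t in times:
        vals = units_at(t)
        if len(vals) == 0:
            rows.append((t, np.nan, np.nan, np.nan, 0))
            continue
        mean_norm = float(np.mean(vals)) / ref
        boots = np.array([
            np.mean(rng.choice(vals, size=len(vals), replace=True)) / ref
            for _ in range(n_boot)
        ])
        rows.append((t, mean_norm,
                     float(np.percentile(boots, 2.5)),
                     float(np.percentile(boots, 97.5)), len(vals)))
    return pd.DataFrame(rows, columns=["time_s", "mean_norm", "ci_low",
                                       "ci_high", "n_foci"])


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rho with average ranks for ties (Pearson on ranks)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    if denom == 0:
        return np.nan
    return float(np.sum(rx * ry) / denom)


def tether_translation_correlation(
    tether_intensity, translation_intensity,
    exact: bool = False, min_points: int = 10,
) -> Tuple[Optional[float], Optional[float]]:
    """Spearman correlation between tethering and translation intensities.

    Default p-value uses the t-approximation on n-2 degrees of freedom; with
    ``exact=True`` (n <= 8) the two-sided p-value is computed by enumerating
    all rank permutations.  Constant input yields (None, None).
    """
    x = np.asarray(tether_intensity, dtype=float)
    y = np.asarray(translation_intensity, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    floor = 2 if exact else min_points
    if n < floor:
        raise ValueError(f"correlation needs >= {floor} paired points, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None, None

    if exact:
        if n > 8:
            raise ValueError("exact permutation p-value limited to n <= 8")
        rho_obs = _spearman_rho(x, y)
        count = 0
        for perm in permutations(range(n)):
            rho_p = _spearman_rho(x, y[list(perm)])
            if abs(rho_p) >= abs(rho_obs) - 1e-12:
                count += 1
        return rho_obs, count / factorial(n)

    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
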