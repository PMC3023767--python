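"""Persistent-random-walk analysis of 2D cell-centroid tracks.

MSD is estimated by the method of non-overlapping intervals: for lag
``t_n = n·Δt`` the track is partitioned from frame 0 into consecutive
disjoint segments of ``n`` frames and ``<d²(t_n)>`` is the mean squared
end-to-start displacement over those segments (remainder frames beyond
the last full segment are dropped).  Cell speed is
``S = sqrt(<d²(Δt)>)/Δt``.  MSD curves are fit to the persistent random
walk model

    <d²(t)> = 2 S² P [ t − P (1 − e^(−t/P)) ]

with S the RMS speed (µm/min) and P the persistence time (min); cells
with fit R² < 0.5 are excluded from condition means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "Track",
    "MSDCurve",
    "PRWFit",
    "msd_nonoverlapping",
    "cell_speed",
    "prw_msd",
    "fit_prw",
    "filter_and_average",
    "speed_vs_ligand",
]


@dataclass
class Track:
    """Centroid positions of one cell at equally spaced frames."""

    cell_id: str
    positions: np.ndarray  # (n_frames, 2) in µm
    dt: float  # frame interval, min
    condition: str = ""
    ligand_ug_per_ml: float = float("nan")
    excluded: bool = False  # divided or touched another cell

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (n_frames, 2) array")
        if self.positions.shape[0] < 3:
            raise ValueError("track must have at least 3 frames")
        if self.dt <= 0:
            raise ValueError("frame interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


@dataclass
class MSDCurve:
    """Non-overlapping-interval MSD of one track."""

    times: np.ndarray  # t_n = n·dt, min
    msd: np.ndarray  # µm²
    n_segments: np.ndarray  # disjoint segments averaged at each lag
    dt: float


@dataclass
class PRWFit:
    """Fitted persistent-random-walk parameters for one cell."""

    S: float  # µm/min
    P: float  # min
    r_squared: float
    converged: bool


def msd_nonoverlapping(track: Track) -> MSDCurve:
    """MSD by disjoint-segment averaging, lags n = 1 .. frames−1."""
    pos = track.positions
    n_disp = track.n_frames - 1
    times, msds, counts = [], [], []
    for n in range(1, n_disp + 1):
        k = n_disp // n
        if k < 1:
            break
        starts = np.arange(k) * n
        d = pos[starts + n] - pos[starts]
        msds.append(float(np.mean(np.sum(d * d, axis=1))))
        times.append(n * track.dt)
        counts.append(k)
    return MSDCurve(
        times=np.array(times), msd=np.array(msds), n_segments=np.array(counts), dt=track.dt
    )


def cell_speed(msd: MSDCurve) -> float:
    """RMS displacement over the shortest interval divided by Δt (µm/min)."""
    if msd.times.size == 0:
        raise ValueError("MSD curve has no intervals")
    return float(np.sqrt(msd.msd[0]) / msd.dt)


def prw_msd(t, S: float, P: float):
    """Persistent-random-walk model MSD, 2S²P[t − P(1 − e^(−t/P))].

    Evaluates stably in both limits: a Taylor branch is used for
    t/P < 1e−4 (→ S²t², the ballistic regime); for t ≫ P the expression
    approaches the diffusive 2S²Pt.
    """
    if P <= 0:
        raise ValueError("persistence time P must be > 0")
    t = np.asarray(t, dtype=float)
    x = t / P
    out = np.empty_like(x)
    small = x < 1e-4
    # bracket = t − P(1 − e^(−t/P)) = P(x + expm1(−x)); series where x is tiny
    xs = x[small]
    out[small] = (S * t[small]) ** 2 * (1.0 - xs / 3.0 + xs**2 / 12.0)
    xl = x[~small]
    out[~small] = 2.0 * S**2 * P * P * (xl + np.expm1(-xl))
    return out if out.ndim else float(out)


def fit_prw(
    msd: MSDCurve,
    max_interval_fraction: float = 0.5,
    min_segments: int = 2,
    init: tuple[float, float] | None = None,
) -> PRWFit:
    """Nonlinear least-squares fit of the PRW model to an MSD curve.

    Only lags with at least ``min_segments`` disjoint segments and within
    the first ``max_interval_fraction`` of available lags enter the fit.
    R² is computed on the fitted points.  Non-convergence (or fewer than
    4 usable points) yields ``converged=False`` with R² = −inf, which
    fails any downstream R² filter.
    """
    usable = msd.n_segments >= min_segments
    n_keep = max(4, int(np.ceil(usable.sum() * max_interval_fraction)))
    idx = np.flatnonzero(usable)[:n_keep]
    t, y = msd.times[idx], msd.msd[idx]
    if t.size < 4:
        return PRWFit(float("nan"), float("nan"), float("-inf"), False)

    if init is None:
        s0 = max(np.sqrt(y[0]) / msd.dt, 1e-6)
        p0 = float(np.median(t))
    else:
        s0, p0 = init
    lb = [1e-12, msd.dt / 100.0]
    ub = [np.inf, 100.0 * t[-1]]
    p0 = float(np.clip(p0, lb[1], ub[1]))

    def resid(theta):
        return prw_msd(t, theta[0], theta[1]) - y

    try:
        sol = least_squares(
            resid, x0=[s0, p0], bounds=(lb, ub), xtol=1e-12, ftol=1e-12, max_nfev=2000
        )
    except Exception:
        return PRWFit(float("nan"), float("nan"), float("-inf"), False)
    if not sol.success:
        return PRWFit(float("nan"), float("nan"), float("-inf"), False)
    s_hat, p_hat = float(sol.x[0]), float(sol.x[1])
    ss_res = float(np.sum(sol.fun**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else float("-inf"))
    return PRWFit(S=s_hat, P=p_hat, r_squared=r2, converged=True)


def filter_and_average(
    per_cell: pd.DataFrame,
    r2_min: float = 0.5,
    min_cells: int = 40,
) -> pd.DataFrame:
    """Condition-level mean speed ± SEM over cells passing the R² filter.

    ``per_cell`` needs columns ``condition``, ``speed_um_per_min`` and
    ``r_squared``; cells with R² < ``r2_min`` (strict) are dropped.  A
    ``low_n`` flag marks conditions with fewer survivors than
    ``min_cells`` (the study design called for at least 40).
    """
    required = {"condition", "speed_um_per_min", "r_squared"}
    missing = required - set(per_cell.columns)
    if missing:
        raise ValueError(f"per-cell table missing columns: {sorted(missing)}")
    kept = per_cell[per_cell["r_squared"] >= r2_min]
    if kept.empty:
        raise ValueError("no cells survive the R² filter")
    rows = []
    for cond, grp in kept.groupby("condition", sort=True):
        v = grp["speed_um_per_min"].to_numpy()
        n = v.size
        if n < min_cells:
            warnings.warn(f"condition {cond!r}: only {n} cells pass the R² filter")
        rows.append(
            {
                "condition": cond,
                "n_cells": n,
                "speed_mean": float(v.mean()),
                "speed_sem": float(v.std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan"),
                "low_n": n < min_cells,
            }
        )
    return pd.DataFrame(rows)


def speed_vs_ligand(summary: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Biphasic speed-vs-ligand profile and per-condition optimum.

    ``summary`` holds one row per (condition, ligand concentration) with
    columns ``condition``, ``ligand_ug_per_ml``, ``speed_mean``,
    ``speed_sem``, ``n_cells``.  Returns the sorted table and a
    per-condition frame listing the concentration(s) of maximum mean
    speed; ties report every tied concentration.  A ``shift_left`` flag
    on the table's attrs marks an acidic optimum below the neutral one
    when exactly two conditions are present.
    """
    required = {"condition", "ligand_ug_per_ml", "speed_mean"}
    missing = required - set(summary.columns)
    if missing:
        raise ValueError(f"summary missing columns: {sorted(missing)}")
    tab = summary.sort_values(["condition", "ligand_ug_per_ml"]).reset_index(drop=True)
    rows = []
    for cond, grp in tab.groupby("condition", sort=True):
        if grp["ligand_ug_per_ml"].nunique() < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 concentrations")
        peak = grp["speed_mean"].max()
        at = grp.loc[grp["speed_mean"] == peak, "ligand_ug_per_ml"].tolist()
        rows.append({"condition": cond, "argmax_ug_per_ml": at, "peak_speed": float(peak)})
    argmax = pd.DataFrame(rows)
    return tab, argmax


def detect_leftward_shift(argmax: pd.DataFrame, acidic: str, neutral: str) -> bool:
    """True when the acidic condition peaks at a lower ligand concentration."""
    a = argmax.loc[argmax["condition"] == acidic, "argmax_ug_per_ml"]
    n = argmax.loc[argmax["condition"] == neutral, "argmax_ug_per_ml"]
    if a.empty or n.empty:
        raise ValueError("conditions not found in argmax table")
    return max(a.iloc[0]) < min(n.iloc[0])
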